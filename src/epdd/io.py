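"""Curve CSV I/O, bundled reference tables, and synthetic scan generation.

Depth-dose curves travel as two-column CSV with header ``depth_mm,dose_percent``
(comma or tab, ``#`` comment lines skipped).  The package also bundles the
commissioning reference tables of a Varian VitalBeam (five energies 6-18 MeV,
SSD 100 cm, parallel-plate chamber in a 3-D water phantom) transcribed
digit-for-digit:

* ``table1a`` — 12 MeV modeled/standard PDD for cone sides 6-25 cm
* ``table1b`` — modeled/standard PDD for 6-18 MeV at the 10 cm cone
* ``table2``  — fitted N, n, mu per energy
* ``table3``  — beam-quality metrics per energy
* ``table4``  — LSE comparison (slope, mu, S_eq) per energy

Individual scans are addressable as ``fixture:table1b/12MeV/standard`` or
``fixture:table1a/10cone/modeled``.  The 12 MeV 10-cone standard scans of the
two tables disagree in a few printed digits; they are kept verbatim under
their own table identifiers, never merged.
"""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_EVEN
from importlib import resources
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .errors import InputError, ParseError
from .model import DepthDoseCurve, PrimaryTailParams, pdd_model

__all__ = [
    "read_curve",
    "write_curve",
    "load_table",
    "fixture_curve",
    "resolve_curve",
    "synth_scan",
]

_REQUIRED_COLUMNS = ("depth_mm", "dose_percent")
_TABLES = ("table1a", "table1b", "table2", "table3", "table4")


def read_curve(source) -> DepthDoseCurve:
    """Read a depth-dose curve from a CSV path or stream.

    Requires columns ``depth_mm`` and ``dose_percent``; the dialect (comma or
    tab) is auto-detected and ``#`` lines are skipped.  Rows are sorted by
    depth; duplicate depths and non-numeric cells are parse errors naming the
    offending row.
    """
    try:
        df = pd.read_csv(source, sep=None, engine="python", comment="#",
                         skip_blank_lines=True)
    except Exception as exc:
        raise ParseError(f"cannot parse CSV: {exc}") from exc
    df.columns = [str(c).strip() for c in df.columns]
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"missing required column(s): {', '.join(missing)}")
    depths = pd.to_numeric(df["depth_mm"], errors="coerce")
    values = pd.to_numeric(df["dose_percent"], errors="coerce")
    bad = depths.isna() | values.isna()
    if bad.any():
        row = int(df.index[bad][0]) + 2  # 1-based, after the header line
        raise ParseError(f"non-numeric cell at data row {row}")
    dup = depths.duplicated()
    if dup.any():
        raise ParseError(f"duplicate depth {depths[dup].iloc[0]:g} mm")
    order = np.argsort(depths.to_numpy())
    try:
        return DepthDoseCurve(
            depths=depths.to_numpy()[order], values=values.to_numpy()[order]
        )
    except InputError as exc:
        raise ParseError(str(exc)) from exc


def _format_dose(value: float) -> str:
    """Two-decimal dose formatting with round-half-even on the decimal digits."""
    return str(Decimal(repr(float(value))).quantize(Decimal("0.01"), ROUND_HALF_EVEN))


def write_curve(curve: DepthDoseCurve, path) -> None:
    """Write a curve as CSV with fixed 2-decimal doses.

    ``read_curve(write_curve(c)) == c`` whenever the doses carry at most two
    decimals.  The label, if any, is preserved as a leading comment.
    """
    if not isinstance(curve, DepthDoseCurve):
        raise InputError("write_curve expects a DepthDoseCurve")
    lines = []
    if curve.label:
        lines.append(f"# {curve.label}")
    lines.append("depth_mm,dose_percent")
    for d, v in zip(curve.depths, curve.values):
        lines.append(f"{d:g},{_format_dose(v)}")
    text = "\n".join(lines) + "\n"
    if hasattr(path, "write"):
        path.write(text)
    else:
        with open(path, "w", encoding="ascii") as fh:
            fh.write(text)


def load_table(name: str) -> pd.DataFrame:
    """Load one of the bundled reference tables by name (``table1a`` ... ``table4``)."""
    if name not in _TABLES:
        raise InputError(f"unknown table {name!r}; choose from {', '.join(_TABLES)}")
    with resources.files("epdd.data").joinpath(f"{name}.csv").open("r") as fh:
        return pd.read_csv(fh)


def _parse_fixture_key(key: str) -> Tuple[str, float, str]:
    parts = key.split("/")
    if len(parts) != 3:
        raise InputError(
            f"fixture key must look like 'table1b/12MeV/standard', got {key!r}"
        )
    table, selector, kind = parts
    kind = {"modeling": "modeled"}.get(kind, kind)
    if kind not in ("modeled", "standard"):
        raise InputError(f"fixture kind must be 'modeled' or 'standard', got {kind!r}")
    num = selector.lower().removesuffix("mev").removesuffix("cone").rstrip()
    try:
        value = float(num)
    except ValueError:
        raise InputError(f"cannot parse energy/cone selector {selector!r}") from None
    return table, value, kind


def fixture_curve(key: str) -> DepthDoseCurve:
    """Return a bundled scan, e.g. ``table1b/12MeV/standard`` or
    ``table1a/10cone/modeled`` (the ``fixture:`` prefix is accepted)."""
    key = key.removeprefix("fixture:")
    table, value, kind = _parse_fixture_key(key)
    if table == "table1a":
        df = load_table("table1a")
        sub = df[df["cone_cm"] == value]
        label = f"12 MeV, {value:g} cm cone, {kind} (table1a)"
    elif table == "table1b":
        df = load_table("table1b")
        sub = df[df["energy_mev"] == value]
        label = f"{value:g} MeV, 10 cm cone, {kind} (table1b)"
    else:
        raise InputError(f"table {table!r} holds no depth-dose curves")
    if sub.empty:
        raise InputError(f"no fixture matches {key!r}")
    return DepthDoseCurve(
        depths=sub["depth_mm"].to_numpy(dtype=float),
        values=sub[kind].to_numpy(dtype=float),
        label=label,
    )


def resolve_curve(source: str) -> DepthDoseCurve:
    """Dispatch a CLI input: ``fixture:...`` keys load bundled scans, anything
    else is read as a CSV path."""
    if isinstance(source, str) and source.startswith("fixture:"):
        return fixture_curve(source)
    return read_curve(source)


def synth_scan(
    params: PrimaryTailParams,
    grid: Tuple[float, float, float] = (1.0, 80.0, 1.0),
    noise_sd: float = 0.5,
    xray_floor: float = 2.0,
    seed: Optional[int] = None,
) -> DepthDoseCurve:
    """Generate a synthetic water-phantom scan from the primary-tail model.

    The normalized model is evaluated on ``arange(start, stop, step)``
    (inclusive of the stop within half a step), floored at ``xray_floor``
    percent beyond the model's distal crossing of that level (a flat
    bremsstrahlung plateau), and perturbed with additive Gaussian noise of
    standard deviation ``noise_sd`` percentage points from a single generator
    seeded with ``seed`` — identical seeds give identical scans.  Negative
    noisy samples are clipped to zero.
    """
    start, stop, step = grid
    if step <= 0:
        raise InputError(f"grid step must be > 0, got {step}")
    if noise_sd < 0:
        raise InputError(f"noise_sd must be >= 0, got {noise_sd}")
    depths = np.arange(start, stop + step / 2.0, step, dtype=float)
    if depths.size < 2:
        raise InputError("grid is degenerate (fewer than 2 points)")
    values = pdd_model(depths, params, normalize=True).values.copy()
    if xray_floor > 0:
        imax = int(np.argmax(values))
        distal = np.arange(imax, depths.size)
        below = distal[values[distal] < xray_floor]
        if below.size:
            values[below[0]:] = xray_floor
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=values.size)
    values = np.clip(values, 0.0, None)
    return DepthDoseCurve(
        depths=depths, values=values,
        label=f"synthetic scan seed={seed} noise_sd={noise_sd} floor={xray_floor}",
    )
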