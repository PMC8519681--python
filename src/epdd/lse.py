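"""Lateral scatter equilibrium (LSE): minimal square-field side length.

Below a certain cutout size the central-axis PDD of an electron field becomes
field-size dependent (out-scattered electrons are no longer replaced by
in-scatter) and the output drops; above it the PDD is field-size independent.
The minimal square side establishing that equilibrium at all depths is
predicted here from the primary-tail parameters and the mean energy:

    S_eq = (n - N)^0.288 / (E0 / n)^0.0195        [cm]

and compared with the classic energy-only rule S_eq = 1.58 * sqrt(E0) cm.
(The energy-only rule is sometimes typeset without the square root; the
square-root form is the one the tabulated values actually follow.)  The
formula is dimensionless as written; its output is read in cm, the only
interpretation consistent with the tabulated mm values.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np

from .errors import DomainError

__all__ = ["LSEResult", "seq_min_side", "seq_sqrt_rule", "check_lse"]


@dataclass(frozen=True)
class LSEResult:
    """S_eq predictions (mm) and, when a field side was supplied, the verdict.

    ``adequate`` is True when field_side_mm >= s_eq_mm (a field exactly at
    S_eq has just reached equilibrium); ``margin_mm`` is field - S_eq.  When
    the field is inadequate, ``warning`` explains the clinical consequence.
    """

    s_eq_mm: float
    s_eq_sqrt_mm: float
    field_side_mm: Optional[float] = None
    adequate: Optional[bool] = None
    margin_mm: Optional[float] = None
    warning: Optional[str] = None

    def to_dict(self) -> dict:
        return asdict(self)


def seq_min_side(n: float, N: float, e0_mev: float) -> float:
    """Minimal LSE square-field side in cm from the model parameters.

    ``S_eq = (n - N)^0.288 / (E0/n)^0.0195`` with the mean energy E0 in MeV;
    requires n > N > 0 and E0 > 0.  Monotone increasing in n: a more
    spread-out beam needs a larger field for equilibrium.
    """
    if not (N > 0):
        raise DomainError(f"N must be > 0, got {N}")
    if not (n > N):
        raise DomainError(f"need n > N for a real S_eq, got n={n}, N={N}")
    if not (e0_mev > 0):
        raise DomainError(f"mean energy must be > 0 MeV, got {e0_mev}")
    return float((n - N) ** 0.288 / (e0_mev / n) ** 0.0195)


def seq_sqrt_rule(e0_mev: float) -> float:
    """Classic energy-only LSE rule: ``1.58 * sqrt(E0)`` cm, E0 in MeV."""
    if not (e0_mev > 0):
        raise DomainError(f"mean energy must be > 0 MeV, got {e0_mev}")
    return float(1.58 * np.sqrt(e0_mev))


def check_lse(
    n: float,
    N: float,
    e0_mev: float,
    field_side_mm: Optional[float] = None,
) -> LSEResult:
    """Compute both S_eq predictions and judge a cutout side if given."""
    s_eq_mm = seq_min_side(n, N, e0_mev) * 10.0
    s_sqrt_mm = seq_sqrt_rule(e0_mev) * 10.0
    if field_side_mm is None:
        return LSEResult(s_eq_mm=s_eq_mm, s_eq_sqrt_mm=s_sqrt_mm)
    adequate = bool(field_side_mm >= s_eq_mm)
    warning = None
    if not adequate:
        warning = (
            f"field side {field_side_mm:.1f} mm is below the lateral-scatter-"
            f"equilibrium minimum {s_eq_mm:.1f} mm: the PDD and the output "
            "become field-size dependent and the monitor units may need correction"
        )
    return LSEResult(
        s_eq_mm=s_eq_mm,
        s_eq_sqrt_mm=s_sqrt_mm,
        field_side_mm=float(field_side_mm),
        adequate=adequate,
        margin_mm=float(field_side_mm) - s_eq_mm,
        warning=warning,
    )
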