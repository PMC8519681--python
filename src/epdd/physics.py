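"""Energy regressions, empirical stopping power, and reading<->dose conversion.

Across the 6-18 MeV clinical range the primary-tail parameters vary nearly
linearly with the mean surface energy E0:

    n      = 31.667 * E0 - 88
    N      = 0.9975 * E0 - 2.8535
    ln(mu) = -0.1355 * E0 - 6.0986      (mu in mm^-1)

so N and n grow while mu shrinks as the beam hardens.  These published
coefficients are kept as the defaults; :func:`refit_energy_regressions`
recomputes them by ordinary least squares from any parameter table.  (Note
the published N coefficients are not exactly what OLS on the published
parameter table returns — the table fit gives about 1.003/-2.92 — but the
printed pair is retained as the reference default.)

The water-to-air stopping-power ratio used to turn an ionization reading
curve into dose is modeled empirically from N and n:

    SP(depth) = (-0.042 ln N + 1.072) * exp((-n * 5e-5 + 0.0381) * depth)

with depth in cm by default: in cm the ratio stays in a physically plausible
band (~0.98-1.10 over a clinical range), whereas reading the depth as mm
drives it beyond 3, which no water/air collision stopping-power ratio
reaches.  A flag forces the mm reading for strict reproduction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError, InconsistencyWarning, InputError, SingularFitError
from .model import DepthDoseCurve, PrimaryTailParams

__all__ = [
    "EnergyRegressions",
    "StoppingPowerModel",
    "params_from_energy",
    "refit_energy_regressions",
    "stopping_power",
    "convert_reading_dose",
    "slope_mu_relation",
    "refit_slope_mu_relation",
]


@dataclass(frozen=True)
class EnergyRegressions:
    """Linear links between mean energy E0 (MeV) and the model parameters.

    ``n = n_slope*E0 + n_intercept``; likewise for N and for ln(mu).
    Defaults are the published coefficients.
    """

    n_slope: float = 31.667
    n_intercept: float = -88.0
    N_slope: float = 0.9975
    N_intercept: float = -2.8535
    lnmu_slope: float = -0.1355
    lnmu_intercept: float = -6.0986


@dataclass(frozen=True)
class StoppingPowerModel:
    """Coefficients of the empirical water/air stopping-power ratio model."""

    prefactor_log_coeff: float = -0.042
    prefactor_const: float = 1.072
    exponent_n_coeff: float = -5e-5
    exponent_const: float = 0.0381
    depth_unit: str = "cm"


def params_from_energy(
    energy_mev: float, reg: EnergyRegressions | None = None
) -> PrimaryTailParams:
    """Primary-tail parameters predicted from the beam's mean energy (t = 0).

    Valid for roughly 4-25 MeV; a warning is raised outside the 6-18 MeV
    span the regressions were built on, and energies whose predicted N or n
    are non-positive are rejected.
    """
    reg = reg or EnergyRegressions()
    if not (6.0 <= energy_mev <= 18.0):
        warnings.warn(
            f"energy {energy_mev} MeV lies outside the 6-18 MeV span of the "
            "energy regressions; extrapolating",
            stacklevel=2,
        )
    n = reg.n_slope * energy_mev + reg.n_intercept
    N = reg.N_slope * energy_mev + reg.N_intercept
    if n <= 0 or N <= 0:
        raise DomainError(
            f"energy {energy_mev} MeV yields non-positive parameters (N={N:.4g}, n={n:.4g})"
        )
    mu = float(np.exp(reg.lnmu_slope * energy_mev + reg.lnmu_intercept))
    return PrimaryTailParams(N=float(N), n=float(n), mu=mu, t=0.0)


def refit_energy_regressions(param_table) -> EnergyRegressions:
    """Ordinary least squares of n, N and ln(mu) against energy.

    ``param_table`` is a DataFrame (or array of rows) with columns/fields
    energy_mev, N, n, mu_per_mm; at least 3 rows with non-degenerate energies.
    """
    if isinstance(param_table, pd.DataFrame):
        df = param_table
        E = df["energy_mev"].to_numpy(dtype=float)
        N = df["N"].to_numpy(dtype=float)
        n = df["n"].to_numpy(dtype=float)
        mu = df["mu_per_mm"].to_numpy(dtype=float)
    else:
        arr = np.asarray(param_table, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 4:
            raise InputError("parameter table must have rows (energy, N, n, mu)")
        E, N, n, mu = arr.T
    if E.size < 3:
        raise InputError(f"need at least 3 rows to refit, got {E.size}")
    if np.ptp(E) == 0:
        raise SingularFitError("all energies identical; regression is singular")
    if np.any(mu <= 0):
        raise DomainError("mu must be > 0 to take its logarithm")
    n_s, n_i = np.polyfit(E, n, 1)
    N_s, N_i = np.polyfit(E, N, 1)
    m_s, m_i = np.polyfit(E, np.log(mu), 1)
    return EnergyRegressions(
        n_slope=float(n_s), n_intercept=float(n_i),
        N_slope=float(N_s), N_intercept=float(N_i),
        lnmu_slope=float(m_s), lnmu_intercept=float(m_i),
    )


def stopping_power(
    N: float, n: float, depth, model: StoppingPowerModel | None = None
) -> float:
    """Empirical water/air stopping-power ratio at a depth.

    ``depth`` is interpreted in ``model.depth_unit`` (default cm).  The ratio
    grows with depth whenever n < 762 (positive exponent coefficient).
    """
    model = model or StoppingPowerModel()
    if not (N > 0):
        raise DomainError(f"N must be > 0, got {N}")
    if not (n > 0):
        raise DomainError(f"n must be > 0, got {n}")
    depth = np.asarray(depth, dtype=float)
    if np.any(depth < 0):
        raise DomainError("depth must be >= 0")
    pref = model.prefactor_log_coeff * np.log(N) + model.prefactor_const
    out = pref * np.exp((model.exponent_n_coeff * n + model.exponent_const) * depth)
    return out if out.ndim else float(out)


def convert_reading_dose(
    curve: DepthDoseCurve,
    params: PrimaryTailParams,
    direction: str,
    model: StoppingPowerModel | None = None,
) -> DepthDoseCurve:
    """Convert between a percent-reading (ionization) curve and a percent
    depth-dose curve via the stopping-power ratio at each depth.

    ``direction`` is required — "reading_to_dose" multiplies by the ratio,
    "dose_to_reading" divides — and the result is renormalized to max 100.
    The round trip is the identity.
    """
    if direction not in ("reading_to_dose", "dose_to_reading"):
        raise InputError(
            "direction must be 'reading_to_dose' or 'dose_to_reading', "
            f"got {direction!r}"
        )
    model = model or StoppingPowerModel()
    depth = curve.depths / 10.0 if model.depth_unit == "cm" else curve.depths
    sp = np.atleast_1d(stopping_power(params.N, params.n, depth, model))
    if np.any(sp <= 0):
        raise DomainError("stopping power is non-positive at some depth")
    values = curve.values * sp if direction == "reading_to_dose" else curve.values / sp
    peak = np.max(values)
    if peak <= 0:
        raise DomainError("converted curve has no positive values")
    return DepthDoseCurve(
        depths=curve.depths.copy(),
        values=values / peak * 100.0,
        label=f"{curve.label} [{direction}]".strip(),
    )


def slope_mu_relation(mu: float) -> float:
    """Published relation between the attenuation factor and the 80-20% slope
    angle: ``tan^-1(slope) = -6.6729 ln(mu) - 16.623``.

    The relation as printed is dimensionally and numerically inconsistent with
    the measured tan^-1(slope) values it claims to describe (it returns ~34 at
    mu = 5e-4 mm^-1 against a measured -1.35 rad), so every evaluation emits
    :class:`InconsistencyWarning`.  Use :func:`refit_slope_mu_relation` to
    rebuild the line from data.
    """
    if not (mu > 0):
        raise DomainError(f"mu must be > 0, got {mu}")
    warnings.warn(
        "the published slope-mu relation tan^-1(slope) = -6.6729 ln(mu) - 16.623 "
        "is inconsistent with measured slope angles (radian-scale); its output "
        "should not be used quantitatively",
        InconsistencyWarning,
        stacklevel=2,
    )
    return -6.6729 * float(np.log(mu)) - 16.623


def refit_slope_mu_relation(mu_values, atan_slope_values) -> tuple[float, float]:
    """Least-squares (slope, intercept) of tan^-1(slope) against ln(mu)."""
    mu_values = np.asarray(mu_values, dtype=float)
    y = np.asarray(atan_slope_values, dtype=float)
    if mu_values.size < 2 or mu_values.size != y.size:
        raise InputError("need >= 2 matched (mu, atan slope) pairs")
    if np.any(mu_values <= 0):
        raise DomainError("mu must be > 0")
    a, b = np.polyfit(np.log(mu_values), y, 1)
    return float(a), float(b)
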