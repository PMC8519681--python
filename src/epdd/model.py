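"""Primary-tail model of the electron-beam percent depth dose (PDD).

The central-axis PDD of a clinical electron beam is described by the product
of two empirical factors of depth ``x`` (mm of water):

* a *primary* factor ``(x^0.1 / (N + x^0.2)) * exp(-mu*x)`` — a slow build-up
  controlled by the harden factor ``N`` times exponential attenuation ``mu``
  (mm^-1); it vanishes at the surface and rises with depth before the
  exponential takes over;
* a *tail* factor ``1 - x/(sqrt(n) + x^2) + t`` — a shallow dip controlled by
  the spreading factor ``n`` plus a constant offset ``t`` that sets the height
  of the bremsstrahlung (X-ray contamination) tail.

The classic tail grouping above is kept as the default because it is the
published form, but it cannot produce the steep distal falloff of a measured
scan (its dip depth is bounded by ``1/(2 n^0.25)``).  A sigmoid variant

    ``1 - x^p / (n^(p/2) + x^p) + t``

with Hill exponent ``p`` (midpoint at ``x = sqrt(n)``, which empirically lands
on R50) is therefore available for fitting measured curves; select it by
giving :class:`PrimaryTailParams` a ``tail_exponent``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .errors import DomainError, InputError, NormalizationError

__all__ = [
    "PrimaryTailParams",
    "DepthDoseCurve",
    "primary",
    "tail",
    "pdd_model",
]


@dataclass(frozen=True)
class PrimaryTailParams:
    """The four scalars of the primary-tail PDD model.

    Attributes
    ----------
    N : float
        Harden factor, dimensionless, > 0.  Larger ``N`` means a harder
        (higher-energy) beam with a slower build-up.
    n : float
        Spreading factor, dimensionless, > 0.  Grows with beam energy.
    mu : float
        Linear attenuation factor in mm^-1, stored positive and applied as
        ``exp(-mu * x)``.
    t : float
        Tail-height offset, dimensionless, |t| < 1.  Fine-tunes the height of
        the X-ray contamination plateau.
    tail_exponent : float or None
        ``None`` selects the classic tail grouping; a value >= 1 selects the
        sigmoid tail with that Hill exponent.
    """

    N: float
    n: float
    mu: float
    t: float = 0.0
    tail_exponent: Optional[float] = field(default=None)

    def __post_init__(self) -> None:
        if not (self.N > 0):
            raise DomainError(f"harden factor N must be > 0, got {self.N}")
        if not (self.n > 0):
            raise DomainError(f"spreading factor n must be > 0, got {self.n}")
        if not (self.mu >= 0):
            raise DomainError(f"attenuation mu must be >= 0 mm^-1, got {self.mu}")
        if not np.isfinite(self.t) or abs(self.t) >= 1:
            raise DomainError(f"tail offset t must be finite with |t| < 1, got {self.t}")
        if self.tail_exponent is not None and not (self.tail_exponent >= 1):
            raise DomainError(
                f"tail_exponent must be None or >= 1, got {self.tail_exponent}"
            )

    def replace(self, **changes) -> "PrimaryTailParams":
        return replace(self, **changes)


@dataclass(eq=False)
class DepthDoseCurve:
    """A sampled relative-dose-versus-depth scan.

    ``depths`` are strictly increasing physical depths in water (mm, measured
    from the phantom surface, no effective-point shift); ``values`` are the
    relative doses in percent.  ``label`` is free text identifying the beam
    (energy, cone, source table ...).
    """

    depths: np.ndarray
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.depths = np.atleast_1d(np.asarray(self.depths, dtype=float))
        self.values = np.atleast_1d(np.asarray(self.values, dtype=float))
        if self.depths.ndim != 1 or self.values.ndim != 1:
            raise InputError("depths and values must be one-dimensional")
        if self.depths.size == 0:
            raise InputError("a depth-dose curve needs at least one sample")
        if self.depths.size != self.values.size:
            raise InputError(
                f"depths ({self.depths.size}) and values ({self.values.size}) differ in length"
            )
        if not np.all(np.isfinite(self.depths)) or not np.all(np.isfinite(self.values)):
            raise InputError("depths and values must be finite")
        if np.any(self.depths < 0):
            raise InputError("depths must be >= 0 mm")
        if np.any(np.diff(self.depths) <= 0):
            raise InputError("depths must be strictly increasing")
        if np.any(self.values < 0):
            raise InputError("dose values must be >= 0 %")

    def __len__(self) -> int:
        return int(self.depths.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DepthDoseCurve):
            return NotImplemented
        return np.array_equal(self.depths, other.depths) and np.array_equal(
            self.values, other.values
        )

    @property
    def max_value(self) -> float:
        return float(np.max(self.values))

    @property
    def d_max(self) -> float:
        """Depth of the (first) maximum value, mm."""
        return float(self.depths[int(np.argmax(self.values))])


def primary(x, N: float, mu: float):
    """Primary factor ``(x^0.1 / (N + x^0.2)) * exp(-mu*x)``.

    ``x`` is depth in mm (scalar or array, >= 0).  Continuous in ``x`` and
    exactly zero at the surface.
    """
    if not (N > 0):
        raise DomainError(f"harden factor N must be > 0, got {N}")
    if not (mu >= 0):
        raise DomainError(f"attenuation mu must be >= 0, got {mu}")
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise DomainError("depth x must be >= 0 mm")
    out = (x ** 0.1 / (N + x ** 0.2)) * np.exp(-mu * x)
    return out if out.ndim else float(out)


def tail(x, n: float, t: float, exponent: Optional[float] = None):
    """Tail factor of the model.

    Classic grouping (``exponent=None``): ``1 - x/(sqrt(n) + x^2) + t``;
    equals ``1 + t`` at the surface and asymptotically, with a shallow minimum
    at ``x = n^0.25``.

    Sigmoid variant (``exponent=p``): ``1 - x^p/(n^(p/2) + x^p) + t``; a Hill
    step from ``1 + t`` down to ``t`` with midpoint at ``x = sqrt(n)``.
    """
    if not (n > 0):
        raise DomainError(f"spreading factor n must be > 0, got {n}")
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise DomainError("depth x must be >= 0 mm")
    if exponent is None:
        out = 1.0 - x / (np.sqrt(n) + x ** 2) + t
    else:
        if not (exponent >= 1):
            raise DomainError(f"tail exponent must be >= 1, got {exponent}")
        xp = x ** exponent
        out = 1.0 - xp / (n ** (exponent / 2.0) + xp) + t
    return out if out.ndim else float(out)


def pdd_model(
    depths, params: PrimaryTailParams, normalize: bool = True
) -> DepthDoseCurve:
    """Evaluate the primary-tail model on a depth grid.

    Parameters
    ----------
    depths : array-like
        Non-empty, strictly increasing depths in mm, all >= 0.
    params : PrimaryTailParams
    normalize : bool
        When true (default) the curve is rescaled so its maximum over the
        grid equals 100, matching how measured PDD tables are reported.  The
        reference is the grid maximum, not an analytic maximum.

    Returns
    -------
    DepthDoseCurve
    """
    depths = np.atleast_1d(np.asarray(depths, dtype=float))
    if depths.size == 0:
        raise InputError("depth grid is empty")
    if np.any(depths < 0) or np.any(np.diff(depths) <= 0):
        raise InputError("depth grid must be strictly increasing and >= 0")
    raw = primary(depths, params.N, params.mu) * tail(
        depths, params.n, params.t, params.tail_exponent
    )
    raw = np.atleast_1d(raw)
    if normalize:
        peak = np.max(raw)
        if peak <= 0:
            raise NormalizationError(
                "model curve is <= 0 everywhere on the grid; cannot normalize to 100"
            )
        raw = raw / peak * 100.0
    return DepthDoseCurve(depths=depths, values=raw, label="primary-tail model")
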