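"""Clinical beam-quality metrics from an electron depth-dose curve.

Implements the standard descriptors used to commission an electron beam:
R90/R50 (depths of 90% and 50% of maximum on the distal falloff), the 80-20%
falloff slope, the practical range Rp (intersection of the falloff tangent
with the bremsstrahlung background), the X-ray contamination plateau, and the
energy-range relations E0 = 2.33 MeV/cm * R50 (mean energy at the surface)
and the NACP quadratic for the most probable energy.

All crossings are located by linear interpolation between bracketing samples
on the distal limb; no smoothing is applied, since commissioning tables are
typically sampled on coarse (5 mm) grids.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np

from .errors import DomainError, InputError, NotFoundError
from .model import DepthDoseCurve

__all__ = [
    "BeamQuality",
    "depth_at_dose_level",
    "slope_80_20",
    "practical_range",
    "xray_contamination",
    "mean_energy_from_r50",
    "most_probable_energy",
    "quality_report",
]

#: Mean-energy coefficient, MeV per cm of R50.
MEAN_ENERGY_PER_CM = 2.33
#: NACP most-probable-energy coefficients for water: MeV, MeV/cm, MeV/cm^2.
NACP_C1, NACP_C2, NACP_C3 = 0.22, 1.98, 0.0025


@dataclass
class BeamQuality:
    """Beam-quality summary; a field is None when its extraction failed
    (never silently zero).

    Depths in mm, slope in %/mm, energies in MeV.  ``r_max`` is the depth of
    the maximum *reading* and ``d_max`` the depth of maximum *dose*; they
    differ only when an ionization curve is analyzed without conversion, so on
    a single input curve both report its argmax.
    """

    r_max: Optional[float] = None
    d_max: Optional[float] = None
    r90: Optional[float] = None
    r50: Optional[float] = None
    rp: Optional[float] = None
    slope_80_20: Optional[float] = None
    xray_level: Optional[float] = None
    e0_mean: Optional[float] = None

    def to_dict(self) -> dict:
        return asdict(self)


def depth_at_dose_level(curve: DepthDoseCurve, level: float) -> float:
    """Depth (mm) where the distal falloff crosses ``level`` percent of the
    curve maximum; linear interpolation between the bracketing samples.

    level=90 gives R90, level=50 gives R50.
    """
    if not (0 < level < 100):
        raise DomainError(f"level must be in (0, 100) percent of max, got {level}")
    values = curve.values
    threshold = np.max(values) * level / 100.0
    imax = int(np.argmax(values))
    if not (values[imax] > threshold):
        raise NotFoundError("curve maximum does not exceed the requested level")
    for i in range(imax, len(curve) - 1):
        if values[i] >= threshold > values[i + 1]:
            frac = (values[i] - threshold) / (values[i] - values[i + 1])
            return float(curve.depths[i] + frac * (curve.depths[i + 1] - curve.depths[i]))
    raise NotFoundError(
        f"curve never falls below {level}% of maximum on the distal side"
    )


def slope_80_20(curve: DepthDoseCurve) -> float:
    """Slope (%/mm, negative) of the least-squares line through the distal
    falloff between 80% and 20% of maximum.

    The interpolated 80% and 20% crossing points are included alongside every
    sample whose dose lies strictly inside the window on the distal limb.
    """
    d80 = depth_at_dose_level(curve, 80.0)
    d20 = depth_at_dose_level(curve, 20.0)
    peak = np.max(curve.values)
    inside = (curve.depths > d80) & (curve.depths < d20)
    xs = np.concatenate(([d80], curve.depths[inside], [d20]))
    ys = np.concatenate(([0.8 * peak], curve.values[inside], [0.2 * peak]))
    if xs.size < 2:
        raise NotFoundError("fewer than 2 points in the 80-20% window")
    slope, _ = np.polyfit(xs, ys, 1)
    return float(slope)


def xray_contamination(curve: DepthDoseCurve) -> float:
    """Bremsstrahlung plateau estimate: the median dose beyond the distal
    10%-of-max crossing.  The median makes the estimate robust to the
    non-monotone sample scatter typical of the low-dose tail."""
    d10 = depth_at_dose_level(curve, 10.0)
    tail_values = curve.values[curve.depths > d10]
    if tail_values.size == 0:
        raise NotFoundError("no samples beyond the distal 10% crossing")
    return float(np.median(tail_values))


def practical_range(
    curve: DepthDoseCurve, background: Optional[float] = None
) -> float:
    """Practical range Rp (mm): depth where the 80-20% falloff line meets the
    horizontal bremsstrahlung background.

    The 80-20% least-squares line stands in for the inflection tangent; the
    background defaults to :func:`xray_contamination` but may be forced.
    """
    d80 = depth_at_dose_level(curve, 80.0)
    d20 = depth_at_dose_level(curve, 20.0)
    peak = np.max(curve.values)
    inside = (curve.depths > d80) & (curve.depths < d20)
    xs = np.concatenate(([d80], curve.depths[inside], [d20]))
    ys = np.concatenate(([0.8 * peak], curve.values[inside], [0.2 * peak]))
    slope, intercept = np.polyfit(xs, ys, 1)
    if background is None:
        background = xray_contamination(curve)
    if slope >= 0:
        raise NotFoundError("falloff slope is not negative; no practical range")
    return float((background - intercept) / slope)


def mean_energy_from_r50(r50_cm: float) -> float:
    """Mean electron energy at the surface, MeV: E0 = 2.33 MeV/cm * R50(cm)."""
    if not (r50_cm > 0):
        raise DomainError(f"R50 must be > 0 cm, got {r50_cm}")
    return MEAN_ENERGY_PER_CM * r50_cm


def most_probable_energy(rp_cm: float) -> float:
    """Most probable energy at the surface (NACP), MeV:
    (E_p)0 = 0.22 + 1.98*Rp + 0.0025*Rp^2 with Rp in cm (water)."""
    if rp_cm < 0:
        raise DomainError(f"practical range must be >= 0 cm, got {rp_cm}")
    return NACP_C1 + NACP_C2 * rp_cm + NACP_C3 * rp_cm ** 2


def quality_report(curve: DepthDoseCurve) -> BeamQuality:
    """Assemble every beam-quality metric for a curve; metrics whose
    extraction fails are reported as None."""
    if len(curve) < 4:
        raise InputError(f"need at least 4 points for quality extraction, got {len(curve)}")
    q = BeamQuality()
    q.r_max = q.d_max = curve.d_max
    for attr, func in (
        ("r90", lambda c: depth_at_dose_level(c, 90.0)),
        ("r50", lambda c: depth_at_dose_level(c, 50.0)),
        ("slope_80_20", slope_80_20),
        ("xray_level", xray_contamination),
        ("rp", practical_range),
    ):
        try:
            setattr(q, attr, func(curve))
        except (NotFoundError, DomainError):
            pass
    if q.r50 is not None:
        q.e0_mean = mean_energy_from_r50(q.r50 / 10.0)  # mm -> cm
    return q
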