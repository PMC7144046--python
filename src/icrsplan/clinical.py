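"""Clinical bookkeeping: visual acuity, keratometry, success criteria.

Visual acuity is handled in decimal scale with its LogMAR equivalent
(LogMAR = −log10(decimal), rounded half-even to two decimals, the scale on
which "one line" of a chart is 0.1).  Simulated keratometry converts the
anterior surface's per-meridian radius of curvature in the central 3 mm
zone to diopters with the keratometric index 1.3375.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.interpolate import RectBivariateSpline, RegularGridInterpolator

from .segments import SegmentSpec
from .zernike import ElevationMap, RmsGroups, ZernikeCoefficients

__all__ = [
    "VAMeasure",
    "KReadings",
    "CaseRecord",
    "SuccessResult",
    "decimal_to_logmar",
    "logmar_to_decimal",
    "grade_visual_limitation",
    "simulated_keratometry",
    "success_filter",
    "progression_criterion",
]

KERATOMETRIC_INDEX = 1.3375
#: diopters for a radius in mm: K = (n_k - 1) * 1000 / R
_K_NUM = (KERATOMETRIC_INDEX - 1.0) * 1000.0

#: one chart line of acuity on the LogMAR scale.
LOGMAR_LINE = 0.1


def decimal_to_logmar(v: float, decimals: int = 2) -> float:
    """LogMAR equivalent of a decimal acuity, rounded half-even."""
    if v <= 0:
        raise ValueError(f"decimal acuity must be positive, got {v}")
    return round(-math.log10(v), decimals)


def logmar_to_decimal(logmar: float) -> float:
    """Decimal acuity for a LogMAR value (inverse of decimal_to_logmar)."""
    return 10.0 ** (-logmar)


@dataclass(frozen=True)
class VAMeasure:
    """Visual acuity as a decimal value with its LogMAR equivalent."""

    decimal: float
    logmar: float

    def __post_init__(self) -> None:
        if not (0 < self.decimal <= 2):
            raise ValueError(f"decimal acuity {self.decimal} outside (0, 2]")

    @classmethod
    def from_decimal(cls, v: float) -> "VAMeasure":
        return cls(decimal=v, logmar=decimal_to_logmar(v))


def grade_visual_limitation(cdva: float) -> str:
    """Keratoconus visual-limitation grade from corrected acuity.

    I: CDVA >= 0.90; II: >= 0.60; III: >= 0.40; IV: >= 0.20;
    Plus: worse than 0.20.
    """
    if cdva <= 0:
        raise ValueError("cdva must be positive")
    if cdva >= 0.90:
        return "I"
    if cdva >= 0.60:
        return "II"
    if cdva >= 0.40:
        return "III"
    if cdva >= 0.20:
        return "IV"
    return "Plus"


@dataclass(frozen=True)
class KReadings:
    """Simulated keratometry in the central zone (diopters)."""

    k1: float
    k2: float
    mean_simk: float
    zone_mm: float = 3.0
    flat_axis_deg: float | None = None
    steep_axis_deg: float | None = None

    def __post_init__(self) -> None:
        if not (self.k1 <= self.mean_simk + 1e-9 and self.mean_simk <= self.k2 + 1e-9):
            raise ValueError("require k1 <= mean_simk <= k2")


def _circle_radius(s: np.ndarray, z: np.ndarray) -> float:
    """Algebraic (Kåsa) circle fit radius for a meridional profile.

    Profile points (arc position s, height z) in mm; exact for circular
    profiles.  A flat profile returns inf.
    """
    a = np.column_stack([s, z, np.ones_like(s)])
    b = -(s**2 + z**2)
    sol, *_ = np.linalg.lstsq(a, b, rcond=None)
    d, e, f = sol
    r2 = d * d / 4.0 + e * e / 4.0 - f
    if not np.isfinite(r2) or r2 <= 0:
        return math.inf
    return math.sqrt(r2)


def simulated_keratometry(
    emap: ElevationMap,
    zone_mm: float = 3.0,
    n_meridians: int = 180,
    n_samples: int = 41,
) -> KReadings:
    """Per-meridian keratometry of the anterior surface in the central zone.

    Each meridian (1° steps over 180°) is sampled across the full zone
    diameter, a circle is fitted to the height profile, and the power is
    K = 337.5 / R_mm.  K1/K2 are the flattest/steepest meridians and
    mean Sim-K their average.
    """
    s = np.linspace(-zone_mm / 2.0, zone_mm / 2.0, n_samples)
    thetas = np.deg2rad(np.arange(n_meridians) * (180.0 / n_meridians))
    ysamp = np.outer(np.sin(thetas), s).ravel()
    xsamp = np.outer(np.cos(thetas), s).ravel()
    if np.all(np.isfinite(emap.z)):
        # bicubic spline: meridian profiles of a smooth surface need better
        # than bilinear accuracy for the circle fit (K to ~0.01 D)
        spline = RectBivariateSpline(emap.ys, emap.xs, emap.z, kx=3, ky=3)
        zsamp = spline.ev(ysamp, xsamp)
        inb = (
            (xsamp >= emap.xs[0]) & (xsamp <= emap.xs[-1])
            & (ysamp >= emap.ys[0]) & (ysamp <= emap.ys[-1])
        )
        zsamp = np.where(inb, zsamp, np.nan)
    else:
        interp = RegularGridInterpolator(
            (emap.ys, emap.xs), emap.z, bounds_error=False, fill_value=np.nan
        )
        zsamp = interp(np.stack([ysamp, xsamp], axis=1))
    z_mm = (zsamp / 1000.0).reshape(n_meridians, n_samples)
    ks = np.empty(n_meridians)
    for i in range(n_meridians):
        good = np.isfinite(z_mm[i])
        if good.sum() < 10:
            raise ValueError(
                f"insufficient elevation samples in the {zone_mm} mm zone "
                f"along meridian {math.degrees(thetas[i]):.0f}°"
            )
        r = _circle_radius(s[good], z_mm[i][good])
        ks[i] = 0.0 if math.isinf(r) else _K_NUM / r
    i_flat = int(np.argmin(ks))
    i_steep = int(np.argmax(ks))
    k1, k2 = float(ks[i_flat]), float(ks[i_steep])
    return KReadings(
        k1=k1,
        k2=k2,
        mean_simk=(k1 + k2) / 2.0,
        zone_mm=zone_mm,
        flat_axis_deg=float(np.rad2deg(thetas[i_flat])),
        steep_axis_deg=float(np.rad2deg(thetas[i_steep])),
    )


# ---------------------------------------------------------------------------
# case records and the success filter
# ---------------------------------------------------------------------------

@dataclass
class CaseRecord:
    """One treated eye: pre/post coefficients, acuities, refraction, RMS.

    The unit both of the success filter and of surrogate training sets.
    Spherical equivalents are signed diopters; RMS groups are μm at 6 mm.
    """

    preop_coeffs: ZernikeCoefficients
    postop_coeffs: ZernikeCoefficients
    preop_udva: VAMeasure
    postop_udva: VAMeasure
    preop_cdva: VAMeasure
    postop_cdva: VAMeasure
    preop_se: float
    postop_se: float
    preop_rms: RmsGroups
    postop_rms: RmsGroups
    implant: Sequence[SegmentSpec] = field(default_factory=list)
    months_followup: int = 6

    def __post_init__(self) -> None:
        self.implant = list(self.implant)
        if not (1 <= len(self.implant) <= 2):
            raise ValueError("implant must contain 1 or 2 segments")
        if self.months_followup < 0:
            raise ValueError("months_followup must be >= 0")


@dataclass(frozen=True)
class SuccessResult:
    is_success: bool
    improved_va: bool
    reduced_se: bool
    reduced_hoa: bool


_EPS = 1e-9


def success_filter(case: CaseRecord) -> SuccessResult:
    """Postoperative success: any one of three criteria.

    (A) one or more chart lines (0.1 LogMAR) gained in uncorrected or
    corrected acuity; (B) spherical equivalent magnitude reduced by 2 D or
    more; (C) higher-order or coma-like RMS reduced by 1 μm or more.
    """
    for name in (
        "preop_udva", "postop_udva", "preop_cdva", "postop_cdva",
        "preop_se", "postop_se", "preop_rms", "postop_rms",
    ):
        if getattr(case, name, None) is None:
            raise ValueError(f"success_filter: missing field {name!r}")
    improved_va = (
        case.preop_udva.logmar - case.postop_udva.logmar >= LOGMAR_LINE - _EPS
        or case.preop_cdva.logmar - case.postop_cdva.logmar >= LOGMAR_LINE - _EPS
    )
    reduced_se = abs(case.preop_se) - abs(case.postop_se) >= 2.0 - _EPS
    reduced_hoa = (
        case.preop_rms.hoa - case.postop_rms.hoa >= 1.0 - _EPS
        or case.preop_rms.coma_like - case.postop_rms.coma_like >= 1.0 - _EPS
    )
    return SuccessResult(
        is_success=improved_va or reduced_se or reduced_hoa,
        improved_va=improved_va,
        reduced_se=reduced_se,
        reduced_hoa=reduced_hoa,
    )


def progression_criterion(
    prior_k: KReadings,
    prior_astigmatism_d: float,
    current_k: KReadings,
    current_astigmatism_d: float,
) -> bool:
    """Ectasia progression (cross-linking indication).

    True only when the steepest-meridian keratometry increased by at least
    1 D *and* refractive astigmatism increased by at least 1 D.
    """
    return (
        current_k.k2 - prior_k.k2 >= 1.0 - _EPS
        and current_astigmatism_d - prior_astigmatism_d >= 1.0 - _EPS
    )
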