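"""Synthetic keratoconic corneas and a mechanistic ring-segment model.

No clinical elevation data ship with the package, so this module provides
the study population: anterior surfaces built from a biconic (aspheric,
toric) base plus a localized Gaussian cone, and a deterministic closed-form
model of the flattening a ring segment induces.  Cohorts of pre/post case
records drawn from it let the surrogate be trained and the planner be
validated end to end.

The implant effect, in sag convention (posterior-positive heights), adds
two smooth positive fields per segment, each scaled linearly by thickness
and by arc coverage (arc/360):

* a central Gaussian dome that lowers curvature in the keratometry zone
  (the central flattening that lowers Sim-K), and
* a ridge-coupled bump at mid-track radius under a raised-cosine angular
  window around the bisecting line, which cancels part of an anterior cone
  bulge sitting on that side (the coma reduction).

This is a stand-in calibrated to produce surgery-scale changes (a 210°,
300 μm segment lowers mean Sim-K by roughly 2 D), not a biomechanical
claim.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np

from .clinical import CaseRecord, VAMeasure, success_filter
from .optics import corneal_wavefront, strehl_ratio, apply_second_order_toggle
from .segments import (
    DEFAULT_THICKNESSES_UM,
    SEGMENT_ARCS,
    SEGMENT_CATALOG,
    SegmentSpec,
)
from .zernike import (
    ElevationMap,
    ZernikeCoefficients,
    fit_elevation,
    rms_groups,
)

__all__ = [
    "CorneaParams",
    "EffectParams",
    "CohortError",
    "generate_cornea",
    "apply_ring_effect",
    "case_metrics",
    "generate_training_cohort",
    "MechanisticRingOracle",
    "default_param_sampler",
    "SYNTH_REF_RADIUS_MM",
    "PROXY_PUPIL_MM",
]


class CohortError(RuntimeError):
    """Raised when cohort rejection sampling cannot reach its target."""


@dataclass(frozen=True)
class CorneaParams:
    """Parameters of one synthetic anterior corneal surface.

    ``apical_radius_mm`` and ``asphericity_q`` define the conicoid base;
    the cone is a Gaussian bulge of ``cone_amplitude_um`` at
    ``cone_center_mm`` with width ``cone_sigma_mm``; ``astigmatism_d`` adds
    corneal toricity with the steep meridian at ``astig_axis_deg``;
    ``noise_sd_um`` is measurement-like Gaussian height noise.
    """

    apical_radius_mm: float = 7.3
    asphericity_q: float = -0.3
    cone_amplitude_um: float = 50.0
    cone_sigma_mm: float = 1.4
    cone_center_mm: tuple[float, float] = (0.7, -0.7)
    astigmatism_d: float = 2.0
    astig_axis_deg: float = 90.0
    noise_sd_um: float = 0.3
    pupil_center_mm: tuple[float, float] = (0.2, 0.1)
    seed: int = 0
    grid_halfwidth_mm: float = 5.0
    grid_step_mm: float = 0.1

    def __post_init__(self) -> None:
        if not (6.0 <= self.apical_radius_mm <= 9.0):
            raise ValueError("apical_radius_mm must be in [6, 9]")
        if self.cone_amplitude_um < 0:
            raise ValueError("cone_amplitude_um must be >= 0")
        if self.noise_sd_um < 0:
            raise ValueError("noise_sd_um must be >= 0")


#: keratometric diopters <-> curvature (1/mm) conversion constant.
_K_NUM = 337.5


def generate_cornea(p: CorneaParams) -> ElevationMap:
    """Sample the parametric surface on a uniform grid covering >= 8 mm.

    Heights are sag-convention μm (posterior positive).  The cone is
    *subtracted* from the sag — an anterior bulge — which locally steepens
    the surface exactly as a keratoconic cone steepens keratometry.
    Deterministic given ``p.seed``.
    """
    n = int(round(2 * p.grid_halfwidth_mm / p.grid_step_mm)) + 1
    xs = np.linspace(-p.grid_halfwidth_mm, p.grid_halfwidth_mm, n)
    ys = xs.copy()
    x, y = np.meshgrid(xs, ys)

    c_flat = 1.0 / p.apical_radius_mm
    c_steep = c_flat + p.astigmatism_d / _K_NUM
    a = np.deg2rad(p.astig_axis_deg)          # steep meridian direction
    u = x * np.cos(a) + y * np.sin(a)         # along steep meridian
    v = -x * np.sin(a) + y * np.cos(a)
    # biconic sag with shared asphericity Q (mm -> μm)
    num = c_steep * u**2 + c_flat * v**2
    root = 1.0 - (1.0 + p.asphericity_q) * (c_steep**2 * u**2 + c_flat**2 * v**2)
    root = np.clip(root, 1e-6, None)
    z = 1000.0 * num / (1.0 + np.sqrt(root))

    cx, cy = p.cone_center_mm
    d2 = (x - cx) ** 2 + (y - cy) ** 2
    z -= p.cone_amplitude_um * np.exp(-d2 / (2.0 * p.cone_sigma_mm**2))

    if p.noise_sd_um > 0:
        rng = np.random.default_rng(p.seed)
        z = z + rng.normal(0.0, p.noise_sd_um, size=z.shape)

    return ElevationMap(
        xs=xs,
        ys=ys,
        z=z,
        center="corneal_vertex",
        diameter_mm=2 * p.grid_halfwidth_mm,
        landmarks={
            "corneal_vertex": (0.0, 0.0),
            "geometric_center": (0.0, 0.0),
            "pupil_center": tuple(p.pupil_center_mm),
        },
    )


@dataclass(frozen=True)
class EffectParams:
    """Closed-form kernel of the segment-induced elevation change.

    Amplitudes are μm for a 300 μm-thick full-ring-equivalent; both fields
    scale by (thickness/300)·(arc/360).
    """

    central_flattening_um: float = 45.0
    central_sigma_scale: float = 0.8        # sigma = scale * track radius
    cone_attenuation_um: float = 30.0
    ridge_radius_scale: float = 0.35        # lobe radius = scale * track radius
    ridge_width_mm: float = 1.2
    angular_margin_deg: float = 30.0


def _angular_window(theta_deg: np.ndarray, seg: SegmentSpec, margin: float):
    half = seg.arc_deg / 2.0 + margin
    d = np.abs((theta_deg - seg.bisecting_line_deg + 180.0) % 360.0 - 180.0)
    w = 0.5 * (1.0 + np.cos(np.pi * np.clip(d / half, 0.0, 1.0)))
    return w


def apply_ring_effect(
    emap: ElevationMap,
    segments: Sequence[SegmentSpec],
    effect: EffectParams | None = None,
) -> ElevationMap:
    """Deterministic postoperative surface under 1–2 segments."""
    effect = effect or EffectParams()
    segs = list(segments)
    if not (1 <= len(segs) <= 2):
        raise ValueError("apply_ring_effect expects 1 or 2 segments")
    x, y = emap.grid()
    r = np.hypot(x, y)
    theta_deg = np.rad2deg(np.arctan2(y, x)) % 360.0
    dz = np.zeros_like(emap.z)
    for seg in segs:
        scale = (seg.thickness_um / 300.0) * (seg.arc_deg / 360.0)
        rt = seg.track_radius_mm
        sigma_c = effect.central_sigma_scale * rt
        dz += (
            scale
            * effect.central_flattening_um
            * np.exp(-(r**2) / (2.0 * sigma_c**2))
        )
        rm = effect.ridge_radius_scale * rt
        dz += (
            scale
            * effect.cone_attenuation_um
            * np.exp(-((r - rm) ** 2) / (2.0 * effect.ridge_width_mm**2))
            * _angular_window(theta_deg, seg, effect.angular_margin_deg)
        )
    return replace(emap, z=emap.z + dz, landmarks=dict(emap.landmarks))


# ---------------------------------------------------------------------------
# clinical proxies
# ---------------------------------------------------------------------------

#: pupil for the PSF-based acuity proxy (photopic).
PROXY_PUPIL_MM = 4.0
#: emmetropic reference radius of the synthetic population (mm).  The
#: biconic bases are drawn flatter than the textbook 7.8 mm cornea so that
#: the cone carries the keratometric steepening; the spherical-equivalent
#: proxy is referenced to the population's own emmetropic base.
SYNTH_REF_RADIUS_MM = 8.3
#: slope/offset of the documented monotone LogMAR(Strehl) stand-in.
_VA_SLOPE = 0.1
_VA_OFFSET = 0.0
_LOGMAR_MIN, _LOGMAR_MAX = -0.1, 1.5


def _logmar_from_strehl(strehl: float, noise: float = 0.0) -> float:
    lm = _VA_OFFSET - _VA_SLOPE * math.log10(max(strehl, 1e-12)) + noise
    return float(np.clip(lm, _LOGMAR_MIN, _LOGMAR_MAX))


def _va_from_logmar(lm: float) -> VAMeasure:
    dec = float(np.clip(round(10.0 ** (-lm), 2), 0.01, 2.0))
    return VAMeasure.from_decimal(dec)


def case_metrics(
    coeffs8: ZernikeCoefficients,
    va_noise: tuple[float, float] = (0.0, 0.0),
    ref_radius_mm: float = SYNTH_REF_RADIUS_MM,
    psf_grid_n: int = 64,
    psf_pad: int = 2,
) -> dict:
    """Clinical proxies derived from an 8 mm elevation vector.

    Returns spherical equivalent (paraxial relation SE = −4√3 c20 / r² on
    the reference-relative OPD at 6 mm), RMS groups (OPD μm, 6 mm), and
    UDVA/CDVA stand-ins mapped monotonically from the Strehl ratio at a
    4 mm photopic pupil — with and without the second order, respectively.
    """
    opd6 = corneal_wavefront(coeffs8, 6.0, ref_radius_mm=ref_radius_mm)
    se = -4.0 * math.sqrt(3.0) * opd6.get(2, 0) / (3.0**2)
    rms6 = rms_groups(opd6, 6.0)
    opd4 = corneal_wavefront(coeffs8, PROXY_PUPIL_MM, ref_radius_mm=ref_radius_mm)
    s_udva = strehl_ratio(opd4, grid_n=psf_grid_n, pad_factor=psf_pad)
    s_cdva = strehl_ratio(
        apply_second_order_toggle(opd4, include_second_order=False),
        grid_n=psf_grid_n,
        pad_factor=psf_pad,
    )
    return {
        "se": se,
        "rms": rms6,
        "strehl_udva": s_udva,
        "strehl_cdva": s_cdva,
        "udva": _va_from_logmar(_logmar_from_strehl(s_udva, va_noise[0])),
        "cdva": _va_from_logmar(_logmar_from_strehl(s_cdva, va_noise[1])),
    }


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def default_param_sampler(rng: np.random.Generator) -> CorneaParams:
    """One random keratoconic cornea from the default study population.

    Ranges give preoperative mean Sim-K around the upper-40s diopters,
    moderate-to-advanced cones displaced 0.4–1.2 mm from the vertex, and
    with-the-rule-leaning astigmatism of 0.5–3.5 D.
    """
    angle = rng.uniform(0.0, 2.0 * np.pi)
    ecc = rng.uniform(0.4, 1.2)
    return CorneaParams(
        apical_radius_mm=rng.uniform(8.1, 8.8),
        asphericity_q=rng.uniform(-0.6, -0.1),
        cone_amplitude_um=rng.uniform(40.0, 100.0),
        cone_sigma_mm=rng.uniform(1.0, 1.6),
        cone_center_mm=(ecc * math.cos(angle), ecc * math.sin(angle)),
        astigmatism_d=rng.uniform(0.5, 3.5),
        astig_axis_deg=rng.uniform(0.0, 180.0),
        noise_sd_um=0.3,
        pupil_center_mm=(rng.uniform(-0.3, 0.3), rng.uniform(-0.3, 0.3)),
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def _sample_segments(
    rng: np.random.Generator,
    cone_axis_deg: float,
    thicknesses: Sequence[float],
    two_segment_prob: float,
) -> list[SegmentSpec]:
    """Random plausible implant: bisecting line near the cone meridian."""
    def one(axis: float) -> SegmentSpec:
        model, arc = SEGMENT_CATALOG[rng.integers(len(SEGMENT_CATALOG))]
        return SegmentSpec(
            model=model,
            arc_deg=arc,
            thickness_um=float(rng.choice(thicknesses)),
            bisecting_line_deg=float(axis % 360.0),
        )

    # mostly cone-aligned placements, with a deliberately misaligned
    # minority so a surrogate trained on the cohort also sees the penalty
    # of off-axis segments (the planner queries the whole axis circle)
    if rng.random() < 0.25:
        axis = rng.uniform(0.0, 360.0)
    else:
        axis = cone_axis_deg + rng.normal(0.0, 35.0)
    segs = [one(axis)]
    if rng.random() < two_segment_prob:
        partner = one(axis + 180.0 + rng.normal(0.0, 20.0))
        from .segments import arcs_overlap

        if not arcs_overlap(segs[0], partner):
            segs.append(partner)
    return segs


def generate_training_cohort(
    n_target: int = 75,
    seed: int = 0,
    param_sampler: Callable[[np.random.Generator], CorneaParams] | None = None,
    effect: EffectParams | None = None,
    thicknesses: Sequence[float] = DEFAULT_THICKNESSES_UM,
    two_segment_prob: float = 0.35,
    va_noise_sd: float = 0.02,
    max_attempts: int | None = None,
    return_params: bool = False,
):
    """Rejection-sample successful pre/post cases for surrogate training.

    Corneas and implants are drawn at random, the mechanistic ring effect
    is applied, clinical proxies are computed for both time points, and
    only cases passing the success filter are kept until ``n_target`` is
    reached.  Reproducible from ``seed`` alone.
    """
    if n_target < 1:
        raise ValueError("n_target must be >= 1")
    sampler = param_sampler or default_param_sampler
    effect = effect or EffectParams()
    rng = np.random.default_rng(seed)
    max_attempts = max_attempts or max(100, 50 * n_target)
    cases: list[CaseRecord] = []
    kept_params: list[CorneaParams] = []
    attempts = 0
    while len(cases) < n_target:
        if attempts >= max_attempts:
            raise CohortError(
                f"only {len(cases)}/{n_target} successful cases after "
                f"{attempts} attempts; revise the cornea or effect parameters"
            )
        attempts += 1
        params = sampler(rng)
        emap = generate_cornea(params)
        cone_axis = math.degrees(
            math.atan2(params.cone_center_mm[1], params.cone_center_mm[0])
        )
        segs = _sample_segments(rng, cone_axis, thicknesses, two_segment_prob)
        post_map = apply_ring_effect(emap, segs, effect)
        pre_c = fit_elevation(emap, 8.0, 7)
        post_c = fit_elevation(post_map, 8.0, 7)
        pre_m = case_metrics(pre_c, va_noise=tuple(rng.normal(0, va_noise_sd, 2)))
        post_m = case_metrics(post_c, va_noise=tuple(rng.normal(0, va_noise_sd, 2)))
        case = CaseRecord(
            preop_coeffs=pre_c,
            postop_coeffs=post_c,
            preop_udva=pre_m["udva"],
            postop_udva=post_m["udva"],
            preop_cdva=pre_m["cdva"],
            postop_cdva=post_m["cdva"],
            preop_se=pre_m["se"],
            postop_se=post_m["se"],
            preop_rms=pre_m["rms"],
            postop_rms=post_m["rms"],
            implant=segs,
            months_followup=6,
        )
        if success_filter(case).is_success:
            cases.append(case)
            kept_params.append(params)
    if return_params:
        return cases, kept_params
    return cases


class MechanisticRingOracle:
    """Ground-truth predictor: applies the mechanistic effect to a stored
    elevation map and refits, exposing the surrogate's prediction
    interface so the planner can be validated against it."""

    def __init__(self, emap: ElevationMap, effect: EffectParams | None = None):
        self.emap = emap
        self.effect = effect or EffectParams()

    def predict_postop(
        self, preop: ZernikeCoefficients, segments: Sequence[SegmentSpec]
    ) -> ZernikeCoefficients:
        post = apply_ring_effect(self.emap, segments, self.effect)
        return fit_elevation(post, preop.pupil_diameter_mm, preop.max_order)
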