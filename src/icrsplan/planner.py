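"""Exhaustive segment-configuration search scored by Strehl ratio.

Every candidate implant (one segment, or two with non-overlapping arcs,
over the catalog × thickness set × bisecting-line grid) is pushed through
the surrogate, the predicted postoperative elevation is turned into a
corneal wavefront, and its PSF Strehl ratio ranks the candidates.  The
best-scoring configuration is the suggested surgery.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .optics import corneal_wavefront, strehl_batch
from .segments import (
    DEFAULT_THICKNESSES_UM,
    SEGMENT_CATALOG,
    SegmentSpec,
    arcs_overlap,
)
from .surrogate import SurrogateModel, predict_postop, predict_postop_batch
from .zernike import (
    ElevationMap,
    ZernikeCoefficients,
    fit_elevation,
    index_to_nm,
    rescale_pupil,
)

__all__ = [
    "ImplantPlan",
    "PlanResult",
    "enumerate_candidates",
    "recenter_elevation",
    "plan",
]


@dataclass
class ImplantPlan:
    """One scored candidate: segments, predicted outcome, Strehl, rank."""

    segments: tuple[SegmentSpec, ...]
    center: str
    include_second_order: bool
    predicted_postop: ZernikeCoefficients | None
    strehl: float
    rank: int = 0

    def label(self) -> str:
        return " + ".join(s.label() for s in self.segments) or "no implant"


@dataclass
class PlanResult:
    """Ranked plans plus the untreated baseline for reference."""

    plans: list[ImplantPlan]
    baseline_strehl: float
    no_benefit: bool
    n_candidates: int
    options: dict = field(default_factory=dict)

    @property
    def best(self) -> ImplantPlan:
        return self.plans[0]


def enumerate_candidates(
    catalog: Sequence[tuple[str, int]] | None = None,
    thickness_set: Sequence[float] = DEFAULT_THICKNESSES_UM,
    axis_step_deg: int = 15,
    max_segments: int = 2,
) -> list[tuple[SegmentSpec, ...]]:
    """All single segments and all unordered non-overlapping pairs.

    Singles count is |catalog| × |thicknesses| × (360 / axis_step); pairs
    are combinations of singles whose arcs do not overlap on the ring.
    Ordering is deterministic (catalog, thickness, axis; then pair order).
    """
    catalog = list(catalog if catalog is not None else SEGMENT_CATALOG)
    if not catalog:
        raise ValueError("segment catalog is empty")
    if 360 % axis_step_deg != 0:
        raise ValueError(f"axis_step_deg={axis_step_deg} must divide 360")
    if not (1 <= max_segments <= 2):
        raise ValueError("max_segments must be 1 or 2")
    axes = range(0, 360, axis_step_deg)
    singles = [
        SegmentSpec(model, arc, float(t), float(a))
        for (model, arc) in catalog
        for t in thickness_set
        for a in axes
    ]
    candidates: list[tuple[SegmentSpec, ...]] = [(s,) for s in singles]
    if max_segments >= 2:
        for s1, s2 in itertools.combinations(singles, 2):
            if not arcs_overlap(s1, s2):
                candidates.append((s1, s2))
    return candidates


def recenter_elevation(emap: ElevationMap, center: str) -> ElevationMap:
    """Translate the grid so the chosen reference is the aperture origin.

    The surface shape is untouched — only the coordinate origin moves (by
    bilinear resampling onto the same grid); a Zernike refit on the new
    origin redistributes tilt/coma accordingly.
    """
    if center not in emap.landmarks:
        raise ValueError(
            f"center {center!r} not present in map landmarks "
            f"{sorted(emap.landmarks)}"
        )
    dx, dy = emap.landmarks[center]
    if abs(dx) < 1e-12 and abs(dy) < 1e-12 and emap.center == center:
        return replace(emap, landmarks=dict(emap.landmarks))
    interp = RegularGridInterpolator(
        (emap.ys, emap.xs), emap.z, bounds_error=False, fill_value=np.nan
    )
    x, y = emap.grid()
    z = interp(np.stack([(y + dy).ravel(), (x + dx).ravel()], axis=1)).reshape(
        emap.z.shape
    )
    landmarks = {
        name: (lx - dx, ly - dy) for name, (lx, ly) in emap.landmarks.items()
    }
    return replace(emap, z=z, center=center, landmarks=landmarks)


def _predict_many(model, preop: ZernikeCoefficients, candidates):
    if isinstance(model, SurrogateModel):
        return predict_postop_batch(model, preop, candidates)
    if hasattr(model, "predict_batch"):          # e.g. SurrogateEnsemble
        return model.predict_batch(preop, candidates)
    # any object exposing predict_postop (e.g. the mechanistic oracle)
    return np.stack(
        [model.predict_postop(preop, segs).values for segs in candidates]
    )


def _tie_key(segs: tuple[SegmentSpec, ...]) -> tuple:
    return (
        len(segs),
        sum(s.thickness_um for s in segs),
        tuple(s.sort_key() for s in segs),
    )


def plan(
    preop_map: ElevationMap,
    model,
    center: str | None = None,
    include_second_order: bool = True,
    pupil_mm: float = 4.0,
    wavelength_nm: float = 550.0,
    axis_step_deg: int = 15,
    thickness_set: Sequence[float] = DEFAULT_THICKNESSES_UM,
    max_segments: int = 2,
    catalog: Sequence[tuple[str, int]] | None = None,
    top_k: int = 10,
    grid_n: int = 128,
    pad_factor: int = 2,
    delta_n: float = 0.376,
    ref_radius_mm: float = 7.8,
    strehl_tolerance: float = 1e-6,
) -> PlanResult:
    """Rank every candidate implant for a preoperative elevation map.

    Pipeline per candidate: surrogate prediction of the postoperative
    8 mm elevation → rescale to the scoring pupil → reference-relative
    wavefront OPD → optional removal of the second order → PSF → Strehl.
    Plans are sorted by Strehl descending; exact ties break toward fewer
    segments, then lower total thickness, then lexicographic encoding.

    ``model`` is a trained :class:`SurrogateModel` or any object with a
    compatible ``predict_postop`` method.  A "no implant" baseline is
    always scored; ``no_benefit`` flags maps the surgery cannot improve.
    """
    if center is not None:
        preop_map = recenter_elevation(preop_map, center)
    center_label = center or preop_map.center
    preop_c = fit_elevation(preop_map, 8.0, 7)
    candidates = enumerate_candidates(
        catalog=catalog,
        thickness_set=thickness_set,
        axis_step_deg=axis_step_deg,
        max_segments=max_segments,
    )

    try:
        post_matrix = _predict_many(model, preop_c, candidates)
    except Exception as exc:
        raise type(exc)(f"candidate prediction failed: {exc}") from exc

    # elevation (8 mm) -> scoring-pupil OPD, vectorized across candidates
    from .zernike import _rescale_matrix  # exact linear map

    ratio = round(pupil_mm / 8.0, 12)
    M = _rescale_matrix(7, ratio)
    from .optics import _reference_sphere_coeffs

    ref = np.asarray(
        _reference_sphere_coeffs(round(float(ref_radius_mm), 9),
                                 round(float(pupil_mm), 9), 7)
    )
    opd = (post_matrix @ M.T - ref) * delta_n
    baseline_opd = ((M @ preop_c.values) - ref) * delta_n
    all_opd = np.vstack([opd, baseline_opd[None, :]])
    if not include_second_order:
        second = [j for j in range(all_opd.shape[1]) if index_to_nm(j)[0] == 2]
        all_opd[:, second] = 0.0
    strehls = strehl_batch(
        all_opd,
        max_order=7,
        wavelength_nm=wavelength_nm,
        grid_n=grid_n,
        pad_factor=pad_factor,
        drop_piston_tilt=True,
    )
    cand_strehl = strehls[:-1]
    baseline_strehl = float(strehls[-1])

    order = sorted(
        range(len(candidates)),
        key=lambda i: (-cand_strehl[i], _tie_key(candidates[i])),
    )
    plans = []
    for rank, i in enumerate(order[: max(1, top_k)], start=1):
        plans.append(
            ImplantPlan(
                segments=candidates[i],
                center=center_label,
                include_second_order=include_second_order,
                predicted_postop=ZernikeCoefficients(
                    post_matrix[i].copy(), pupil_diameter_mm=8.0, max_order=7
                ),
                strehl=float(cand_strehl[i]),
                rank=rank,
            )
        )
    best_strehl = plans[0].strehl
    return PlanResult(
        plans=plans,
        baseline_strehl=baseline_strehl,
        no_benefit=best_strehl <= baseline_strehl + strehl_tolerance,
        n_candidates=len(candidates),
        options={
            "center": center_label,
            "include_second_order": include_second_order,
            "pupil_mm": pupil_mm,
            "wavelength_nm": wavelength_nm,
            "axis_step_deg": axis_step_deg,
            "thickness_set": list(thickness_set),
            "max_segments": max_segments,
            "grid_n": grid_n,
            "pad_factor": pad_factor,
        },
    )
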