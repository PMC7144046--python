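"""Candidate enumeration, recentering, ranking and oracle equivalence."""

import numpy as np
import pytest

from icrsplan.planner import (
    ImplantPlan,
    enumerate_candidates,
    plan,
    recenter_elevation,
)
from icrsplan.segments import SEGMENT_CATALOG, SegmentSpec, arcs_overlap
from icrsplan.synthetic import (
    CorneaParams,
    MechanisticRingOracle,
    SYNTH_REF_RADIUS_MM,
    generate_cornea,
)
from icrsplan.zernike import fit_elevation, reconstruct


class TestEnumeration:
    def test_singles_count_formula(self):
        for step, thicknesses in [(45, (150, 300)), (90, (200,))]:
            cands = enumerate_candidates(
                thickness_set=thicknesses, axis_step_deg=step, max_segments=1
            )
            assert len(cands) == 8 * len(thicknesses) * (360 // step)

    def test_minimal_grid_has_eight_singles(self):
        cands = enumerate_candidates(
            thickness_set=(200,), axis_step_deg=360, max_segments=1
        )
        assert len(cands) == 8
        assert {c[0].model + "-" + str(c[0].arc_deg) for c in cands} == {
            f"{m}-{a}" for m, a in SEGMENT_CATALOG
        }

    def test_pairs_exclude_overlapping_arcs(self):
        cands = enumerate_candidates(
            thickness_set=(200,), axis_step_deg=90, max_segments=2
        )
        pairs = [c for c in cands if len(c) == 2]
        assert pairs  # some opposite placements must survive
        for s1, s2 in pairs:
            assert not arcs_overlap(s1, s2)
        # two 210° arcs can never coexist (210 + 210 > 360)
        assert not any(
            s1.arc_deg == 210 and s2.arc_deg == 210 for s1, s2 in pairs
        )

    def test_pair_count_matches_brute_force(self):
        import itertools

        cands = enumerate_candidates(
            thickness_set=(200,), axis_step_deg=120, max_segments=2
        )
        singles = [c[0] for c in cands if len(c) == 1]
        expected_pairs = sum(
            1 for a, b in itertools.combinations(singles, 2)
            if not arcs_overlap(a, b)
        )
        assert len(cands) == len(singles) + expected_pairs

    def test_bad_arguments(self):
        with pytest.raises(ValueError, match="divide"):
            enumerate_candidates(axis_step_deg=70)
        with pytest.raises(ValueError, match="empty"):
            enumerate_candidates(catalog=[])


class TestRecenter:
    def test_identity_when_already_centered(self, kc_map):
        out = recenter_elevation(kc_map, "corneal_vertex")
        assert np.array_equal(out.z, kc_map.z)

    def test_round_trip_translation(self, kc_map):
        shifted = recenter_elevation(kc_map, "pupil_center")
        assert shifted.landmarks["pupil_center"] == (0.0, 0.0)
        restored = recenter_elevation(shifted, "corneal_vertex")
        x, y = kc_map.grid()
        core = np.hypot(x, y) <= 3.5
        assert np.nanmax(np.abs(restored.z[core] - kc_map.z[core])) < 0.5

    def test_shape_preserved_under_recentering(self, kc_map):
        """Recentering moves tilt/coma between terms but not the surface."""
        shifted = recenter_elevation(kc_map, "pupil_center")
        dx, dy = kc_map.landmarks["pupil_center"]
        c = fit_elevation(shifted, 8.0, 7)
        x, y = kc_map.grid()
        core = np.hypot(x, y) <= 2.5
        recon = reconstruct(c, x, y)
        # same physical region of the original map, expressed at new origin
        from scipy.interpolate import RegularGridInterpolator

        interp = RegularGridInterpolator((kc_map.ys, kc_map.xs), kc_map.z)
        orig = interp(
            np.stack([(y + dy)[core], (x + dx)[core]], axis=1)
        )
        assert np.nanmean(np.abs(recon[core] - orig)) < 0.6

    def test_unknown_center_rejected(self, kc_map):
        import dataclasses

        bare = dataclasses.replace(kc_map, landmarks={})
        with pytest.raises(ValueError, match="not present"):
            recenter_elevation(bare, "pupil_center")


PLAN_OPTS = dict(
    include_second_order=False,
    pupil_mm=3.0,
    axis_step_deg=90,
    thickness_set=(150, 300),
    max_segments=1,
    grid_n=64,
    pad_factor=2,
    ref_radius_mm=SYNTH_REF_RADIUS_MM,
)


class TestPlan:
    def test_oracle_plan_matches_brute_force_argmax(self, kc_map):
        """Planner with the mechanistic oracle returns the same best as an
        independent exhaustive evaluation of every candidate."""
        from icrsplan.optics import (
            apply_second_order_toggle,
            corneal_wavefront,
            strehl_ratio,
        )
        from icrsplan.synthetic import apply_ring_effect

        oracle = MechanisticRingOracle(kc_map)
        res = plan(kc_map, oracle, top_k=3, **PLAN_OPTS)
        cands = enumerate_candidates(
            thickness_set=(150, 300), axis_step_deg=90, max_segments=1
        )
        best_s, best_segs = -1.0, None
        for segs in cands:
            post = fit_elevation(apply_ring_effect(kc_map, segs), 8.0, 7)
            opd = corneal_wavefront(post, 3.0, ref_radius_mm=SYNTH_REF_RADIUS_MM)
            opd = apply_second_order_toggle(opd, include_second_order=False)
            s = strehl_ratio(opd, grid_n=64, pad_factor=2)
            if s > best_s:
                best_s, best_segs = s, segs
        assert res.best.segments == best_segs
        assert res.best.strehl == pytest.approx(best_s, rel=1e-9)
        assert res.n_candidates == len(cands)

    def test_determinism(self, kc_map, trained_model):
        a = plan(kc_map, trained_model, top_k=5, **PLAN_OPTS)
        b = plan(kc_map, trained_model, top_k=5, **PLAN_OPTS)
        assert [p.segments for p in a.plans] == [p.segments for p in b.plans]
        assert [p.strehl for p in a.plans] == [p.strehl for p in b.plans]

    def test_ranks_are_sequential_and_sorted(self, kc_map, trained_model):
        res = plan(kc_map, trained_model, top_k=8, **PLAN_OPTS)
        assert [p.rank for p in res.plans] == list(range(1, len(res.plans) + 1))
        strehls = [p.strehl for p in res.plans]
        assert strehls == sorted(strehls, reverse=True)

    def test_near_perfect_cornea_flags_no_benefit(self, trained_model):
        emap = generate_cornea(CorneaParams(
            apical_radius_mm=8.3, asphericity_q=0.0, cone_amplitude_um=0.0,
            astigmatism_d=0.0, noise_sd_um=0.0))
        oracle = MechanisticRingOracle(emap)
        res = plan(emap, oracle, top_k=1, **PLAN_OPTS)
        assert res.no_benefit
        assert res.best.strehl <= res.baseline_strehl + 1e-6

    def test_best_of_monotone_in_thickness_set(self, kc_map):
        oracle = MechanisticRingOracle(kc_map)
        small = plan(kc_map, oracle, top_k=1, **{**PLAN_OPTS,
                                                 "thickness_set": (150,)})
        large = plan(kc_map, oracle, top_k=1, **{**PLAN_OPTS,
                                                 "thickness_set": (150, 300)})
        assert large.best.strehl >= small.best.strehl - 1e-12

    def test_tie_break_ordering(self):
        """Exact Strehl ties resolve to fewer segments, then thinner."""
        from icrsplan.planner import _tie_key

        one_thin = (SegmentSpec("SI5", 90, 150, 0.0),)
        one_thick = (SegmentSpec("SI5", 90, 300, 0.0),)
        two = (SegmentSpec("SI5", 90, 150, 0.0), SegmentSpec("SI5", 90, 150, 180.0))
        assert _tie_key(one_thin) < _tie_key(one_thick) < _tie_key(two)
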