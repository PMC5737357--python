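"""Rigid fusion, DSC, mask warping and the deformable registration core."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dirdose as dd
from dirdose.phantom import DeformationSpec, generate_deformed_frame
from dirdose.registration import (
    deformable_register,
    hybrid_config,
    intensity_config,
    replace_applicator_hu,
    surface_voxels,
    warp_mask,
)


class TestReplaceApplicatorHu:
    def test_inside_mask_set_to_air(self, default_case):
        frame = default_case.frames["bt1"]
        out = replace_applicator_hu(frame.ct, frame.structures["applicator"])
        assert np.all(out.values[frame.structures["applicator"]] == -1000.0)

    def test_outside_mask_untouched_and_count_matches(self, default_case):
        frame = default_case.frames["bt1"]
        app = frame.structures["applicator"]
        out = replace_applicator_hu(frame.ct, app)
        changed = out.values != frame.ct.values
        assert np.array_equal(changed, changed & app)
        assert changed.sum() == (frame.ct.values[app] != -1000.0).sum()

    def test_empty_mask_is_noop(self, default_case):
        frame = default_case.frames["bt1"]
        out = replace_applicator_hu(frame.ct, np.zeros(frame.ct.shape, bool))
        assert np.array_equal(out.values, frame.ct.values)

    def test_grid_mismatch_rejected(self, default_case, small_grid):
        frame = default_case.frames["bt1"]
        with pytest.raises(ValueError, match="grid"):
            replace_applicator_hu(frame.ct, np.zeros(small_grid.shape, bool))


class TestDice:
    def test_identical_masks_give_one(self):
        m = np.zeros((6, 6, 6), bool)
        m[2:4, 2:4, 2:4] = True
        assert dd.dice(m, m) == 1.0

    def test_disjoint_masks_give_zero(self):
        a = np.zeros((6, 6, 6), bool)
        b = np.zeros((6, 6, 6), bool)
        a[0], b[5] = True, True
        assert dd.dice(a, b) == 0.0

    def test_half_overlap(self):
        # |A| = |B| = 8, |A ∩ B| = 4 -> 2*4 / 16 = 0.5
        a = np.zeros((4, 4, 4), bool)
        b = np.zeros((4, 4, 4), bool)
        a[0, 0, :4] = True
        a[1, 0, :4] = True
        b[1, 0, :4] = True
        b[2, 0, :4] = True
        assert dd.dice(a, b) == 0.5

    def test_both_empty_rejected(self):
        empty = np.zeros((3, 3, 3), bool)
        with pytest.raises(ValueError, match="empty"):
            dd.dice(empty, empty)

    @settings(deadline=None, max_examples=50)
    @given(seed=st.integers(0, 10_000), p=st.floats(0.05, 0.95))
    def test_symmetric_bounded_and_matches_count_formula(self, seed, p):
        rng = np.random.default_rng(seed)
        a = rng.random((5, 5, 5)) < p
        b = rng.random((5, 5, 5)) < p
        if not (a.any() or b.any()):
            return
        d = dd.dice(a, b)
        assert d == dd.dice(b, a)
        assert 0.0 <= d <= 1.0
        assert d == pytest.approx(
            (a & b).sum() / (((a.sum() + b.sum())) / 2)
        )


class TestWarpMask:
    def test_identity_returns_input(self, small_grid):
        rng = np.random.default_rng(0)
        m = rng.random(small_grid.shape) > 0.5
        out = warp_mask(m, dd.DisplacementField.identity(small_grid))
        assert np.array_equal(out, m)

    def test_one_voxel_translation(self, small_grid):
        m = np.zeros(small_grid.shape, bool)
        m[4:7, 3:6, 2:5] = True
        offsets = np.zeros(small_grid.shape + (3,), np.float32)
        offsets[..., 0] = small_grid.spacing[0]
        out = warp_mask(m, dd.DisplacementField(offsets, small_grid))
        assert np.array_equal(out[:-1], m[1:])

    def test_output_is_binary(self, small_grid):
        rng = np.random.default_rng(1)
        m = rng.random(small_grid.shape) > 0.5
        offsets = rng.normal(0, 1.5, small_grid.shape + (3,)).astype(np.float32)
        out = warp_mask(m, dd.DisplacementField(offsets, small_grid))
        assert out.dtype == bool


class TestRigidRegister:
    def test_self_registration_is_identity(self, coarse_spec):
        _, ss = dd.generate_reference_case(coarse_spec)
        T = dd.rigid_register(ss, ss, "uterus")
        assert np.allclose(T.translation_mm, 0, atol=coarse_spec.spacing[0])
        assert np.allclose(T.rotation_deg, 0, atol=2.0)

    def test_known_translation_recovered(self, coarse_spec):
        _, ss = dd.generate_reference_case(coarse_spec)
        shift = dd.RigidTransform(translation_mm=(5.0, 0.0, 0.0))
        moved = {
            n: dd.apply_rigid(
                dd.ScalarVolume(m.astype(np.float32), ss.grid), shift
            ).values >= 0.5
            for n, m in ss.masks.items()
        }
        moving = dd.StructureSet(moved, ss.grid, validate=False)
        T = dd.rigid_register(moving, ss, "uterus")
        assert T.translation_mm[0] == pytest.approx(-5.0,
                                                    abs=coarse_spec.spacing[0] / 2)

    def test_never_worse_than_identity(self, coarse_spec):
        _, fixed = dd.generate_reference_case(coarse_spec)
        frame = generate_deformed_frame(coarse_spec, DeformationSpec(), "EBRT", 1)
        T = dd.rigid_register(frame.structures, fixed, "uterus")
        moved = dd.apply_rigid(
            dd.ScalarVolume(frame.structures["uterus"].astype(np.float32),
                            frame.structures.grid), T
        ).values >= 0.5
        before = dd.dice(frame.structures["uterus"], fixed["uterus"])
        after = dd.dice(moved, fixed["uterus"])
        assert after >= before

    def test_empty_structure_rejected(self, coarse_spec):
        _, ss = dd.generate_reference_case(coarse_spec)
        empty = ss.copy()
        empty.masks["uterus"] = np.zeros(ss.grid.shape, bool)
        with pytest.raises(ValueError, match="uterus"):
            dd.rigid_register(empty, ss, "uterus")


def _coarse_pair(coarse_spec, kind="EBRT"):
    ref_ct, ref_ss = dd.generate_reference_case(coarse_spec)
    frame = generate_deformed_frame(coarse_spec, DeformationSpec(seed=2), kind, 1)
    fixed_ct = replace_applicator_hu(ref_ct, ref_ss["applicator"])
    rigid = dd.rigid_register(frame.structures, ref_ss, "uterus")
    aligned_ct = dd.apply_rigid(frame.ct, rigid, fill=-1000.0)
    masks = {
        n: dd.apply_rigid(dd.ScalarVolume(m.astype(np.float32), ref_ss.grid),
                          rigid).values >= 0.5
        for n, m in frame.structures.masks.items()
    }
    aligned = dd.StructureSet(masks, ref_ss.grid, validate=False)
    return fixed_ct, ref_ss, aligned_ct, aligned, rigid, frame


# fast DIR settings for the coarse 5 mm phantom
FAST = dict(downsample=(2, 1), iterations=(30, 10))


class TestDeformableRegister:
    def test_self_registration_keeps_zero_field_objective(self, coarse_spec):
        ct, ss = dd.generate_reference_case(coarse_spec)
        ct = replace_applicator_hu(ct, ss["applicator"])
        log = []
        field = deformable_register(ct, ct, ss, ss, hybrid_config(**FAST), log=log)
        for level in log:
            assert level["objective"][-1] <= level["objective"][0] + 1e-12
        for s in ("uterus", "rectum", "bladder"):
            assert dd.dice(warp_mask(ss[s], field), ss[s]) >= 1.0 - 1e-12

    def test_objective_non_increasing_per_level(self, coarse_spec):
        fixed_ct, ref_ss, aligned_ct, aligned, _, _ = _coarse_pair(coarse_spec)
        log = []
        deformable_register(aligned_ct, fixed_ct, aligned, ref_ss,
                            hybrid_config(**FAST), log=log)
        for level in log:
            trace = np.asarray(level["objective"])
            assert np.all(np.diff(trace) <= 1e-12)

    def test_hybrid_improves_mean_dsc_over_rigid(self, coarse_spec):
        fixed_ct, ref_ss, aligned_ct, aligned, _, _ = _coarse_pair(coarse_spec)
        field = deformable_register(aligned_ct, fixed_ct, aligned, ref_ss,
                                    hybrid_config(**FAST))
        organs = ("uterus", "rectum", "bladder")
        before = np.mean([dd.dice(aligned[s], ref_ss[s]) for s in organs])
        after = np.mean([
            dd.dice(warp_mask(aligned[s], field), ref_ss[s]) for s in organs
        ])
        assert after > before

    def test_bit_deterministic(self, coarse_spec):
        fixed_ct, ref_ss, aligned_ct, aligned, _, _ = _coarse_pair(coarse_spec)
        f1 = deformable_register(aligned_ct, fixed_ct, aligned, ref_ss,
                                 hybrid_config(**FAST))
        f2 = deformable_register(aligned_ct, fixed_ct, aligned, ref_ss,
                                 hybrid_config(**FAST))
        assert np.array_equal(f1.offsets, f2.offsets)

    def test_missing_structure_rejected(self, coarse_spec):
        fixed_ct, ref_ss, aligned_ct, aligned, _, _ = _coarse_pair(coarse_spec)
        stripped = dd.StructureSet(
            {n: m for n, m in aligned.masks.items() if n != "rectum"},
            aligned.grid, validate=False,
        )
        with pytest.raises(ValueError, match="rectum"):
            deformable_register(aligned_ct, fixed_ct, stripped, ref_ss,
                                hybrid_config(**FAST))

    def test_intensity_mode_forces_zero_structure_weight(self):
        cfg = intensity_config(w_struct=5.0)
        assert cfg.w_struct == 0.0
        assert cfg.structures == ("body",)


class TestSurfaceVoxels:
    def test_shell_of_solid_box(self):
        m = np.zeros((8, 8, 8), bool)
        m[2:6, 2:6, 2:6] = True
        shell = surface_voxels(m)
        assert shell.sum() == m.sum() - 2 * 2 * 2
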