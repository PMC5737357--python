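"""Synthetic phantom: geometry, ground-truth deformations, dose models."""

from __future__ import annotations

import numpy as np
import pytest

import dirdose as dd
from dirdose.phantom import (
    DeformationSpec,
    dwell_positions,
    generate_deformed_frame,
    map_jacobian_det,
)


class TestReferenceCase:
    def test_same_seed_is_bit_identical(self):
        spec = dd.PhantomSpec(shape=(48, 48, 32), spacing=(5.0, 5.0, 5.0), seed=11)
        ct1, _ = dd.generate_reference_case(spec)
        ct2, _ = dd.generate_reference_case(spec)
        assert np.array_equal(ct1.values, ct2.values)

    def test_organ_masks_disjoint_and_inside_body(self, default_case):
        ss = default_case.frames["bt1"].structures
        assert not np.any(ss["uterus"] & ss["rectum"])
        assert not np.any(ss["uterus"] & ss["bladder"])
        assert not np.any(ss["bladder"] & ss["rectum"])
        for name in ("uterus", "rectum", "bladder", "hrctv", "applicator"):
            assert not np.any(ss[name] & ~ss["body"])

    def test_bladder_volume_matches_analytic_ellipsoid(self, default_case):
        spec = dd.PhantomSpec()
        a, b, c = spec.bladder_semi
        analytic = 4.0 / 3.0 * np.pi * a * b * c / 1000.0
        voxel = default_case.frames["bt1"].structures.volume_cm3("bladder")
        assert voxel == pytest.approx(analytic, rel=0.10)

    def test_applicator_voxels_are_metal_like(self, default_case):
        frame = default_case.frames["bt1"]
        app = frame.structures["applicator"]
        assert frame.ct.values[app].mean() > 1000

    def test_hu_range_respected(self, default_case):
        ct = default_case.frames["bt1"].ct.values
        assert ct.min() >= -1024 and ct.max() <= 3071


class TestDeformedFrames:
    def test_zero_amplitude_is_identity(self, coarse_spec):
        null = DeformationSpec(
            push_mm=0.0, bladder_scales=(1.0,), rectum_scales=(1.0,),
            ebrt_bladder_scale=1.0, ebrt_rectum_scale=1.0,
            scale_jitter_sd=0.0, pose_jitter_mm=0.0, pose_jitter_deg=0.0,
            ebrt_rotation_deg=(0, 0, 0), ebrt_translation_mm=(0, 0, 0),
        )
        frame = generate_deformed_frame(coarse_spec, null, "BT_fraction", 2)
        assert not np.any(frame.gt_field.offsets)
        ref_ct, ref_ss = dd.generate_reference_case(coarse_spec)
        assert np.array_equal(
            frame.structures["bladder"], ref_ss["bladder"]
        )

    def test_filling_scale_grows_bladder(self, coarse_spec):
        spec_def = DeformationSpec(bladder_scales=(1.2,), rectum_scales=(1.0,),
                                   scale_jitter_sd=0.0)
        _, ref_ss = dd.generate_reference_case(coarse_spec)
        frame = generate_deformed_frame(coarse_spec, spec_def, "BT_fraction", 2)
        assert frame.structures["bladder"].sum() > ref_ss["bladder"].sum()

    def test_nonzero_deformation_changes_masks(self, coarse_spec):
        _, ref_ss = dd.generate_reference_case(coarse_spec)
        frame = generate_deformed_frame(coarse_spec, DeformationSpec(), "EBRT", 1)
        assert dd.dice(frame.structures["uterus"], ref_ss["uterus"]) < 1.0

    def test_ebrt_frame_has_no_applicator(self, default_case):
        assert not default_case.frames["ebrt"].structures["applicator"].any()

    @pytest.mark.parametrize("kind,index", [("BT_fraction", 2), ("BT_fraction", 3),
                                            ("BT_fraction", 4), ("EBRT", 1)])
    def test_ground_truth_fields_invertible(self, kind, index):
        frame = generate_deformed_frame(dd.PhantomSpec(), DeformationSpec(seed=3),
                                        kind, index)
        det = map_jacobian_det(frame.gt_field)
        assert det.min() > 0

    def test_excessive_amplitude_rejected(self, coarse_spec):
        wild = DeformationSpec(push_mm=60.0, push_falloff_mm=12.0)
        with pytest.raises(ValueError, match="non-invertible"):
            generate_deformed_frame(coarse_spec, wild, "EBRT", 1)


class TestBtDose:
    def test_inverse_square_ratio(self, default_case):
        frame = default_case.frames["bt1"]
        dwell = np.array([[120.0, 115.0, 70.0]])  # on-grid voxel centre
        dose = dd.simulate_bt_dose(frame, dwell, prescription_gy=6.0)
        near = dose.values[52, 46, 28]  # (130, 115, 70) mm: 10 mm away
        far = dose.values[56, 46, 28]   # (140, 115, 70) mm: 20 mm away
        assert near / far == pytest.approx(4.0, rel=1e-6)

    def test_d90_normalised_to_prescription(self, default_case):
        for label in ("BT1", "BT2", "BT3", "BT4"):
            frame = default_case.plan_frame(label)
            d90 = dd.d90(default_case.doses[label], frame.structures["hrctv"])
            assert d90 == pytest.approx(6.0, abs=1e-6)

    def test_normalisation_absorbs_scale(self, default_case):
        frame = default_case.frames["bt1"]
        dwells = dwell_positions(dd.PhantomSpec())
        d1 = dd.simulate_bt_dose(frame, dwells, prescription_gy=6.0)
        d2 = dd.simulate_bt_dose(frame, dwells, prescription_gy=12.0)
        assert np.allclose(d2.values, 2.0 * d1.values, rtol=1e-6)

    def test_sharp_gradient_isodose_volumes(self, default_case):
        dose = default_case.doses["BT1"].values
        v90 = (dose >= 0.9 * 6.0).sum()
        v30 = (dose >= 0.3 * 6.0).sum()
        assert v30 >= 4 * v90

    def test_empty_hrctv_rejected(self, default_case):
        frame = default_case.frames["bt1"]
        broken = dd.Frame(
            "broken", frame.ct,
            dd.StructureSet(
                {**{n: frame.structures[n] for n in ("body", "applicator")},
                 "hrctv": np.zeros(frame.ct.shape, dtype=bool)},
                frame.ct.grid, validate=False,
            ),
        )
        with pytest.raises(ValueError, match="HR-CTV"):
            dd.simulate_bt_dose(broken, np.array([[120.0, 116.0, 70.0]]))


class TestEbrtDose:
    def test_wp_flat_inside_box(self, default_case):
        wp = default_case.doses["WP"]
        center = wp.values[48, 48, 32]
        assert center == pytest.approx(30.0, rel=0.03)

    def test_wp_zero_far_outside(self, default_case):
        wp = default_case.doses["WP"]
        assert wp.values[0, 0, 0] < 0.01 * 30.0

    def test_penumbra_midpoint_half_dose(self, default_case):
        frame = default_case.frames["ebrt"]
        from dirdose.phantom import _field_box
        box = _field_box(frame)
        grid = default_case.doses["WP"].grid
        mesh = grid.world_mesh()
        # sample the dose profile along x through the box centre
        yc = int(round((box[1][0] + box[1][1]) / 2 / grid.spacing[1]))
        zc = int(round((box[2][0] + box[2][1]) / 2 / grid.spacing[2]))
        xs = mesh[0][:, yc, zc]
        prof = default_case.doses["WP"].values[:, yc, zc]
        mid = np.interp(box[0][0], xs, prof)
        assert mid == pytest.approx(0.5 * 30.0, abs=0.05 * 30.0)

    def test_cs_blocked_on_midline_open_laterally(self, default_case):
        cs = default_case.doses["CS"]
        grid = cs.grid
        ix = lambda x: int(round(x / grid.spacing[0]))
        yc, zc = ix(116.0), 32
        assert cs.values[ix(120.0), yc, zc] == pytest.approx(0.0, abs=1e-6)
        assert cs.values[ix(150.0), yc, zc] == pytest.approx(20.0, rel=0.03)

    def test_cs_block_width_on_dose_grid(self, default_case):
        cs = default_case.doses["CS"]
        grid = cs.grid
        prof = cs.values[:, int(round(116.0 / grid.spacing[1])), 32]
        # contiguous below-50% run inside the field
        inside = np.where(prof > 0.5 * 20.0)[0]
        blocked = np.where(prof < 0.5 * 20.0)[0]
        central = blocked[(blocked > inside.min()) & (blocked < inside.max())]
        width = (central.max() - central.min() + 1) * grid.spacing[0]
        assert width == pytest.approx(40.0, abs=grid.spacing[0])

    def test_block_wider_than_field_rejected(self, default_case):
        frame = default_case.frames["ebrt"]
        with pytest.raises(ValueError, match="wider"):
            dd.simulate_ebrt_cs(frame, 20.0, block_width_mm=500.0)

    def test_cs_zero_in_top_bt_dose_voxels(self, default_case):
        """The midline block fully spares the zone of highest BT dose —
        the premise for excluding CS from DVH parameter addition."""
        bt_sum = sum(default_case.doses[f"BT{i}"].values for i in range(1, 5))
        cs = default_case.doses["CS"].values
        n_top = int(round(2.0 / default_case.doses["CS"].voxel_volume_cm3))
        for organ in ("rectum", "bladder"):
            mask = default_case.frames["bt1"].structures[organ]
            order = np.argsort(bt_sum[mask])[::-1][:n_top]
            cs_at_hotspot = cs[mask][order]
            assert cs_at_hotspot.max() <= 0.02 * 20.0


class TestCaseIO:
    def test_save_load_round_trip(self, tmp_path, coarse_spec):
        case = dd.generate_case(spec=coarse_spec, seed=5)
        dd.save_case(case, tmp_path / "case")
        back = dd.load_case(tmp_path / "case")
        assert set(back.frames) == set(case.frames)
        assert np.array_equal(back.frames["bt2"].ct.values,
                              case.frames["bt2"].ct.values)
        assert np.array_equal(back.frames["bt2"].gt_field.offsets,
                              case.frames["bt2"].gt_field.offsets)
        assert np.array_equal(back.doses["BT1"].values, case.doses["BT1"].values)
        assert back.manifest == case.manifest
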