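"""Regional partition, through-plane flow, peak extraction, kinetic energy."""

import numpy as np
import pytest

from lvflow.core import SegmentationCine, VelocityField4D
from lvflow.flow_metrics import (
    FlowCurveSet,
    kinetic_energy,
    partition_regions,
    peak_flows,
    throughplane_flow,
)


def _stack_seg(n_slices_in_mask, spacing_z=9.0, n_frames=2, sign=1):
    """Mask occupying a contiguous block of short-axis slices."""
    nz = n_slices_in_mask + 4
    mask = np.zeros((6, 6, nz, n_frames), dtype=bool)
    mask[1:5, 1:5, 2 : 2 + n_slices_in_mask, :] = True
    return SegmentationCine(
        mask=mask, spacing=(1.0, 1.0, spacing_z), slice_axis=2, apex_to_base_sign=sign
    )


class TestPartition:
    def test_nine_slices_split_three_three_three(self):
        part = partition_regions(_stack_seg(9))
        counts = {r: len(part.slices(r)) for r in ("apex", "mid", "base")}
        assert counts == {"apex": 3, "mid": 3, "base": 3}
        # apical slices are the low-index end for apex_to_base_sign = +1
        assert set(part.slices("apex")) == {2, 3, 4}
        assert set(part.slices("base")) == {8, 9, 10}

    def test_ten_slices_follow_physical_thirds(self):
        part = partition_regions(_stack_seg(10))
        counts = {r: len(part.slices(r)) for r in ("apex", "mid", "base")}
        # boundaries at exactly 1/3 and 2/3 of the extent round up to mid/base
        assert counts == {"apex": 3, "mid": 3, "base": 4}

    def test_flipped_sign_swaps_apex_and_base(self):
        part = partition_regions(_stack_seg(9, sign=-1))
        assert set(part.slices("base")) == {2, 3, 4}
        assert set(part.slices("apex")) == {8, 9, 10}

    def test_fewer_than_three_slices_rejected(self):
        with pytest.raises(ValueError, match="3 in-mask slices"):
            partition_regions(_stack_seg(2))

    def test_coordinate_labels_extend_beyond_extent(self):
        part = partition_regions(_stack_seg(9))
        assert part.label_coordinate(part.base_mm + 50.0) == "base"
        assert part.label_coordinate(part.apex_mm - 5.0) == "apex"


class TestThroughplaneFlow:
    def test_uniform_velocity_times_area(self, uniform_field):
        """Uniform apex->base velocity: flow = v * in-mask area * 0.06 on every slice
        (the same arithmetic that makes 10 cm/s over 10 cm^2 equal 6 L/min)."""
        field, seg = uniform_field
        mask = np.zeros(seg.mask.shape, dtype=bool)
        mask[:, :, 2:7, :] = True
        seg2 = SegmentationCine(mask=mask, spacing=seg.spacing, slice_axis=2)
        part = partition_regions(seg2)
        curves = throughplane_flow(field, seg2, part)
        area_cm2 = 36 * (1.25 * 1.25) / 100.0
        expected = 10.0 * area_cm2 * 0.06
        np.testing.assert_allclose(curves.slice_flow[2:7, :], expected)

    def test_zero_field_gives_zero_curves(self, uniform_field):
        field, seg = uniform_field
        zero = VelocityField4D(
            vx=np.zeros(field.shape), vy=np.zeros(field.shape), vz=np.zeros(field.shape),
            spacing=field.spacing, rr_interval=1.0,
        )
        mask = np.zeros(seg.mask.shape, dtype=bool)
        mask[1:5, 1:5, 2:7, :] = True
        seg2 = SegmentationCine(mask=mask, spacing=seg.spacing, slice_axis=2)
        part = partition_regions(seg2)
        curves = throughplane_flow(zero, seg2, part)
        assert np.nanmax(np.abs(curves.slice_flow)) == 0.0

    def test_region_curve_is_mean_of_member_slices(self, ellipsoid_small):
        _, field, seg, _ = ellipsoid_small
        part = partition_regions(seg)
        curves = throughplane_flow(field, seg, part)
        for region in ("base", "mid", "apex"):
            members = part.slices(region)
            np.testing.assert_allclose(
                curves.region_flow[region],
                np.nanmean(curves.slice_flow[members, :], axis=0),
            )

    def test_sign_flip_negates_curves_and_swaps_peaks(self, ellipsoid_small):
        _, field, seg, _ = ellipsoid_small
        part = partition_regions(seg)
        flipped = SegmentationCine(
            mask=seg.mask, spacing=seg.spacing, slice_axis=seg.slice_axis,
            apex_to_base_sign=-seg.apex_to_base_sign,
        )
        a = throughplane_flow(field, seg, part)
        b = throughplane_flow(field, flipped, part)
        np.testing.assert_array_equal(b.slice_flow, -a.slice_flow)
        pa, pb = peak_flows(a), peak_flows(b)
        for region in ("base", "mid", "apex"):
            assert pb.peak_systolic[region] == pa.peak_diastolic[region]
            assert pb.peak_diastolic[region] == pa.peak_systolic[region]


class TestPeaks:
    def _curves(self, curve):
        arr = np.asarray(curve, dtype=float)[None, :]
        return FlowCurveSet(
            slice_flow=arr, region_flow={"base": arr[0]}, frame_interval=0.05
        )

    def test_max_positive_and_negative(self):
        peaks = peak_flows(self._curves([2.0, 6.0, -4.0, -1.0]))
        assert peaks.peak_systolic["base"] == 6.0
        assert peaks.peak_diastolic["base"] == 4.0

    def test_constant_zero_curve(self):
        peaks = peak_flows(self._curves([0.0, 0.0, 0.0]))
        assert peaks.peak_systolic["base"] == 0.0
        assert peaks.peak_diastolic["base"] == 0.0

    def test_tie_reports_earliest_frame(self):
        peaks = peak_flows(self._curves([6.0, 6.0]))
        assert peaks.systolic_frame["base"] == 0

    def test_all_nan_curve_rejected(self):
        with pytest.raises(ValueError, match="all-NaN"):
            peak_flows(self._curves([np.nan, np.nan]))


class TestKineticEnergy:
    def test_single_voxel_reference_value(self):
        """One 1.25 mm isotropic voxel at |v| = 100 cm/s carries 1.035 uJ."""
        shape = (3, 3, 3, 2)
        vz = np.zeros(shape)
        mask = np.zeros(shape, dtype=bool)
        vz[1, 1, 1, :] = 100.0
        mask[1, 1, 1, :] = True
        field = VelocityField4D(
            vx=np.zeros(shape), vy=np.zeros(shape), vz=vz,
            spacing=(1.25,) * 3, rr_interval=1.0,
        )
        seg = SegmentationCine(mask=mask, spacing=(1.25,) * 3)
        ke = kinetic_energy(field, seg, edv_ml=1.0)
        assert ke.ke_avg_uj == pytest.approx(1.0352, abs=5e-4)

    def test_uniform_speed_indexes_to_half_rho_v_squared(self, uniform_field):
        """KEi_EDV = 0.5 * rho * v^2 = 5.3 uJ/mL at 10 cm/s when mask volume = EDV."""
        field, seg = uniform_field
        edv = seg.volume_curve_ml()[0]
        ke = kinetic_energy(field, seg, edv)
        assert ke.kei_edv_uj_ml == pytest.approx(5.3, abs=1e-9)

    def test_zero_field_and_sign_invariance(self, uniform_field):
        field, seg = uniform_field
        zero = VelocityField4D(
            vx=np.zeros(field.shape), vy=np.zeros(field.shape), vz=np.zeros(field.shape),
            spacing=field.spacing, rr_interval=1.0,
        )
        assert kinetic_energy(zero, seg, 1.0).ke_avg_uj == 0.0
        neg = VelocityField4D(
            vx=-field.vx, vy=-field.vy, vz=-field.vz,
            spacing=field.spacing, rr_interval=1.0,
        )
        assert kinetic_energy(neg, seg, 10.0).ke_avg_uj == pytest.approx(
            kinetic_energy(field, seg, 10.0).ke_avg_uj
        )

    def test_additive_over_disjoint_voxel_sets(self, uniform_field):
        field, seg = uniform_field
        half_a = seg.mask.copy()
        half_a[3:, ...] = False
        half_b = seg.mask & ~half_a
        seg_a = SegmentationCine(mask=half_a, spacing=seg.spacing)
        seg_b = SegmentationCine(mask=half_b, spacing=seg.spacing)
        total = kinetic_energy(field, seg, 10.0).ke_avg_uj
        parts = (
            kinetic_energy(field, seg_a, 10.0).ke_avg_uj
            + kinetic_energy(field, seg_b, 10.0).ke_avg_uj
        )
        assert parts == pytest.approx(total, rel=1e-12)
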