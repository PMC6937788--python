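"""Pathline integration and flow-compartment classification."""

import numpy as np
import pytest

from lvflow.core import SegmentationCine, VelocityField4D
from lvflow.flow_metrics import partition_regions
from lvflow.pathlines import (
    compartment_fractions,
    integrate_pathline,
    seed_pathlines,
    trace_compartments,
    track_pathlines,
)
from lvflow.phantom import PlugPhantomConfig, make_plug_phantom, plug_truth_fractions


class TestSeeding:
    def test_one_seed_per_ed_voxel(self, plug_default):
        _, _, seg, truth = plug_default
        seeds, volumes = seed_pathlines(seg, truth.ed_frame, density=1.0)
        assert len(seeds) == seg.mask[..., truth.ed_frame].sum()
        assert volumes[0] == pytest.approx(seg.voxel_volume_ml)

    def test_quarter_density_checker_pattern(self, plug_default):
        _, _, seg, truth = plug_default
        full, _ = seed_pathlines(seg, truth.ed_frame, density=1.0)
        quarter, volumes = seed_pathlines(seg, truth.ed_frame, density=0.25)
        # in-plane decimation by 2 along both axes
        assert len(quarter) == pytest.approx(len(full) / 4, rel=0.15)
        assert volumes[0] == pytest.approx(4 * seg.voxel_volume_ml)

    def test_empty_mask_rejected(self):
        mask = np.zeros((4, 4, 4, 2), dtype=bool)
        mask[1, 1, 1, 1] = True  # frame 0 stays empty
        mask[1, 1, 1, 0] = True
        seg = SegmentationCine(mask=mask, spacing=(1.0,) * 3)
        seg.mask[1, 1, 1, 0] = False  # bypass constructor check to hit the seeder
        with pytest.raises(ValueError, match="empty"):
            seed_pathlines(seg, 0)


class TestIntegration:
    def test_zero_field_stays_at_seed(self):
        shape = (6, 6, 6, 3)
        field = VelocityField4D(
            vx=np.zeros(shape), vy=np.zeros(shape), vz=np.zeros(shape),
            spacing=(1.0,) * 3, rr_interval=0.9,
        )
        traj = integrate_pathline(field, [2.5, 2.5, 2.5], 0.0, 0.9, substeps=3)
        np.testing.assert_allclose(traj.positions, np.full((len(traj.times), 3), 2.5))

    def test_constant_field_integrated_exactly(self):
        shape = (6, 6, 30, 4)
        vz = np.full(shape, 10.0)  # cm/s
        field = VelocityField4D(
            vx=np.zeros(shape), vy=np.zeros(shape), vz=vz,
            spacing=(1.0, 1.0, 2.0), rr_interval=1.0,
        )
        traj = integrate_pathline(field, [2.0, 2.0, 4.0], 0.0, 0.1, substeps=5)
        # 10 cm/s for 0.1 s -> 1 cm = 10 mm exactly
        assert traj.positions[-1][2] == pytest.approx(14.0, abs=1e-12)

    def test_rotation_one_period_closes_to_1e4_cm(self, rotation_field):
        field, center = rotation_field
        seed = center + [10.0, 0.0, 0.0]  # r = 1 cm
        traj = integrate_pathline(field, seed, 0.0, 1.0, substeps=10)  # h = 0.01 s
        err_cm = np.linalg.norm(traj.positions[-1] - seed) / 10.0
        assert err_cm < 1e-4

    def test_rk4_fourth_order_convergence(self, rotation_field):
        field, center = rotation_field
        seed = center + [10.0, 0.0, 0.0]
        errs = []
        for substeps in (5, 10):
            traj = integrate_pathline(field, seed, 0.0, 1.0, substeps=substeps)
            errs.append(np.linalg.norm(traj.positions[-1] - seed))
        ratio = errs[0] / errs[1]
        assert 10.0 < ratio < 24.0  # ~16x per step halving

    def test_time_reversal_consistency(self, rotation_field):
        field, center = rotation_field
        seed = center + [8.0, 3.0, 0.0]
        back = integrate_pathline(field, seed, 0.4, 0.0, substeps=10)
        fwd = integrate_pathline(field, back.positions[0], 0.0, 0.4, substeps=10)
        assert np.linalg.norm(fwd.positions[-1] - seed) < 1e-3  # mm

    def test_leaving_grid_freezes_trajectory(self):
        shape = (4, 4, 8, 2)
        vz = np.full(shape, 50.0)
        field = VelocityField4D(
            vx=np.zeros(shape), vy=np.zeros(shape), vz=vz,
            spacing=(1.0,) * 3, rr_interval=1.0,
        )
        traj = integrate_pathline(field, [1.0, 1.0, 6.0], 0.0, 1.0, substeps=4)
        assert traj.positions[-1][2] <= 7.0
        assert np.array_equal(traj.positions[-1], traj.positions[-2])


class TestClassification:
    @pytest.mark.parametrize(
        "din,dout",
        [(8.0, 8.0), (0.0, 0.0), (4.0, 4.0), (6.0, 2.0), (2.0, 6.0)],
    )
    def test_plug_fractions_match_slab_overlap_oracle(self, din, dout):
        cfg = PlugPhantomConfig(d_in_cm=din, d_out_cm=dout)
        field, seg, truth = make_plug_phantom(cfg)
        part = partition_regions(seg, ed_frame=truth.ed_frame)
        fractions, _ = trace_compartments(
            field, seg, part, truth.ed_frame, truth.es_frame, density=1.0, substeps=5
        )
        measured = fractions.as_dict()
        for name, expected in plug_truth_fractions(cfg).items():
            assert measured[name] == pytest.approx(expected, abs=2.0), name
        assert sum(measured.values()) == pytest.approx(100.0, abs=1e-9)

    def test_stagnant_plug_is_all_residual_none_excluded(self):
        cfg = PlugPhantomConfig(d_in_cm=0.0, d_out_cm=0.0)
        field, seg, truth = make_plug_phantom(cfg)
        part = partition_regions(seg, ed_frame=truth.ed_frame)
        fractions, labels = trace_compartments(
            field, seg, part, truth.ed_frame, truth.es_frame, density=1.0, substeps=2
        )
        assert fractions.residual == pytest.approx(100.0)
        assert fractions.excluded == 0.0
        assert set(labels) == {"residual"}

    def test_delayed_seeds_sit_in_exit_slab_beyond_entry_slab(self):
        """With d_out > d_in the slab between them holds delayed-ejection blood."""
        cfg = PlugPhantomConfig(d_in_cm=2.0, d_out_cm=6.0)
        field, seg, truth = make_plug_phantom(cfg)
        part = partition_regions(seg, ed_frame=truth.ed_frame)
        _, labels = trace_compartments(
            field, seg, part, truth.ed_frame, truth.es_frame, density=1.0, substeps=5
        )
        seeds, _ = seed_pathlines(seg, truth.ed_frame, 1.0)
        z = seeds[:, 2]
        top = truth.base_mm
        delayed_band = (z > top - 60.0 + 1.3) & (z < top - 20.0 - 1.3)
        assert np.all(labels[delayed_band] == "delayed")
        direct_band = z > top - 20.0 + 1.3
        assert np.all(labels[direct_band] == "direct")

    def test_wall_crossing_in_apical_region_excluded(self):
        """A lateral drift that pushes blood out through the apical wall is discarded."""
        cfg = PlugPhantomConfig(d_in_cm=0.0, d_out_cm=0.0)
        field, seg, truth = make_plug_phantom(cfg)
        # add outward x-velocity confined to the apical third during systole
        part = partition_regions(seg, ed_frame=truth.ed_frame)
        apex_slices = part.slices("apex")
        field.vx[:, :, apex_slices, :] = 8.0
        fractions, labels = trace_compartments(
            field, seg, part, truth.ed_frame, truth.es_frame, density=1.0, substeps=5
        )
        assert fractions.excluded > 10.0
        # residual fraction of the surviving pathlines is still 100%
        assert fractions.residual == pytest.approx(100.0)


class TestFractions:
    def test_label_proportions(self):
        labels = np.array(
            ["direct"] * 50 + ["retained"] * 25 + ["delayed"] * 15 + ["residual"] * 10
        )
        fr = compartment_fractions(labels)
        assert (fr.direct, fr.retained, fr.delayed, fr.residual) == (50, 25, 15, 10)
        assert fr.excluded == 0.0

    def test_volume_weighting_and_excluded_share(self):
        labels = np.array(["direct", "residual", "excluded", "excluded"])
        volumes = np.array([3.0, 1.0, 1.0, 1.0])
        fr = compartment_fractions(labels, volumes)
        assert fr.direct == pytest.approx(75.0)
        assert fr.residual == pytest.approx(25.0)
        assert fr.excluded == pytest.approx(100.0 * 2.0 / 6.0)

    def test_all_excluded_rejected(self):
        with pytest.raises(ValueError, match="excluded"):
            compartment_fractions(np.array(["excluded", "excluded"]))
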