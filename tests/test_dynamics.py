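import dataclasses
import math

import numpy as np
import pytest

from mitodyn.dynamics import (
    MitoDetection,
    TrackSet,
    detect_mitochondria,
    fit_lognormal,
    link_tracks,
    mito_volume,
    net_displacement,
    regional_volumes,
    track_net_displacements,
)
from mitodyn.regions import REGION_PERINUCLEAR, REGION_PERIPHERAL
from mitodyn.synthetic import Optics, SyntheticCellSpec, generate_cell, render_stack, simulate_tracks


def det(frame, x, y, length=1000.0, width=500.0, region=None):
    return MitoDetection(frame, x, y, length, width, region)


class TestDetect:
    def test_single_rod_dimensions_recovered(self):
        """Rendered 2000x500 nm rod: length within 15%, width within 25%."""
        spec = SyntheticCellSpec(
            image_shape=(256, 256), nucleus_radius=4_000.0, cell_radius=12_000.0,
            n_mito=1, n_frames=2, mito_length_range=(2000.0, 2000.0),
            mito_width_range=(500.0, 500.0), seed=0,
        )
        geo = generate_cell(spec)
        ts, truth = simulate_tracks(spec, geo)
        stack = render_stack(ts, geo, optics=Optics(snr=np.inf),
                             orientations=truth.orientations)
        dets = detect_mitochondria(stack[0], geo.masks)
        assert len(dets) == 1
        assert abs(dets[0].length_nm - 2000.0) / 2000.0 < 0.15
        assert abs(dets[0].width_nm - 500.0) / 500.0 < 0.25

    def test_blank_frame_yields_empty_list(self, small_geometry):
        dets = detect_mitochondria(
            np.zeros(small_geometry.spec.image_shape), small_geometry.masks
        )
        assert dets == []

    def test_two_separated_rods_detected(self):
        spec = SyntheticCellSpec(
            image_shape=(256, 256), nucleus_radius=4_000.0, cell_radius=12_000.0,
            n_mito=2, n_frames=2, seed=4,
        )
        geo = generate_cell(spec)
        ts, truth = simulate_tracks(spec, geo)
        stack = render_stack(ts, geo, optics=Optics(snr=np.inf),
                             orientations=truth.orientations)
        assert len(detect_mitochondria(stack[0], geo.masks)) == 2


class TestLink:
    def test_single_detection_per_frame_yields_one_track(self):
        dets = [det(f, 1000.0 + 10 * f, 2000.0) for f in range(10)]
        ts = link_tracks(dets, max_disp=100.0, n_frames=10)
        assert len(ts.tracks) == 1
        assert len(ts.tracks[0]) == 10

    def test_gate_splits_tracks_on_jumps(self):
        dets = [det(0, 0.0, 0.0), det(1, 50.0, 0.0), det(2, 5000.0, 0.0)]
        ts = link_tracks(dets, max_disp=200.0, n_frames=3)
        assert sorted(len(t) for t in ts.tracks) == [1, 2]

    def test_gap_bridged_with_interpolation(self):
        dets = [det(0, 0.0, 0.0), det(1, 20.0, 0.0), det(3, 60.0, 0.0)]
        ts = link_tracks(dets, max_disp=100.0, n_frames=4)
        assert len(ts.tracks) == 1
        frames = [d.frame_index for d in ts.tracks[0]]
        assert frames == [0, 1, 2, 3]
        assert ts.tracks[0][2].x_nm == pytest.approx(40.0)

    def test_ground_truth_links_recovered_at_low_density(self):
        """Sparse stack: nearly all pipeline links match ground-truth tracks."""
        spec = SyntheticCellSpec(
            image_shape=(384, 384), nucleus_radius=5_000.0,
            cell_radius=18_000.0, n_mito=10, n_frames=12, seed=8,
        )
        geo = generate_cell(spec)
        ts_true, truth = simulate_tracks(spec, geo)
        stack = render_stack(ts_true, geo, orientations=truth.orientations)
        per_frame = [detect_mitochondria(stack[f], geo.masks)
                     for f in range(spec.n_frames)]
        per_frame = [
            [dataclasses.replace(d, frame_index=f) for d in dets]
            for f, dets in enumerate(per_frame)
        ]
        ts = link_tracks(per_frame, max_disp=300.0, n_frames=spec.n_frames)
        good, total = 0, 0
        for t in ts.tracks:
            for a, b in zip(t, t[1:]):
                total += 1
                # a link is correct if both ends sit on the same true track
                da = np.linalg.norm(
                    truth.tracks[:, a.frame_index] - [a.x_nm, a.y_nm], axis=1
                )
                db = np.linalg.norm(
                    truth.tracks[:, b.frame_index] - [b.x_nm, b.y_nm], axis=1
                )
                if da.argmin() == db.argmin():
                    good += 1
        assert total >= 10 * (spec.n_frames - 1) * 0.8
        assert good / total >= 0.95

    def test_track_frame_indices_strictly_increase(self):
        with pytest.raises(ValueError, match="strictly increase"):
            TrackSet([[det(0, 0, 0), det(0, 1, 1)]], 3.0, 2)


class TestNetDisplacement:
    def test_three_four_five(self):
        track = [det(0, 0.0, 0.0), det(1, 30.0, 40.0)]
        assert net_displacement(track) == pytest.approx(50.0)

    def test_single_frame_track_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            net_displacement([det(0, 0.0, 0.0)])

    def test_returning_path_has_zero_net(self):
        track = [det(0, 0.0, 0.0), det(1, 100.0, 0.0), det(2, 0.0, 0.0)]
        assert net_displacement(track) == pytest.approx(0.0)

    def test_invariant_under_rigid_translation(self, rng):
        track = [det(f, *rng.uniform(0, 5000, 2)) for f in range(5)]
        shifted = [
            dataclasses.replace(d, x_nm=d.x_nm + 12_345.0, y_nm=d.y_nm - 777.0)
            for d in track
        ]
        assert net_displacement(shifted) == pytest.approx(net_displacement(track))

    def test_zero_displacement_floored(self):
        ts = TrackSet([[det(0, 10.0, 10.0), det(1, 10.0, 10.0)]], 3.0, 2)
        d, _, _ = track_net_displacements(ts, floor_nm=1.0)
        assert d[0] == 1.0


class TestFitLognormal:
    def test_two_point_geometric_mean(self):
        dist = fit_lognormal([10.0, 100.0, 31.6227766])
        assert dist.geometric_mean == pytest.approx(math.sqrt(1000.0), rel=1e-6)

    def test_constant_sample_has_unit_spread(self):
        dist = fit_lognormal([42.0] * 5)
        assert dist.geometric_mean == pytest.approx(42.0)
        assert dist.geometric_sd == pytest.approx(1.0)

    def test_recovers_parameters_from_large_sample(self, rng):
        d = np.exp(rng.normal(np.log(80.0), np.log(1.5), size=1000))
        dist = fit_lognormal(d)
        assert abs(dist.geometric_mean - 80.0) / 80.0 < 0.05
        assert abs(dist.geometric_sd - 1.5) / 1.5 < 0.05

    def test_summary_recomputable_from_displacements(self, rng):
        d = np.exp(rng.normal(4.0, 0.4, size=50))
        dist = fit_lognormal(d)
        assert dist.geometric_mean == pytest.approx(
            float(np.exp(np.log(dist.displacements).mean()))
        )

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            fit_lognormal([1.0, 0.0, 2.0])

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError, match="n >= 3"):
            fit_lognormal([1.0, 2.0])


class TestVolume:
    def test_sphere_limit(self):
        assert mito_volume(1000.0, 1000.0) == pytest.approx(math.pi / 6, rel=1e-9)

    def test_spherocylinder_hand_value(self):
        # pi*(0.5^2)*(2-1) + (4/3)*pi*0.5^3 = 1.30900 um^3
        assert mito_volume(2000.0, 1000.0) == pytest.approx(1.3089969, rel=1e-6)

    def test_cylinder_alternative(self):
        assert mito_volume(2000.0, 1000.0, model="cylinder") == pytest.approx(
            math.pi * 0.25 * 2.0, rel=1e-9
        )

    def test_invalid_dimensions_rejected(self):
        with pytest.raises(ValueError):
            mito_volume(500.0, 1000.0)
        with pytest.raises(ValueError):
            mito_volume(1000.0, 0.0)

    def test_voxel_counting_oracle(self, rng):
        """Analytic spherocylinder volume within 1% of a 10-nm voxel count."""
        for _ in range(3):
            width = rng.uniform(300.0, 700.0)
            length = width + rng.uniform(0.0, 1500.0)
            analytic = mito_volume(length, width)
            step = 10.0  # nm
            r = width / 2.0
            half_seg = (length - width) / 2.0
            ox, oy, oz = rng.uniform(0.0, step, size=3)
            xs = np.arange(-length / 2 - step, length / 2 + 2 * step, step) + ox
            ys = np.arange(-r - step, r + 2 * step, step)
            X, Y, Z = np.meshgrid(xs, ys + oy, ys + oz, indexing="ij")
            ax = np.clip(X, -half_seg, half_seg)
            inside = (X - ax) ** 2 + Y**2 + Z**2 <= r**2
            voxel = inside.sum() * step**3 / 1e9  # um^3
            assert abs(voxel - analytic) / analytic < 0.01


class TestRegionalVolumes:
    def test_all_perinuclear_gives_unit_fraction(self):
        dets = [det(0, 0, 0, region=REGION_PERINUCLEAR) for _ in range(3)]
        assert regional_volumes(dets).fraction_perinuclear == 1.0

    def test_symmetric_split(self):
        dets = [
            det(0, 0, 0, region=REGION_PERINUCLEAR),
            det(0, 5000, 5000, region=REGION_PERIPHERAL),
        ]
        assert regional_volumes(dets).fraction_perinuclear == pytest.approx(0.5)

    def test_generator_fraction_recovered(self):
        """Seeding fraction 0.3 with equal rod sizes: volume fraction ~ 0.3."""
        spec = SyntheticCellSpec(
            n_mito=200, n_frames=2, perinuclear_fraction=0.3,
            mito_length_range=(1500.0, 1500.0), mito_width_range=(500.0, 500.0),
            seed=21,
        )
        geo = generate_cell(spec)
        ts, truth = simulate_tracks(spec, geo)
        frame0 = [t[0] for t in ts.tracks]
        frac = regional_volumes(frame0).fraction_perinuclear
        assert abs(frac - 0.3) < 0.05

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            regional_volumes([])
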