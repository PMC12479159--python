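import dataclasses

import numpy as np
import pytest

from mitodyn.regions import REGION_PERINUCLEAR
from mitodyn.synthetic import (
    Optics,
    SyntheticCellSpec,
    SyntheticPlateSpec,
    generate_cell,
    render_stack,
    render_tmrm,
    simulate_plate,
    simulate_tracks,
    stack_metadata,
    substream,
)


class TestSpecValidation:
    def test_nucleus_must_be_smaller_than_cell(self):
        with pytest.raises(ValueError, match="nucleus_radius"):
            SyntheticCellSpec(nucleus_radius=16_000.0, cell_radius=15_000.0)

    def test_cell_must_fit_in_frame(self):
        with pytest.raises(ValueError, match="does not fit"):
            SyntheticCellSpec(image_shape=(128, 128), cell_radius=30_000.0)

    def test_forced_disk_geometry(self):
        """5 um nucleus in a 15 um cell at 100 nm/px: 100 px disk in 300 px disk."""
        spec = SyntheticCellSpec(
            image_shape=(512, 512),
            pixel_size=100.0,
            nucleus_radius=5_000.0,
            cell_radius=15_000.0,
        )
        geo = generate_cell(spec)
        # diameter from mask extent along the center row
        row = int(spec.center_px[0])
        nuc_d = geo.nucleus_mask[row].sum()
        cell_d = geo.cell_mask[row].sum()
        assert abs(nuc_d - 100) <= 2
        assert abs(cell_d - 300) <= 2

    def test_plate_spec_background_floor(self):
        with pytest.raises(ValueError, match="background"):
            SyntheticPlateSpec(n_background_wells=2)

    def test_plate_spec_measurement_floor(self):
        with pytest.raises(ValueError, match="measurements_per_stage"):
            SyntheticPlateSpec(measurements_per_stage=0)


class TestGenerateCell:
    def test_deterministic_under_seed(self, small_spec):
        a = generate_cell(small_spec)
        b = generate_cell(small_spec)
        assert np.array_equal(a.nucleus_image, b.nucleus_image)
        assert np.array_equal(a.cell_mask, b.cell_mask)

    def test_nucleus_strictly_inside_cell(self, small_geometry):
        assert np.all(small_geometry.cell_mask[small_geometry.nucleus_mask])
        assert small_geometry.cell_mask.sum() > small_geometry.nucleus_mask.sum()


class TestSimulateTracks:
    def test_sample_geometric_mean_recovers_median(self):
        """n=1000 draws, median 80 nm, spread 1.5: sample gm within 5%."""
        spec = SyntheticCellSpec(
            n_mito=1000, n_frames=2, geo_mean_displacement=80.0, geo_sd=1.5, seed=7
        )
        geo = generate_cell(spec)
        _, truth = simulate_tracks(spec, geo)
        gm = float(np.exp(np.log(truth.net_displacements).mean()))
        assert abs(gm - 80.0) / 80.0 < 0.05

    def test_degenerate_spread_gives_constant_displacement(self, small_spec):
        spec = dataclasses.replace(small_spec, geo_sd=1.0)
        geo = generate_cell(spec)
        _, truth = simulate_tracks(spec, geo)
        assert np.allclose(truth.net_displacements, spec.geo_mean_displacement)

    def test_net_displacement_equals_endpoint_distance(self, small_spec,
                                                       small_geometry):
        _, truth = simulate_tracks(small_spec, small_geometry)
        d = np.linalg.norm(truth.tracks[:, -1] - truth.tracks[:, 0], axis=1)
        assert np.allclose(d, truth.net_displacements)

    def test_full_perinuclear_seeding(self, small_spec):
        spec = dataclasses.replace(small_spec, perinuclear_fraction=1.0)
        geo = generate_cell(spec)
        _, truth = simulate_tracks(spec, geo)
        assert all(lab == REGION_PERINUCLEAR for lab in truth.region_labels)

    def test_tracks_stay_inside_cell(self, small_spec, small_geometry):
        _, truth = simulate_tracks(small_spec, small_geometry)
        px = small_spec.pixel_size
        for i in range(truth.tracks.shape[0]):
            for f in range(truth.tracks.shape[1]):
                r = int(round(truth.tracks[i, f, 1] / px))
                c = int(round(truth.tracks[i, f, 0] / px))
                assert small_geometry.cell_mask[r, c]

    def test_log_displacements_are_normal(self):
        """Normality rejection of log displacements stays near nominal alpha."""
        from scipy.stats import normaltest

        spec = SyntheticCellSpec(n_mito=100, n_frames=2, seed=0)
        geo = generate_cell(spec)
        rejections = 0
        n_rep = 200
        for k in range(n_rep):
            s = dataclasses.replace(spec, seed=k)
            _, truth = simulate_tracks(s, geo)
            if normaltest(np.log(truth.net_displacements)).pvalue < 0.05:
                rejections += 1
        # 95% binomial interval around alpha=0.05 at 200 replicates
        assert rejections / n_rep < 0.10


class TestRenderStack:
    def test_stationary_rod_centroid_is_exact(self):
        """Noiseless render: intensity centroid within 0.5 px of truth."""
        spec = SyntheticCellSpec(
            image_shape=(256, 256),
            nucleus_radius=4_000.0,
            cell_radius=12_000.0,
            n_mito=1,
            n_frames=3,
            geo_sd=1.0,
            geo_mean_displacement=1e-6,
            step_noise_nm=0.0,
            seed=5,
        )
        geo = generate_cell(spec)
        ts, truth = simulate_tracks(spec, geo)
        stack = render_stack(
            ts, geo, optics=Optics(snr=np.inf), orientations=truth.orientations
        )
        px = spec.pixel_size
        for f in range(spec.n_frames):
            frame = stack[f]
            rr, cc = np.mgrid[0 : frame.shape[0], 0 : frame.shape[1]]
            r0 = np.average(rr, weights=frame)
            c0 = np.average(cc, weights=frame)
            assert abs(r0 - truth.tracks[0, f, 1] / px) < 0.5
            assert abs(c0 - truth.tracks[0, f, 0] / px) < 0.5

    def test_noiseless_render_is_deterministic(self, small_spec, small_geometry):
        ts, truth = simulate_tracks(small_spec, small_geometry)
        optics = Optics(snr=np.inf)
        a = render_stack(ts, small_geometry, optics, orientations=truth.orientations)
        b = render_stack(ts, small_geometry, optics, orientations=truth.orientations)
        assert np.array_equal(a, b)

    def test_metadata_reports_five_minute_epoch(self):
        """101 frames at 3 s: the epoch spans 5 minutes."""
        spec = SyntheticCellSpec(n_frames=101, frame_interval=3.0)
        meta = stack_metadata(spec)
        assert meta["epoch_s"] == 300.0
        assert meta["n_frames"] == 101


class TestRenderTmrm:
    def test_regional_mean_intensities_match_construction(self, tmrm_spec,
                                                          tmrm_geometry):
        scene = render_tmrm(
            tmrm_geometry,
            {"perinuclear": 100.0, "peripheral": 50.0},
            background_level=20.0,
            optics=Optics(snr=np.inf),
        )
        img, mask = scene.tmrm_image, scene.mito_mask
        peri = [i for i, lab in enumerate(scene.region_labels)
                if lab == "perinuclear"]
        assert peri  # mito seeded in both regions
        # mito-pixel mean per region ~ background + potential
        m = tmrm_geometry.masks
        peri_px = mask & m.perinuclear_mask
        periph_px = mask & m.peripheral_mask
        assert abs(img[peri_px].mean() - 120.0) < 6.0
        assert abs(img[periph_px].mean() - 70.0) < 6.0
        # non-mito pixels sit at the background level up to blur tails
        bg_px = ~mask & m.peripheral_mask
        assert abs(img[bg_px].mean() - 20.0) < 2.0

    def test_zero_potential_blends_into_background(self, tmrm_geometry):
        scene = render_tmrm(
            tmrm_geometry,
            {"perinuclear": 0.0, "peripheral": 0.0},
            background_level=20.0,
            optics=Optics(snr=np.inf),
        )
        assert np.allclose(scene.tmrm_image, 20.0, atol=1e-4)

    def test_seeds_change_noise_not_expectation(self, tmrm_geometry):
        pot = {"perinuclear": 80.0, "peripheral": 40.0}
        a = render_tmrm(tmrm_geometry, pot, 20.0, seed=1)
        b = render_tmrm(tmrm_geometry, pot, 20.0, seed=2)
        assert not np.array_equal(a.tmrm_image, b.tmrm_image)
        assert np.array_equal(a.positions, b.positions)  # layout from cell seed

    def test_negative_potential_rejected(self, tmrm_geometry):
        with pytest.raises(ValueError, match=">= 0"):
            render_tmrm(tmrm_geometry, {"perinuclear": -1.0, "peripheral": 0.0})


class TestSimulatePlate:
    def test_noiseless_stage_means(self):
        spec = SyntheticPlateSpec(
            baseline_ocr=100.0, leak_fraction=0.2, maximal_factor=2.0,
            nonmito_ocr=10.0, noise_sd=0.0,
        )
        plate, truth = simulate_plate(spec)
        trace = plate.well_trace("C01")
        means = trace.groupby("stage")["ocr"].mean()
        assert means["baseline"] == pytest.approx(110.0)
        assert means["oligomycin"] == pytest.approx(30.0)
        assert means["fccp"] == pytest.approx(210.0)
        assert means["rotenone"] == pytest.approx(10.0)
        assert truth["src"] == pytest.approx(100.0)
        assert truth["atp_linked"] == pytest.approx(80.0)

    def test_reproducible_under_seed(self):
        spec = SyntheticPlateSpec(seed=3)
        a, _ = simulate_plate(spec)
        b, _ = simulate_plate(spec)
        assert a.data.equals(b.data)

    def test_background_wells_are_zero_mean(self):
        plate, _ = simulate_plate(SyntheticPlateSpec(noise_sd=1.0, seed=9))
        bg = plate.data[plate.data["well"].isin(plate.background_wells)]
        assert abs(bg["ocr"].mean()) < 1.0


class TestSubstream:
    def test_streams_are_independent_and_stable(self):
        a = substream(1, "x").normal(size=4)
        b = substream(1, "x").normal(size=4)
        c = substream(1, "y").normal(size=4)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)
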