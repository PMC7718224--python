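"""Lane-analysis pipeline: segmentation, linking, profiles, fits, QC."""

import numpy as np
import pandas as pd
import pytest

from projep import analysis, synth
from projep.stack import ImageStack
from tests.conftest import match_band


def make_stack(voxels, dz=5.0, dxy=2.0, channels=()):
    return ImageStack(
        voxels=voxels, voxel_size_um=(dz, dxy, dxy), channels=list(channels)
    )


class TestSegmentation:
    def test_centroids_within_one_pixel_of_truth(self, clean_single_band):
        params, layout, stack = clean_single_band
        cents = analysis.segment_slices(stack)
        band = layout.bands.iloc[0]
        zi = int(band["z_um"] / stack.voxel_size_um[0])
        at_peak = cents[cents.z_index == zi]
        d = np.hypot(at_peak.x_um - band["x_um"], at_peak.y_um - band["y_um"])
        assert d.min() < params.voxel_dxy_um

    def test_blank_stack_yields_no_centroids(self):
        stack = make_stack(np.zeros((10, 32, 32)))
        assert analysis.segment_slices(stack).empty

    def test_border_touching_object_removed(self):
        vox = np.zeros((4, 64, 64))
        vox[:, :12, :12] = 100.0  # bright blob in the image corner
        cents = analysis.segment_slices(
            make_stack(vox), threshold=10.0, smooth_sigma_px=0.0
        )
        assert cents.empty

    def test_empty_stack_raises(self):
        with pytest.raises(ValueError):
            analysis.segment_slices(make_stack(np.zeros((0, 4, 4))))


class TestLinking:
    @staticmethod
    def grid_centroids(n=3, pitch=100.0, n_z=20, jitter=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for zi in range(n_z):
            for i in range(n):
                for j in range(n):
                    rows.append(
                        {
                            "z_index": zi,
                            "x_um": 50 + i * pitch + rng.normal(0, jitter),
                            "y_um": 50 + j * pitch + rng.normal(0, jitter),
                        }
                    )
        return pd.DataFrame(rows)

    def test_grid_fully_tracked_with_correct_assignment(self):
        cents = self.grid_centroids(jitter=1.0)
        tracks = analysis.link_lanes(cents, n_slices=20)
        assert len(tracks) == 9
        anchors = sorted(
            (round(t.anchor_x_um, -1), round(t.anchor_y_um, -1)) for t in tracks
        )
        want = sorted((50 + 100 * i, 50 + 100 * j) for i in range(3) for j in range(3))
        assert anchors == [(float(a), float(b)) for a, b in want]
        assert all(len(t.slices) == 20 for t in tracks)
        assert not any(t.ambiguous for t in tracks)

    def test_single_slice_rejected(self):
        cents = self.grid_centroids(n_z=1)
        with pytest.raises(ValueError):
            analysis.link_lanes(cents, n_slices=10)

    def test_crossing_drift_flagged_ambiguous(self):
        # two lanes drifting through each other within the linking gate
        rows = []
        for zi in range(20):
            rows.append({"z_index": zi, "x_um": 100 + zi * 1.0, "y_um": 50.0})
            rows.append({"z_index": zi, "x_um": 110 - zi * 1.0, "y_um": 50.0})
        tracks = analysis.link_lanes(
            pd.DataFrame(rows), n_slices=20, merge_radius_um=2.0
        )
        assert any(t.ambiguous for t in tracks)

    def test_short_blip_tracks_removed(self):
        cents = self.grid_centroids(n=1, n_z=20)
        blip = pd.DataFrame(
            [{"z_index": 5, "x_um": 400.0, "y_um": 400.0}]
        )
        tracks = analysis.link_lanes(
            pd.concat([cents, blip], ignore_index=True), n_slices=20
        )
        assert len(tracks) == 1


class TestProfiles:
    def make_gaussian_stack(self, amount=1e5, mu=150.0, sigma=25.0, offset=0.0):
        nz, nxy, dz, dxy = 60, 100, 5.0, 2.0
        z = (np.arange(nz) + 0.5) * dz
        c = (np.arange(nxy) + 0.5) * dxy
        gz = np.exp(-0.5 * ((z - mu) / sigma) ** 2) / (sigma * np.sqrt(2 * np.pi))
        gx = np.exp(-0.5 * ((c - 100.0) / 15.0) ** 2) / (15.0 * np.sqrt(2 * np.pi))
        vox = amount * gz[:, None, None] * gx[None, :, None] * gx[None, None, :]
        vox *= dz * dxy * dxy
        return make_stack(vox + offset, dz=dz, dxy=dxy)

    @staticmethod
    def center_track(nz=60):
        sl = pd.DataFrame(
            {"z_index": [0, nz - 1], "x_um": [100.0, 100.0], "y_um": [100.0, 100.0]}
        )
        return analysis.LaneTrack(0, 100.0, 100.0, sl, span_fraction=1.0)

    def test_profile_integral_conserves_band_amount(self):
        stack = self.make_gaussian_stack(offset=3.0)
        prof = analysis.extract_profile(stack, self.center_track(), roi_side_um=150.0)
        auc = prof.intensity.sum()  # per-slice sums; dz implicit
        assert auc == pytest.approx(1e5, rel=0.02)

    def test_zero_stack_zero_profile(self):
        stack = make_stack(np.zeros((20, 64, 64)))
        track = analysis.LaneTrack(
            0, 64.0, 64.0,
            pd.DataFrame({"z_index": [0, 19], "x_um": [64.0] * 2, "y_um": [64.0] * 2}),
            span_fraction=1.0,
        )
        prof = analysis.extract_profile(stack, track)
        assert np.allclose(prof.intensity, 0.0)

    def test_constant_offset_invariance(self):
        base = self.make_gaussian_stack(offset=0.0)
        shifted = self.make_gaussian_stack(offset=7.5)
        track = self.center_track()
        p0 = analysis.extract_profile(base, track)
        p1 = analysis.extract_profile(shifted, track)
        assert np.allclose(p0.intensity, p1.intensity, atol=1e-6 * p0.intensity.max())

    def test_roi_fully_outside_rejected(self):
        stack = make_stack(np.ones((10, 32, 32)))
        track = analysis.LaneTrack(
            0, 1e5, 1e5,
            pd.DataFrame({"z_index": [0, 9], "x_um": [1e5] * 2, "y_um": [1e5] * 2}),
            span_fraction=1.0,
        )
        with pytest.raises(ValueError):
            analysis.extract_profile(stack, track)


class TestPeakFit:
    @staticmethod
    def profile(mu=346.0, sigma=30.0, amp=1000.0, noise=None, nz=120):
        z = (np.arange(nz) + 0.5) * 5.0
        y = amp * np.exp(-0.5 * ((z - mu) / sigma) ** 2)
        noise_trace = np.zeros(nz) if noise is None else noise
        return analysis.ZProfile(
            z_um=z, intensity=y, noise=noise_trace, roi_side_um=102.0,
            background_per_z=np.zeros(nz),
        )

    def test_exact_gaussian_recovered(self):
        fit = analysis.fit_peak(self.profile())
        assert fit.mu_um == pytest.approx(346.0, abs=1e-6)
        assert fit.sigma_um == pytest.approx(30.0, abs=1e-6)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.qc_pass

    def test_r_squared_threshold_is_strict(self):
        rng = np.random.default_rng(0)
        prof = self.profile()
        prof.intensity = prof.intensity + rng.normal(0, 150.0, prof.z_um.size)
        fit = analysis.fit_peak(prof)
        assert 0 < fit.r_squared < 1
        refit = analysis.fit_peak(prof, r2_threshold=fit.r_squared)
        assert not refit.qc_pass
        assert refit.reason == "low_r2"

    def test_snr_threshold_is_strict(self):
        rng = np.random.default_rng(1)
        noise = rng.normal(0, 40.0, 120)
        fit = analysis.fit_peak(self.profile(noise=noise))
        assert np.isfinite(fit.snr)
        refit = analysis.fit_peak(self.profile(noise=noise), snr_threshold=fit.snr)
        assert not refit.qc_pass
        assert refit.reason == "low_snr"

    def test_snr_definition_amplitude_over_twice_noise_sd(self):
        rng = np.random.default_rng(2)
        noise = rng.normal(0, 40.0, 120)
        fit = analysis.fit_peak(self.profile(noise=noise))
        sel = (np.arange(120) + 0.5) * 5.0
        sel = (sel >= fit.mu_um - 2 * fit.sigma_um) & (
            sel <= fit.mu_um + 2 * fit.sigma_um
        )
        assert fit.snr == pytest.approx(fit.amplitude / (2 * noise[sel].std()))

    def test_raising_snr_threshold_never_passes_more(self, default_stack):
        records_low, _ = analysis.analyze_stack(default_stack, snr_threshold=1.0)
        records_high, _ = analysis.analyze_stack(default_stack, snr_threshold=10.0)
        assert records_high["qc_pass"].sum() <= records_low["qc_pass"].sum()

    def test_no_signal_fails_without_exception(self):
        prof = self.profile(amp=0.0)
        fit = analysis.fit_peak(prof)
        assert not fit.qc_pass
        assert fit.reason == "no_signal"

    def test_window_too_small_raises(self):
        with pytest.raises(ValueError):
            analysis.fit_peak(self.profile(), window_um=(0.0, 10.0))


class TestXYWidth:
    def make_band_stack(self, sx, sy, mu_z=150.0):
        nz, nxy, dz, dxy = 60, 128, 5.0, 2.0
        z = (np.arange(nz) + 0.5) * dz
        c = (np.arange(nxy) + 0.5) * dxy
        gz = np.exp(-0.5 * ((z - mu_z) / 25.0) ** 2)
        gy = np.exp(-0.5 * ((c - 128.0) / sy) ** 2)
        gx = np.exp(-0.5 * ((c - 128.0) / sx) ** 2)
        vox = 100.0 * gz[:, None, None] * gy[None, :, None] * gx[None, None, :]
        stack = make_stack(vox, dz=dz, dxy=dxy)
        track = analysis.LaneTrack(
            0, 128.0, 128.0,
            pd.DataFrame({"z_index": [0, nz - 1], "x_um": [128.0] * 2,
                          "y_um": [128.0] * 2}),
            span_fraction=1.0,
        )
        return stack, track

    def test_isotropic_width_recovered(self):
        stack, track = self.make_band_stack(30.0, 30.0)
        xy = analysis.fit_xy_width(stack, track, roi_side_um=200.0)
        assert xy.sigma_xy_um == pytest.approx(30.0, abs=1.0)

    def test_anisotropic_width_mean_and_ratio(self):
        stack, track = self.make_band_stack(20.0, 40.0)
        xy = analysis.fit_xy_width(stack, track, roi_side_um=220.0)
        assert xy.sigma_xy_um == pytest.approx(30.0, abs=1.5)
        assert xy.anisotropy == pytest.approx(2.0, rel=0.1)

    def test_peak_slice_located_automatically(self):
        stack, track = self.make_band_stack(25.0, 25.0, mu_z=200.0)
        xy = analysis.fit_xy_width(stack, track, roi_side_um=200.0)
        assert xy.z_index == pytest.approx(200.0 / 5.0 - 0.5, abs=1)


class TestGelSummary:
    def test_uniform_gel_low_migration_cv(self):
        p = synth.SynthesisParams(
            seed=6, wells_per_side=3, occupancy_p=1.0, doublet_p=0.0,
            abundance_cv=0.0, field_tilt=0.0,
        )
        stack = synth.render_stack(synth.make_layout(p), p)
        records, _ = analysis.analyze_stack(stack)
        summary = analysis.summarize_gel(records)
        for ch in summary["channels"].values():
            assert ch["migration_cv"] < 0.01

    def test_field_tilt_produces_matching_migration_cv(self):
        """A linear E-field tilt of fraction f across x gives CV = f/sqrt(12)."""
        tilt = 0.30
        p = synth.SynthesisParams(
            seed=6, wells_per_side=4, occupancy_p=1.0, doublet_p=0.0,
            abundance_cv=0.0, field_tilt=tilt,
        )
        stack = synth.render_stack(synth.make_layout(p), p)
        records, _ = analysis.analyze_stack(stack)
        summary = analysis.summarize_gel(records)
        got = summary["channels"]["ch_gapdh"]["migration_cv"]
        # uniform well positions spanning +-tilt/2 modulation
        assert got == pytest.approx(tilt / np.sqrt(12.0), rel=0.25)

    def test_channel_pair_migration_gap(self, default_records, default_layout):
        records, _ = default_records
        summary = analysis.summarize_gel(
            records, channel_pairs=[("ch_gapdh", "ch_actinin")]
        )
        truth_gap = 346.0 - 164.0
        assert summary["pairs"]["ch_gapdh-ch_actinin"] == pytest.approx(
            truth_gap, abs=3.0
        )

    def test_empty_records_warn(self):
        empty = pd.DataFrame(columns=["channel", "mu_um", "sigma_z_um",
                                      "sigma_xy_um", "qc_pass"])
        with pytest.warns(UserWarning):
            summary = analysis.summarize_gel(empty)
        assert summary["channels"] == {}


class TestCellBandMatching:
    def test_identical_images_full_correspondence(self):
        p = synth.SynthesisParams(seed=3, wells_per_side=3)
        layout = synth.make_layout(p)
        img = synth.render_livecell_image(layout, miss_p=0.0, extra_p=0.0)
        stats = analysis.match_cells_to_bands(img, img, layout.wells, pixel_um=2.0)
        assert stats["pct_cells_with_bands"] == 100.0
        assert stats["pct_bands_without_cells"] == 0.0

    def test_empty_band_image_zero_correspondence(self):
        p = synth.SynthesisParams(seed=3, wells_per_side=3)
        layout = synth.make_layout(p)
        img = synth.render_livecell_image(layout, miss_p=0.0, extra_p=0.0)
        stats = analysis.match_cells_to_bands(
            img, np.zeros_like(img), layout.wells, pixel_um=2.0
        )
        assert stats["pct_cells_with_bands"] == 0.0

    def test_default_loss_rates_emulate_observed_correspondence(self):
        """Cell loss during handling leaves 60-80% of cells with bands."""
        p = synth.SynthesisParams(seed=8, wells_per_side=10)
        layout = synth.make_layout(p)
        live = synth.render_livecell_image(layout, miss_p=0.0, extra_p=0.0)
        # band image: every occupied well separates, but some cells were
        # lost before live imaging -> regenerate live image with misses
        live_missy = synth.render_livecell_image(layout, miss_p=0.25, extra_p=0.02)
        stats = analysis.match_cells_to_bands(
            live_missy, live, layout.wells, pixel_um=2.0
        )
        assert 60.0 <= stats["pct_cells_with_bands"] <= 100.0
        assert 0.0 <= stats["pct_bands_without_cells"] <= 40.0

    def test_unregistered_inputs_rejected(self):
        with pytest.raises(ValueError):
            analysis.match_cells_to_bands(
                np.zeros((10, 10)), np.zeros((12, 12)), pd.DataFrame(), 2.0
            )


class TestLysisKinetics:
    def test_default_movie_reports_86_percent(self):
        tl = synth.render_lysis_timelapse(seed=1)
        per_cell, summary = analysis.lysis_kinetics(
            tl.frames, tl.times_s, tl.pixel_um
        )
        assert summary["n_cells"] == 36
        assert summary["fraction_within_window"] == pytest.approx(31 / 36, abs=0.03)

    def test_onsets_within_one_frame_of_truth(self):
        tl = synth.render_lysis_timelapse(seed=1)
        per_cell, _ = analysis.lysis_kinetics(tl.frames, tl.times_s, tl.pixel_um)
        merged = per_cell.merge(
            tl.truth, on=["cell_id"], suffixes=("", "_truth"), how="inner"
        )
        lysed = merged[np.isfinite(merged["onset_s_truth"])]
        dt = tl.times_s[1] - tl.times_s[0]
        assert (lysed["onset_s"] - lysed["onset_s_truth"]).abs().max() <= dt + 1e-9

    def test_constant_intensity_no_onset(self):
        tl = synth.render_lysis_timelapse(
            n_cells=4, n_fast=0, n_never=4, duration_s=20.0, seed=0
        )
        per_cell, summary = analysis.lysis_kinetics(
            tl.frames, tl.times_s, tl.pixel_um
        )
        assert per_cell["onset_s"].isna().all()
        assert summary["fraction_within_window"] == 0.0

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError):
            analysis.lysis_kinetics(np.zeros((1, 8, 8)), np.array([0.0]), 2.0)


class TestEndToEnd:
    def test_noise_free_recovery_to_half_voxel(self, clean_single_band):
        params, layout, stack = clean_single_band
        records, tracks = analysis.analyze_stack(stack)
        assert len(tracks) == len(layout.occupied)
        for _, r in records.iterrows():
            truth = match_band(layout, r.x_um, r.y_um, r.channel)
            assert abs(r.mu_um - truth.z_um) < 0.5 * stack.voxel_size_um[0]
            assert abs(r.sigma_z_um / truth.sigma_z_um - 1) < 0.05

    def test_lane_anchor_matches_well_position(self, default_records, default_layout):
        records, tracks = default_records
        for t in tracks:
            d = np.hypot(
                default_layout.occupied.x_um - t.anchor_x_um,
                default_layout.occupied.y_um - t.anchor_y_um,
            )
            assert d.min() < 10.0
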