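"""Synthetic-frame generator: flux bookkeeping, determinism and the
end-to-end forward model."""

import numpy as np
import pytest

from tchasim.imaging import (
    ImagingConfig,
    read_frame,
    render_frame,
    render_stack,
    simulate_assay_frame,
)
from tchasim.kinetics import OccupancyParams
from tchasim.spots import intensity_histogram


def _quiet(**kw):
    return ImagingConfig(background_sd_cps=0.0, **kw)


class TestRenderFrame:
    def test_blank_histogram_peaks_at_background(self, imaging_config):
        frame = render_frame(np.empty((0, 2)), np.empty(0), imaging_config, seed=0)
        hist = intensity_histogram(frame.pixels)
        assert abs(hist.background_peak_cps - 2400.0) <= 50.0

    def test_single_anchor_peak_location_and_flux(self):
        cfg = _quiet()
        frame = render_frame([[50.0, 30.0]], 100, cfg, seed=0)
        img = frame.pixels.astype(float)
        iy, ix = np.unravel_index(np.argmax(img), img.shape)
        assert abs(ix * cfg.pixel_size_um - 50.0) <= cfg.pixel_size_um
        assert abs(iy * cfg.pixel_size_um - 30.0) <= cfg.pixel_size_um
        added = img.sum() - cfg.background_mean_cps * img.size
        expected = 100 * cfg.counts_per_emitter_cps * 2 * np.pi * cfg.sigma_px ** 2
        # quantisation of ~1000 pixels can move the sum by a few hundred counts
        assert added == pytest.approx(expected, rel=0.02)

    def test_flux_conservation_multiple_interior_anchors(self):
        cfg = _quiet()
        rng = np.random.default_rng(1)
        pos = rng.uniform(20.0, 80.0, size=(25, 2))
        emitters = rng.integers(50, 178, size=25)
        frame = render_frame(pos, emitters, cfg, seed=0)
        img = frame.pixels.astype(float)
        added = img.sum() - cfg.background_mean_cps * img.size
        expected = emitters.sum() * cfg.counts_per_emitter_cps * 2 * np.pi * cfg.sigma_px ** 2
        assert added == pytest.approx(expected, rel=0.005)

    def test_doubling_brightness_doubles_added_flux(self):
        pos = [[40.0, 60.0]]
        f1 = render_frame(pos, 100, _quiet(), seed=0).pixels.astype(float)
        f2 = render_frame(pos, 100, _quiet(counts_per_emitter_cps=60.0), seed=0).pixels.astype(float)
        bg = 2400.0 * f1.size
        assert f2.sum() - bg == pytest.approx(2 * (f1.sum() - bg), rel=1e-3)

    def test_same_seed_bit_identical(self, imaging_config):
        pos = [[10.0, 10.0], [90.0, 90.0]]
        a = render_frame(pos, 100, imaging_config, seed=3)
        b = render_frame(pos, 100, imaging_config, seed=3)
        assert np.array_equal(a.pixels, b.pixels)

    def test_rejects_outside_anchors(self, imaging_config):
        with pytest.raises(ValueError):
            render_frame([[120.0, 50.0]], 10, imaging_config, seed=0)

    def test_blank_mean_close_to_background(self, imaging_config):
        frame = render_frame(np.empty((0, 2)), np.empty(0), imaging_config, seed=4)
        n_pix = frame.pixels.size
        tol = 3 * imaging_config.background_sd_cps / np.sqrt(n_pix)
        assert abs(frame.pixels.mean() - 2400.0) < tol + 0.5  # 0.5 for quantisation

    def test_tiff_round_trip(self, tmp_path, imaging_config):
        frame = render_frame([[50.0, 50.0]], 150, imaging_config, seed=5)
        frame.to_tiff(tmp_path / "frame.tiff")
        back = read_frame(tmp_path / "frame.tiff")
        assert back.dtype == np.uint16
        assert np.array_equal(back, frame.pixels)


class TestAssayFrame:
    def test_zero_concentration_empty_truth(self, assay, layer, design9, occupancy, imaging_config):
        frame = simulate_assay_frame(0.0, assay, layer, design9, occupancy, imaging_config, seed=0)
        assert len(frame.truth) == 0

    def test_truth_count_linear_in_concentration(self, assay, layer, design9, occupancy, imaging_config):
        conc = np.array([1e-16, 1e-15, 1e-14, 1e-13])
        means = []
        for c in conc:
            counts = [
                len(simulate_assay_frame(c, assay, layer, design9, occupancy,
                                         imaging_config, seed=[int(c * 1e18), s]).truth)
                for s in range(12)
            ]
            means.append(np.mean(counts))
        r = np.corrcoef(conc, means)[0, 1]
        assert r ** 2 > 0.99

    def test_emitters_capped_by_docking_capacity(self, assay, layer, design9, occupancy, imaging_config):
        frame = simulate_assay_frame(1e-14, assay, layer, design9, occupancy, imaging_config, seed=1)
        assert frame.truth.emitters.max() <= 178

    def test_dense_frame_is_overlap_limited(self, assay, layer, design9, occupancy, imaging_config):
        """At the top of the calibration range spots crowd the field:
        a large fraction of pixels rises above the counting threshold and
        the intensity distribution shifts well above the blank."""
        frame = simulate_assay_frame(1e-12, assay, layer, design9, occupancy, imaging_config, seed=2)
        hist = intensity_histogram(frame.pixels, threshold_cps=3000.0)
        assert hist.above_threshold_fraction > 0.2
        blank = render_frame(np.empty((0, 2)), np.empty(0), imaging_config, seed=2)
        assert frame.pixels.mean() > blank.pixels.mean() + 10 * 120.0 / np.sqrt(blank.pixels.size)


class TestStack:
    def test_frozen_occupancy_frames_differ_only_in_noise(self, imaging_config):
        # occupancy saturated long before the first checkpoint
        occ = OccupancyParams(k_on=1e5, c_ha_mol_l=1e-6, capacity=100)
        pos = [[25.0, 25.0], [75.0, 75.0]]
        frames = render_stack(pos, occ, [36000.0, 36600.0, 37200.0], imaging_config, seed=0)
        emitters = [f.truth.emitters.to_numpy() for f in frames]
        assert np.array_equal(emitters[0], emitters[1]) and np.array_equal(emitters[1], emitters[2])
        diff = frames[0].pixels.astype(float) - frames[1].pixels.astype(float)
        assert abs(diff.mean()) < 1.0
        assert diff.std() == pytest.approx(np.sqrt(2) * 120.0, rel=0.05)

    def test_single_checkpoint_matches_render_frame(self, imaging_config):
        occ = OccupancyParams(k_on=1e5, c_ha_mol_l=1e-6, capacity=100)
        frames = render_stack([[50.0, 50.0]], occ, [36000.0], imaging_config, seed=1)
        assert len(frames) == 1
        direct = render_frame(
            [[50.0, 50.0]], frames[0].truth.emitters.to_numpy(), imaging_config,
            np.random.default_rng(np.random.SeedSequence(1).spawn(2)[1]),
        )
        assert np.array_equal(frames[0].pixels, direct.pixels)

    def test_mean_spot_signal_rises_with_occupancy(self, imaging_config):
        occ = OccupancyParams(k_on=1e5, c_ha_mol_l=1e-8, capacity=178)
        t = [600.0, 1800.0, 3600.0, 7200.0]
        frames = render_stack([[50.0, 50.0]], occ, t, imaging_config, seed=2)
        peaks = [f.pixels.max() for f in frames]
        assert all(b > a for a, b in zip(peaks, peaks[1:]))

    def test_rejects_bad_checkpoints(self, imaging_config):
        occ = OccupancyParams()
        with pytest.raises(ValueError):
            render_stack([[50.0, 50.0]], occ, [], imaging_config, seed=0)
        with pytest.raises(ValueError):
            render_stack([[50.0, 50.0]], occ, [10.0, 5.0], imaging_config, seed=0)
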