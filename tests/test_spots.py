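"""Histogramming, thresholding, spot counting and per-spot tracking."""

import numpy as np
import pytest

from tchasim.imaging import ImagingConfig, render_frame, render_stack
from tchasim.kinetics import FitError, KineticTrace, OccupancyParams, fit_logistic
from tchasim.spots import (
    count_spots,
    intensity_histogram,
    saturation_flag,
    spot_peak_stats,
    track_spots,
)


def _grid_positions(n, spacing_um=10.0, offset_um=5.0):
    """Well-separated anchors on a regular grid inside a 100x100 um field."""
    side = int(np.ceil(np.sqrt(n)))
    pts = [
        (offset_um + i * spacing_um, offset_um + j * spacing_um)
        for i in range(side)
        for j in range(side)
    ]
    return np.array(pts[:n], dtype=float)


class TestHistogram:
    def test_blank_peak_at_background(self, imaging_config):
        frame = render_frame(np.empty((0, 2)), np.empty(0), imaging_config, seed=0)
        hist = intensity_histogram(frame.pixels)
        assert abs(hist.background_peak_cps - 2400.0) <= 50.0

    def test_constant_frame_single_bin(self):
        hist = intensity_histogram(np.full((50, 50), 1234))
        assert (hist.counts > 0).sum() == 1
        assert hist.n_pixels == 2500

    def test_bimodal_frame_keeps_background_peak(self):
        rng = np.random.default_rng(1)
        frame = rng.normal(2400.0, 100.0, (100, 100))
        idx = rng.random(frame.shape) < 0.10
        frame[idx] += 2000.0
        hist = intensity_histogram(frame)
        assert abs(hist.background_peak_cps - 2400.0) <= 100.0
        occupied = hist.counts > 0
        # a separated cluster of occupied bins exists around 4400 cps
        centres = hist.bin_edges[:-1][occupied] + 25.0
        assert centres.max() > 4000.0

    def test_empty_frame_rejected(self):
        with pytest.raises(ValueError):
            intensity_histogram(np.empty((0, 0)))


class TestCountSpots:
    def test_recovers_well_separated_spots(self, imaging_config):
        pos = _grid_positions(38)
        frame = render_frame(pos, 178, imaging_config, seed=0)
        assert count_spots(frame.pixels).nfs == 38

    def test_blank_counts_zero(self, imaging_config):
        frame = render_frame(np.empty((0, 2)), np.empty(0), imaging_config, seed=1)
        assert count_spots(frame.pixels).nfs == 0

    def test_saturated_frame_is_one_component(self):
        assert count_spots(np.full((64, 64), 5000.0)).nfs == 1

    def test_monotone_in_threshold_and_min_area(self, imaging_config):
        pos = _grid_positions(25)
        rng = np.random.default_rng(2)
        frame = render_frame(pos, rng.integers(30, 178, 25), imaging_config, seed=2)
        nfs_by_t = [count_spots(frame.pixels, t).nfs for t in (2800.0, 3000.0, 3500.0, 5000.0)]
        assert nfs_by_t == sorted(nfs_by_t, reverse=True)
        nfs_by_a = [count_spots(frame.pixels, min_area_px=a).nfs for a in (1, 2, 5, 12)]
        assert nfs_by_a == sorted(nfs_by_a, reverse=True)

    def test_absolute_intensity_convention(self, imaging_config):
        """The fixed threshold works on absolute cps: shifting the whole
        frame changes the result (no background auto-adjustment)."""
        pos = _grid_positions(10)
        frame = render_frame(pos, 178, imaging_config, seed=3)
        base = count_spots(frame.pixels).nfs
        shifted = count_spots(frame.pixels.astype(float) + 2000.0).nfs
        assert base == 10
        assert shifted != base  # background itself crosses the threshold

    def test_centroids_near_truth(self, imaging_config):
        pos = _grid_positions(9, spacing_um=20.0, offset_um=15.0)
        frame = render_frame(pos, 178, imaging_config, seed=4)
        spots = count_spots(frame.pixels).spots
        detected = spots[["x_um", "y_um"]].to_numpy()
        # every true anchor has a detected centroid within half a micron
        for x, y in pos:
            dist = np.hypot(detected[:, 0] - x, detected[:, 1] - y).min()
            assert dist < 0.5


class TestPeakStats:
    def test_mean_of_two_spots(self):
        import pandas as pd

        from tchasim.spots import SpotSet

        df = pd.DataFrame({"x_um": [1, 2], "y_um": [1, 2], "area_px": [5, 5],
                           "peak_cps": [4000.0, 6000.0], "integrated_cps": [1e4, 2e4]})
        stats = spot_peak_stats(SpotSet(df, 3000.0, 2))
        assert stats.mean_peak_cps == 5000.0

    def test_empty_set_is_defined(self, imaging_config):
        frame = render_frame(np.empty((0, 2)), np.empty(0), imaging_config, seed=5)
        stats = spot_peak_stats(count_spots(frame.pixels))
        assert np.isnan(stats.mean_peak_cps)
        assert stats.peaks_cps.size == 0

    def test_permutation_invariant_mean(self, imaging_config):
        pos = _grid_positions(12)
        rng = np.random.default_rng(6)
        frame = render_frame(pos, rng.integers(100, 178, 12), imaging_config, seed=6)
        stats = spot_peak_stats(count_spots(frame.pixels))
        assert stats.mean_peak_cps == pytest.approx(np.mean(sorted(stats.peaks_cps)))


class TestSaturationFlag:
    def test_blank_regime(self, imaging_config):
        frame = render_frame(np.empty((0, 2)), np.empty(0), imaging_config, seed=7)
        hist = intensity_histogram(frame.pixels)
        assert not saturation_flag(hist, 3000.0)

    def test_definition_boundary(self):
        hist = intensity_histogram(np.full((10, 10), 3100.0))
        assert saturation_flag(hist, 3000.0)
        hist2 = intensity_histogram(np.full((10, 10), 2400.0))
        assert not saturation_flag(hist2, 3000.0)


class TestTrackSpots:
    def test_logistic_round_trip_recovers_midpoint(self, imaging_config):
        # checkpoints bracket the half-saturation time of the docking
        # kinetics; traces are background-subtracted before fitting so
        # the logistic's zero baseline matches the data
        occ = OccupancyParams(k_on=1e5, c_ha_mol_l=1e-8, capacity=178)
        pos = _grid_positions(16, spacing_um=20.0, offset_um=12.0)
        t = np.array([60.0, 240.0, 480.0, 720.0, 1080.0, 1440.0, 2160.0, 3600.0])
        frames = render_stack(pos, occ, t, imaging_config, seed=8)
        traces = track_spots([f.pixels for f in frames], t)
        assert len(traces) >= 14
        # reference midpoint: logistic fit of the noiseless mean-field trace
        from tchasim.kinetics import occupancy_closed_form

        ref_trace = KineticTrace(t, 30.0 * occupancy_closed_form(occ, t))
        t50_ref = fit_logistic(ref_trace).midpoint
        t50s = []
        for tr in traces:
            try:
                sub = KineticTrace(tr.times, tr.intensities - 2400.0)
                t50s.append(fit_logistic(sub).midpoint)
            except FitError:
                pass
        rel_err = np.abs(np.array(t50s) - t50_ref) / t50_ref
        assert np.median(rel_err) < 0.15

    def test_frozen_stack_traces_are_flat(self, imaging_config):
        from scipy import stats as sps

        occ = OccupancyParams(k_on=1e5, c_ha_mol_l=1e-6, capacity=178)
        pos = _grid_positions(20, spacing_um=15.0, offset_um=10.0)
        t = 36000.0 + 600.0 * np.arange(8)
        frames = render_stack(pos, occ, t, imaging_config, seed=9)
        traces = track_spots([f.pixels for f in frames], t)
        flat = sum(sps.linregress(tr.times, tr.intensities).pvalue > 0.01 for tr in traces)
        assert flat >= 0.95 * len(traces)

    def test_single_frame_rejected(self, imaging_config):
        frame = render_frame(_grid_positions(4), 178, imaging_config, seed=10)
        with pytest.raises(ValueError):
            track_spots([frame.pixels], [0.0])

    def test_no_spots_anywhere_empty(self, imaging_config):
        blank = [
            render_frame(np.empty((0, 2)), np.empty(0), imaging_config, seed=s).pixels
            for s in (11, 12)
        ]
        assert track_spots(blank, [0.0, 600.0]) == []
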