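"""Functional-trace analysis tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mtpm.functional import (
    Trace,
    TransientModel,
    consensus_roi,
    dff,
    estimate_noise,
    extracellular_ring,
    fit_amplitude,
    local_correlation_map,
    psnr,
    psnr_db,
    segment_functional_roi,
    slr,
    transient_waveform,
)


class TestLocalCorrelationMap:
    def test_shared_time_course_gives_unit_map(self):
        t = np.sin(np.linspace(0, 6, 50))
        movie = np.ones((50, 10, 10)) * t[:, None, None]
        assert np.allclose(local_correlation_map(movie), 1.0, atol=1e-10)

    def test_white_noise_gives_near_zero_map(self, rng):
        movie = rng.normal(0, 1, (200, 12, 12))
        cmap = local_correlation_map(movie)
        assert abs(cmap.mean()) < 0.05

    def test_flickering_disc_stands_out(self, rng):
        movie = rng.normal(10, 0.3, (120, 20, 20))
        t = 2.0 * (np.sin(np.linspace(0, 12, 120)) > 0)
        yy, xx = np.mgrid[0:20, 0:20]
        disc = np.hypot(yy - 10, xx - 10) <= 4
        movie[:, disc] += t[:, None]
        cmap = local_correlation_map(movie)
        inner = np.hypot(yy - 10, xx - 10) <= 2.5
        outer = np.hypot(yy - 10, xx - 10) >= 7
        assert cmap[inner].mean() > 0.8
        assert abs(cmap[outer].mean()) < 0.1

    def test_constant_pixels_contribute_zero(self):
        movie = np.zeros((10, 5, 5))
        movie[:, 2, 2] = np.arange(10.0)
        cmap = local_correlation_map(movie)
        assert cmap[2, 2] == 0.0

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError):
            local_correlation_map(np.zeros((2, 4, 4)))


class TestRoiSegmentation:
    def test_largest_component_chosen(self):
        img = np.zeros((40, 40))
        yy, xx = np.mgrid[0:40, 0:40]
        small = np.hypot(yy - 10, xx - 10) <= 3
        large = np.hypot(yy - 28, xx - 28) <= 7
        img[small] = 1.0
        img[large] = 1.0
        mask, empty = segment_functional_roi(img)
        assert not empty
        assert mask[large].mean() > 0.8 and not mask[small].any()

    def test_uniform_map_flagged_empty(self):
        mask, empty = segment_functional_roi(np.full((20, 20), 0.5))
        assert empty and not mask.any()

    def test_variance_map_recovers_disc_mask(self, rng):
        """Dice overlap > 0.8 against the ground-truth disc on a
        variance-map segmentation of a noisy movie."""
        yy, xx = np.mgrid[0:30, 0:30]
        disc = np.hypot(yy - 15, xx - 15) <= 6
        movie = rng.normal(100, 1, (150, 30, 30))
        movie[:, disc] += rng.normal(0, 8, (150, int(disc.sum())))
        var_map = movie.var(axis=0)
        mask, empty = segment_functional_roi(var_map, mode="variance")
        dice = 2 * (mask & disc).sum() / (mask.sum() + disc.sum())
        assert not empty and dice > 0.8


class TestConsensusAndRing:
    def test_strictly_more_than_quarter(self):
        base = np.zeros((4, 3, 3), dtype=bool)
        base[0, 1, 1] = True  # 1 of 4 = 0.25, not included
        base[:2, 0, 0] = True  # 2 of 4 = 0.5, included
        out = consensus_roi(base)
        assert not out[1, 1] and out[0, 0]

    def test_single_trial_is_identity(self, rng):
        m = rng.random((8, 8)) > 0.5
        assert np.array_equal(consensus_roi([m]), m)

    def test_ring_pixel_count(self):
        intra = np.zeros((20, 20), dtype=bool)
        intra[9:12, 9:12] = True  # centered 3x3 cell
        ring = extracellular_ring(intra, mode="5-pixel-ring")
        assert ring.sum() == 13 * 13 - 9
        assert not (ring & intra).any()

    def test_full_surround_complement_count(self):
        intra = np.zeros((20, 20), dtype=bool)
        intra[9:12, 9:12] = True
        assert extracellular_ring(intra, mode="full-surround").sum() == 400 - 9

    def test_corner_cell_ring_clipped(self):
        intra = np.zeros((20, 20), dtype=bool)
        intra[0:3, 0:3] = True
        ring = extracellular_ring(intra, mode="5-pixel-ring")
        assert ring.sum() == 8 * 8 - 9  # box clipped at the image corner


class TestDff:
    def test_constant_movie_gives_zero_trace(self):
        movie = np.full((10, 6, 6), 50.0)
        mask = np.ones((6, 6), dtype=bool)
        assert np.allclose(dff(movie, mask, 0.0, (0, 5), 10.0).values, 0.0)

    def test_step_amplitude(self):
        movie = np.full((20, 4, 4), 100.0)
        movie[10:] = 110.0
        mask = np.ones((4, 4), dtype=bool)
        tr = dff(movie, mask, 0.0, (0, 10), 10.0)
        assert tr.values[-1] == pytest.approx(0.10)

    def test_dark_level_rescales_step(self):
        movie = np.full((20, 4, 4), 100.0)
        movie[10:] = 110.0
        mask = np.ones((4, 4), dtype=bool)
        tr = dff(movie, mask, 50.0, (0, 10), 10.0)
        assert tr.values[-1] == pytest.approx(0.20)

    def test_gain_invariance_with_scaled_dark(self):
        movie = np.full((20, 4, 4), 100.0)
        movie[10:] = 120.0
        mask = np.ones((4, 4), dtype=bool)
        a = dff(movie, mask, 40.0, (0, 10), 10.0).values
        b = dff(movie * 3, mask, 120.0, (0, 10), 10.0).values
        assert np.allclose(a, b)

    def test_nonpositive_baseline_rejected(self):
        movie = np.full((10, 4, 4), 10.0)
        mask = np.ones((4, 4), dtype=bool)
        with pytest.raises(ValueError):
            dff(movie, mask, 10.0, (0, 5), 10.0)


class TestSlr:
    def _trace(self, values):
        return Trace(values=np.asarray(values, dtype=float), frame_rate=10.0)

    def test_direct_ratio(self):
        intra = self._trace([0.0, 0.4, 0.1, 0.0])
        extra = self._trace([0.0, 0.1, 0.05, 0.0])
        assert slr(intra, extra, (0.0, 0.3)) == pytest.approx(4.0)

    def test_identical_traces_give_unity(self):
        t = self._trace([0.0, 0.2, 0.1, 0.0])
        assert slr(t, t, (0.0, 0.3)) == pytest.approx(1.0)

    def test_nonpositive_extracellular_peak_floored(self):
        intra = self._trace([0.3, 0.3, 0.3])
        extra = self._trace([-0.1, -0.2, -0.1])
        assert slr(intra, extra, (0.0, 0.2), eps=1e-6) == pytest.approx(3e5)


class TestTransientModel:
    def test_no_spikes_is_zero(self):
        assert np.all(transient_waveform(np.linspace(0, 2, 50), []) == 0)

    def test_causal_before_first_spike(self):
        f = transient_waveform(np.array([0.0, 0.49, 0.51]), [0.5])
        assert f[0] == 0 and f[1] == 0 and f[2] > 0

    def test_single_pulse_peaks_at_amplitude(self):
        model = TransientModel(amplitude=1.0, alpha=3.18, gamma=34.39)
        t = np.linspace(0, 2, 200_001)
        f = transient_waveform(t, [0.0], model)
        assert f.max() == pytest.approx(1.0, abs=1e-6)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(
        alpha=st.floats(0.5, 10.0),
        ratio=st.floats(1.5, 50.0),
        amplitude=st.floats(0.1, 5.0),
    )
    def test_peak_normalization_for_any_rates(self, alpha, ratio, amplitude):
        model = TransientModel(amplitude=amplitude, alpha=alpha, gamma=alpha * ratio)
        t = np.linspace(0, 10 / alpha, 50_001)
        f = transient_waveform(t, [0.0], model)
        assert f.max() == pytest.approx(amplitude, rel=1e-4)

    def test_linear_in_amplitude_and_superposition(self):
        t = np.linspace(0, 3, 301)
        one = transient_waveform(t, [0.5], TransientModel(amplitude=1.0))
        two = transient_waveform(t, [0.5], TransientModel(amplitude=2.0))
        assert np.allclose(two, 2 * one, rtol=1e-12)
        pair = transient_waveform(t, [0.5, 1.5], TransientModel(amplitude=1.0))
        other = transient_waveform(t, [1.5], TransientModel(amplitude=1.0))
        assert np.allclose(pair, one + other, rtol=1e-12)

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            TransientModel(alpha=10.0, gamma=3.0)


class TestAmplitudeFit:
    def test_noiseless_recovery_is_exact(self):
        model = TransientModel(amplitude=2.0)
        t = np.arange(100) / 50.0
        trace = Trace(values=transient_waveform(t, [0.4], model), frame_rate=50.0)
        assert fit_amplitude(trace, [0.4]) == pytest.approx(2.0, abs=1e-9)

    def test_zero_trace_gives_zero(self):
        trace = Trace(values=np.zeros(100), frame_rate=50.0)
        assert fit_amplitude(trace, [0.4]) == 0.0

    def test_monte_carlo_variance_matches_closed_form(self, rng):
        """Estimator spread over replicates agrees with the linear
        least-squares variance sigma^2 / sum(r^2) within 20%."""
        t = np.arange(100) / 50.0
        r = transient_waveform(t, [0.4], TransientModel(amplitude=1.0))
        sigma = 0.2
        estimates = []
        for _ in range(100):
            y = r + rng.normal(0, sigma, r.size)
            estimates.append(
                fit_amplitude(Trace(values=y, frame_rate=50.0), [0.4])
            )
        estimates = np.asarray(estimates)
        se = estimates.std(ddof=1) / np.sqrt(len(estimates))
        assert abs(estimates.mean() - 1.0) < 3 * se
        analytic_sd = sigma / np.sqrt(np.sum(r**2))
        assert estimates.std(ddof=1) == pytest.approx(analytic_sd, rel=0.2)

    def test_no_spike_in_range_rejected(self):
        trace = Trace(values=np.zeros(50), frame_rate=50.0)
        with pytest.raises(ValueError):
            fit_amplitude(trace, [10.0])


class TestNoiseAndPsnr:
    def test_constant_tail_gives_zero(self):
        tr = Trace(values=np.r_[np.random.default_rng(0).normal(0, 1, 40), np.full(10, 0.3)],
                   frame_rate=50.0)
        assert estimate_noise(tr, 0.2) == pytest.approx(0.0, abs=1e-12)

    def test_alternating_tail_with_bessel_correction(self):
        # ten samples of +-1: sd with n-1 denominator = sqrt(10/9)
        tail = np.tile([1.0, -1.0], 5)
        tr = Trace(values=np.r_[np.zeros(40), tail], frame_rate=50.0)
        assert estimate_noise(tr, 0.2) == pytest.approx(np.sqrt(10 / 9), abs=1e-12)

    def test_gaussian_tail_consistency(self, rng):
        n = 10_000
        tr = Trace(values=rng.normal(0, 0.5, n), frame_rate=n / 0.2)
        se = 0.5 / np.sqrt(2 * (n - 1))
        assert abs(estimate_noise(tr, 0.2) - 0.5) < 3 * se

    def test_psnr_values(self):
        assert psnr(10.0, 2.0) == pytest.approx(25.0)
        assert psnr(0.0, 1.0) == 0.0
        assert psnr(1.0, 0.0) == float("inf")

    def test_db_convention(self):
        # a PSNR of 126 is 21.0 dB
        assert psnr_db(126.0) == pytest.approx(21.0, abs=0.05)
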