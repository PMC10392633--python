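"""Filtering, noise estimation, baseline tracking and detection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ampero import (
    DetectionConfig,
    ParameterError,
    SimulationConfig,
    binomial_smooth,
    detect_spikes,
    estimate_baseline,
    estimate_noise_sd,
    simulate_trace,
    smoothing_passes,
    template_peak,
)
from ampero.processing import _KERNEL

from conftest import FS, make_trace, plant_spikes


class TestBinomialSmooth:
    def test_constant_trace_unchanged(self):
        trace = make_trace(np.full(1000, 7.5))
        out = binomial_smooth(trace, 1000.0)
        np.testing.assert_allclose(out.current, 7.5, rtol=1e-12)

    def test_impulse_response_is_kernel(self):
        cur = np.zeros(101)
        cur[50] = 1.0
        out = binomial_smooth(make_trace(cur), 1000.0)  # one pass at fs/cutoff = 5
        assert smoothing_passes(1000.0, FS) == 1
        np.testing.assert_allclose(out.current[49:52], [0.25, 0.5, 0.25], rtol=1e-12)
        assert out.current.sum() == pytest.approx(1.0)

    def test_noise_gain_matches_convolution_oracle(self):
        # iterated kernel computed by brute-force convolution predicts the
        # white-noise SD reduction
        p = smoothing_passes(300.0, FS)
        assert p > 1
        kernel = np.array([1.0])
        for _ in range(p):
            kernel = np.convolve(kernel, _KERNEL)
        gain = np.sqrt((kernel**2).sum())
        rng = np.random.default_rng(0)
        trace = make_trace(rng.normal(0, 10.0, 200_000))
        out = binomial_smooth(trace, 300.0)
        assert out.current.std() / 10.0 == pytest.approx(gain, rel=0.02)

    def test_minus3db_point_at_or_below_cutoff(self):
        for cutoff in (250.0, 500.0, 1000.0, 2000.0):
            p = smoothing_passes(cutoff, FS)
            att = np.cos(np.pi * cutoff / FS) ** (2 * p)
            assert att <= 2 ** -0.5 + 1e-12
            if p > 1:  # p-1 passes would leave the cutoff under-attenuated
                assert np.cos(np.pi * cutoff / FS) ** (2 * (p - 1)) > 2 ** -0.5

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ParameterError):
            binomial_smooth(make_trace(np.zeros(100)), 3000.0)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.floats(-5, 5), st.floats(-5, 5), st.integers(0, 2**31 - 1))
    def test_linearity(self, a, b, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=500), rng.normal(size=500)
        lhs = binomial_smooth(make_trace(a * x + b * y), 500.0).current
        rhs = a * binomial_smooth(make_trace(x), 500.0).current + b * binomial_smooth(
            make_trace(y), 500.0
        ).current
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)


class TestNoiseEstimate:
    def test_gaussian_sd_recovered(self):
        rng = np.random.default_rng(1)
        trace = make_trace(rng.normal(0, 3.0, 10_000))
        assert estimate_noise_sd(trace, (0.0, 2.0)) == pytest.approx(3.0, abs=0.15)

    def test_robust_to_planted_spikes(self):
        # spikes on <10% of the window barely move the estimate
        trace = plant_spikes(4.0, np.arange(0.3, 3.8, 0.4), [400.0] * 9, noise_sd=2.0, seed=5)
        assert estimate_noise_sd(trace, (0.0, 4.0)) == pytest.approx(2.0, rel=0.10)

    def test_zero_trace_gives_zero(self):
        assert estimate_noise_sd(make_trace(np.zeros(1000)), (0.0, 0.2)) == 0.0

    def test_window_outside_trace_rejected(self):
        trace = make_trace(np.zeros(1000))
        with pytest.raises(ParameterError):
            estimate_noise_sd(trace, (5.0, 6.0))

    def test_short_window_rejected(self):
        trace = make_trace(np.zeros(1000))
        with pytest.raises(ParameterError):
            estimate_noise_sd(trace, (0.0, 0.01))

    def test_automatic_window_is_prestim_for_sca(self):
        rng = np.random.default_rng(2)
        cur = rng.normal(0, 1.0, 10_000)
        cur[5000:] += 50.0  # big step after stimulation start
        trace = make_trace(cur, mode="sca", stim_window=(1.0, 1.9))
        assert estimate_noise_sd(trace) == pytest.approx(1.0, rel=0.1)


class TestDetectSpikes:
    def test_planted_spikes_found_at_peak_positions(self):
        onsets = np.arange(0.5, 5.5, 0.5)
        trace = plant_spikes(6.0, onsets, [400.0] * 10)
        cands = detect_spikes(trace, noise_sd=0.3)
        assert len(cands) == 10
        t_star = template_peak(400.0, 0.5, 3.0)[0]
        det = trace.time[[c.peak_index for c in cands]]
        np.testing.assert_allclose(det, onsets + t_star, atol=1.5 / FS)

    def test_subthreshold_spikes_ignored(self):
        # all peaks below 5 x SD -> empty result
        trace = plant_spikes(2.0, [0.5, 1.0], [5.0, 5.0], noise_sd=1.0, seed=8)
        assert detect_spikes(trace, noise_sd=1.0) == []

    def test_close_spikes_split_at_clear_valley(self):
        # two spikes 2 ms apart (< min_separation) with a valley to baseline
        fs = FS
        n = int(0.5 * fs)
        cur = np.zeros(n)
        tri = np.concatenate([np.linspace(0, 10, 6), np.linspace(10, 0, 6)[1:]])
        i0 = 1000
        cur[i0 : i0 + 11] += tri
        i1 = i0 + 10  # second rise starts where the first returns to baseline
        cur[i1 : i1 + 11] += tri
        cands = detect_spikes(make_trace(cur), noise_sd=0.3)
        assert len(cands) == 2
        assert cands[0].end_index <= cands[1].onset_index + 1
        valley = i0 + 10
        assert abs(cands[0].end_index - valley) <= 3

    def test_ripple_on_tail_not_split_into_events(self):
        # a small bump riding on the decay tail belongs to its parent spike
        trace = plant_spikes(1.0, [0.3], [600.0])
        bump_start = int(0.308 * FS)  # on the tail, ~8 ms after onset
        bump = np.concatenate([np.linspace(0, 6.0, 5), np.linspace(6.0, 0, 5)[1:]])
        cur = trace.current.copy()
        cur[bump_start : bump_start + 9] += bump
        cands = detect_spikes(make_trace(cur), noise_sd=0.3)
        assert len(cands) == 1

    def test_threshold_monotonicity(self):
        cfg = SimulationConfig(seed=13, event_rate=4.0)
        trace, _ = simulate_trace(cfg, "sca")
        trace = binomial_smooth(trace, 1000.0)
        counts = []
        for mult in (4.0, 5.0, 7.0, 10.0):
            cands = detect_spikes(trace, DetectionConfig(threshold_multiplier=mult))
            counts.append(len(cands))
        assert counts == sorted(counts, reverse=True)

    def test_stim_only_restricts_sca_events(self):
        onsets = [0.5, 2.5, 4.0, 8.5]  # stim window (2, 7) + 1 s post
        trace = plant_spikes(10.0, onsets, [400.0] * 4)
        trace = trace.copy_with(mode="sca", stim_window=(2.0, 7.0))
        cfg = DetectionConfig(stim_only=True, noise_window=(0.0, 0.4))
        cands = detect_spikes(trace, cfg, noise_sd=0.3)
        kept = trace.time[[c.peak_index for c in cands]]
        assert len(cands) == 2
        assert np.all((kept >= 2.0) & (kept <= 8.0))


class TestEstimateBaseline:
    def test_flat_trace_baseline_near_zero(self):
        rng = np.random.default_rng(3)
        sd = 1.5
        trace = make_trace(rng.normal(0, sd, 20_000))
        base = estimate_baseline(trace, [])
        assert np.abs(base).max() < sd / 3

    def test_linear_drift_tracked(self):
        cur = np.linspace(0, 10, 50_000)
        base = estimate_baseline(make_trace(cur), [])
        assert np.abs(base - cur).max() < 0.5

    def test_all_event_trace_falls_back_to_endpoint_line(self):
        from ampero import SpikeCandidate

        cur = np.linspace(2.0, 4.0, 1000) + np.sin(np.linspace(0, 3, 1000))
        trace = make_trace(cur)
        base = estimate_baseline(trace, [SpikeCandidate(0, 500, 1000, 0.0)])
        np.testing.assert_allclose(base, np.linspace(cur[0], cur[-1], 1000), rtol=1e-9)

    def test_baseline_interpolated_across_events(self):
        # drifting trace with one big spike: baseline ignores the spike
        trace = plant_spikes(4.0, [2.0], [2000.0])
        drift = np.linspace(0, 5, trace.n_samples)
        trace = trace.copy_with(current=trace.current + drift)
        cands = detect_spikes(trace, noise_sd=0.3)
        assert len(cands) == 1
        base = estimate_baseline(trace, cands)
        sl = slice(cands[0].onset_index, cands[0].end_index)
        assert np.abs(base[sl] - drift[sl]).max() < 0.5
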