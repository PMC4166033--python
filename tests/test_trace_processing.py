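"""dF/F computation, averaging, responsiveness, decay and stability."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from texturemap import synthetic_data as sd
from texturemap import trace_processing as tp


def _time(n=400, ts=0.0125):
    return np.arange(n) * ts


class TestComputeDff:
    def test_constant_trace_is_zero(self):
        t = _time()
        d = tp.compute_dff(np.full(t.size, 250.0), t, 1.0, 3.0)
        assert np.allclose(d.r, 0.0, atol=1e-12)
        assert d.baseline == 250.0

    def test_forced_arithmetic_plateau(self):
        """90% of samples at 100, late plateau at 150 -> B=100, R=0.5."""
        t = _time(300)
        f = np.full(300, 100.0)
        f[-30:] = 150.0
        d = tp.compute_dff(f, t, 1.0, 3.0)
        assert d.baseline == pytest.approx(100.0)
        assert np.allclose(d.r[-30:], 0.5, atol=1e-12)

    def test_linear_drift_removed_exactly(self):
        """A pure multiplicative ramp leaves |R| below 1e-9 after detrend."""
        t = _time()
        f = 1000.0 * (1.0 + 0.03 * t)
        d = tp.compute_dff(f, t, 1.0, 3.0)
        assert np.abs(d.r).max() < 1e-9

    @pytest.mark.parametrize("c", [0.5, 3.0, 1e4])
    def test_multiplicative_invariance(self, c, rng):
        t = _time()
        f = 500.0 + 50.0 * rng.random(t.size)
        r1 = tp.compute_dff(f, t, 1.0, 3.0).r
        r2 = tp.compute_dff(c * f, t, 1.0, 3.0).r
        assert np.allclose(r1, r2, atol=1e-9)

    def test_nonpositive_baseline_rejected(self):
        t = _time()
        with pytest.raises(ValueError):
            tp.compute_dff(np.linspace(-10, 100, t.size), t, 1.0, 3.0)

    def test_baseline_fraction_bounds(self):
        t = _time()
        with pytest.raises(ValueError):
            tp.compute_dff(np.ones(t.size), t, 1.0, 3.0, baseline_fraction=1.5)


def _pulse_trace(t, height, center=2.0, width=0.5):
    r = np.zeros_like(t)
    r[np.abs(t - center) < width / 2] = height
    return r


def _as_dff(r, t):
    return tp.DffTrace(r=r, t=t, baseline=1.0, detrend_slope=0.0,
                       detrend_intercept=0.0, stim_onset=1.0, stim_offset=3.0)


class TestAverageAndSummarize:
    def test_identical_trials_average_to_any_trial(self):
        t = _time()
        r = _pulse_trace(t, 1.0)
        s = tp.average_and_summarize([_as_dff(r, t)] * 3)
        assert np.array_equal(s.mean_trace, r)
        assert np.allclose(s.trial_peaks, s.trial_peaks[0])

    def test_linearity_of_peak(self):
        t = _time()
        bump = np.exp(-((t - 2.0) ** 2) / 0.1)  # unique maximum
        p1 = tp.average_and_summarize([_as_dff(bump, t)]).peak
        s = tp.average_and_summarize([_as_dff(bump, t), _as_dff(3.0 * bump, t)])
        assert s.peak == pytest.approx(2.0 * p1)

    def test_windowed_peak_matches_brute_force(self, rng):
        """10-sample window mean around the argmax, by direct enumeration."""
        t = _time()
        r = rng.standard_normal((4, t.size)) * 0.1
        s = tp.average_and_summarize([_as_dff(x, t) for x in r])
        mean = r.mean(0)
        i = int(np.argmax(mean))
        lo = max(0, min(i - 4, mean.size - 10))  # centered, clipped
        oracle = sum(mean[lo + m] for m in range(10)) / 10.0
        assert s.peak == pytest.approx(oracle)
        assert s.peak >= mean.min()

    def test_trial_permutation_commutes(self, rng):
        t = _time()
        r = [rng.standard_normal(t.size) for _ in range(5)]
        s1 = tp.average_and_summarize([_as_dff(x, t) for x in r])
        s2 = tp.average_and_summarize([_as_dff(x, t) for x in reversed(r)])
        assert s1.peak == pytest.approx(s2.peak)
        assert s1.area == pytest.approx(s2.area)

    def test_unequal_lengths_truncate_to_shortest(self, rng):
        t = _time()
        a = _as_dff(rng.standard_normal(t.size), t)
        b = tp.DffTrace(r=rng.standard_normal(t.size - 37), t=t[:-37], baseline=1.0,
                        detrend_slope=0.0, detrend_intercept=0.0, stim_onset=1.0, stim_offset=3.0)
        s = tp.average_and_summarize([a, b])
        assert s.mean_trace.size == t.size - 37

    def test_empty_condition_raises(self):
        with pytest.raises(ValueError):
            tp.average_and_summarize([])


class TestResponsiveness:
    def test_zero_variance_convention(self):
        t = _time()
        s = tp.average_and_summarize([_as_dff(np.zeros(t.size), t)] * 3)
        responsive, _ = tp.responsiveness_test(s)
        assert not responsive

    def test_strong_signal_always_detected(self, clustered_population):
        """amp = 10x noise_sd -> essentially certain detection."""
        tspec = sd.TransientSpec(noise_sd=0.01, amp_dff=0.10, seed=21)
        trials = sd.generate_trials(clustered_population, tspec)
        sel = clustered_population.table.query("truth_label == 'P320'")
        ci = clustered_population.conditions.index("P320")
        for j in sel["neuron_id"].iloc[:5]:
            dffs = [tp.compute_dff(trials.f[int(j), ci, r], trials.t, 1.0, 3.0)
                    for r in range(trials.f.shape[2])]
            s = tp.average_and_summarize(dffs)
            assert tp.responsiveness_test(s)[0]


class TestDecay:
    @pytest.mark.parametrize("tau,kept", [(0.8, True), (0.3, False)])
    def test_threshold_decision(self, tau, kept, clustered_population):
        tspec = sd.TransientSpec(noise_sd=0.0, decay_tau=tau, n_trials_per_block=2, seed=0)
        trials = sd.generate_trials(clustered_population, tspec)
        j = int(clustered_population.table.query("truth_label == 'P120'")["neuron_id"].iloc[0])
        ci = clustered_population.conditions.index("P120")
        dffs = [tp.compute_dff(trials.f[j, ci, r], trials.t, 1.0, 3.0) for r in range(4)]
        s = tp.average_and_summarize(dffs)
        fitted = tp.fit_decay_tau(s)
        assert tp.decay_filter(fitted) is kept

    def test_tau_recovery_within_ten_percent(self, clustered_population):
        tspec = sd.TransientSpec(noise_sd=0.008, amp_dff=0.10, decay_tau=0.8, seed=2)
        trials = sd.generate_trials(clustered_population, tspec)
        j = int(clustered_population.table.query("truth_label == 'P120'")["neuron_id"].iloc[0])
        ci = clustered_population.conditions.index("P120")
        dffs = [tp.compute_dff(trials.f[j, ci, r], trials.t, 1.0, 3.0)
                for r in range(trials.f.shape[2])]
        fitted = tp.fit_decay_tau(tp.average_and_summarize(dffs))
        assert abs(fitted - 0.8) / 0.8 < 0.10


class TestStability:
    def test_identical_blocks_pass(self):
        t = _time()
        r = _pulse_trace(t, 1.0)
        s = tp.average_and_summarize([_as_dff(r, t)] * 4,
                                     block_of_trial=np.array([1, 1, 2, 2]))
        ok, pvals = tp.stability_test([s])
        assert ok and pvals[""] == 1.0

    def test_planted_block_drift_fails(self, clustered_population):
        tspec = sd.TransientSpec(noise_sd=0.01, block_gain=(1.0, 2.0), seed=3)
        trials = sd.generate_trials(clustered_population, tspec)
        j = int(clustered_population.table.query("truth_label == 'P120'")["neuron_id"].iloc[0])
        ci = clustered_population.conditions.index("P120")
        dffs = [tp.compute_dff(trials.f[j, ci, r], trials.t, 1.0, 3.0)
                for r in range(trials.f.shape[2])]
        s = tp.average_and_summarize(dffs, "P120", block_of_trial=trials.block_of_trial)
        ok, _ = tp.stability_test([s])
        assert not ok

    def test_missing_block_raises(self):
        t = _time()
        s = tp.average_and_summarize([_as_dff(_pulse_trace(t, 1.0), t)] * 2,
                                     block_of_trial=np.array([1, 1]))
        with pytest.raises(ValueError):
            tp.stability_test([s])


class TestPsth:
    def test_no_spikes_all_zero(self):
        counts, edges = tp.psth(np.array([]), 0.01, (0.0, 0.1))
        assert counts.sum() == 0 and counts.size == 10

    def test_one_spike_per_bin(self):
        centers = np.arange(0.005, 0.1, 0.01)
        counts, _ = tp.psth(centers, 0.01, (0.0, 0.1))
        assert np.array_equal(counts, np.ones(10, dtype=int))

    def test_poisson_total_count(self, rng):
        lam, T = 40.0, 2.0
        spikes = np.sort(rng.uniform(0, T, rng.poisson(lam * T)))
        counts, _ = tp.psth(spikes, 0.1, (0.0, T))
        assert abs(counts.sum() - lam * T) <= 3 * np.sqrt(lam * T)

    def test_negative_bin_rejected(self):
        with pytest.raises(ValueError):
            tp.psth(np.array([0.1]), -0.01, (0.0, 1.0))


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(min_value=0, max_value=390), st.integers(min_value=11, max_value=400))
def test_window_bounds_always_ten_samples_inside(i, n):
    lo, hi = tp.window_bounds(n, min(i, n - 1))
    assert hi - lo == 10
    assert 0 <= lo and hi <= n
    assert lo <= min(i, n - 1) < hi
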