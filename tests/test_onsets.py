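"""Onset detection, overrides, and reaction-time group statistics."""

import itertools

import numpy as np
import pytest

import startreact as sr
from startreact.trials import Trial


def _trial_from_rectified(level: np.ndarray, fs: float = 5000.0,
                          stim_ms: float = 250.0, **over) -> Trial:
    """Trial whose |signal| equals ``level`` exactly (one-signed signal)."""
    kwargs = dict(
        subject_id="S01", task_id="T01", cue="quiet", trial_index=1,
        stimulus_time_ms=stim_ms, sample_rate_hz=fs,
        muscles=tuple(f"M{i}" for i in range(level.shape[0])),
        signal=level,
    )
    kwargs.update(over)
    return Trial(**kwargs)


def _brute_force_rt(trial, baseline_ms=200.0, k_sd=3.0, limit_ms=500.0):
    """Naive per-sample scan: the independent oracle for detect_rt."""
    t = trial.rel_times_ms()
    rect = np.abs(trial.signal)
    out = []
    for m in range(rect.shape[0]):
        base = [
            rect[m, i] for i in range(len(t)) if -baseline_ms <= t[i] < 0
        ]
        thr = np.mean(base) + k_sd * np.std(base, ddof=1)
        rt = np.nan
        for i in range(len(t)):
            if 0 < t[i] <= limit_ms and rect[m, i] > thr:
                rt = t[i]
                break
        out.append(rt)
    return np.array(out)


class TestDetectRT:
    def test_threshold_is_mean_plus_3sd(self):
        # baseline engineered to mean 5, SD 2 exactly (n-1 denominator)
        base = np.full(1000, 5.0)
        base[: 500] += 2.0 * np.sqrt(999 / 1000)
        base[500:] -= 2.0 * np.sqrt(999 / 1000)
        sig = np.concatenate([base, np.zeros(2500)])[None, :]
        trial = _trial_from_rectified(sig, stim_ms=200.0)
        res = sr.detect_rt(trial)
        assert np.isclose(res.baseline_mean[0], 5.0)
        assert np.isclose(res.baseline_sd[0], 2.0)
        assert np.isclose(res.threshold[0], 11.0)

    def test_all_zero_signal_has_no_onset(self):
        trial = _trial_from_rectified(np.zeros((3, 5000)))
        res = sr.detect_rt(trial)
        assert np.all(res.threshold == 0.0)
        assert np.all(np.isnan(res.rt_ms))
        assert np.isnan(res.ert_ms)

    def test_step_onset_matches_brute_force_oracle(self):
        # bounded (uniform) baseline noise: mean + 3 SD lies above the noise
        # ceiling, so the first strict crossing is exactly the step onset
        rng = np.random.default_rng(42)
        fs, stim = 5000.0, 250.0
        sigma = np.sqrt(1.0 / 12.0)  # SD of U[0, 1]
        n = int(0.9 * fs)
        t = np.arange(n) / fs * 1000.0 - stim
        sig = rng.uniform(0.0, 1.0, size=(2, n))
        sig[:, t >= 150.0] += 10 * sigma  # step to 10 sigma at +150 ms
        trial = _trial_from_rectified(sig, stim_ms=stim)
        res = sr.detect_rt(trial)
        oracle = _brute_force_rt(trial)
        np.testing.assert_allclose(res.rt_ms, oracle)
        assert abs(res.ert_ms - 150.0) <= 1000.0 / fs + 1e-9

    def test_agrees_with_naive_scan_on_random_trials(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            n = int(0.8 * 2000)
            sig = rng.normal(0, 1, size=(3, n))
            onset = rng.uniform(50, 300)
            t = np.arange(n) / 2000.0 * 1000.0 - 300.0
            sig[:, t >= onset] += rng.uniform(3, 8)
            trial = _trial_from_rectified(sig, fs=2000.0, stim_ms=300.0)
            res = sr.detect_rt(trial)
            oracle = _brute_force_rt(trial)
            np.testing.assert_allclose(res.rt_ms, oracle, equal_nan=True)

    def test_rt_invariant_to_positive_rescaling(self):
        rng = np.random.default_rng(3)
        sig = np.abs(rng.normal(0, 1, size=(2, 4500)))
        t = np.arange(4500) / 5.0 - 250.0
        sig[:, t >= 120.0] += 8.0
        trial = _trial_from_rectified(sig)
        scaled = _trial_from_rectified(sig * 37.5)
        r1, r2 = sr.detect_rt(trial), sr.detect_rt(scaled)
        np.testing.assert_allclose(r1.rt_ms, r2.rt_ms, equal_nan=True)
        np.testing.assert_allclose(r2.threshold, 37.5 * r1.threshold)

    def test_constant_offset_in_one_signed_regime_preserves_rt(self):
        rng = np.random.default_rng(4)
        sig = np.abs(rng.normal(0, 1, size=(1, 4500))) + 5.0
        t = np.arange(4500) / 5.0 - 250.0
        sig[:, t >= 100.0] += 9.0
        r1 = sr.detect_rt(_trial_from_rectified(sig))
        r2 = sr.detect_rt(_trial_from_rectified(sig + 3.0))
        np.testing.assert_allclose(r1.rt_ms, r2.rt_ms, equal_nan=True)

    def test_debounce_rejects_single_sample_spikes(self):
        sig = np.zeros((1, 4500))
        sig[0, :1250] = np.tile([1.0, 3.0], 625)  # baseline mean 2, sd ~1
        spike_idx = 1250 + 100
        sig[0, spike_idx] = 50.0       # 1-sample artifact at +20 ms
        sig[0, 2250:] = 50.0           # sustained onset at +200 ms
        trial = _trial_from_rectified(sig)
        assert sr.detect_rt(trial).ert_ms == pytest.approx(20.2, abs=0.3)
        res = sr.detect_rt(trial, debounce_ms=1.0)
        assert res.ert_ms == pytest.approx(200.2, abs=0.3)

    def test_missing_baseline_raises(self):
        trial = _trial_from_rectified(np.zeros((1, 500)), stim_ms=50.0)
        with pytest.raises(ValueError, match="baseline"):
            sr.detect_rt(trial, baseline_ms=200.0)


class TestOverrides:
    @pytest.fixture()
    def detected(self, tiny_experiment):
        _, trialset, _ = tiny_experiment
        return trialset, sr.detect_trialset(trialset, debounce_ms=1.0)

    def test_empty_overrides_change_nothing(self, detected):
        _, results = detected
        out = sr.apply_overrides(results, [])
        for key in results:
            np.testing.assert_array_equal(
                out[key].rt_ms, results[key].rt_ms
            )

    def test_earlier_override_lowers_ert(self, detected):
        trialset, results = detected
        key = trialset.trials[0].key
        muscle = results[key].muscles[0]
        out = sr.apply_overrides(results, [(key, muscle, 5.0)])
        assert out[key].ert_ms == 5.0
        assert out[key].overrides_applied == [(muscle, 5.0)]
        # original untouched
        assert results[key].overrides_applied == []

    def test_clearing_all_rts_clears_ert(self, detected):
        trialset, results = detected
        key = trialset.trials[0].key
        overrides = [(key, m, None) for m in results[key].muscles]
        out = sr.apply_overrides(results, overrides)
        assert np.isnan(out[key].ert_ms)

    def test_unknown_key_or_muscle_raises(self, detected):
        trialset, results = detected
        key = trialset.trials[0].key
        with pytest.raises(KeyError):
            sr.apply_overrides(results, [(key, "NotAMuscle", 10.0)])
        bad = sr.TrialKey("S99", "T99", "quiet", 1)
        with pytest.raises(KeyError):
            sr.apply_overrides(results, [(bad, "1DI", 10.0)])


class TestCompareReactionTimes:
    def test_identical_samples_give_p_one(self):
        x = np.arange(1.0, 30.0)
        cmp = sr.compare_reaction_times(x, x)
        assert cmp.ranksum_p == pytest.approx(1.0)
        assert cmp.mean_difference == 0.0

    def test_ranksum_matches_exhaustive_enumeration(self):
        """Two-sided rank-sum p on {1,2,3} vs {4,5,6} equals the exact
        probability of a rank assignment at least as extreme."""
        quiet, loud = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        cmp = sr.compare_reaction_times(quiet, loud)
        pooled = quiet + loud
        observed = sum(sorted(pooled).index(v) + 1 for v in quiet)
        stats = []
        for combo in itertools.combinations(range(6), 3):
            ranks = [i + 1 for i in combo]
            stats.append(sum(ranks))
        mean = np.mean(stats)
        exact = np.mean(
            [abs(s - mean) >= abs(observed - mean) for s in stats]
        )
        assert exact == pytest.approx(0.1)
        assert cmp.ranksum_p == pytest.approx(exact)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            sr.compare_reaction_times([], [1.0, 2.0])
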