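"""Synthetic generator: ground truth, RT distributions, CPVE sampling, power."""

import numpy as np
import pytest

import startreact as sr
from startreact.simulate import draw_reaction_times

# a plausible experimental-like spectrum: geometric eigenvalue decay
MEAN_CURVE = (
    np.cumsum(np.exp(-np.arange(15) / 3.0))
    / np.exp(-np.arange(15) / 3.0).sum() * 100.0
)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"synergy_rank": 0},
            {"synergy_rank": 16},
            {"synergy_rank_loud": 0},
            {"loud_slow_fraction": 1.5},
            {"pattern_sparsity": 1.0},
            {"rt_loud_mean_ms": -5.0},
            {"noise_sd": -1.0},
            {"n_subjects": 0},
            {"pre_stimulus_ms": 100.0},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            sr.SynthConfig(**kwargs).validate()


class TestGroundTruth:
    def test_programmed_ert_is_min_of_muscle_onsets(self, tiny_experiment):
        cfg, _, truth = tiny_experiment
        onset_cols = [f"onset_{m}" for m in cfg.muscles]
        per_muscle_min = truth.onsets[onset_cols].min(axis=1)
        np.testing.assert_allclose(
            per_muscle_min, truth.onsets["ert_programmed_ms"]
        )

    def test_patterns_nonnegative_and_shared_between_cues(self, tiny_experiment):
        cfg, _, truth = tiny_experiment
        for (subj, task, cue), pat in truth.patterns.items():
            assert np.all(pat >= 0)
            np.testing.assert_array_equal(
                pat, truth.patterns[(subj, task, "quiet")]
            )

    def test_loud_rank_gives_cue_specific_patterns(self):
        cfg = sr.SynthConfig(n_subjects=1, n_tasks=2, trials_per_cue=1,
                             seed=3, synergy_rank_loud=1)
        _, truth = sr.generate_experiment(cfg)
        assert truth.synergies[("S01", "loud")].shape[1] == 1
        assert truth.synergies[("S01", "quiet")].shape[1] == 8

    def test_baseline_level_below_activation_level(self, small_experiment):
        """Mean rectified EMG during activation exceeds baseline for every
        active muscle whose amplitude is resolvable above the finite-window
        sampling error of the rectified mean (checked empirically at
        generator defaults; the expected lift scales as ~0.4 a^2 / sigma,
        which vanishes below the noise floor for near-zero weights)."""
        cfg, trialset, truth = small_experiment
        checked = 0
        for trial in trialset.trials[:20]:
            t = trial.rel_times_ms()
            rect = np.abs(trial.signal)
            row = truth.onsets[
                (truth.onsets["task_id"] == trial.task_id)
                & (truth.onsets["cue"] == trial.cue)
                & (truth.onsets["trial_index"] == trial.trial_index)
            ].iloc[0]
            pattern = truth.patterns[
                (trial.subject_id, trial.task_id, trial.cue)
            ]
            for i, m in enumerate(cfg.muscles):
                onset = row[f"onset_{m}"]
                if not np.isfinite(onset) or pattern[i] < 0.5 * cfg.noise_sd:
                    continue
                base = rect[i, (t >= -200) & (t < 0)].mean()
                act = rect[i, (t >= onset + cfg.onset_ramp_ms)].mean()
                assert act > base
                checked += 1
        assert checked > 50

    def test_determinism_identical_seed_identical_bytes(self, tmp_path):
        cfg = sr.SynthConfig(n_subjects=1, n_tasks=2, trials_per_cue=2,
                             seed=77, post_stimulus_ms=300.0)
        for name in ("a", "b"):
            ts, _ = sr.generate_experiment(cfg)
            sr.write_trialset(ts, tmp_path / name)
        files_a = sorted((tmp_path / "a").iterdir())
        files_b = sorted((tmp_path / "b").iterdir())
        assert [f.name for f in files_a] == [f.name for f in files_b]
        for fa, fb in zip(files_a, files_b):
            assert fa.read_bytes() == fb.read_bytes()


class TestReactionTimeDistributions:
    def test_programmed_quiet_mean_is_204(self):
        rng = np.random.default_rng(11)
        cfg = sr.SynthConfig()
        rts = draw_reaction_times(cfg, "quiet", 200_000, rng)
        sem = cfg.rt_quiet_sd_ms / np.sqrt(rts.size)
        assert np.all(rts >= 30.0)
        assert abs(rts.mean() - 204.0) < 4 * sem

    def test_programmed_loud_mean_is_144_without_slow_admixture(self):
        rng = np.random.default_rng(12)
        cfg = sr.SynthConfig(loud_slow_fraction=0.0)
        rts = draw_reaction_times(cfg, "loud", 200_000, rng)
        sem = cfg.rt_loud_sd_ms / np.sqrt(rts.size)
        assert abs(rts.mean() - 144.0) < 4 * sem

    def test_slow_admixture_raises_loud_mean(self):
        rng = np.random.default_rng(13)
        cfg = sr.SynthConfig(loud_slow_fraction=0.5)
        rts = draw_reaction_times(cfg, "loud", 50_000, rng)
        assert rts.mean() > 160.0  # halfway toward the quiet mean

    def test_noiseless_single_muscle_detection_matches_programmed(self):
        cfg = sr.SynthConfig(
            n_subjects=1, n_tasks=1, trials_per_cue=3, muscles=("M0",),
            synergy_rank=1, pattern_sparsity=0.0, noise_sd=0.0, seed=5,
        )
        ts, truth = sr.generate_experiment(cfg)
        one_sample_ms = 1000.0 / cfg.sample_rate_hz
        for trial in ts:
            res = sr.detect_rt(trial)
            row = truth.onsets[
                (truth.onsets["cue"] == trial.cue)
                & (truth.onsets["trial_index"] == trial.trial_index)
            ].iloc[0]
            assert abs(res.ert_ms - row["ert_programmed_ms"]) <= \
                one_sample_ms + 1e-9

    def test_detected_erts_recover_configured_means_approximately(self):
        """Threshold detection adds a small positive latency (the envelope
        must clear baseline-mean + 3 SD), so detected means sit a few ms
        above the programmed 204/144; the cue difference cancels it."""
        q = sr.simulate_detected_erts(sr.SynthConfig(seed=31), "quiet", 1500,
                                      seed=31)
        l = sr.simulate_detected_erts(
            sr.SynthConfig(seed=31, loud_slow_fraction=0.0), "loud", 1500,
            seed=31,
        )
        mq, ml = np.nanmean(q), np.nanmean(l)
        assert abs(mq - 204.0) < 10.0
        assert abs(ml - 144.0) < 10.0
        assert abs((mq - ml) - 60.0) < 6.0


class TestCPVESampling:
    def test_zero_noise_zero_delta_reproduces_mean_exactly(self):
        a, b = sr.generate_cpve_samples(MEAN_CURVE, 0.0, 4, delta=0.0, seed=1)
        np.testing.assert_allclose(a, np.tile(MEAN_CURVE, (4, 1)))
        np.testing.assert_allclose(b, np.tile(MEAN_CURVE, (4, 1)))

    def test_samples_are_valid_cpve_curves(self):
        a, b = sr.generate_cpve_samples(MEAN_CURVE, 3.0, 50, delta=4.0,
                                        component=2, seed=2)
        for curves in (a, b):
            assert np.all(np.diff(curves, axis=1) >= -1e-12)
            np.testing.assert_allclose(curves[:, -1], 100.0)
            assert np.all(curves <= 100.0 + 1e-12)

    def test_delta_shifts_target_component_upward(self):
        a, b = sr.generate_cpve_samples(MEAN_CURVE, 0.0, 6, delta=5.0,
                                        component=3, seed=3)
        np.testing.assert_allclose(b[:, :2], a[:, :2])
        np.testing.assert_allclose(
            b[:, 2:-1], np.minimum(a[:, 2:-1] + 5.0, 100.0)
        )

    def test_non_monotone_mean_rejected(self):
        bad = MEAN_CURVE.copy()
        bad[3] = bad[2] - 5.0
        with pytest.raises(ValueError):
            sr.generate_cpve_samples(bad, 1.0, 3)


class TestPowerAnalysis:
    def test_zero_delta_power_matches_calibrated_level(self):
        out = sr.power_analysis(MEAN_CURVE, 1.5, 10, deltas=[0.0],
                                replicates=500, seed=4)
        # calibrated level <= 51/1024 ~ 0.0498; binomial 3 SE ~ 0.029
        assert 0.01 <= out["power"].iloc[0] <= 0.09

    def test_power_monotone_in_delta(self):
        out = sr.power_analysis(MEAN_CURVE, 1.5, 10,
                                deltas=[0.0, 3.0, 6.0, 12.0],
                                replicates=150, seed=5)
        p = out["power"].to_numpy()
        assert np.all(np.diff(p) >= -0.05)  # within Monte Carlo error
        assert p[-1] > p[0]

    def test_noiseless_nonzero_delta_power_is_one(self):
        out = sr.power_analysis(MEAN_CURVE, 0.0, 10, deltas=[5.0],
                                replicates=100, seed=6)
        assert out["power"].iloc[0] == 1.0

    def test_replicates_floor_enforced(self):
        with pytest.raises(ValueError):
            sr.power_analysis(MEAN_CURVE, 1.0, 10, deltas=[0.0], replicates=50)
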