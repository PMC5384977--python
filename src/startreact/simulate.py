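"""Synthetic StartReact EMG experiments with known ground truth.

The generator emulates the statistical structure of a cued multi-muscle
experiment rather than the biophysics of the interference pattern:

* **Design** — ``n_subjects x n_tasks`` task conditions, ``trials_per_cue``
  repetitions per cue (quiet/loud), 15 muscles sampled at 5 kHz.
* **Reaction times** — the earliest onset of each trial is drawn from a
  truncated normal per cue (lower bound 30 ms; the location parameter is
  solved so that the truncated distribution's *mean* equals the configured
  mean).  Defaults: quiet 204 +/- 79 ms, loud 144 +/- 75 ms.  A fraction
  ``loud_slow_fraction`` of loud trials draws from the quiet distribution
  instead, so that the >100 ms loud-trial exclusion path is exercised.
* **Activation patterns** — each subject owns ``synergy_rank`` nonnegative
  synergy vectors; each task's 15-muscle pattern is a nonnegative mixture
  of them with a fraction of weights zeroed (sparsity).  The synergy rank
  is therefore the ground-truth fractionation dimensionality.
* **Signal** — amplitude-modulated Gaussian noise: baseline noise of SD
  ``noise_sd`` plus a zero-mean carrier whose SD follows the activation
  envelope (linear ramp over ``onset_ramp_ms`` to ``weight * (1 + jitter)``).
  The mean rectified level is then monotone in the envelope, which makes
  window-mean features approximately linear in the pattern weights.

All randomness descends from ``SynthConfig.seed`` through a documented
splitting scheme (`numpy.random.SeedSequence` keyed by purpose and trial),
so the same seed reproduces the same experiment byte-for-byte on disk.

The module also provides abstract CPVE-curve sampling
(:func:`generate_cpve_samples`) and :func:`power_analysis` for the
Monte Carlo comparison of CPVE curves.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .trials import CUES, DEFAULT_MUSCLES, Trial, TrialSet
from . import onsets as _onsets

__all__ = [
    "GroundTruth",
    "SynthConfig",
    "draw_reaction_times",
    "generate_cpve_samples",
    "generate_experiment",
    "generate_trials",
    "power_analysis",
    "simulate_detected_erts",
]

_RT_LOWER_MS = 30.0  # physical lower bound on a programmed earliest onset
_CUE_CODE = {"quiet": 0, "loud": 1}


@dataclass
class SynthConfig:
    """Parameters of the synthetic experiment; defaults are the study design."""

    n_subjects: int = 10
    n_tasks: int = 32
    trials_per_cue: int = 5
    muscles: tuple[str, ...] = DEFAULT_MUSCLES
    sample_rate_hz: float = 5000.0
    rt_quiet_mean_ms: float = 204.0
    rt_quiet_sd_ms: float = 79.0
    rt_loud_mean_ms: float = 144.0
    rt_loud_sd_ms: float = 75.0
    #: probability that a loud trial draws its RT from the quiet distribution
    loud_slow_fraction: float = 0.15
    synergy_rank: int = 8
    #: if set, loud-cue trials draw their task patterns from a separate
    #: synergy basis of this rank (cue-dependent fractionation ground truth);
    #: by default both cues share the same task patterns
    synergy_rank_loud: int | None = None
    pattern_sparsity: float = 0.3
    noise_sd: float = 1.0
    #: peak muscle weight of each task pattern, in signal units
    pattern_amplitude: float = 10.0
    #: SD of the multiplicative per-trial amplitude jitter
    amplitude_jitter_sd: float = 0.1
    onset_ramp_ms: float = 10.0
    muscle_lag_max_ms: float = 10.0
    #: recording span around the stimulus
    pre_stimulus_ms: float = 250.0
    post_stimulus_ms: float = 700.0
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_subjects, self.n_tasks, self.trials_per_cue) < 1:
            raise ValueError("design counts must be >= 1")
        if len(set(self.muscles)) != len(self.muscles):
            raise ValueError("muscle labels must be unique")
        if not 1 <= self.synergy_rank <= len(self.muscles):
            raise ValueError("synergy_rank must lie in [1, n_muscles]")
        if self.synergy_rank_loud is not None and not (
            1 <= self.synergy_rank_loud <= len(self.muscles)
        ):
            raise ValueError("synergy_rank_loud must lie in [1, n_muscles]")
        if self.rt_quiet_mean_ms <= 0 or self.rt_loud_mean_ms <= 0:
            raise ValueError("RT means must be positive")
        if min(self.rt_quiet_sd_ms, self.rt_loud_sd_ms, self.noise_sd,
               self.amplitude_jitter_sd) < 0:
            raise ValueError("SDs must be >= 0")
        if not 0.0 <= self.loud_slow_fraction <= 1.0:
            raise ValueError("loud_slow_fraction must lie in [0, 1]")
        if not 0.0 <= self.pattern_sparsity < 1.0:
            raise ValueError("pattern_sparsity must lie in [0, 1)")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if self.pattern_amplitude <= 0:
            raise ValueError("pattern_amplitude must be positive")
        if self.onset_ramp_ms < 0 or self.muscle_lag_max_ms < 0:
            raise ValueError("ramp and lag durations must be >= 0")
        if self.pre_stimulus_ms < 200.0:
            raise ValueError("recording must cover a 200 ms baseline")


@dataclass
class GroundTruth:
    """Programmed quantities behind a generated experiment.

    ``onsets`` has one row per trial with the programmed earliest onset and
    one ``onset_<muscle>`` column per muscle (NaN = muscle inactive).
    ``patterns`` maps (subject, task, cue) to the nonnegative 15-vector
    weight pattern (identical between cues unless ``synergy_rank_loud`` is
    set); ``synergies`` maps (subject, cue) to its muscles x rank basis.
    """

    onsets: pd.DataFrame
    patterns: dict[tuple[str, str], np.ndarray]
    synergies: dict[str, np.ndarray]


# --------------------------------------------------------------------------
# reaction-time distribution


def _truncnorm_location(target_mean: float, sd: float,
                        lower: float = _RT_LOWER_MS) -> float:
    """Location mu such that a normal(mu, sd) truncated below at ``lower``
    has mean ``target_mean``."""
    if sd == 0:
        return target_mean

    def mean_gap(mu: float) -> float:
        a = (lower - mu) / sd
        tail = stats.norm.sf(a)
        if tail <= 0:
            return lower - target_mean
        return mu + sd * stats.norm.pdf(a) / tail - target_mean

    lo, hi = target_mean - 6 * sd, target_mean + sd
    return float(optimize.brentq(mean_gap, lo, hi, xtol=1e-10))


def _draw_truncnorm(mu: float, sd: float, n: int, rng: np.random.Generator,
                    lower: float = _RT_LOWER_MS) -> np.ndarray:
    """Inverse-CDF sampling from normal(mu, sd) truncated below at lower."""
    if sd == 0:
        return np.full(n, max(mu, lower))
    a = stats.norm.cdf((lower - mu) / sd)
    u = rng.uniform(a, 1.0, size=n)
    return mu + sd * special.ndtri(u)


def draw_reaction_times(cfg: SynthConfig, cue: str, n: int,
                        rng: np.random.Generator) -> np.ndarray:
    """Programmed earliest-onset times (ms after stimulus) for ``n`` trials.

    Loud trials are a mixture: with probability ``loud_slow_fraction`` the
    draw comes from the quiet distribution (a trial where the startle
    shortcut failed to engage), otherwise from the loud distribution.
    """
    if cue not in CUES:
        raise ValueError(f"unknown cue {cue!r}")
    mu_q = _truncnorm_location(cfg.rt_quiet_mean_ms, cfg.rt_quiet_sd_ms)
    if cue == "quiet":
        return _draw_truncnorm(mu_q, cfg.rt_quiet_sd_ms, n, rng)
    mu_l = _truncnorm_location(cfg.rt_loud_mean_ms, cfg.rt_loud_sd_ms)
    rt = _draw_truncnorm(mu_l, cfg.rt_loud_sd_ms, n, rng)
    slow = rng.random(n) < cfg.loud_slow_fraction
    if slow.any():
        rt[slow] = _draw_truncnorm(mu_q, cfg.rt_quiet_sd_ms, int(slow.sum()), rng)
    return rt


# --------------------------------------------------------------------------
# patterns and signals


def _subject_rng(cfg: SynthConfig, purpose: int, *key: int) -> np.random.Generator:
    """Deterministic child stream: seed -> (purpose, key...) splitting."""
    return np.random.default_rng(
        np.random.SeedSequence([int(cfg.seed), int(purpose), *map(int, key)])
    )


def _subject_synergies(cfg: SynthConfig, subject_idx: int,
                       cue: str = "quiet") -> np.ndarray:
    if cue == "loud" and cfg.synergy_rank_loud is not None:
        rank, purpose = cfg.synergy_rank_loud, 7
    else:
        rank, purpose = cfg.synergy_rank, 1
    rng = _subject_rng(cfg, purpose, subject_idx)
    # half-normal weights: nonnegative, a few dominant muscles per synergy.
    # Sparsity zeroes weights at the synergy level, not per task pattern:
    # task patterns must stay inside the span of the K synergies so that
    # the configured rank really is the fractionation dimensionality.
    syn = np.abs(rng.normal(size=(len(cfg.muscles), rank)))
    n_zero = int(np.floor(cfg.pattern_sparsity * len(cfg.muscles)))
    n_zero = min(n_zero, len(cfg.muscles) - 1)
    for k in range(rank):
        if n_zero:
            syn[rng.choice(len(cfg.muscles), size=n_zero, replace=False), k] = 0.0
        if syn[:, k].max() <= 0:  # keep every synergy usable
            syn[rng.integers(len(cfg.muscles)), k] = 1.0
    return syn


def _subject_patterns(cfg: SynthConfig, subject_idx: int,
                      cue: str) -> np.ndarray:
    """All task patterns of one subject/cue as an (n_tasks, n_muscles) array.

    Each task engages a random subset of the subject's synergies (between
    one and half of them) with coefficients drawn from U[0.2, 1]: distinct
    tasks thereby recruit visibly different muscle combinations, the way a
    varied movement battery does, while every pattern stays inside the
    synergy span so the configured rank really bounds the fractionation
    dimensionality.  The collection is scaled once per subject so the
    *median* task peak equals ``pattern_amplitude`` — per-task
    normalisation would cancel the mixing coefficients for low ranks and
    destroy the controlled dimensionality, so task-to-task amplitude
    diversity is deliberately preserved.
    """
    synergies = _subject_synergies(cfg, subject_idx, cue)
    rank = synergies.shape[1]
    pats = np.empty((cfg.n_tasks, len(cfg.muscles)))
    for k in range(cfg.n_tasks):
        rng = _subject_rng(cfg, 2, subject_idx, k)
        coeffs = rng.uniform(0.2, 1.0, size=rank)
        if rank > 1:
            n_active = int(rng.integers(1, max(rank // 2, 1) + 1))
            mask = np.zeros(rank)
            mask[rng.choice(rank, size=n_active, replace=False)] = 1.0
            coeffs = coeffs * mask
        pats[k] = synergies @ coeffs
    peak = float(np.median(pats.max(axis=1)))
    return pats * (cfg.pattern_amplitude / peak)


def _trial_envelope_params(
    cfg: SynthConfig, pattern: np.ndarray, ert_ms: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-muscle onset times (NaN = inactive) and peak amplitudes."""
    active = pattern > 0
    onsets = np.full(pattern.size, np.nan)
    lags = rng.uniform(0.0, cfg.muscle_lag_max_ms, size=int(active.sum()))
    # one active muscle leads at zero lag so the programmed earliest onset
    # is exactly the drawn reaction time
    lags[rng.integers(lags.size)] = 0.0
    onsets[active] = ert_ms + lags
    jitter = rng.normal(0.0, cfg.amplitude_jitter_sd, size=pattern.size)
    amps = pattern * np.clip(1.0 + jitter, 0.1, None)
    amps[~active] = 0.0
    return onsets, amps


def _envelopes(cfg: SynthConfig, t_rel_ms: np.ndarray, onsets: np.ndarray,
               amps: np.ndarray) -> np.ndarray:
    """Activation envelope per muscle: 0 before onset, linear ramp over
    ``onset_ramp_ms``, then sustained at the trial amplitude."""
    env = np.zeros((onsets.size, t_rel_ms.size))
    ramp = max(cfg.onset_ramp_ms, 1e-9)
    for m in range(onsets.size):
        if not np.isfinite(onsets[m]) or amps[m] <= 0:
            continue
        env[m] = amps[m] * np.clip((t_rel_ms - onsets[m]) / ramp, 0.0, 1.0)
    return env


def _signal_from_envelope(env: np.ndarray, noise_sd: float,
                          rng: np.random.Generator) -> np.ndarray:
    """Amplitude-modulated Gaussian noise: baseline + carrier with SD = envelope."""
    base = noise_sd * rng.standard_normal(env.shape) if noise_sd > 0 else 0.0
    carrier = env * rng.standard_normal(env.shape)
    return base + carrier


def generate_trials(cfg: SynthConfig) -> Iterator[tuple[Trial, dict]]:
    """Lazily generate every trial of the design with its ground-truth row.

    Trials are ordered by (subject, task, cue, trial_index).  Each yielded
    ground-truth dict holds the programmed earliest onset and per-muscle
    onsets/amplitudes.
    """
    cfg.validate()
    n_samples = int(round(
        (cfg.pre_stimulus_ms + cfg.post_stimulus_ms) * cfg.sample_rate_hz / 1000.0
    )) + 1
    t_rel = (np.arange(n_samples) * (1000.0 / cfg.sample_rate_hz)
             - cfg.pre_stimulus_ms)
    for s in range(cfg.n_subjects):
        subject = f"S{s + 1:02d}"
        patterns = {cue: _subject_patterns(cfg, s, cue) for cue in CUES}
        for k in range(cfg.n_tasks):
            task = f"T{k + 1:02d}"
            for cue in CUES:
                pattern = patterns[cue][k]
                for j in range(cfg.trials_per_cue):
                    rng = _subject_rng(cfg, 3, s, k, _CUE_CODE[cue], j)
                    ert = float(draw_reaction_times(cfg, cue, 1, rng)[0])
                    m_onsets, amps = _trial_envelope_params(cfg, pattern, ert, rng)
                    env = _envelopes(cfg, t_rel, m_onsets, amps)
                    signal = _signal_from_envelope(env, cfg.noise_sd, rng)
                    trial = Trial(
                        subject_id=subject,
                        task_id=task,
                        cue=cue,
                        trial_index=j + 1,
                        stimulus_time_ms=cfg.pre_stimulus_ms,
                        sample_rate_hz=cfg.sample_rate_hz,
                        muscles=cfg.muscles,
                        signal=signal,
                    )
                    truth = {
                        "subject_id": subject,
                        "task_id": task,
                        "cue": cue,
                        "trial_index": j + 1,
                        "ert_programmed_ms": ert,
                        **{
                            f"onset_{m}": m_onsets[i]
                            for i, m in enumerate(cfg.muscles)
                        },
                    }
                    yield trial, truth


def generate_experiment(cfg: SynthConfig) -> tuple[TrialSet, GroundTruth]:
    """Generate the full experiment as an in-memory TrialSet + GroundTruth."""
    cfg.validate()
    trials, truth_rows = [], []
    for trial, truth in generate_trials(cfg):
        trials.append(trial)
        truth_rows.append(truth)
    patterns = {}
    synergies = {}
    for s in range(cfg.n_subjects):
        subject = f"S{s + 1:02d}"
        for cue in CUES:
            synergies[(subject, cue)] = _subject_synergies(cfg, s, cue)
            pats = _subject_patterns(cfg, s, cue)
            for k in range(cfg.n_tasks):
                patterns[(subject, f"T{k + 1:02d}", cue)] = pats[k]
    trialset = TrialSet(
        trials=trials,
        design={
            "n_subjects": cfg.n_subjects,
            "n_tasks": cfg.n_tasks,
            "trials_per_cue": cfg.trials_per_cue,
            "muscles": list(cfg.muscles),
        },
        provenance={"generator_seed": cfg.seed},
    )
    truth = GroundTruth(
        onsets=pd.DataFrame(truth_rows),
        patterns=patterns,
        synergies=synergies,
    )
    return trialset, truth


def simulate_detected_erts(
    cfg: SynthConfig,
    cue: str,
    n_trials: int,
    seed: int | None = None,
    baseline_ms: float = 200.0,
    k_sd: float = 3.0,
    search_limit_ms: float = 500.0,
    debounce_ms: float = 1.0,
    batch_size: int = 128,
) -> np.ndarray:
    """Detected eRTs for ``n_trials`` single-cue trials, generated in batches.

    This is the scalable path for RT-recovery studies: signals are built
    and rectified batch-wise and passed through the same threshold-crossing
    core (:func:`startreact.onsets.first_crossing_times`) as
    :func:`startreact.onsets.detect_rt`, without materialising Trial
    objects.  Uses the first subject/task pattern of the design.  Returns
    an array with NaN for trials in which no muscle crossed threshold.
    """
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence(
        [int(cfg.seed if seed is None else seed), 4, _CUE_CODE[cue]]
    ))
    fs = cfg.sample_rate_hz
    # cover baseline plus the full search window only; trims memory
    pre = max(baseline_ms, 200.0)
    post = search_limit_ms + cfg.onset_ramp_ms
    n_samples = int(round((pre + post) * fs / 1000.0)) + 1
    t_rel = np.arange(n_samples) * (1000.0 / fs) - pre
    base_mask = (t_rel >= -baseline_ms) & (t_rel < 0)
    post_mask = (t_rel > 0) & (t_rel <= search_limit_ms)
    first_offset = float(t_rel[post_mask][0])
    min_run = max(1, int(round(debounce_ms * fs / 1000.0)))

    # a representative task: the one whose peak amplitude is the median
    pats = _subject_patterns(cfg, 0, cue)
    pattern = pats[np.argsort(pats.max(axis=1))[len(pats) // 2]]
    ramp = max(cfg.onset_ramp_ms, 1e-9)
    t32 = t_rel.astype(np.float32)
    out = np.empty(n_trials)
    done = 0
    while done < n_trials:
        b = min(batch_size, n_trials - done)
        erts = draw_reaction_times(cfg, cue, b, rng)
        m_onsets = np.empty((b, pattern.size), dtype=np.float32)
        amps = np.empty((b, pattern.size), dtype=np.float32)
        for i in range(b):
            m_onsets[i], amps[i] = _trial_envelope_params(cfg, pattern,
                                                          erts[i], rng)
        # envelope, then pointwise SD of (baseline noise + AM carrier); a
        # single Gaussian draw with that SD has the identical distribution
        env = np.clip(
            (t32 - np.nan_to_num(m_onsets, nan=np.float32(np.inf))[:, :, None])
            / np.float32(ramp), 0.0, 1.0,
        )
        env *= amps[:, :, None]
        np.square(env, out=env)
        env += np.float32(cfg.noise_sd) ** 2
        np.sqrt(env, out=env)
        rect = rng.standard_normal((b, pattern.size, n_samples),
                                   dtype=np.float32)
        np.abs(rect, out=rect)
        rect *= env
        mean = rect[:, :, base_mask].mean(axis=2, dtype=np.float64)
        sd = rect[:, :, base_mask].astype(np.float64).std(axis=2, ddof=1)
        rt = _onsets.first_crossing_times(
            rect[:, :, post_mask], mean + k_sd * sd, fs, first_offset, min_run
        )
        any_det = np.isfinite(rt).any(axis=1)
        earliest = np.where(np.isfinite(rt), rt, np.inf).min(axis=1)
        out[done:done + b] = np.where(any_det, earliest, np.nan)
        done += b
    return out


# --------------------------------------------------------------------------
# abstract CPVE-curve sampling and power analysis


def _valid_cpve(curve: np.ndarray) -> np.ndarray:
    """Project a noisy curve onto the valid CPVE set: nonnegative,
    nondecreasing, capped at 100, final value exactly 100."""
    c = np.maximum.accumulate(np.clip(curve, 0.0, 100.0))
    c = np.minimum(c, 100.0)
    c[-1] = 100.0
    return c


def generate_cpve_samples(
    mean_curve: np.ndarray,
    sd_curve: np.ndarray,
    n_subjects: int,
    delta: float = 0.0,
    component: int = 1,
    seed: int | None = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Paired per-subject CPVE curves for two conditions (A, B).

    Each subject's curve is ``mean_curve`` plus independent per-component
    Gaussian noise of SD ``sd_curve``; condition B additionally receives
    ``delta`` percentage points at ``component`` (1-based) and at all later
    components — a CPVE offset at component c propagates cumulatively —
    then both are projected back onto the valid CPVE set (nondecreasing,
    <= 100, final value 100).

    Returns (A, B) arrays of shape (n_subjects, n_components).
    """
    mean_curve = np.asarray(mean_curve, dtype=float)
    sd_curve = np.broadcast_to(
        np.asarray(sd_curve, dtype=float), mean_curve.shape
    ).copy()
    if np.any(np.diff(mean_curve) < -1e-9):
        raise ValueError("mean_curve must be nondecreasing")
    if abs(mean_curve[-1] - 100.0) > 1e-6:
        raise ValueError("mean_curve must end at 100")
    if np.any(sd_curve < 0):
        raise ValueError("sd_curve must be >= 0")
    if not 1 <= component <= mean_curve.size:
        raise ValueError("component index out of range")
    rng = np.random.default_rng(seed)
    shape = (n_subjects, mean_curve.size)
    a = mean_curve + rng.normal(0.0, sd_curve, size=shape)
    b = mean_curve + rng.normal(0.0, sd_curve, size=shape)
    b[:, component - 1:] += delta
    a = np.apply_along_axis(_valid_cpve, 1, a)
    b = np.apply_along_axis(_valid_cpve, 1, b)
    return a, b


def power_analysis(
    mean_curve: np.ndarray,
    sd_curve: np.ndarray,
    n_subjects: int,
    deltas,
    replicates: int = 200,
    component: int = 2,
    target_count: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Detection power of the Monte Carlo CPVE test per injected delta.

    For each delta, ``replicates`` experiments are simulated with
    :func:`generate_cpve_samples` and tested with the exhaustive
    within-subject swap test; power is the fraction declared significant.
    The Monte Carlo standard error ``sqrt(p(1-p)/replicates)`` is reported.
    """
    from .mctest import run_cpve_test

    if replicates < 100:
        raise ValueError("replicates must be >= 100")
    root = np.random.SeedSequence([int(seed), 5])
    rows = []
    for d_idx, delta in enumerate(deltas):
        hits = 0
        for r in range(replicates):
            child = np.random.SeedSequence([int(seed), 5, d_idx, r])
            a, b = generate_cpve_samples(
                mean_curve, sd_curve, n_subjects, delta=float(delta),
                component=component, seed=child,
            )
            result = run_cpve_test(loud=b, quiet=a, target_count=target_count)
            hits += int(result.significant)
        p = hits / replicates
        rows.append(
            {
                "delta": float(delta),
                "power": p,
                "mc_se": float(np.sqrt(p * (1 - p) / replicates)),
                "replicates": replicates,
            }
        )
    return pd.DataFrame(rows)
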