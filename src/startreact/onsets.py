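"""Per-muscle EMG onset detection and earliest-reaction-time (eRT) analysis.

The detection rule: rectify the signal, take the mean and SD of the 200 ms
of rectified baseline preceding the stimulus, set the threshold at
``mean + 3 SD``, and call the reaction time the first post-stimulus sample
strictly exceeding it.  The trial's eRT is the minimum across muscles.

An optional ``debounce_ms`` requires the signal to stay supra-threshold
for a minimum duration before a crossing counts; this is an automated
stand-in for the visual inspection and manual correction that spurious
single-sample crossings (artifacts, baseline noise excursions) otherwise
require.  With Gaussian-like baseline noise roughly 0.9% of rectified
baseline samples exceed mean + 3 SD, so a single-sample criterion
false-triggers on almost every trial whose true onset is more than a few
tens of ms after the cue; a 1 ms debounce suppresses this while adding
little latency.  Explicit per-trial overrides are also supported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .trials import Trial, TrialKey

__all__ = [
    "OnsetResult",
    "RTComparison",
    "apply_overrides",
    "compare_reaction_times",
    "detect_rt",
    "detect_trialset",
    "onsets_table",
]

logger = logging.getLogger(__name__)


@dataclass
class OnsetResult:
    """Per-muscle thresholds and reaction times for one trial.

    ``rt_ms`` holds NaN where no supra-threshold crossing was found; the
    trial-level ``ert_ms`` is the minimum of the detected values, NaN when
    no muscle crossed.
    """

    trial_key: TrialKey
    muscles: tuple[str, ...]
    baseline_mean: np.ndarray
    baseline_sd: np.ndarray
    threshold: np.ndarray
    rt_ms: np.ndarray
    ert_ms: float
    overrides_applied: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if np.any(self.threshold < self.baseline_mean - 1e-12):
            raise ValueError("threshold below baseline mean")

    def rt_of(self, muscle: str) -> float:
        return float(self.rt_ms[self.muscles.index(muscle)])


def _recompute_ert(rt_ms: np.ndarray) -> float:
    detected = rt_ms[np.isfinite(rt_ms)]
    return float(detected.min()) if detected.size else float("nan")


def first_crossing_times(
    rect_post: np.ndarray,
    threshold: np.ndarray,
    sample_rate_hz: float,
    first_offset_ms: float,
    min_run: int = 1,
) -> np.ndarray:
    """First time each row strictly exceeds its threshold for ``min_run``
    consecutive samples.

    Parameters
    ----------
    rect_post : ndarray, (..., n_samples)
        Rectified signal restricted to the post-stimulus search window.
    threshold : ndarray, broadcastable to ``rect_post[..., 0]``
        Per-row threshold.
    first_offset_ms : float
        Time (ms after stimulus) of the first column of ``rect_post``.
    min_run : int
        Number of consecutive supra-threshold samples required; the
        reported time is that of the first sample of the run.

    Returns
    -------
    ndarray of times in ms after the stimulus; NaN where no crossing.
    """
    above = rect_post > np.asarray(threshold)[..., None]
    n = above.shape[-1]
    if min_run > 1:
        if n < min_run:
            return np.full(above.shape[:-1], np.nan)
        # run[i] = all of above[i : i+min_run]; shifted ANDs beat a cumsum
        run = above[..., : n - min_run + 1].copy()
        for k in range(1, min_run):
            run &= above[..., k : n - min_run + 1 + k]
        idx = np.argmax(run, axis=-1)
        found = np.take_along_axis(run, idx[..., None], axis=-1)[..., 0]
    else:
        idx = np.argmax(above, axis=-1)
        found = np.take_along_axis(above, idx[..., None], axis=-1)[..., 0]
    times = first_offset_ms + idx * (1000.0 / sample_rate_hz)
    return np.where(found, times, np.nan)


def detect_rt(
    trial: Trial,
    baseline_ms: float = 200.0,
    k_sd: float = 3.0,
    search_limit_ms: float = 500.0,
    debounce_ms: float = 0.0,
) -> OnsetResult:
    """Detect per-muscle reaction times and the trial's eRT.

    Baseline statistics use the half-open window [-baseline_ms, 0) ms
    relative to the stimulus (SD with n-1 denominator); the search window
    is (0, search_limit_ms].

    Raises
    ------
    ValueError
        If the recording does not cover the baseline window, or the
        search window is empty.
    """
    if baseline_ms <= 0:
        raise ValueError("baseline_ms must be positive")
    if search_limit_ms <= 0:
        raise ValueError("zero-length search window")
    t = trial.rel_times_ms()
    if t[0] > -baseline_ms:
        raise ValueError(
            f"trial {trial.key}: signal does not cover the "
            f"[-{baseline_ms:g}, 0) ms baseline window"
        )
    rect = np.abs(trial.signal)
    base = rect[:, (t >= -baseline_ms) & (t < 0)]
    if base.shape[1] < 2:
        raise ValueError(f"trial {trial.key}: fewer than 2 baseline samples")
    mean = base.mean(axis=1)
    sd = base.std(axis=1, ddof=1)
    threshold = mean + k_sd * sd

    post_mask = (t > 0) & (t <= search_limit_ms)
    if not post_mask.any():
        raise ValueError(f"trial {trial.key}: empty post-stimulus search window")
    first_offset = float(t[post_mask][0])
    min_run = max(1, int(round(debounce_ms * trial.sample_rate_hz / 1000.0)))
    rt = first_crossing_times(
        rect[:, post_mask], threshold, trial.sample_rate_hz, first_offset, min_run
    )
    return OnsetResult(
        trial_key=trial.key,
        muscles=trial.muscles,
        baseline_mean=mean,
        baseline_sd=sd,
        threshold=threshold,
        rt_ms=rt,
        ert_ms=_recompute_ert(rt),
    )


def detect_trialset(trialset, **kwargs) -> dict[TrialKey, OnsetResult]:
    """Run :func:`detect_rt` on every trial; returns a key -> result map."""
    return {trial.key: detect_rt(trial, **kwargs) for trial in trialset}


def apply_overrides(
    results: Mapping[TrialKey, OnsetResult],
    overrides: Iterable[tuple[TrialKey, str, float | None]],
) -> dict[TrialKey, OnsetResult]:
    """Replace listed per-muscle reaction times and recompute each eRT.

    Each override is ``(trial_key, muscle, rt_ms)`` with ``rt_ms=None``
    (or NaN) marking the rt as missing.  Unknown keys or muscles raise
    ``KeyError``.  Provenance is recorded on the returned results; the
    input mapping is not modified.
    """
    out = dict(results)
    for key, muscle, rt in overrides:
        if key not in out:
            raise KeyError(f"unknown trial key in override: {key}")
        res = out[key]
        if muscle not in res.muscles:
            raise KeyError(f"unknown muscle {muscle!r} for trial {key}")
        new_rt = res.rt_ms.copy()
        value = np.nan if rt is None else float(rt)
        if np.isfinite(value) and value < 0:
            raise ValueError(f"override rt_ms must be >= 0, got {value}")
        new_rt[res.muscles.index(muscle)] = value
        out[key] = replace(
            res,
            rt_ms=new_rt,
            ert_ms=_recompute_ert(new_rt),
            overrides_applied=res.overrides_applied + [(muscle, value)],
        )
    return out


def onsets_table(results: Mapping[TrialKey, OnsetResult]) -> pd.DataFrame:
    """Tidy per-(trial, muscle) table of thresholds and reaction times."""
    rows = []
    for key, res in results.items():
        for i, muscle in enumerate(res.muscles):
            rows.append(
                {
                    "subject_id": key.subject_id,
                    "task_id": key.task_id,
                    "cue": key.cue,
                    "trial_index": key.trial_index,
                    "muscle": muscle,
                    "baseline_mean": res.baseline_mean[i],
                    "baseline_sd": res.baseline_sd[i],
                    "threshold": res.threshold[i],
                    "rt_ms": res.rt_ms[i],
                    "ert_ms": res.ert_ms,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class RTComparison:
    """Group comparison of eRT samples between quiet and loud cues."""

    n_quiet: int
    n_loud: int
    mean_quiet: float
    sd_quiet: float
    mean_loud: float
    sd_loud: float
    mean_difference: float  # quiet - loud
    ranksum_statistic: float
    ranksum_p: float
    normality_p_quiet: float
    normality_p_loud: float


def compare_reaction_times(
    erts_quiet: Sequence[float], erts_loud: Sequence[float]
) -> RTComparison:
    """Compare eRT distributions between cue conditions.

    Normality of each sample is assessed with a Kolmogorov-Smirnov test
    against a normal distribution with estimated parameters (Lilliefors
    correction); the location comparison uses the two-sided Wilcoxon
    rank-sum test, appropriate because reaction times are typically
    right-skewed.
    """
    from statsmodels.stats.diagnostic import lilliefors

    q = np.asarray(erts_quiet, dtype=float)
    l = np.asarray(erts_loud, dtype=float)
    q = q[np.isfinite(q)]
    l = l[np.isfinite(l)]
    if q.size == 0 or l.size == 0:
        raise ValueError("both eRT samples must be nonempty")

    def _norm_p(x: np.ndarray) -> float:
        if x.size < 4 or np.ptp(x) == 0:
            return float("nan")
        return float(lilliefors(x, dist="norm")[1])

    # Wilcoxon rank-sum == Mann-Whitney U; exact null distribution for
    # small tie-free samples, normal approximation otherwise
    stat, p = stats.mannwhitneyu(q, l, alternative="two-sided", method="auto")
    return RTComparison(
        n_quiet=int(q.size),
        n_loud=int(l.size),
        mean_quiet=float(q.mean()),
        sd_quiet=float(q.std(ddof=1)) if q.size > 1 else float("nan"),
        mean_loud=float(l.mean()),
        sd_loud=float(l.std(ddof=1)) if l.size > 1 else float("nan"),
        mean_difference=float(q.mean() - l.mean()),
        ranksum_statistic=float(stat),
        ranksum_p=float(p),
        normality_p_quiet=_norm_p(q),
        normality_p_loud=_norm_p(l),
    )
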