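"""eRT-referenced window features, exclusion matching, condition matrices.

For each trial the mean rectified EMG of every muscle is taken in windows
referenced to the trial's earliest reaction time (defaults 0-10, 10-20,
20-30 and 50-100 ms after eRT; all windows half-open [start, end) so
adjacent windows never share a sample).

Loud trials with eRT > 100 ms are excluded (they show no startle
shortening), and an equal number of quiet trials is excluded uniformly at
random per subject so both conditions keep the same trial count.  Included
trials are stacked into per-(subject, cue, window) matrices of n trials x
15 muscles, which are z-scored per muscle before the covariance/PCA stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .onsets import OnsetResult
from .trials import Trial, TrialKey

__all__ = [
    "ConditionMatrix",
    "DEFAULT_WINDOWS",
    "MatchResult",
    "WindowSpec",
    "build_condition_matrix",
    "exclude_and_match",
    "features_table",
    "window_label",
    "window_means",
    "zscore_columns",
]

logger = logging.getLogger(__name__)

DEFAULT_WINDOWS = ((0.0, 10.0), (10.0, 20.0), (20.0, 30.0), (50.0, 100.0))

KEY_COLUMNS = ["subject_id", "task_id", "cue", "trial_index"]


def window_label(window: tuple[float, float]) -> str:
    return f"{window[0]:g}-{window[1]:g}"


@dataclass(frozen=True)
class WindowSpec:
    """Feature windows in ms relative to the eRT; need not be contiguous."""

    windows: tuple[tuple[float, float], ...] = DEFAULT_WINDOWS

    def __post_init__(self) -> None:
        for start, end in self.windows:
            if start >= end:
                raise ValueError(f"window start must precede end: ({start}, {end})")

    @property
    def labels(self) -> list[str]:
        return [window_label(w) for w in self.windows]

    @property
    def max_end_ms(self) -> float:
        return max(end for _, end in self.windows)


def window_means(
    trial: Trial, onset: OnsetResult, spec: WindowSpec = WindowSpec()
) -> dict[str, np.ndarray]:
    """Mean rectified EMG per muscle in each eRT-referenced window.

    Returns a mapping window label -> 15-vector.  The trial must have a
    detected eRT and cover eRT + the last window end.
    """
    if not np.isfinite(onset.ert_ms):
        raise ValueError(f"trial {trial.key}: eRT missing")
    t = trial.rel_times_ms()
    if t[-1] < onset.ert_ms + spec.max_end_ms:
        raise ValueError(
            f"trial {trial.key}: signal too short for window ending "
            f"{spec.max_end_ms:g} ms after eRT {onset.ert_ms:.1f} ms"
        )
    rect = np.abs(trial.signal)
    out = {}
    for window in spec.windows:
        mask = (t >= onset.ert_ms + window[0]) & (t < onset.ert_ms + window[1])
        if not mask.any():
            raise ValueError(f"trial {trial.key}: empty window {window}")
        out[window_label(window)] = rect[:, mask].mean(axis=1)
    return out


def features_table(
    trialset,
    onset_results: Mapping[TrialKey, OnsetResult],
    spec: WindowSpec = WindowSpec(),
) -> pd.DataFrame:
    """Long-format window features for every trial with a detected eRT.

    One row per (trial, window): key columns, ``window``, ``ert_ms``, then
    one column per muscle with the mean rectified EMG.  Trials whose eRT
    is missing are skipped with a logged warning; they take no further
    part in the analysis.
    """
    muscles = list(trialset.muscles)
    rows = []
    n_skipped = 0
    for trial in trialset:
        res = onset_results[trial.key]
        if not np.isfinite(res.ert_ms):
            n_skipped += 1
            logger.warning("trial %s: no muscle crossed threshold; skipped",
                           trial.key)
            continue
        try:
            means = window_means(trial, res, spec)
        except ValueError as exc:  # recording too short for the last window
            n_skipped += 1
            logger.warning("%s; trial skipped", exc)
            continue
        for label, vec in means.items():
            rows.append(
                {
                    "subject_id": trial.subject_id,
                    "task_id": trial.task_id,
                    "cue": trial.cue,
                    "trial_index": trial.trial_index,
                    "window": label,
                    "ert_ms": res.ert_ms,
                    **dict(zip(muscles, vec)),
                }
            )
    if n_skipped:
        logger.warning("%d trials dropped for missing eRT", n_skipped)
    return pd.DataFrame(rows, columns=KEY_COLUMNS + ["window", "ert_ms"] + muscles)


@dataclass
class MatchResult:
    """Outcome of the loud >cutoff exclusion with matched quiet exclusion."""

    subject_id: str
    included_loud: list[TrialKey]
    included_quiet: list[TrialKey]
    excluded_loud: list[TrialKey]
    excluded_quiet: list[TrialKey]
    seed: object

    @property
    def n_excluded(self) -> int:
        return len(self.excluded_loud)


def _trial_erts(features: pd.DataFrame) -> pd.DataFrame:
    """One row per trial (keys + ert_ms) from a long feature table."""
    return features[KEY_COLUMNS + ["ert_ms"]].drop_duplicates(KEY_COLUMNS)


def exclude_and_match(
    subject_features: pd.DataFrame,
    cutoff_ms: float = 100.0,
    seed: object = 0,
) -> MatchResult:
    """Exclude loud trials with eRT > cutoff and as many random quiet trials.

    The quiet exclusions are drawn uniformly from the subject's pooled
    quiet trials (not stratified by task).  If the quiet condition has more
    trials than the loud condition even before matching (e.g. loud trials
    lost to detection failures), the surplus is removed too, so the two
    included lists always have equal length.

    Raises
    ------
    ValueError
        If the required number of quiet exclusions exceeds the available
        quiet trials, or the features span only one subject is violated.
    """
    subjects = subject_features["subject_id"].unique()
    if len(subjects) != 1:
        raise ValueError("exclude_and_match operates on a single subject")
    trials = _trial_erts(subject_features)
    loud = trials[trials["cue"] == "loud"]
    quiet = trials[trials["cue"] == "quiet"]

    def keys(df: pd.DataFrame) -> list[TrialKey]:
        return [
            TrialKey(r.subject_id, r.task_id, r.cue, int(r.trial_index))
            for r in df.itertuples(index=False)
        ]

    slow = loud["ert_ms"] > cutoff_ms
    included_loud = keys(loud[~slow])
    excluded_loud = keys(loud[slow])
    n_remove_quiet = len(quiet) - len(included_loud)
    if n_remove_quiet < 0:
        raise ValueError(
            f"subject {subjects[0]}: cannot match {len(included_loud)} loud "
            f"trials with only {len(quiet)} quiet trials"
        )
    rng = np.random.default_rng(seed)
    quiet_keys = keys(quiet)
    drop_idx = rng.choice(len(quiet_keys), size=n_remove_quiet, replace=False)
    drop = set(drop_idx.tolist())
    included_quiet = [k for i, k in enumerate(quiet_keys) if i not in drop]
    excluded_quiet = [quiet_keys[i] for i in sorted(drop)]
    return MatchResult(
        subject_id=str(subjects[0]),
        included_loud=included_loud,
        included_quiet=included_quiet,
        excluded_loud=excluded_loud,
        excluded_quiet=excluded_quiet,
        seed=seed,
    )


@dataclass
class ConditionMatrix:
    """n trials x 15 muscles activation matrix for one subject/cue/window."""

    subject_id: str
    cue: str
    window: str
    muscles: tuple[str, ...]
    matrix: np.ndarray
    trial_keys: list[TrialKey]
    zscored: bool = False
    degenerate_muscles: tuple[str, ...] = ()
    excluded: list = field(default_factory=list)
    seed: object = None

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


def build_condition_matrix(
    features: pd.DataFrame,
    included: Sequence[TrialKey],
    subject_id: str,
    cue: str,
    window: str,
) -> ConditionMatrix:
    """Stack included trials' window vectors in (task, trial_index) order."""
    wanted = {
        k for k in included if k.subject_id == subject_id and k.cue == cue
    }
    if not wanted:
        raise ValueError(f"no included trials for {subject_id}/{cue}")
    sel = features[
        (features["subject_id"] == subject_id)
        & (features["cue"] == cue)
        & (features["window"] == window)
    ]
    by_key = {
        TrialKey(r["subject_id"], r["task_id"], r["cue"], int(r["trial_index"])): r
        for _, r in sel.iterrows()
    }
    missing = wanted - set(by_key)
    if missing:
        raise ValueError(f"features missing for trials: {sorted(map(str, missing))}")
    muscles = tuple(features.columns[6:])
    ordered = sorted(wanted, key=lambda k: (k.task_id, k.trial_index))
    matrix = np.array([[by_key[k][m] for m in muscles] for k in ordered])
    return ConditionMatrix(
        subject_id=subject_id,
        cue=cue,
        window=window,
        muscles=muscles,
        matrix=matrix,
        trial_keys=ordered,
    )


def zscore_columns(cm: ConditionMatrix, tol: float = 1e-12) -> ConditionMatrix:
    """Standardize each muscle column to zero mean, unit SD (n-1 denominator).

    Zero-variance columns cannot be standardized; they are set to all-zero
    and flagged as degenerate so the eigen-analysis stays well defined and
    reports can surface the condition.  Idempotent within tolerance.
    """
    if cm.n < 2:
        raise ValueError("z-scoring requires at least 2 trials")
    m = cm.matrix.astype(float).copy()
    mean = m.mean(axis=0)
    sd = m.std(axis=0, ddof=1)
    degenerate = sd <= tol
    sd_safe = np.where(degenerate, 1.0, sd)
    z = (m - mean) / sd_safe
    z[:, degenerate] = 0.0
    if degenerate.any():
        logger.warning(
            "%s/%s/%s: degenerate (zero-variance) muscles: %s",
            cm.subject_id, cm.cue, cm.window,
            [mu for mu, d in zip(cm.muscles, degenerate) if d],
        )
    return replace(
        cm,
        matrix=z,
        zscored=True,
        degenerate_muscles=tuple(
            mu for mu, d in zip(cm.muscles, degenerate) if d
        ),
    )
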