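"""Cosine similarity of muscle activation patterns across trials.

Each trial's window-mean activation is a nonnegative 15-vector x_j; the
similarity of two trials is cos(angle) = x_j . x_k / (|x_j||x_k|), which
is 1 for parallel vectors, 0 for orthogonal ones, and scale-invariant per
trial — so the *non*-z-scored window features are the right input.

Four comparison sets are pooled across tasks and subjects (pairs are
always formed within subject, never across electrode placements):

1. same-task quiet-quiet   — consistency of a task's pattern,
2. same-task loud-loud     — the same under startle cues,
3. different-task quiet-quiet — heterogeneity across tasks,
4. same-task quiet-loud    — whether startle trials reuse the task pattern.

Within-task same-cue sets use unordered distinct pairs (no self-pairs);
the quiet-loud set uses all cross-cue pairs within task; the
different-task set uses unordered pairs of quiet trials from distinct
tasks.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .trials import TrialKey
from .windows import KEY_COLUMNS

__all__ = [
    "SET_LABELS",
    "SimilarityDistribution",
    "cosine_similarity",
    "similarity_sets",
    "summarize_similarity",
]

logger = logging.getLogger(__name__)

SET_LABELS = (
    "same_task_quiet_quiet",
    "same_task_loud_loud",
    "different_task_quiet_quiet",
    "same_task_quiet_loud",
)


def cosine_similarity(x: np.ndarray, y: np.ndarray) -> float:
    """cos(angle) between two activation vectors; requires nonzero magnitude."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx = np.linalg.norm(x)
    ny = np.linalg.norm(y)
    if nx == 0 or ny == 0:
        raise ValueError("cosine similarity undefined for zero-magnitude vector")
    return float(x @ y / (nx * ny))


@dataclass
class SimilarityDistribution:
    """Pooled similarity values for one comparison set and window."""

    label: str
    window: str
    values: np.ndarray
    n_skipped_zero: int = 0
    cutoff: float = 0.8

    @property
    def mean(self) -> float:
        return float(self.values.mean()) if self.values.size else float("nan")

    @property
    def fraction_above_cutoff(self) -> float:
        if not self.values.size:
            return float("nan")
        return float((self.values > self.cutoff).mean())


def _normalized_rows(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rows scaled to unit norm; second return flags zero rows."""
    norms = np.linalg.norm(mat, axis=1)
    zero = norms == 0
    safe = np.where(zero, 1.0, norms)
    return mat / safe[:, None], zero


def similarity_sets(
    features: pd.DataFrame,
    window: str,
    included: Sequence[TrialKey] | None = None,
    cutoff: float = 0.8,
) -> dict[str, SimilarityDistribution]:
    """Compute the four pooled similarity distributions for one window.

    ``features`` is the long non-z-scored window-feature table; if
    ``included`` is given, only those (post-exclusion) trials contribute.
    Cells with fewer than two usable trials contribute no pairs; trials
    whose activation vector is all-zero are skipped and counted.
    """
    sel = features[features["window"] == window]
    if included is not None:
        inc = {
            (k.subject_id, k.task_id, k.cue, int(k.trial_index)) for k in included
        }
        mask = [
            (r.subject_id, r.task_id, r.cue, int(r.trial_index)) in inc
            for r in sel[KEY_COLUMNS].itertuples(index=False)
        ]
        sel = sel[np.asarray(mask, dtype=bool)]
    muscles = list(features.columns[6:])
    pools: dict[str, list[np.ndarray]] = {label: [] for label in SET_LABELS}
    n_skipped = 0

    for subject, sub in sel.groupby("subject_id", sort=True):
        # unit-normalised activation vectors per (task, cue)
        unit: dict[tuple[str, str], np.ndarray] = {}
        for (task, cue), grp in sub.groupby(["task_id", "cue"], sort=True):
            mat = grp[muscles].to_numpy(dtype=float)
            u, zero = _normalized_rows(mat)
            n_skipped += int(zero.sum())
            unit[(task, cue)] = u[~zero]

        tasks = sorted({t for t, _ in unit})
        for task in tasks:
            q = unit.get((task, "quiet"), np.empty((0, len(muscles))))
            l = unit.get((task, "loud"), np.empty((0, len(muscles))))
            if len(q) >= 2:
                g = q @ q.T
                pools["same_task_quiet_quiet"].append(
                    g[np.triu_indices(len(q), k=1)]
                )
            if len(l) >= 2:
                g = l @ l.T
                pools["same_task_loud_loud"].append(
                    g[np.triu_indices(len(l), k=1)]
                )
            if len(q) and len(l):
                pools["same_task_quiet_loud"].append((q @ l.T).ravel())
        for t1, t2 in itertools.combinations(tasks, 2):
            q1 = unit.get((t1, "quiet"), np.empty((0, len(muscles))))
            q2 = unit.get((t2, "quiet"), np.empty((0, len(muscles))))
            if len(q1) and len(q2):
                pools["different_task_quiet_quiet"].append((q1 @ q2.T).ravel())

    if n_skipped:
        logger.warning("similarity: skipped %d all-zero activation vectors",
                       n_skipped)
    out = {}
    for label in SET_LABELS:
        values = (
            np.concatenate(pools[label]) if pools[label] else np.empty(0)
        )
        # clip round-off outside [0, 1]; inputs are nonnegative vectors
        out[label] = SimilarityDistribution(
            label=label,
            window=window,
            values=np.clip(values, 0.0, 1.0),
            n_skipped_zero=n_skipped,
            cutoff=cutoff,
        )
    return out


def summarize_similarity(
    dists_by_window: Mapping[str, Mapping[str, SimilarityDistribution]],
    cutoff: float = 0.8,
) -> pd.DataFrame:
    """Per-window summary: means, fractions above cutoff, pairwise tests.

    Welch two-sample t-tests compare each of sets 2-4 against the
    same-task quiet-quiet reference, plus same-task loud-loud against
    same-task quiet-loud.  Dependence between overlapping pairs is
    ignored, as is conventional for these pooled similarity samples; the
    p-values are therefore anti-conservative and should be read with the
    effect sizes.
    """
    rows = []
    for window, dists in dists_by_window.items():
        for label in SET_LABELS:
            d = dists[label]
            if d.values.size == 0:
                raise ValueError(f"empty similarity distribution: {window}/{label}")
        ref = dists["same_task_quiet_quiet"].values
        row = {"window": window}
        for label in SET_LABELS:
            d = dists[label]
            row[f"mean_{label}"] = d.mean
            row[f"frac_above_{cutoff:g}_{label}"] = float(
                (d.values > cutoff).mean()
            )
        for label in SET_LABELS[1:]:
            t, p = stats.ttest_ind(
                dists[label].values, ref, equal_var=False
            )
            row[f"t_vs_quiet_quiet_{label}"] = float(t)
            row[f"p_vs_quiet_quiet_{label}"] = float(p)
        t, p = stats.ttest_ind(
            dists["same_task_loud_loud"].values,
            dists["same_task_quiet_loud"].values,
            equal_var=False,
        )
        row["t_loud_loud_vs_quiet_loud"] = float(t)
        row["p_loud_loud_vs_quiet_loud"] = float(p)
        rows.append(row)
    return pd.DataFrame(rows)
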