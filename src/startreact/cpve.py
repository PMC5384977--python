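"""Covariance eigendecomposition and cumulative-percent-variance curves.

The fractionation statistic: from a z-scored n x 15 condition matrix,
compute the 15 x 15 muscle covariance, its eigenvalues sorted descending,
and express their running sum as a percentage of total variance (CPVE).
A CPVE curve that rises slowly indicates highly fractionated
(high-dimensional) muscle use; one that saturates after few components
indicates stereotyped coupling.

Because quiet trials are excluded at random to match the loud count, the
per-subject CPVE curve is averaged over repeated random draws (default
100); the loud curve does not depend on the draw, which
:func:`averaged_cpve` verifies rather than assumes.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd

from .windows import (
    ConditionMatrix,
    build_condition_matrix,
    exclude_and_match,
    zscore_columns,
)

__all__ = [
    "CPVECurve",
    "averaged_cpve",
    "covariance_matrix",
    "cpve_from_covariance",
    "cpve_values",
]

#: eigenvalues more negative than -RELATIVE_EIG_TOL * trace signal non-PSD input
RELATIVE_EIG_TOL = 1e-10


@dataclass
class CPVECurve:
    """Cumulative percent variance explained, one value per component."""

    values: np.ndarray
    condition: str = ""
    subject_id: str = ""
    window: str = ""
    n_trials: int = 0
    repeats: int = 1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.values) < -1e-9):
            raise ValueError("CPVE curve must be nondecreasing")
        if abs(self.values[-1] - 100.0) > 1e-6:
            raise ValueError("CPVE curve must end at 100")


def covariance_matrix(cm: ConditionMatrix) -> np.ndarray:
    """Sample covariance (n-1 denominator) of a z-scored condition matrix.

    The diagonal is 1 for every non-degenerate muscle by construction.
    """
    if not cm.zscored:
        raise ValueError("condition matrix must be z-scored first")
    if cm.n < 2:
        raise ValueError("covariance requires at least 2 trials")
    c = np.cov(cm.matrix, rowvar=False, ddof=1)
    return (c + c.T) / 2.0


def cpve_values(cov: np.ndarray) -> np.ndarray:
    """CPVE from a symmetric covariance matrix.

    Eigenvalues are clipped at zero when their negativity is numerical
    noise (magnitude below ``RELATIVE_EIG_TOL * trace``); a genuinely
    negative eigenvalue means the input was not a covariance matrix and
    raises.  An all-zero matrix has no variance to apportion and raises.
    """
    cov = np.asarray(cov, dtype=float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise ValueError("covariance must be square")
    if not np.allclose(cov, cov.T, atol=1e-8):
        raise ValueError("covariance must be symmetric")
    eig = np.linalg.eigvalsh(cov)
    trace = float(np.trace(cov))
    if trace <= 0:
        raise ValueError("zero total variance: all-zero covariance")
    if eig.min() < -RELATIVE_EIG_TOL * max(trace, 1.0):
        raise ValueError(f"covariance is not PSD (min eigenvalue {eig.min():g})")
    eig = np.clip(eig, 0.0, None)[::-1]  # descending
    pve = 100.0 * eig / eig.sum()
    cpve = np.cumsum(pve)
    cpve[-1] = 100.0  # pin the forced endpoint against round-off
    return cpve


def cpve_from_covariance(cov: np.ndarray, **labels) -> CPVECurve:
    """Labelled :class:`CPVECurve` from a covariance matrix."""
    return CPVECurve(values=cpve_values(cov), **labels)


def _repeat_seed(base_seed: int, subject_id: str, repeat: int) -> np.random.SeedSequence:
    """Deterministic per-(subject, repeat) seed for the quiet-exclusion draw."""
    import zlib

    subj = zlib.crc32(subject_id.encode())
    return np.random.SeedSequence([int(base_seed), subj, int(repeat)])


def averaged_cpve(
    subject_features: pd.DataFrame,
    window: str,
    repeats: int = 100,
    base_seed: int = 0,
    cutoff_ms: float = 100.0,
) -> dict[str, CPVECurve]:
    """Per-condition CPVE for one subject, averaged over exclusion draws.

    For each repeat, the quiet exclusion is redrawn with a seed derived
    from (base_seed, subject, repeat), matrices rebuilt, z-scored, and
    CPVE computed; the returned quiet curve is the mean across repeats.
    The loud curve is unaffected by the draw — this invariance is asserted
    on the first two repeats instead of being assumed.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    subject_id = str(subject_features["subject_id"].iloc[0])
    quiet_curves = []
    loud_curve = None
    loud_keys_first = None
    n_trials = {}
    for r in range(repeats):
        match = exclude_and_match(
            subject_features, cutoff_ms=cutoff_ms,
            seed=_repeat_seed(base_seed, subject_id, r),
        )
        if r == 0:
            loud_keys_first = list(match.included_loud)
        elif r == 1 and list(match.included_loud) != loud_keys_first:
            raise AssertionError(
                "loud inclusion changed across repeats; the loud exclusion "
                "must be deterministic"
            )
        for cue, included in (
            ("quiet", match.included_quiet), ("loud", match.included_loud)
        ):
            if cue == "loud" and loud_curve is not None:
                continue
            cm = build_condition_matrix(
                subject_features, included, subject_id, cue, window
            )
            curve = cpve_values(covariance_matrix(zscore_columns(cm)))
            n_trials[cue] = cm.n
            if cue == "loud":
                loud_curve = curve
            else:
                quiet_curves.append(curve)
    out = {
        "quiet": CPVECurve(
            values=np.mean(quiet_curves, axis=0),
            condition="quiet",
            subject_id=subject_id,
            window=window,
            n_trials=n_trials["quiet"],
            repeats=repeats,
        ),
        "loud": CPVECurve(
            values=loud_curve,
            condition="loud",
            subject_id=subject_id,
            window=window,
            n_trials=n_trials["loud"],
            repeats=repeats,
        ),
    }
    return out
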