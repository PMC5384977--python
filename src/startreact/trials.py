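"""Trial-structured surface-EMG data model and plain-text disk I/O.

A :class:`Trial` is the atomic unit of a StartReact experiment: one cued
movement, recorded as a muscles x samples array of signed EMG amplitude
around an auditory stimulus.  A :class:`TrialSet` is a validated collection
of trials sharing one muscle montage, typically 10 subjects x 32 tasks x
5 trials per cue (quiet/loud).

The normative on-disk layout is deliberately human-inspectable: a
``trials.csv`` metadata table plus one CSV per trial (first column
``time_ms``, one column per muscle).  Values are written with >= 10
significant digits so that write -> read is an identity within floating
precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

__all__ = [
    "CUES",
    "DEFAULT_MUSCLES",
    "Trial",
    "TrialKey",
    "TrialSet",
    "TrialSetError",
    "read_trialset",
    "write_trialset",
]

CUES = ("quiet", "loud")

#: The 15-muscle upper-limb montage used throughout: intrinsic hand
#: (1DI, AbPB, AbDM), extrinsic wrist/finger flexors and extensors,
#: elbow flexors/extensor, and shoulder girdle.
DEFAULT_MUSCLES = (
    "1DI", "AbPB", "AbDM", "FDS", "FCU", "FCR", "ECU", "ECR", "EDC",
    "BR", "BIC", "TRI", "DeltA", "DeltP", "Pec",
)

METADATA_FILE = "trials.csv"
_META_COLUMNS = [
    "subject_id", "task_id", "cue", "trial_index",
    "stimulus_time_ms", "sample_rate_hz", "signal_file",
]
_FLOAT_FMT = "%.10g"


class TrialSetError(ValueError):
    """Raised for malformed trials, duplicate keys, or unreadable stores."""


@dataclass(frozen=True)
class TrialKey:
    """Unique identifier of a trial within an experiment."""

    subject_id: str
    task_id: str
    cue: str
    trial_index: int

    def __str__(self) -> str:  # used in filenames and error messages
        return f"{self.subject_id}_{self.task_id}_{self.cue}_{self.trial_index}"


@dataclass
class Trial:
    """One cued movement: signal array plus acquisition metadata.

    Parameters
    ----------
    subject_id, task_id : str
        Labels; the default synthetic design uses ``S01..S10`` / ``T01..T32``.
    cue : {"quiet", "loud"}
        Auditory cue intensity condition.
    trial_index : int
        1-based repetition index within (subject, task, cue).
    stimulus_time_ms : float
        Cue time, milliseconds from the first sample of ``signal``.
    sample_rate_hz : float
        Sampling rate; 5000 Hz in the default design.
    muscles : sequence of str
        Ordered unique muscle labels, one per signal row.
    signal : ndarray, shape (n_muscles, n_samples)
        Signed EMG amplitude (arbitrary microvolt-like units).
    """

    subject_id: str
    task_id: str
    cue: str
    trial_index: int
    stimulus_time_ms: float
    sample_rate_hz: float
    muscles: tuple[str, ...]
    signal: np.ndarray

    def __post_init__(self) -> None:
        if self.cue not in CUES:
            raise TrialSetError(f"cue must be one of {CUES}, got {self.cue!r}")
        if self.sample_rate_hz <= 0:
            raise TrialSetError("sample_rate_hz must be positive")
        if int(self.trial_index) < 1:
            raise TrialSetError("trial_index must be >= 1")
        self.muscles = tuple(str(m) for m in self.muscles)
        if len(set(self.muscles)) != len(self.muscles):
            raise TrialSetError("muscle labels must be unique")
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2 or self.signal.shape[0] != len(self.muscles):
            raise TrialSetError(
                f"signal must be (n_muscles={len(self.muscles)}, n_samples); "
                f"got shape {self.signal.shape}"
            )
        if not np.all(np.isfinite(self.signal)):
            raise TrialSetError(f"trial {self.key}: signal contains non-finite values")

    @property
    def key(self) -> TrialKey:
        return TrialKey(self.subject_id, self.task_id, self.cue, int(self.trial_index))

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    def times_ms(self) -> np.ndarray:
        """Sample times in ms from the start of the recording."""
        return np.arange(self.n_samples) * (1000.0 / self.sample_rate_hz)

    def rel_times_ms(self) -> np.ndarray:
        """Sample times in ms relative to the stimulus (negative = baseline)."""
        return self.times_ms() - self.stimulus_time_ms

    def covers_ms(self, start_rel_ms: float, end_rel_ms: float) -> bool:
        """Whether the recording spans [start, end] ms around the stimulus."""
        t = self.rel_times_ms()
        return bool(t[0] <= start_rel_ms and t[-1] >= end_rel_ms)


@dataclass
class TrialSet:
    """A validated collection of trials sharing one muscle montage.

    ``design`` carries the experiment layout (subjects, tasks,
    trials-per-cue) and ``provenance`` the generator seed or source path.
    """

    trials: list[Trial] = field(default_factory=list)
    design: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen: set[TrialKey] = set()
        muscles = None
        for trial in self.trials:
            if trial.key in seen:
                raise TrialSetError(f"duplicate trial key: {trial.key}")
            seen.add(trial.key)
            if muscles is None:
                muscles = trial.muscles
            elif trial.muscles != muscles:
                raise TrialSetError(
                    f"trial {trial.key}: muscle ordering {trial.muscles} "
                    f"differs from the set's {muscles}"
                )

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self) -> Iterator[Trial]:
        return iter(self.trials)

    @property
    def muscles(self) -> tuple[str, ...]:
        if not self.trials:
            return tuple(self.design.get("muscles", ()))
        return self.trials[0].muscles

    @property
    def subjects(self) -> list[str]:
        return sorted({t.subject_id for t in self.trials})

    def by_subject(self, subject_id: str) -> list[Trial]:
        return [t for t in self.trials if t.subject_id == subject_id]

    def get(self, key: TrialKey) -> Trial:
        for t in self.trials:
            if t.key == key:
                return t
        raise KeyError(str(key))


def write_trialset(trialset: TrialSet, path: str | Path) -> None:
    """Write a TrialSet to ``path`` as ``trials.csv`` plus per-trial CSVs.

    An empty set yields a header-only ``trials.csv`` and no signal files.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    rows = []
    for trial in trialset:
        fname = f"signal_{trial.key}.csv"
        rows.append(
            {
                "subject_id": trial.subject_id,
                "task_id": trial.task_id,
                "cue": trial.cue,
                "trial_index": trial.trial_index,
                "stimulus_time_ms": trial.stimulus_time_ms,
                "sample_rate_hz": trial.sample_rate_hz,
                "signal_file": fname,
            }
        )
        sig = pd.DataFrame(trial.signal.T, columns=list(trial.muscles))
        sig.insert(0, "time_ms", trial.times_ms())
        sig.to_csv(path / fname, index=False, float_format=_FLOAT_FMT)
    meta = pd.DataFrame(rows, columns=_META_COLUMNS)
    meta.to_csv(path / METADATA_FILE, index=False, float_format=_FLOAT_FMT)


def read_trialset(path: str | Path) -> TrialSet:
    """Read a TrialSet written by :func:`write_trialset`.

    Validation failures are reported with the offending trial key.
    """
    path = Path(path)
    meta_path = path / METADATA_FILE
    if not meta_path.exists():
        raise TrialSetError(f"missing metadata file: {meta_path}")
    meta = pd.read_csv(meta_path, dtype={"subject_id": str, "task_id": str})
    missing = [c for c in _META_COLUMNS if c not in meta.columns]
    if missing:
        raise TrialSetError(f"trials.csv missing columns: {missing}")
    trials = []
    for row in meta.itertuples(index=False):
        key = TrialKey(str(row.subject_id), str(row.task_id), str(row.cue),
                       int(row.trial_index))
        sig_path = path / str(row.signal_file)
        if not sig_path.exists():
            raise TrialSetError(f"trial {key}: signal file not found: {sig_path}")
        sig = pd.read_csv(sig_path)
        if sig.columns[0] != "time_ms":
            raise TrialSetError(f"trial {key}: first signal column must be time_ms")
        muscles = tuple(sig.columns[1:])
        if sig.isna().any().any():
            raise TrialSetError(f"trial {key}: missing values in signal file")
        trials.append(
            Trial(
                subject_id=key.subject_id,
                task_id=key.task_id,
                cue=key.cue,
                trial_index=key.trial_index,
                stimulus_time_ms=float(row.stimulus_time_ms),
                sample_rate_hz=float(row.sample_rate_hz),
                muscles=muscles,
                signal=sig[list(muscles)].to_numpy().T,
            )
        )
    return TrialSet(trials=trials, provenance={"source_path": str(path)})
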