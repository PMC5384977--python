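"""Shared fixtures: small synthetic experiments and canned feature tables."""

import numpy as np
import pandas as pd
import pytest

import startreact as sr
from startreact.windows import KEY_COLUMNS


@pytest.fixture(scope="session")
def tiny_experiment():
    """2 subjects x 3 tasks x 3 trials/cue; fast, full signal path."""
    cfg = sr.SynthConfig(n_subjects=2, n_tasks=3, trials_per_cue=3, seed=101)
    trialset, truth = sr.generate_experiment(cfg)
    return cfg, trialset, truth


@pytest.fixture(scope="session")
def small_experiment():
    """1 subject x 8 tasks x 5 trials/cue with moderate noise."""
    cfg = sr.SynthConfig(n_subjects=1, n_tasks=8, trials_per_cue=5, seed=202)
    trialset, truth = sr.generate_experiment(cfg)
    return cfg, trialset, truth


def make_features(
    n_tasks: int,
    trials_per_cue: int,
    muscles: int = 15,
    subject: str = "S01",
    windows=("0-10",),
    ert_quiet: float = 200.0,
    ert_loud: float = 80.0,
    pattern_fn=None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Directly construct a long-format window-feature table.

    ``pattern_fn(task_index) -> 15-vector`` sets each task's mean activation
    (default: distinct nonnegative patterns); per-trial Gaussian noise of SD
    ``noise_sd`` is added and clipped at zero to stay rectified-mean-like.
    """
    rng = np.random.default_rng(seed)
    cols = [f"M{i:02d}" for i in range(muscles)]
    if pattern_fn is None:
        base = rng.uniform(0.5, 10.0, size=(n_tasks, muscles))
        pattern_fn = lambda k: base[k]  # noqa: E731
    rows = []
    for k in range(n_tasks):
        pat = np.asarray(pattern_fn(k), dtype=float)
        for cue, ert in (("quiet", ert_quiet), ("loud", ert_loud)):
            for j in range(trials_per_cue):
                vec = np.clip(pat + rng.normal(0, noise_sd, muscles), 0, None)
                for window in windows:
                    rows.append(
                        {
                            "subject_id": subject,
                            "task_id": f"T{k + 1:02d}",
                            "cue": cue,
                            "trial_index": j + 1,
                            "window": window,
                            "ert_ms": ert,
                            **dict(zip(cols, vec)),
                        }
                    )
    return pd.DataFrame(
        rows, columns=KEY_COLUMNS + ["window", "ert_ms"] + cols
    )
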