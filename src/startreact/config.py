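"""Pipeline configuration: flat key-value files, defaults, validation.

The config file is a flat YAML mapping (no nesting).  Analysis keys carry
the canonical defaults (200 ms baseline, 3 SD threshold, 100 ms loud
cutoff, 100 exclusion repeats, family-wise bound 51/1,024, similarity
cutoff 0.8).  Generator keys are prefixed ``simulate_`` and populate a
:class:`~startreact.simulate.SynthConfig`; their presence switches the
pipeline to synthetic input.  Unknown keys are errors, not warnings.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

from .simulate import SynthConfig
from .windows import DEFAULT_WINDOWS, WindowSpec

__all__ = ["PipelineConfig", "validate_config", "write_effective_config"]

_SIM_PREFIX = "simulate_"


@dataclass
class PipelineConfig:
    """Every tunable of the end-to-end analysis."""

    input_dir: str | None = None
    output_dir: str = "startreact_out"
    simulate: SynthConfig | None = None
    baseline_ms: float = 200.0
    k_sd: float = 3.0
    search_limit_ms: float = 500.0
    debounce_ms: float = 1.0
    cutoff_ms: float = 100.0
    windows: tuple[tuple[float, float], ...] = DEFAULT_WINDOWS
    repeats: int = 100
    target_count: int = 51
    similarity_cutoff: float = 0.8
    seed: int = 0

    def validate(self) -> None:
        if self.baseline_ms <= 0 or self.search_limit_ms <= 0:
            raise ValueError("baseline_ms and search_limit_ms must be positive")
        if self.k_sd < 0 or self.debounce_ms < 0:
            raise ValueError("k_sd and debounce_ms must be >= 0")
        if self.cutoff_ms <= 0:
            raise ValueError("cutoff_ms must be positive")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if self.target_count < 0:
            raise ValueError("target_count must be >= 0")
        if not 0 <= self.similarity_cutoff <= 1:
            raise ValueError("similarity_cutoff must lie in [0, 1]")
        WindowSpec(tuple(tuple(w) for w in self.windows))  # raises if invalid
        if self.simulate is not None:
            self.simulate.validate()


_SYNTH_FIELDS = {f.name: f for f in dataclasses.fields(SynthConfig)}
_PIPE_FIELDS = {
    f.name for f in dataclasses.fields(PipelineConfig) if f.name != "simulate"
}


def _parse_windows(raw) -> tuple[tuple[float, float], ...]:
    if isinstance(raw, str):
        parts = [p for p in raw.replace(";", ",").split(",") if p.strip()]
        pairs = []
        for p in parts:
            a, b = p.split("-")
            pairs.append((float(a), float(b)))
        return tuple(pairs)
    return tuple((float(a), float(b)) for a, b in raw)


def validate_config(path: str | Path) -> PipelineConfig:
    """Parse, default and validate a flat config file.

    An empty file yields the all-defaults configuration.  Windows may be
    written compactly, e.g. ``windows: 0-10, 10-20, 20-30, 50-100``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a flat key: value mapping")
    cfg_kwargs: dict = {}
    sim_kwargs: dict = {}
    for key, value in raw.items():
        if key in _PIPE_FIELDS:
            cfg_kwargs[key] = _parse_windows(value) if key == "windows" else value
        elif key.startswith(_SIM_PREFIX) and key[len(_SIM_PREFIX):] in _SYNTH_FIELDS:
            name = key[len(_SIM_PREFIX):]
            sim_kwargs[name] = tuple(value) if name == "muscles" else value
        else:
            raise ValueError(f"unknown config key: {key!r}")
    cfg = PipelineConfig(**cfg_kwargs)
    if sim_kwargs:
        cfg.simulate = SynthConfig(**sim_kwargs)
    cfg.validate()
    return cfg


def write_effective_config(cfg: PipelineConfig, path: str | Path) -> None:
    """Emit the fully defaulted config so it re-parses to an equal config."""
    out: dict = {}
    for name in sorted(_PIPE_FIELDS):
        value = getattr(cfg, name)
        if name == "windows":
            value = ", ".join(f"{a:g}-{b:g}" for a, b in value)
        out[name] = value
    if cfg.simulate is not None:
        for name, f in _SYNTH_FIELDS.items():
            value = getattr(cfg.simulate, name)
            if isinstance(value, tuple):
                value = list(value)
            out[_SIM_PREFIX + name] = value
    Path(path).write_text(yaml.safe_dump(out, sort_keys=True))
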