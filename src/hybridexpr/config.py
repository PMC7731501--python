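"""Run configuration for the pipeline CLI."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml


class ConfigError(Exception):
    """Invalid configuration (missing files, out-of-range thresholds)."""


class DataError(Exception):
    """Inconsistent input data (missing groups, sample/site mismatches)."""


@dataclass
class RunConfig:
    counts: str | None = None
    lengths: str | None = None
    metadata: str | None = None
    soil: str | None = None
    go_edges: str | None = None
    annotations: str | None = None
    outdir: str = "hybridexpr_out"
    seed: int = 0
    log_level: str = "INFO"
    # thresholds
    fdr_max: float = 0.001
    min_abs_log2fc: float = 5.0
    min_total_count: int = 10
    lfmm_k: int = 2
    ridge_lambda: float = 1e-5
    alpha: float = 0.05
    elim_cutoff: float = 0.01
    sim_threshold: float = 0.5
    min_genes: int = 5

    def validate(self, require_inputs: bool = True) -> None:
        if not 0 < self.fdr_max <= 1:
            raise ConfigError("fdr_max must be in (0, 1]")
        if self.min_abs_log2fc < 0:
            raise ConfigError("min_abs_log2fc must be non-negative")
        if self.min_total_count < 0:
            raise ConfigError("min_total_count must be non-negative")
        if self.lfmm_k < 0:
            raise ConfigError("lfmm_k must be non-negative")
        if self.ridge_lambda <= 0:
            raise ConfigError("ridge_lambda must be positive")
        for name in ("alpha", "elim_cutoff"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must be in [0, 1]")
        if not 0 <= self.sim_threshold <= 1:
            raise ConfigError("sim_threshold must be in [0, 1]")
        if require_inputs:
            for name in ("counts", "lengths", "metadata"):
                path = getattr(self, name)
                if path is None:
                    raise ConfigError(f"config is missing the {name} path")
                if not Path(path).exists():
                    raise ConfigError(f"{name} file not found: {path}")
            for name in ("soil", "go_edges", "annotations"):
                path = getattr(self, name)
                if path is not None and not Path(path).exists():
                    raise ConfigError(f"{name} file not found: {path}")


def load_config(path: str | Path, **overrides) -> RunConfig:
    """Read a YAML config file; keyword overrides win over file values."""
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    except OSError as exc:
        raise ConfigError(f"cannot read config file {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError("config file must hold a mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    raw.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**raw)
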