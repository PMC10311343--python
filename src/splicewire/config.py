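"""Run configuration: one YAML file, strict keys, CLI flags win."""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields
from pathlib import Path

import yaml

from .prior import ConfigurationError


@dataclass
class RunConfig:
    """Resolved settings of one inference run.

    Paths are stored absolute (resolved against the config file's directory);
    ``evidence: null`` selects a splice-unaware run. ``alpha``/``beta`` of
    None defer to the objective's documented defaults.
    """

    interactions: str = "interactions.tsv"
    regulons: str = "regulons.tsv"
    gene_stats: str = "gene_stats.tsv"
    evidence: str | None = "evidence.tsv"
    gene_sets: str | None = None
    roots: list | None = None
    mode: str = "hard"
    p_skip: float = 0.05
    p_tf: float = 0.05
    n_perm: int = 1000
    alpha: float | None = None
    lam: float = 0.01
    beta: float | None = None
    backend: str = "highs"
    time_limit_s: float = 3600.0
    mip_gap: float = 0.0
    threads: int = 1
    seed: int = 0
    k_max: int = 10
    tolerance: float = 0.0
    output_dir: str = "results"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        base = path.parent
        for attr in ("interactions", "regulons", "gene_stats", "evidence", "gene_sets"):
            value = getattr(cfg, attr)
            if value is not None and not Path(value).is_absolute():
                setattr(cfg, attr, str(base / value))
        if not Path(cfg.output_dir).is_absolute():
            cfg.output_dir = str(base / cfg.output_dir)
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)
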