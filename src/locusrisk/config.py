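"""Run configuration: every tunable in one YAML-serializable object."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .gibbs import SamplerConfig

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """All tunables for an end-to-end run.

    window_bp: candidate window per side around each index SNP (bp).
    n_components: retained decorrelated components ("auto" drops numerically
        null directions only).
    tail: which normal tail converts oriented components to p-values.
    restart_prob: RWR restart probability r.
    combine: multi-network combination rule for the prior.
    e_gibbs: convergence threshold on ||Freq_i - Freq_{i-1}||_2.
    """

    window_bp: int = 1_000_000
    n_components: int | str = "auto"
    tail: str = "upper"
    boxcox_interval: tuple[float, float] = (-5.0, 5.0)
    restart_prob: float = 0.5
    rwr_tol: float = 1e-10
    floor_eps: float = 1e-6
    combine: str = "mean"
    go_jaccard_threshold: float = 0.3
    e_gibbs: float = 0.01
    min_sweeps: int = 10
    max_sweeps: int = 5_000
    seed: int = 0
    scan: str = "systematic"
    pp_source: str = "cycle2"
    top_fraction: float = 0.10
    distance_mode: str = "interval"  # or "tss"
    pvalue_columns: list[str] = field(default_factory=list)
    continuous_columns: list[str] = field(default_factory=list)

    def sampler(self) -> SamplerConfig:
        return SamplerConfig(
            e_gibbs=self.e_gibbs,
            min_sweeps=self.min_sweeps,
            max_sweeps=self.max_sweeps,
            seed=self.seed,
            restart_prob=self.restart_prob,
            floor_eps=self.floor_eps,
            combine=self.combine,
            scan=self.scan,
            pp_source=self.pp_source,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["boxcox_interval"] = list(self.boxcox_interval)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with Path(path).open() as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "boxcox_interval" in data:
            data["boxcox_interval"] = tuple(data["boxcox_interval"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
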