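"""Run configuration: a flat YAML file with nested kernel/sampling blocks.

CLI flags override file values; every output artifact embeds the resolved
configuration and base seed so runs are reproducible end to end.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import evaluation, gpr, sampling

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """Everything a benchmark run needs, resolvable from YAML + CLI flags."""

    map_paths: list[str] = field(default_factory=list)
    preset: str | None = None
    n_maps: int = 4
    families: list[str] = field(
        default_factory=lambda: ["rbf", "matern15", "hybrid"]
    )
    strategies: list[str] = field(
        default_factory=lambda: ["uniform", "spatial", "adaptive"]
    )
    n_grid: list[int] = field(default_factory=lambda: [10, 20, 30, 40, 50])
    iterations: int = 10
    base_seed: int = 0
    use_log: bool = True
    n_restarts: int = 10
    include_censored: bool = False
    adaptive_n_init: int = 5
    output_dir: str = "threshmap-out"

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.n_grid):
            raise ValueError("n_grid entries must be positive")
        self.n_grid = sorted(self.n_grid)
        if not self.map_paths and self.preset is None:
            raise ValueError("config must name map files or a synthetic preset")

    def eval_config(self) -> evaluation.EvalConfig:
        return evaluation.EvalConfig(
            gp=gpr.GPConfig(use_log=self.use_log, n_restarts=self.n_restarts),
            include_censored=self.include_censored,
            adaptive_n_init=self.adaptive_n_init,
            pds_params=sampling.PDSParams(),
        )

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def load_config(path: str | Path | None, **overrides) -> RunConfig:
    """Read a YAML config (flat keys, nested ``gpr``/``sampling`` blocks) and
    apply non-None keyword overrides."""
    data: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for block in ("gpr", "sampling"):
            data.update(raw.pop(block, None) or {})
        data.update(raw)
    data.update({k: v for k, v in overrides.items() if v is not None})
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)
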