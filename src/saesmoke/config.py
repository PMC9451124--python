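"""Pipeline configuration: a single YAML file, strictly validated.

Unknown keys are rejected at load time so typos fail fast; CLI flags may
override ``seed`` and ``outdir`` after loading.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

_TOP_KEYS = {"outdir", "seed", "verbose", "simulate", "inputs", "model", "ladder", "sam"}
_SIM_KEYS = {
    "n_areas", "layout", "n_insample_areas", "clusters_per_area",
    "persons_per_cluster", "icc", "missingness", "mean_population",
    "sigma", "phi",
}
_INPUT_KEYS = {"microdata", "adjacency", "population", "mortality"}
_MODEL_KEYS = {"covariates", "pc_u", "pc_alpha", "n_chains", "n_iter", "burn_in", "thin"}
_SAM_KEYS = {"n_draws", "rr_study", "rr_mapping", "rr_table"}


@dataclass
class PipelineConfig:
    outdir: str = "out"
    seed: int = 0
    verbose: bool = False
    simulate: dict | None = None
    inputs: dict | None = None
    model: dict = field(default_factory=dict)
    ladder: list = field(
        default_factory=lambda: ["heavy", "heavy_moderate", "current", "ever"]
    )
    sam: dict = field(default_factory=dict)

    def __post_init__(self):
        if not isinstance(self.seed, int) or self.seed < 0:
            raise ValueError("seed must be a non-negative integer")
        if self.simulate is None and self.inputs is None:
            raise ValueError("config needs either a 'simulate' block or 'inputs' paths")
        for block, allowed, name in (
            (self.simulate, _SIM_KEYS, "simulate"),
            (self.inputs, _INPUT_KEYS, "inputs"),
            (self.model, _MODEL_KEYS, "model"),
            (self.sam, _SAM_KEYS, "sam"),
        ):
            if block is None:
                continue
            unknown = set(block) - allowed
            if unknown:
                raise ValueError(f"unknown keys in '{name}' block: {sorted(unknown)}")
        if self.inputs is not None:
            missing_keys = _INPUT_KEYS - set(self.inputs)
            if missing_keys:
                raise ValueError(f"'inputs' block lacks {sorted(missing_keys)}")
            for k, p in self.inputs.items():
                if not Path(p).exists():
                    raise ValueError(f"input path for {k!r} does not exist: {p}")


def load_config(path, **overrides) -> PipelineConfig:
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
    raw.update({k: v for k, v in overrides.items() if v is not None})
    return PipelineConfig(**raw)
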