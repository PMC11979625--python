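"""Scenario and pipeline configuration with strict validation."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any

import yaml


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of one synthetic study scenario.

    Defaults mirror desk-scale versions of the study design this package
    emulates: two case-control GWAS of a few thousand samples each read out
    as summary z-scores, a ~400-sample protein-weight training panel, and
    sparse cis-genetic control of protein abundance.
    """

    n_variants: int = 20_000
    n_blocks: int = 200
    block_rho: float = 0.8            # within-block AR(1) LD decay
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_genes: int = 50
    cis_window_bp: int = 40_000       # full window width around the gene center
    h2_cis: float = 0.3               # cis heritability of protein abundance
    n_causal_cis: int = 1             # causal cis-SNPs per gene
    n_ref: int = 400                  # weight-training sample size
    pi_shared: float = 0.002          # fraction of variants causal for both traits
    pi1: float = 0.002                # trait-1 only
    pi2: float = 0.002                # trait-2 only
    sigma_beta: float = 0.05          # per-causal-variant effect SD
    n_gwas1: int = 8_477              # trait-1 GWAS sample size
    n_gwas2: int = 6_618              # trait-2 GWAS sample size
    seed: int = 0

    def __post_init__(self):
        counts = {
            "n_variants": self.n_variants,
            "n_blocks": self.n_blocks,
            "n_genes": self.n_genes,
            "cis_window_bp": self.cis_window_bp,
            "n_ref": self.n_ref,
            "n_gwas1": self.n_gwas1,
            "n_gwas2": self.n_gwas2,
        }
        for name, value in counts.items():
            if int(value) != value or value <= 0:
                raise ValueError(f"{name} must be a positive integer, got {value}")
        if self.n_causal_cis < 0:
            raise ValueError(f"n_causal_cis must be >= 0, got {self.n_causal_cis}")
        if self.n_blocks > self.n_variants:
            raise ValueError("n_blocks cannot exceed n_variants")
        if not (0 <= self.block_rho < 1):
            raise ValueError(f"block_rho must lie in [0, 1), got {self.block_rho}")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must satisfy 0 < low <= high <= 0.5, got {self.maf_range}")
        if not (0 <= self.h2_cis <= 1):
            raise ValueError(f"h2_cis must lie in [0, 1], got {self.h2_cis}")
        for name in ("pi_shared", "pi1", "pi2"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.pi_shared + self.pi1 + self.pi2 > 1:
            raise ValueError("pi_shared + pi1 + pi2 must not exceed 1")
        if self.sigma_beta < 0:
            raise ValueError(f"sigma_beta must be nonnegative, got {self.sigma_beta}")

    def replace(self, **kwargs) -> "ScenarioConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class PlantedConfig:
    """End-to-end planting: genes that are simultaneously cis-regulators of
    their protein, shared causal for both traits, and shifted in expression."""

    n_genes: int = 0
    lead_z: float = 6.5               # target |z| of the planted shared variant
    expression_shift: float = -2.0    # case-group shift, in baseline SDs


@dataclass
class StageToggles:
    simulate: bool = True
    fit_weights: bool = True
    pwas: bool = True
    pleiofdr: bool = True
    de: bool = True


@dataclass
class PwasOptions:
    model: str = "best"               # "best" or a fixed model family
    mt_method: str = "bh_fdr"         # bh_fdr | bonferroni
    alpha: float = 0.05
    min_overlap: float = 0.5
    k_folds: int = 5


@dataclass
class PleiofdrOptions:
    conjfdr_threshold: float = 0.01
    r2_prune: float = 0.1
    prune_iters: int = 100
    r2_clump: float = 0.1
    grid_max: float = 10.0
    grid_n: int = 101
    gene_flank_bp: int = 0
    exclude_regions: list = field(default_factory=list)


@dataclass
class DeOptions:
    alpha: float = 0.05
    case_group: str = "case"
    control_group: str = "control"
    n_case: int = 10
    n_control: int = 10


@dataclass
class PipelineConfig:
    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    planted: PlantedConfig = field(default_factory=PlantedConfig)
    stages: StageToggles = field(default_factory=StageToggles)
    pwas: PwasOptions = field(default_factory=PwasOptions)
    pleiofdr: PleiofdrOptions = field(default_factory=PleiofdrOptions)
    de: DeOptions = field(default_factory=DeOptions)
    out_dir: str | None = None
    seed: int = 0


def _build(cls, data: Any, path: str):
    """Recursively build a dataclass from a mapping, rejecting unknown keys."""
    if not dataclasses.is_dataclass(cls):
        return data
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping, got {type(data).__name__}")
    known = {f.name: f for f in fields(cls)}
    unknown = sorted(set(data) - set(known))
    if unknown:
        raise ValueError(f"{path}: unknown configuration keys {unknown}")
    kwargs = {}
    for name, value in data.items():
        f = known[name]
        if dataclasses.is_dataclass(f.type) or (
            isinstance(f.type, str) and f.type in _NESTED
        ):
            kwargs[name] = _build(_NESTED[f.type if isinstance(f.type, str) else f.type.__name__], value, f"{path}.{name}")
        elif name == "maf_range" and isinstance(value, (list, tuple)):
            kwargs[name] = tuple(value)
        else:
            kwargs[name] = value
    return cls(**kwargs)


_NESTED = {
    "ScenarioConfig": ScenarioConfig,
    "PlantedConfig": PlantedConfig,
    "StageToggles": StageToggles,
    "PwasOptions": PwasOptions,
    "PleiofdrOptions": PleiofdrOptions,
    "DeOptions": DeOptions,
}


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    """Load a YAML pipeline configuration, failing fast on unknown keys."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return _build(PipelineConfig, data, "config")


def dump_pipeline_config(config: PipelineConfig, path: str | Path) -> None:
    """Write the fully-resolved configuration next to a run's outputs."""
    data = dataclasses.asdict(config)
    data["scenario"]["maf_range"] = list(data["scenario"]["maf_range"])
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
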