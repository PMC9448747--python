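"""Pipeline configuration: one block per stage, defaults matching the
published parameter values (merge distance 50 bp; filter call rate 0.5,
MAC 3, quality 30; top 0.5% FST; 150 bp flanks; DE p < 0.05 and
|log2FC| >= 1; QC gene floors 300/500 and 20% mito; resolutions 0.5 and
0.1; 20/30 PCs; novelty threshold r < 0.31)."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields

from .simulate import SimConfig


@dataclass
class MergeConfig:
    max_dist_bp: int = 50
    require_type_match: bool = True
    min_support: int = 1


@dataclass
class FilterConfig:
    max_missing: float = 0.5
    mac: int = 3
    min_qual: float = 30.0


@dataclass
class FstConfig:
    estimator: str = "weir_cockerham"
    top_fraction: float = 0.005


@dataclass
class AnnotateConfig:
    promoter_bp: int = 2000
    flank_bp: int = 150


@dataclass
class DeConfig:
    alpha: float = 0.05
    min_abs_lfc: float = 1.0


@dataclass
class ScConfig:
    min_genes_a: int = 300
    min_genes_b: int = 500
    max_mito: float = 0.20
    n_pcs: int = 20
    resolution: float = 0.5
    joint_n_pcs: int = 30
    joint_resolution: float = 0.1
    novel_r_threshold: float = 0.31
    k_neighbors: int = 20


@dataclass
class PipelineConfig:
    seed: int = 0
    ortholog_fraction_shared: float = 0.9
    sim: SimConfig = field(default_factory=SimConfig)
    merge: MergeConfig = field(default_factory=MergeConfig)
    filter: FilterConfig = field(default_factory=FilterConfig)
    fst: FstConfig = field(default_factory=FstConfig)
    annotate: AnnotateConfig = field(default_factory=AnnotateConfig)
    de: DeConfig = field(default_factory=DeConfig)
    sc: ScConfig = field(default_factory=ScConfig)

    def validate(self) -> None:
        if not 0 < self.fst.top_fraction <= 1:
            raise ValueError("fst.top_fraction must be in (0, 1]")
        if self.fst.estimator not in ("weir_cockerham", "hudson"):
            raise ValueError(f"unknown fst.estimator {self.fst.estimator!r}")
        if not 0 <= self.filter.max_missing <= 1:
            raise ValueError("filter.max_missing must be in [0, 1]")
        if self.merge.max_dist_bp < 0:
            raise ValueError("merge.max_dist_bp must be >= 0")
        if not 0 <= self.sc.max_mito <= 1:
            raise ValueError("sc.max_mito must be in [0, 1]")
        if not 0 <= self.ortholog_fraction_shared <= 1:
            raise ValueError("ortholog_fraction_shared must be in [0, 1]")
        self.sim.validate()

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        kwargs = {}
        block_types = {f.name: f.type for f in fields(cls)}
        blocks = {
            "sim": SimConfig, "merge": MergeConfig, "filter": FilterConfig,
            "fst": FstConfig, "annotate": AnnotateConfig, "de": DeConfig, "sc": ScConfig,
        }
        for key, value in data.items():
            if key in blocks:
                block_cls = blocks[key]
                known = {f.name for f in fields(block_cls)}
                extra = set(value) - known
                if extra:
                    raise ValueError(f"unknown config key(s) {key}.{sorted(extra)}")
                kwargs[key] = block_cls(**value)
            elif key in block_types:
                kwargs[key] = value
            else:
                raise ValueError(f"unknown config key {key!r}")
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)


def default_synthetic_config(seed: int = 0) -> PipelineConfig:
    """Defaults sized for the synthetic end-to-end run.

    The QC gene floors are lowered to 100 because the synthetic gene
    universe (200 genes) is far smaller than a real transcriptome; every
    other threshold keeps its published default.
    """
    cfg = PipelineConfig(seed=seed, sim=SimConfig(seed=seed))
    cfg.sc.min_genes_a = 100
    cfg.sc.min_genes_b = 100
    return cfg
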