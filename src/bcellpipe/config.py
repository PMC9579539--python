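"""Pipeline configuration: one structured block per stage, YAML-loadable."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .demux import DemuxParams
from .kinetics import FitOptions, PreprocessParams
from .synthetic.elisa import LogisticParams
from .synthetic.expression import ExpressionConfig
from .synthetic.hashtags import HashtagConfig
from .synthetic.repertoire import RepertoireConfig
from .synthetic.spr import SprConfig
from .transcriptome import ClusterParams


@dataclass
class StageToggles:
    demux: bool = True
    repertoire: bool = True
    transcriptome: bool = True
    kinetics: bool = True


@dataclass
class PipelineConfig:
    outdir: str = "pipeline_out"
    seed: int = 0
    stages: StageToggles = field(default_factory=StageToggles)
    repertoire: RepertoireConfig = field(default_factory=RepertoireConfig)
    hashtags: HashtagConfig = field(default_factory=HashtagConfig)
    demux_params: DemuxParams = field(default_factory=DemuxParams)
    expression: ExpressionConfig = field(default_factory=ExpressionConfig)
    cluster_params: ClusterParams = field(default_factory=ClusterParams)
    spr: SprConfig = field(default_factory=SprConfig)
    elisa: LogisticParams = field(default_factory=LogisticParams)
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    fit_options: FitOptions = field(default_factory=FitOptions)

    def to_yaml(self, path: str | Path) -> None:
        blob = asdict(self)
        blob["repertoire"]["clonotypes"] = [
            [c.v_gene, c.j_gene, c.variant, c.probability]
            for c in self.repertoire.clonotypes
        ]
        blob["expression"]["marker_sets"] = {
            str(k): v for k, v in self.expression.marker_sets.items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(blob, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            blob = yaml.safe_load(fh) or {}
        return cls.from_dict(blob)

    @classmethod
    def from_dict(cls, blob: dict) -> "PipelineConfig":
        from .synthetic.repertoire import ClonotypeSpec

        kwargs: dict = {}
        if "outdir" in blob:
            kwargs["outdir"] = str(blob["outdir"])
        if "seed" in blob:
            kwargs["seed"] = int(blob["seed"])
        if "stages" in blob:
            kwargs["stages"] = StageToggles(**blob["stages"])

        simple = {
            "hashtags": HashtagConfig,
            "demux_params": DemuxParams,
            "cluster_params": ClusterParams,
            "spr": SprConfig,
            "elisa": LogisticParams,
            "preprocess": PreprocessParams,
            "fit_options": FitOptions,
        }
        for key, typ in simple.items():
            if key in blob:
                sub = dict(blob[key])
                for tup_key in ("concentrations", "log_ka_starts", "log_kd_starts", "k_range"):
                    if tup_key in sub:
                        sub[tup_key] = tuple(sub[tup_key])
                kwargs[key] = typ(**sub)
        if "repertoire" in blob:
            sub = dict(blob["repertoire"])
            if "clonotypes" in sub:
                sub["clonotypes"] = [ClonotypeSpec(*row) for row in sub["clonotypes"]]
            if "cells_per_mouse" in sub:
                sub["cells_per_mouse"] = tuple(sub["cells_per_mouse"])
            kwargs["repertoire"] = RepertoireConfig(**sub)
        if "expression" in blob:
            sub = dict(blob["expression"])
            if "marker_sets" in sub:
                sub["marker_sets"] = {int(k): list(v) for k, v in sub["marker_sets"].items()}
            if "cluster_proportions" in sub:
                sub["cluster_proportions"] = tuple(sub["cluster_proportions"])
            kwargs["expression"] = ExpressionConfig(**sub)
        return cls(**kwargs)
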