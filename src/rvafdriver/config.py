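"""Run configuration with the method's published default settings."""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """Every tunable of the pipeline, at its default.

    cap                mutations kept per gene per sample
    min_nonsyn         nonsynonymous mutations required to test a gene
    min_depth          RNA depth those mutations must reach
    min_bg_depth       RNA depth required of background synonymous mutations
    depth_percentile   cap on RNA depth before the log weight transform
    B                  bootstrap repetitions of sampling + model fit
    q_thresh           BH q-value below which a gene is called a driver
    rate_cap           upper bound on the exponential sampling rate
    rho                beta-binomial over-dispersion of the ASE test
    n_cgc_pan/type     top-rank cutoffs of the CGC score (pan-cancer / per type)
    """

    cap: int = 3
    min_nonsyn: int = 2
    min_depth: int = 8
    min_bg_depth: int = 8
    min_class_n: int = 2
    depth_percentile: float = 90.0
    B: int = 25
    q_thresh: float = 0.25
    rate_cap: float = 0.202
    rho: float = 0.05
    nmd_min_nonsense: int = 10
    include_gene_syn: bool = False
    k_grid_lo: float = 0.25
    k_grid_hi: float = 4.0
    k_grid_step: float = 0.001
    n_cgc_pan: int = 250
    n_cgc_type: int = 40
    mode: str = "per_class_min"
    seed: int = 42

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)
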