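"""Pipeline configuration: paths, thresholds, paralog maps, seed.

Defaults are the analysis constants used throughout: common-variant MAF
cutoff 0.05, per-sample minimum of 100 unique sequences, gene retention at
sequence count 10, alpha 0.05 with LD-collapsed Bonferroni correction,
major-allele cutoff 0.95 for "no allelic variation", Gabriel thresholds
(0.70 / 0.98 / 0.90 / 95%), and side-chain charge at pH 7.4.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import yaml

from .ld import GabrielThresholds
from .repertoire import DEFAULT_AMBI_MAP, DEFAULT_PARALOG_PAIRS


@dataclass
class PipelineConfig:
    # paths
    vcf: str | None = None
    airr_dir: str | None = None
    germline_fasta: str | None = None
    germline_alleles: str | None = None
    annotation_bed: str | None = None
    tfbs_bed: str | None = None
    output_dir: str = "guqtl_out"
    # thresholds
    min_maf: float = 0.05
    min_unique: int = 100
    min_count: int = 10
    alpha: float = 0.05
    major_allele_cutoff: float = 0.95
    ph: float = 7.4
    #: optional usage transformation before regression: None | logit | rankint
    usage_transform: str | None = None
    gabriel: GabrielThresholds = field(default_factory=GabrielThresholds)
    # paralog handling
    ambi_map: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_AMBI_MAP))
    paralog_pairs: list = field(default_factory=lambda: [list(p) for p in DEFAULT_PARALOG_PAIRS])
    # cohort simulation (simulate stage only)
    n_individuals: int = 150
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.min_maf <= 0.5:
            raise ValueError("min_maf must lie in [0, 0.5]")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must lie in (0, 1]")
        if self.min_unique < 0 or self.min_count < 0:
            raise ValueError("count thresholds must be non-negative")
        if not 0 < self.major_allele_cutoff <= 1:
            raise ValueError("major_allele_cutoff must lie in (0, 1]")

    def config_hash(self) -> str:
        payload = asdict(self)
        return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        gabriel = raw.pop("gabriel", None)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if gabriel:
            cfg.gabriel = GabrielThresholds(**gabriel)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str) -> None:
        payload = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)
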