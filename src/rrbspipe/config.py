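"""Pipeline configuration: defaults, YAML round-trip, validation.

Defaults encode the study design the pipeline emulates: MspI+TaqI double
digestion, 40-240 bp size selection, 114-bp single-end reads, ~99.5%
bisulfite conversion, mean-Q > 20 / min-length 30 read retention with 2-bp
end trims, >= 10x coverage per sample, FDR < 0.05 with > 25 percentage-point
effect, 2-kb promoter and 10-kb integration windows.  Genome and depth
parameters are desk-scale synthetic stand-ins.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field

import yaml

__all__ = ["PipelineConfig", "ConfigError"]


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    seed: int = 1

    # genome simulation
    n_contigs: int = 2
    contig_length: int = 10_000
    cpg_enrichment: float = 4.0
    spikein_length: int = 2_000
    genes_per_contig: int = 4

    # digestion / size selection
    enzymes: list = field(default_factory=lambda: ["MspI", "TaqI"])
    min_fragment: int = 40
    max_fragment: int = 240

    # methylome / variants
    groups: dict = field(default_factory=lambda: {"DuPi": 3, "Duroc": 3, "PiPP": 2, "PiNN": 2})
    diff_fraction: float = 0.15
    delta: float = 40.0
    snp_fraction: float = 0.011

    # reads
    read_len: int = 114
    depth: int = 30
    genomic_depth: int = 30
    conversion_rate: float = 0.995
    error_rate: float = 0.001
    spikein_mass: float = 0.01

    # QC
    min_mean_q: float = 20.0
    min_read_len: int = 30
    adapter: str = "AGATCGGAAGAGC"

    # alignment / calling
    max_mismatch: int = 2

    # differential testing
    min_coverage: int = 10
    q_threshold: float = 0.05
    diff_threshold: float = 25.0

    # variant screen
    pileup_min_cov: int = 10
    pileup_min_alt_frac: float = 0.2
    pileup_min_alt_count: int = 2

    # annotation / integration
    promoter_bp: int = 2_000
    integration_window: int = 10_000
    expression_groups: list = field(default_factory=lambda: ["Duroc", "PiNN"])
    expression_samples_per_group: int = 5
    de_fraction: float = 0.1
    effect_size: float = 2.0
    noise_sd: float = 0.5
    link_fraction: float = 1.0

    # origin attribution (F2 population and parental groups); empty disables
    origin: dict = field(default_factory=lambda: {"f2": "DuPi", "duroc": "Duroc",
                                                  "pietrain": ["PiPP", "PiNN"]})

    def validate(self) -> None:
        checks = [
            (self.seed is not None, "seed is mandatory"),
            (self.n_contigs >= 1, "n_contigs must be >= 1"),
            (self.contig_length >= 1000, "contig_length must be >= 1000"),
            (0 <= self.min_fragment <= self.max_fragment, "bad fragment size window"),
            (0 <= self.diff_fraction <= 1, "diff_fraction must be in [0, 1]"),
            (0 <= self.snp_fraction <= 1, "snp_fraction must be in [0, 1]"),
            (0 <= self.conversion_rate <= 1, "conversion_rate must be in [0, 1]"),
            (0 <= self.error_rate < 1, "error_rate must be in [0, 1)"),
            (self.read_len >= 1, "read_len must be >= 1"),
            (self.depth >= 1, "depth must be >= 1"),
            (self.min_coverage >= 1, "min_coverage must be >= 1"),
            (0 < self.q_threshold < 1, "q_threshold must be in (0, 1)"),
            (self.diff_threshold >= 0, "diff_threshold must be >= 0"),
            (len(self.groups) >= 2, "at least two groups required"),
            (all(n >= 2 for n in self.groups.values()), "each group needs >= 2 samples"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ConfigError(msg)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def hash(self) -> str:
        canon = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def sample_groups(self) -> dict[str, str]:
        """Expand {group: n} into {sample_name: group}."""
        out = {}
        for g, n in self.groups.items():
            for i in range(int(n)):
                out[f"{g}_{i + 1}"] = g
        return out
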