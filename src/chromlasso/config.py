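"""Configuration objects for the simulation and the end-to-end pipeline.

All knobs that downstream stages share (r² thresholds, top-percentile
fractions, MAF floor for matched controls, CV fold count) live here so that
a single validated object drives a reproducible run.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import yaml


class ConfigError(ValueError):
    """Raised when a configuration field violates its declared invariant."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic GWAS universe.

    The defaults describe a cohort with 500 trait-associated sentinel SNPs
    per trait, 200 chromatin feature tracks of which 20 carry planted signal
    (case coverage 0.8 against a 0.05 background), and LD blocks of 5
    proxies per sentinel whose r² decays geometrically with proxy rank.

    Parameters
    ----------
    n_snps
        Total SNPs in the universe (sentinels + proxies + null background).
    n_chroms, chrom_length
        Number of chromosomes (named ``chr1`` ...) and their length in bp.
    n_features, n_enriched_features
        Total chromatin feature tracks and how many of them carry planted
        enrichment at case SNPs.
    p_overlap_case, p_overlap_null
        Coverage probability of an enriched track at a case sentinel versus
        any background SNP. LD proxies of sentinels are covered at the
        r²-interpolated rate ``p_null + r2 * (p_case - p_null)`` so that
        marginally associated SNPs inherit part of the planted signal.
    n_case_snps
        Sentinel (case) SNPs designated per trait.
    ld_block_size
        Proxies stored per block lead; every SNP belongs to a block.
    r2_decay
        Geometric decay of r² with proxy rank; rank-k proxy gets
        ``r2_decay ** k`` plus uniform jitter.
    maf_floor, maf_ceiling
        Bounds of the uniform MAF distribution.
    eqtl_fraction
        Fraction of SNPs assigned at least one (snp, gene, tissue) eQTL row.
    motif_window
        Width in bp of the sequence window extracted around each SNP of
        interest; must fit a hexamer overlapping the SNP base.
    n_genes
        Genes placed per universe (uniformly across chromosomes).
    n_candidate_snps
        Designated "validated candidate" SNPs: high-r² proxies that receive
        an eQTL assignment and a planted allele-specific GATA motif.
    traits
        Trait names; each trait gets its own disjoint set of case sentinels.
    seed
        Master seed for all RNG streams.
    """

    n_snps: int = 20_000
    n_chroms: int = 4
    chrom_length: int = 10_000_000
    n_features: int = 200
    n_enriched_features: int = 20
    p_overlap_case: float = 0.8
    p_overlap_null: float = 0.05
    n_case_snps: int = 500
    ld_block_size: int = 5
    r2_decay: float = 0.9
    maf_floor: float = 0.05
    maf_ceiling: float = 0.5
    eqtl_fraction: float = 0.10
    motif_window: int = 41
    n_genes: int = 400
    n_candidate_snps: int = 10
    traits: tuple[str, ...] = ("plt",)
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        def bad(name: str, why: str) -> None:
            raise ConfigError(f"SimulationConfig.{name}: {why}")

        if not (0.0 < self.p_overlap_null < 1.0):
            bad("p_overlap_null", "must be in (0, 1)")
        if not (self.p_overlap_null <= self.p_overlap_case <= 1.0):
            bad("p_overlap_case",
                "must satisfy 0 < p_overlap_null <= p_overlap_case <= 1")
        if self.n_enriched_features > self.n_features:
            bad("n_enriched_features", "cannot exceed n_features")
        if self.n_case_snps * max(1, len(self.traits)) >= self.n_snps:
            bad("n_case_snps", "case SNPs (all traits) must be < n_snps")
        if self.maf_floor < 0.01:
            bad("maf_floor", "must be >= 0.01")
        if not (self.maf_floor < self.maf_ceiling <= 0.5):
            bad("maf_ceiling", "must be in (maf_floor, 0.5]")
        if not (0.0 < self.r2_decay < 1.0):
            bad("r2_decay", "must be in (0, 1)")
        if self.motif_window < 12:
            bad("motif_window", "must be >= 12 to host a hexamer "
                "overlapping the SNP base")
        if not (0.0 <= self.eqtl_fraction <= 1.0):
            bad("eqtl_fraction", "must be in [0, 1]")
        for positive in ("n_snps", "n_chroms", "chrom_length", "n_features",
                         "ld_block_size", "n_genes"):
            if getattr(self, positive) <= 0:
                bad(positive, "must be positive")
        if not self.traits:
            bad("traits", "need at least one trait name")

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["traits"] = list(self.traits)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimulationConfig":
        d = dict(d)
        if "traits" in d:
            d["traits"] = tuple(d["traits"])
        return cls(**d)


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings: paths, thresholds, and the seed.

    Thresholds default to the published constants of the method: proxies at
    r² >= 0.8, LD-block expansion at r² > 0.7, top 5% dual-model filter,
    top 1% for pathway enrichment, control MAF > 10%, FDR < 5%, ~100
    controls per case, 10 CV folds.
    """

    workdir: Path = Path("chromlasso_run")
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    proxy_r2: float = 0.8
    block_r2: float = 0.7
    top_fraction: float = 0.05
    top1_fraction: float = 0.01
    maf_min: float = 0.10
    fdr: float = 0.05
    n_controls: int = 100
    folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        self.workdir = Path(self.workdir)
        self.validate()

    def validate(self) -> None:
        def bad(name: str, why: str) -> None:
            raise ConfigError(f"PipelineConfig.{name}: {why}")

        for name in ("proxy_r2", "block_r2"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                bad(name, "r² threshold must be in [0, 1]")
        for name in ("top_fraction", "top1_fraction", "fdr"):
            if not (0.0 < getattr(self, name) < 1.0):
                bad(name, "fraction must be in (0, 1)")
        if not (0.0 <= self.maf_min < 0.5):
            bad("maf_min", "must be in [0, 0.5)")
        if self.n_controls <= 0:
            bad("n_controls", "must be positive")
        if self.folds < 2:
            bad("folds", "need at least 2 CV folds")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        sim = raw.pop("simulation", None)
        try:
            cfg = cls(**raw)
        except TypeError as exc:
            raise ConfigError(f"{path}: {exc}") from exc
        if sim is not None:
            cfg.simulation = SimulationConfig.from_dict(sim)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        d: dict[str, Any] = {
            k: v for k, v in self.__dict__.items() if k != "simulation"
        }
        d["workdir"] = str(self.workdir)
        d["simulation"] = self.simulation.to_dict()
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)
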