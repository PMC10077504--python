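"""Configuration objects for the simulator and the pipeline.

Defaults follow the source study's analysis parameters (significance and QC
thresholds) and, for the simulator, a desk-scale version of its two-isolate
design: two cohorts of 1000 samples, a dense single-chromosome panel with
blockwise LD, founder-effect allele-frequency drift against a cosmopolitan
reference, and planted cis/trans protein effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence


@dataclass
class SimConfig:
    """Parameters of the two-cohort synthetic study.

    Attributes
    ----------
    n_samples_per_cohort
        Diploid samples simulated per cohort.
    n_variants
        Biallelic variants on the panel (single synthetic chromosome,
        evenly spaced positions).
    n_proteins
        Olink-style protein assays.
    drift_fst
        Balding-Nichols divergence parameter between each cohort and the
        shared ancestral (reference) population.
    ld_block_size, ld_rho
        Haplotypes are first-order Markov within blocks of
        ``ld_block_size`` consecutive variants with latent correlation
        ``ld_rho``; blocks are independent.
    n_cis_effects, n_trans_effects
        Planted protein-level effects within / beyond 1 Mb of the encoding
        gene start.
    effect_size_sd
        Spread of planted effect sizes (NPX units per alternate allele).
    polygenic_h2
        Variance fraction of the polygenic term whose covariance is
        proportional to the realized GRM.
    lod_quantile
        Per-protein quantile used as the assay lower limit of detection.
    relatedness_block_size
        Sibship size; samples within a block share parental haplotypes.
    causal_protein_effects
        ``(protein, trait, beta)`` triples describing true protein->trait
        causal effects for the outcome-GWAS generator.
    genotype_missing_rate
        Per-call probability of a missing genotype.
    drift_report_fold
        Minimum cohort/reference MAF ratio for a variant to be listed as
        drifted in the ground truth.
    """

    n_samples_per_cohort: int = 1000
    n_variants: int = 4000
    n_proteins: int = 20
    drift_fst: float = 0.02
    ld_block_size: int = 20
    ld_rho: float = 0.8
    n_cis_effects: int = 10
    n_trans_effects: int = 5
    effect_size_sd: float = 0.8
    polygenic_h2: float = 0.2
    lod_quantile: float = 0.05
    relatedness_block_size: int = 4
    causal_protein_effects: Sequence[tuple[str, str, float]] = field(
        default_factory=list
    )
    genotype_missing_rate: float = 0.002
    drift_report_fold: float = 2.25
    variant_spacing: int = 5000
    effect_betas: Sequence[float] | None = None
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_samples_per_cohort, self.n_variants, self.n_proteins) <= 0:
            raise ValueError("counts must be positive")
        if not 0.0 <= self.drift_fst < 1.0:
            raise ValueError("drift_fst must be in [0, 1)")
        if not 0.0 <= self.ld_rho < 1.0:
            raise ValueError("ld_rho must be in [0, 1)")
        if not 0.0 <= self.polygenic_h2 < 1.0:
            raise ValueError("polygenic_h2 must be in [0, 1)")
        if not 0.0 <= self.lod_quantile < 1.0:
            raise ValueError("lod_quantile must be in [0, 1)")
        if not 0.0 <= self.genotype_missing_rate < 1.0:
            raise ValueError("genotype_missing_rate must be in [0, 1)")
        # at most eight independent signals per protein were ever observed
        if self.n_cis_effects + self.n_trans_effects > self.n_proteins * 8:
            raise ValueError(
                "too many planted effects: at most 8 per protein are supported"
            )
        if self.relatedness_block_size < 1:
            raise ValueError("relatedness_block_size must be >= 1")


@dataclass
class RunConfig:
    """End-to-end pipeline parameters (study defaults)."""

    # phenotype QC
    max_protein_missing: float = 0.40
    # variant QC
    max_variant_missing: float = 0.01
    min_mac: int = 10
    hwe_alpha: float = 1e-5
    # GRM
    grm_min_maf: float = 0.01
    prune_window: int = 50
    prune_step: int = 5
    prune_vif: float = 2.0
    # association QC
    lambda_gc_band: tuple[float, float] = (0.97, 1.05)
    # significance
    alpha: float = 0.05
    # signal extraction
    p_extract: float = 1e-6
    r2_drop: float = 0.2
    group_dist: float = 2e6
    clump_r2: float = 0.1
    clump_window: float = 1e6
    cojo_collinearity_r2: float = 0.9
    cojo_window: float = 1e7
    merge_r2: float = 0.1
    merge_dist: float = 1e6
    # annotation
    cis_window: float = 1e6
    drift_min_fold: float = 2.25
    rare_maf: float = 0.01
    proxy_r2: float = 0.8
    # colocalization
    coloc_p1: float = 1e-4
    coloc_p2: float = 1e-4
    coloc_p12: float = 1e-5
    coloc_w: float = 1.0
    coloc_posterior: float = 0.8
    seed: int = 0

    def as_dict(self) -> dict:
        d = asdict(self)
        d["lambda_gc_band"] = list(self.lambda_gc_band)
        return d
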