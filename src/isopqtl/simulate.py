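"""Synthetic two-isolate pQTL study generator.

Emulates the design of a WGS-based serum-proteome QTL study in two related
founder-population cohorts:

* ancestral (reference-population) allele frequencies drawn from a U-shaped
  distribution, with per-cohort frequencies diverged by a Balding-Nichols
  step with parameter ``drift_fst`` -- rare alleles can drift up in
  frequency in either cohort while the reference table keeps the ancestral
  values;
* haplotypes generated as a first-order Markov (latent Gaussian AR(1))
  chain within LD blocks, so r^2-based logic downstream has real structure
  to work on;
* relatedness induced by sibship blocks that share parental haplotypes,
  making the empirical GRM non-trivial;
* protein levels (NPX scale) = planted cis/trans allelic effects
  + a polygenic term with covariance proportional to the realized GRM
  + fixed effects of age, age^2, sex, plate, season and a per-sample mean
  shift + Gaussian noise, with a per-protein limit of detection at a
  configurable quantile;
* outcome-trait GWAS summary statistics generated from an independent
  cosmopolitan sample in which traits are driven by the planted
  protein->trait causal effects.

All randomness flows through ``numpy.random.default_rng`` (PCG64); a fixed
seed yields byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import SimConfig
from .containers import GenotypePanel, ProteinMatrix

COHORT_NAMES = ("cohortA", "cohortB")

# fixed-effect coefficients of the covariate model (NPX units)
_BETA_AGE = 0.02
_BETA_AGE2 = -2e-4
_BETA_SEX = 0.2
_BETA_SEASON = 0.3
_PLATE_SD = 0.25
_MEAN_SHIFT_SD = 0.3
_PLATE_SIZE = 88
_SEASON_RUN = 150


@dataclass
class GroundTruth:
    """Planted truth of a simulated study."""

    pqtls: pd.DataFrame  # protein, rsid, chrom, pos, beta, kind
    gene_locations: pd.DataFrame  # protein, chrom, start
    drifted: pd.DataFrame  # cohort, rsid, cohort_maf, reference_maf, fold
    causal_effects: pd.DataFrame  # protein, trait, beta


@dataclass
class SimulatedStudy:
    panels: dict[str, GenotypePanel]
    proteins: dict[str, ProteinMatrix]
    reference_af: pd.DataFrame
    truth: GroundTruth
    config: SimConfig = field(repr=False, default=None)


def _block_bounds(n_variants: int, block_size: int) -> np.ndarray:
    """Start indices of LD blocks."""
    return np.arange(0, n_variants, block_size)


def _haplotypes(
    rng: np.random.Generator,
    freqs: np.ndarray,
    n_hap: int,
    block_size: int,
    rho: float,
) -> np.ndarray:
    """Draw ``n_hap`` haplotypes over ``len(freqs)`` variants.

    A latent Gaussian AR(1) chain with coefficient ``rho`` runs within each
    block of ``block_size`` consecutive variants and restarts at block
    boundaries; the allele at variant j is 1 when the latent value falls
    below the standard-normal quantile of the allele frequency, so marginal
    frequencies are preserved while neighbours are correlated.
    """
    m = len(freqs)
    z = rng.standard_normal((n_hap, m))
    if rho > 0:
        carry = np.sqrt(1.0 - rho * rho)
        for j in range(1, m):
            if j % block_size == 0:
                continue  # new block: independent start
            z[:, j] = rho * z[:, j - 1] + carry * z[:, j]
    thresh = stats.norm.ppf(np.clip(freqs, 1e-12, 1 - 1e-12))
    return (z < thresh[None, :]).astype(np.int8)


def _sibship_genotypes(
    rng: np.random.Generator,
    freqs: np.ndarray,
    n_samples: int,
    block_size: int,
    rho: float,
    sib_size: int,
) -> np.ndarray:
    """Genotypes for samples organised in sibships sharing parental haplotypes."""
    n_blocks = int(np.ceil(n_samples / sib_size))
    parental = _haplotypes(rng, freqs, 4 * n_blocks, block_size, rho)
    block = np.arange(n_samples) // sib_size
    # each child draws one of the two maternal and one of the two paternal
    # haplotypes of its sibship block
    mother = 4 * block + rng.integers(0, 2, size=n_samples)
    father = 4 * block + 2 + rng.integers(0, 2, size=n_samples)
    return (parental[mother] + parental[father]).astype(float)


def _u_shaped_freqs(rng: np.random.Generator, m: int) -> np.ndarray:
    """Ancestral frequencies from a U-shaped Beta(0.5, 0.5), bounded away from 0/1."""
    return np.clip(rng.beta(0.5, 0.5, size=m), 0.005, 0.995)


def _balding_nichols(
    rng: np.random.Generator, p: np.ndarray, fst: float
) -> np.ndarray:
    if fst <= 0:
        return p.copy()
    a = p * (1.0 - fst) / fst
    b = (1.0 - p) * (1.0 - fst) / fst
    return np.clip(rng.beta(a, b), 0.0, 1.0)


def _variant_table(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    m = config.n_variants
    pos = (np.arange(m) + 1) * config.variant_spacing
    bases = np.array(list("ACGT"))
    ref_idx = rng.integers(0, 4, size=m)
    alt_idx = (ref_idx + rng.integers(1, 4, size=m)) % 4
    return pd.DataFrame(
        {
            "chrom": "1",
            "pos": pos,
            "rsid": [f"rs{100000 + j}" for j in range(m)],
            "ref": bases[ref_idx],
            "alt": bases[alt_idx],
        }
    )


def _covariate_sheet(
    rng: np.random.Generator, n: int, cohort: str
) -> pd.DataFrame:
    """Sample sheet: samples are plated in collection order, which makes
    plate and season largely (not perfectly) correlated."""
    idx = np.arange(n)
    return pd.DataFrame(
        {
            "age": np.round(rng.uniform(25, 85, size=n), 1),
            "sex": rng.integers(0, 2, size=n),
            "plate": [f"P{i // _PLATE_SIZE + 1:02d}" for i in idx],
            "season": (idx // _SEASON_RUN) % 2,
            "cohort": cohort,
        },
        index=[f"{cohort}_{i:04d}" for i in idx],
    )


def _plant_effects(
    config: SimConfig,
    rng: np.random.Generator,
    variants: pd.DataFrame,
    ancestral: np.ndarray,
    genes: pd.DataFrame,
) -> pd.DataFrame:
    """Choose planted pQTL variants and effect sizes.

    Cis variants lie within 1 Mb of the protein's gene start; trans variants
    lie farther away.  Planted variants are preferentially common
    (ancestral MAF >= 5%) so that effects are detectable at desk scale.
    """
    maf = np.minimum(ancestral, 1 - ancestral)
    pos = variants["pos"].to_numpy()
    rows = []
    used: set[int] = set()
    per_protein: dict[str, int] = {}
    kinds = ["cis"] * config.n_cis_effects + ["trans"] * config.n_trans_effects
    proteins = [f"PROT{i:03d}" for i in range(config.n_proteins)]
    gene_start = dict(zip(genes["protein"], genes["start"]))
    p_cycle = 0
    for k, kind in enumerate(kinds):
        # round-robin over proteins, capped at 8 signals per protein
        while per_protein.get(proteins[p_cycle % len(proteins)], 0) >= 8:
            p_cycle += 1
        prot = proteins[p_cycle % len(proteins)]
        p_cycle += 1
        per_protein[prot] = per_protein.get(prot, 0) + 1
        near = np.abs(pos - gene_start[prot]) <= 1e6
        cand = near if kind == "cis" else ~near
        cand = np.flatnonzero(cand & (maf >= 0.05))
        cand = np.array([c for c in cand if c not in used])
        if cand.size == 0:  # fall back to any unused variant in the zone
            cand = np.array(
                [c for c in np.flatnonzero(near if kind == "cis" else ~near)
                 if c not in used]
            )
        j = int(rng.choice(cand))
        used.add(j)
        if config.effect_betas is not None and k < len(config.effect_betas):
            beta = float(config.effect_betas[k])
        else:
            beta = float(rng.normal(0.0, config.effect_size_sd))
        rows.append(
            {
                "protein": prot,
                "rsid": variants["rsid"].iat[j],
                "chrom": variants["chrom"].iat[j],
                "pos": int(variants["pos"].iat[j]),
                "variant_index": j,
                "beta": beta,
                "kind": kind,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["protein", "rsid", "chrom", "pos", "variant_index", "beta", "kind"],
    )


def _protein_levels(
    config: SimConfig,
    rng: np.random.Generator,
    dosages: np.ndarray,
    planted: pd.DataFrame,
    ancestral: np.ndarray,
    covs: pd.DataFrame,
) -> pd.DataFrame:
    n = dosages.shape[0]
    proteins = [f"PROT{i:03d}" for i in range(config.n_proteins)]
    y = np.zeros((n, len(proteins)))

    # planted allelic effects
    for _, row in planted.iterrows():
        pi = proteins.index(row["protein"])
        y[:, pi] += row["beta"] * dosages[:, row["variant_index"]]

    # polygenic term u = Z w: covariance proportional to the realized GRM
    if config.polygenic_h2 > 0:
        maf = np.minimum(ancestral, 1 - ancestral)
        common = np.flatnonzero(maf >= 0.05)
        if common.size > 1000:
            common = common[:: max(1, common.size // 1000)]
        G = dosages[:, common]
        mu = G.mean(axis=0)
        sd = G.std(axis=0)
        sd[sd == 0] = 1.0
        Z = (G - mu) / sd
        w = rng.normal(0.0, 1.0, size=(Z.shape[1], len(proteins)))
        u = Z @ w
        u_sd = u.std(axis=0)
        u_sd[u_sd == 0] = 1.0
        y += u / u_sd * np.sqrt(config.polygenic_h2)

    # fixed effects of the covariate model
    age = covs["age"].to_numpy()
    fixed = (
        _BETA_AGE * age
        + _BETA_AGE2 * age**2
        + _BETA_SEX * covs["sex"].to_numpy()
        + _BETA_SEASON * covs["season"].to_numpy()
    )
    plates = covs["plate"].unique()
    plate_eff = dict(zip(plates, rng.normal(0.0, _PLATE_SD, size=len(plates))))
    fixed = fixed + covs["plate"].map(plate_eff).to_numpy()
    mean_shift = rng.normal(0.0, _MEAN_SHIFT_SD, size=n)
    y += (fixed + mean_shift)[:, None]

    # residual noise
    y += rng.normal(0.0, np.sqrt(1.0 - config.polygenic_h2), size=y.shape)
    return pd.DataFrame(y, index=covs.index, columns=proteins)


def simulate_cohorts(config: SimConfig) -> SimulatedStudy:
    """Simulate the two-cohort study with planted ground truth.

    Returns per-cohort genotype panels and protein matrices, the ancestral
    (reference-population) allele-frequency table, and the planted truth:
    pQTL effects, drifted variants and protein->trait causal effects.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    variants = _variant_table(config, rng)
    ancestral = _u_shaped_freqs(rng, config.n_variants)
    pos_max = int(variants["pos"].iloc[-1])
    proteins = [f"PROT{i:03d}" for i in range(config.n_proteins)]
    genes = pd.DataFrame(
        {
            "protein": proteins,
            "chrom": "1",
            "start": rng.integers(1, pos_max, size=config.n_proteins),
        }
    )
    planted = _plant_effects(config, rng, variants, ancestral, genes)

    panels: dict[str, GenotypePanel] = {}
    matrices: dict[str, ProteinMatrix] = {}
    drift_rows = []
    for cohort in COHORT_NAMES:
        p_c = _balding_nichols(rng, ancestral, config.drift_fst)
        dosages = _sibship_genotypes(
            rng,
            p_c,
            config.n_samples_per_cohort,
            config.ld_block_size,
            config.ld_rho,
            config.relatedness_block_size,
        )
        covs = _covariate_sheet(rng, config.n_samples_per_cohort, cohort)
        values = _protein_levels(config, rng, dosages, planted, ancestral, covs)

        # censoring threshold: per-protein LOD at the configured quantile
        lod = values.quantile(config.lod_quantile)

        # genotype missingness applied after phenotypes are formed
        if config.genotype_missing_rate > 0:
            mask = (
                rng.random(dosages.shape) < config.genotype_missing_rate
            )
            dosages[mask] = np.nan

        panel = GenotypePanel(dosages, variants.copy(), list(covs.index))
        panels[cohort] = panel
        matrices[cohort] = ProteinMatrix(values, lod, covs)

        maf_c = panel.maf()
        maf_ref = np.minimum(ancestral, 1 - ancestral)
        with np.errstate(divide="ignore", invalid="ignore"):
            fold = maf_c / maf_ref
        hit = np.flatnonzero(
            np.isfinite(fold) & (fold >= config.drift_report_fold)
        )
        for j in hit:
            drift_rows.append(
                {
                    "cohort": cohort,
                    "rsid": variants["rsid"].iat[j],
                    "cohort_maf": float(maf_c[j]),
                    "reference_maf": float(maf_ref[j]),
                    "fold": float(fold[j]),
                }
            )

    reference_af = variants.copy()
    reference_af["af"] = ancestral
    reference_af["maf"] = np.minimum(ancestral, 1 - ancestral)

    causal = pd.DataFrame(
        list(config.causal_protein_effects),
        columns=["protein", "trait", "beta"],
    )
    truth = GroundTruth(
        pqtls=planted,
        gene_locations=genes,
        drifted=pd.DataFrame(
            drift_rows,
            columns=["cohort", "rsid", "cohort_maf", "reference_maf", "fold"],
        ),
        causal_effects=causal,
    )
    return SimulatedStudy(panels, matrices, reference_af, truth, config)


def simulate_outcome_gwas(
    config: SimConfig,
    truth: GroundTruth,
    n_gwas: int,
    overlap_fraction: float = 0.9,
    traits: list[str] | None = None,
) -> dict[str, pd.DataFrame]:
    """Outcome-trait GWAS summary statistics from an independent sample.

    An unrelated cosmopolitan sample of size ``n_gwas`` is drawn at the
    ancestral frequencies with the same LD structure; each trait is the sum
    of the planted causal protein effects plus unit Gaussian noise, and
    marginal per-variant OLS effects are reported.  Only a random
    ``overlap_fraction`` of the panel's variants appear in the output, to
    exercise proxy lookup downstream.
    """
    config.validate()
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ValueError("overlap_fraction must be in [0, 1]")
    rng = np.random.default_rng([config.seed % (2**31), 7919])

    # regenerate the panel layout deterministically from the study config
    layout_rng = np.random.default_rng(config.seed)
    variants = _variant_table(config, layout_rng)
    ancestral = _u_shaped_freqs(layout_rng, config.n_variants)

    if traits is None:
        traits = sorted(truth.causal_effects["trait"].unique())
        if not traits:
            traits = ["trait1"]

    # independent unrelated genotypes, generated in haplotype chunks
    m = config.n_variants
    dosages = np.empty((n_gwas, m), dtype=np.float32)
    chunk = max(1, min(n_gwas, 64_000_000 // (8 * m) // 2))
    for start in range(0, n_gwas, chunk):
        k = min(chunk, n_gwas - start)
        haps = _haplotypes(rng, ancestral, 2 * k, config.ld_block_size, config.ld_rho)
        dosages[start : start + k] = haps[:k] + haps[k:]

    proteins = [f"PROT{i:03d}" for i in range(config.n_proteins)]
    levels = np.zeros((n_gwas, len(proteins)), dtype=np.float64)
    for _, row in truth.pqtls.iterrows():
        pi = proteins.index(row["protein"])
        levels[:, pi] += row["beta"] * dosages[:, row["variant_index"]]
    levels += rng.normal(0.0, 1.0, size=levels.shape)

    keep = np.sort(
        rng.choice(m, size=int(round(overlap_fraction * m)), replace=False)
    )
    G = np.asarray(dosages[:, keep], dtype=np.float64)
    mu = G.mean(axis=0)
    var_g = G.var(axis=0)
    ok = var_g > 0

    out: dict[str, pd.DataFrame] = {}
    for trait in traits:
        rows = truth.causal_effects[truth.causal_effects["trait"] == trait]
        y = rng.normal(0.0, 1.0, size=n_gwas)
        for _, r in rows.iterrows():
            y += r["beta"] * levels[:, proteins.index(r["protein"])]
        yc = y - y.mean()
        sxy = (G - mu).T @ yc / n_gwas
        with np.errstate(divide="ignore", invalid="ignore"):
            beta = np.where(ok, sxy / var_g, np.nan)
            sse = n_gwas * (yc @ yc / n_gwas - np.where(ok, beta * sxy, 0.0))
            se = np.sqrt(
                np.where(ok, sse / (n_gwas - 2) / (n_gwas * var_g), np.nan)
            )
        tstat = beta / se
        p = 2 * stats.t.sf(np.abs(tstat), df=n_gwas - 2)
        tab = variants.iloc[keep].reset_index(drop=True)
        out[trait] = pd.DataFrame(
            {
                "rsid": tab["rsid"],
                "chrom": tab["chrom"],
                "pos": tab["pos"],
                "effect_allele": tab["alt"],
                "other_allele": tab["ref"],
                "af": mu / 2.0,
                "beta": beta,
                "se": se,
                "p": p,
                "n": n_gwas,
            }
        ).dropna(subset=["beta", "se"])
    return out
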