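"""Cross-cohort harmonization, inverse-variance meta-analysis, sex heterogeneity.

Single-point output can carry alleles truncated to one character (a quirk
of the mixed-model software dialect this pipeline mirrors); alleles are
restored by joining summary statistics to the cohort VCF on chromosome and
position, matching by frequency for biallelic sites and by smallest
allele-frequency difference for multiallelic sites.  Cohorts are then
combined with METAL-style fixed-effect inverse-variance weighting, and sex
heterogeneity is assessed with a Cochran's-Q-type contrast of the male and
female meta-analysis effects.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


def harmonize_alleles(
    assoc: pd.DataFrame, vcf_variants: pd.DataFrame
) -> pd.DataFrame:
    """Restore full allele labels by matching summary stats to VCF metadata.

    ``vcf_variants`` must have columns ``chrom, pos, ref, alt, af`` with one
    row per alternate allele (multiallelic sites contribute several rows).
    Biallelic sites are matched by allele labels when unambiguous, else by
    minor/major frequency.  At multiallelic sites the alternate allele
    minimizing ``|stats MAF - VCF allele AF|`` is chosen; exact frequency
    ties are dropped as ambiguous, as are positions absent from the VCF.
    """
    # fast path: biallelic positions whose labels already match exactly
    dup_pos = vcf_variants.duplicated(["chrom", "pos"], keep=False)
    biallelic = vcf_variants[~dup_pos]
    merged = assoc.merge(
        biallelic[["chrom", "pos", "ref", "alt"]],
        left_on=["chr", "pos"],
        right_on=["chrom", "pos"],
        how="left",
    )
    exact = (
        (merged["allele1"].astype(str) == merged["alt"])
        & (merged["allele0"].astype(str) == merged["ref"])
    ).to_numpy()
    passthrough = assoc[exact].copy()
    assoc = assoc[~exact]

    vcf_groups = {
        key: grp for key, grp in vcf_variants.groupby(["chrom", "pos"], sort=False)
    }
    rows = []
    n_dropped = 0
    for _, rec in assoc.iterrows():
        key = (rec["chr"], rec["pos"])
        grp = vcf_groups.get(key)
        if grp is None:
            n_dropped += 1
            continue
        stats_maf = min(rec["af"], 1.0 - rec["af"])
        rec = rec.copy()
        if len(grp) == 1:
            v = grp.iloc[0]
            a1, a0 = str(rec["allele1"]), str(rec["allele0"])
            ref, alt = str(v["ref"]), str(v["alt"])
            if alt.startswith(a1) and ref.startswith(a0):
                rec["allele1"], rec["allele0"] = alt, ref
            elif ref.startswith(a1) and alt.startswith(a0):
                # stats oriented to the reference allele: flip to alt
                rec["allele1"], rec["allele0"] = alt, ref
                rec["beta"] = -rec["beta"]
                rec["af"] = 1.0 - rec["af"]
            else:
                # labels unusable (heavy truncation): match minor/major by frequency
                vcf_af = float(v["af"])
                minor_is_alt = vcf_af <= 0.5
                stats_minor_is_a1 = rec["af"] <= 0.5
                rec["allele1"], rec["allele0"] = alt, ref
                if minor_is_alt != stats_minor_is_a1:
                    rec["beta"] = -rec["beta"]
                    rec["af"] = 1.0 - rec["af"]
        else:
            diffs = np.abs(grp["af"].to_numpy(dtype=float) - stats_maf)
            best = np.flatnonzero(diffs <= diffs.min() + 1e-15)
            if len(best) > 1:
                n_dropped += 1  # exact frequency tie: ambiguous
                continue
            v = grp.iloc[best[0]]
            rec["allele1"], rec["allele0"] = str(v["alt"]), str(v["ref"])
        rows.append(rec)
    if n_dropped:
        log.info("harmonization dropped %d unresolvable records", n_dropped)
    slow = pd.DataFrame(rows) if rows else assoc.iloc[0:0]
    out = pd.concat([passthrough, slow], ignore_index=True)
    return out.sort_values(["chr", "pos"], kind="stable").reset_index(drop=True)


def ivw_meta(stats_a: pd.DataFrame, stats_b: pd.DataFrame) -> pd.DataFrame:
    """Fixed-effect inverse-variance-weighted meta-analysis of two cohorts.

    Effects are oriented to cohort A's alleles (sign-flipping records whose
    alleles are swapped); variants present in only one cohort pass through
    flagged ``cohorts_present = 1``.  Allele mismatches after orientation
    are dropped with a log entry, as are positions duplicated within a
    cohort (ambiguous join).
    """
    key = ["chr", "pos"]
    a = stats_a[~stats_a.duplicated(key, keep=False)].reset_index(drop=True)
    b = stats_b[~stats_b.duplicated(key, keep=False)].reset_index(drop=True)
    m = a.merge(b, on=key, suffixes=("_a", "_b"), how="inner")

    same = (m["allele1_a"] == m["allele1_b"]) & (m["allele0_a"] == m["allele0_b"])
    swap = (m["allele1_a"] == m["allele0_b"]) & (m["allele0_a"] == m["allele1_b"])
    n_mismatch = int((~(same | swap)).sum())
    joined_keys = set(zip(m["chr"], m["pos"]))  # incl. mismatches: those drop entirely
    if n_mismatch:
        log.info("meta-analysis dropped %d allele-mismatched variants", n_mismatch)
    m = m[same | swap].reset_index(drop=True)
    flip = (
        (m["allele1_a"] == m["allele0_b"]) & (m["allele0_a"] == m["allele1_b"])
        & ~((m["allele1_a"] == m["allele1_b"]) & (m["allele0_a"] == m["allele0_b"]))
    ).to_numpy()
    beta_b = np.where(flip, -m["beta_b"], m["beta_b"])
    af_b = np.where(flip, 1.0 - m["af_b"], m["af_b"])

    wa = 1.0 / m["se_a"].to_numpy() ** 2
    wb = 1.0 / m["se_b"].to_numpy() ** 2
    beta = (wa * m["beta_a"].to_numpy() + wb * beta_b) / (wa + wb)
    se = 1.0 / np.sqrt(wa + wb)
    z = beta / se
    n_tot = (m["n_a"] + m["n_b"]).to_numpy()
    both = pd.DataFrame(
        {
            "chr": m["chr"],
            "pos": m["pos"],
            "rsid": m["rsid_a"],
            "allele1": m["allele1_a"],
            "allele0": m["allele0_a"],
            "af": (m["n_a"] * m["af_a"] + m["n_b"] * af_b) / n_tot,
            "beta": beta,
            "se": se,
            "p": np.maximum(2 * stats.norm.sf(np.abs(z)), 5e-324),
            "n": n_tot.astype(int),
            "direction": [
                _dir(x) + _dir(y) for x, y in zip(m["beta_a"], beta_b)
            ],
            "cohorts_present": 2,
        }
    )
    if "mac_a" in m.columns and "mac_b" in m.columns:
        both["mac"] = np.minimum(m["mac_a"], m["mac_b"])

    singles = []
    common_keys = joined_keys
    for tab, pattern in ((a, "{}?"), (b, "?{}")):
        only = tab[~pd.Series(list(zip(tab["chr"], tab["pos"]))).isin(common_keys)]
        if only.empty:
            continue
        z1 = only["beta"].to_numpy() / only["se"].to_numpy()
        single = pd.DataFrame(
            {
                "chr": only["chr"],
                "pos": only["pos"],
                "rsid": only["rsid"],
                "allele1": only["allele1"],
                "allele0": only["allele0"],
                "af": only["af"],
                "beta": only["beta"],
                "se": only["se"],
                "p": np.maximum(2 * stats.norm.sf(np.abs(z1)), 5e-324),
                "n": only["n"].astype(int),
                "direction": [pattern.format(_dir(x)) for x in only["beta"]],
                "cohorts_present": 1,
            }
        )
        if "mac" in only.columns:
            single["mac"] = only["mac"].to_numpy()
        singles.append(single)
    out = pd.concat([both, *singles], ignore_index=True)
    if len(out):
        out = out.sort_values(["chr", "pos"]).reset_index(drop=True)
    return out


def _dir(beta: float) -> str:
    return "+" if beta >= 0 else "-"


def sex_het_test(
    beta_m: float, se_m: float, beta_f: float, se_f: float
) -> tuple[float, float]:
    """Cochran's-Q-type sex-heterogeneity test on one variant.

    Q = (beta_m - beta_f)^2 / (se_m^2 + se_f^2), referred to chi-square(1).
    Returns (Q, P).  Callers apply a Bonferroni threshold of
    alpha / (number of tested pQTLs).
    """
    if any(not np.isfinite(v) for v in (beta_m, se_m, beta_f, se_f)):
        return float("nan"), float("nan")
    q = (beta_m - beta_f) ** 2 / (se_m**2 + se_f**2)
    return float(q), float(stats.chi2.sf(q, df=1))
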