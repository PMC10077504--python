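"""End-to-end orchestration of the pQTL analysis on a two-cohort study.

Stage order is fixed: phenotype QC -> variant QC / GRM -> per-protein LMM
association (overall, plus sex-stratified runs at candidate pQTLs) ->
cross-cohort IVW meta-analysis with allele harmonization -> peak
extraction -> clumping + COJO model selection -> annotation (cis/trans,
drift, novelty, replication) -> colocalization -> Mendelian randomization.
A manifest records parameters, seeds and per-stage row counts;
re-running the same configuration reproduces it byte for byte.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, annotate as ann, coloc as cl, mr as mrmod
from .association import LMMFit, assoc_single_with_covariates, fit_null_lmm, lmm_assoc
from .config import RunConfig
from .containers import AdjustedPhenotypes, GenotypePanel
from .genostats import (
    PanelLD,
    SignificancePlan,
    compute_grm,
    lambda_gc,
    ld_prune,
    significance_threshold,
    variant_qc,
)
from .meta import harmonize_alleles, ivw_meta, sex_het_test
from .phenotypes import adjust_and_int, censor_below_lod, filter_proteins
from .signals import Peak, clump, cojo_condition, cojo_select, extract_peaks, merge_adjacent_peaks
from .simulate import SimulatedStudy

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    adjusted: dict
    qc: dict
    grm: dict
    assoc: dict  # cohort -> protein -> per-variant association table
    plan: SignificancePlan
    lambda_gc: pd.DataFrame
    excluded_proteins: list
    meta_tables: dict
    peaks: dict
    conditional: dict
    sex_het: pd.DataFrame
    annotations: pd.DataFrame
    coloc_results: pd.DataFrame
    mr_results: pd.DataFrame
    manifest: dict = field(default_factory=dict)


def _merged_panel(panels: dict[str, GenotypePanel]) -> GenotypePanel:
    """Pool cohorts (same variant set) for cross-cohort LD."""
    names = sorted(panels)
    dosages = np.vstack([panels[c].dosages for c in names])
    samples = [s for c in names for s in panels[c].samples]
    return GenotypePanel(dosages, panels[names[0]].variants.copy(), samples)


def _protein_fits(
    adjusted: AdjustedPhenotypes, K: np.ndarray
) -> dict[str, tuple[np.ndarray, np.ndarray, LMMFit]]:
    """Null REML fit per protein on its complete-case samples."""
    fits = {}
    for prot in adjusted.residuals.columns:
        y = adjusted.residuals[prot]
        idx = np.flatnonzero(y.notna().to_numpy())
        if idx.size < 30:
            continue
        yv = y.to_numpy(dtype=float)[idx]
        fit = fit_null_lmm(yv, K[np.ix_(idx, idx)])
        fits[prot] = (idx, yv, fit)
    return fits


def run_pipeline(
    study: SimulatedStudy,
    rc: RunConfig,
    outcome_gwas: dict[str, pd.DataFrame] | None = None,
    known_signals: pd.DataFrame | None = None,
    replication_stats: pd.DataFrame | None = None,
    out_dir: str | Path | None = None,
    run_sex_het: bool = True,
) -> PipelineResult:
    """Run every stage on a (simulated or loaded) two-cohort study.

    ``outcome_gwas`` maps trait names to GWAS summary tables for the
    colocalization and MR stages (skipped when absent).  ``known_signals``
    (rsid column) feeds the novelty conditioning; ``replication_stats``
    feeds the replication lookup.  When ``out_dir`` is given every stage
    writes its table there along with ``manifest.json``.
    """
    cohorts = sorted(study.panels)
    counts: dict[str, int] = {}

    # ---- stage 1: phenotype QC ------------------------------------------
    adjusted: dict[str, AdjustedPhenotypes] = {}
    for c in cohorts:
        censored = censor_below_lod(study.proteins[c])
        sample_mean = censored.values.mean(axis=1)  # before protein exclusion
        filtered, excluded = filter_proteins(censored, rc.max_protein_missing)
        adjusted[c] = adjust_and_int(filtered, sample_mean)
    counts["proteins_adjusted"] = sum(a.residuals.shape[1] for a in adjusted.values())

    # ---- stage 2: variant QC and GRM ------------------------------------
    qc, grms = {}, {}
    for c in cohorts:
        panel = study.panels[c]
        qc[c] = variant_qc(panel, rc.max_variant_missing, rc.min_mac, rc.hwe_alpha)
        rec = qc[c].records
        grm_idx = np.flatnonzero(
            (rec["maf"] > rc.grm_min_maf) & (rec["hwe_p"] >= rc.hwe_alpha)
        )
        grm_panel = panel.subset_variants(grm_idx)
        pruned = ld_prune(grm_panel, rc.prune_window, rc.prune_step, rc.prune_vif)
        grms[c] = compute_grm(grm_panel.subset_variants(pruned))
    counts["variants_pass_qc"] = int(sum(len(q.kept) for q in qc.values()))

    # ---- stage 3: significance plan -------------------------------------
    first = cohorts[0]
    rec = qc[first].records
    neff_idx = np.flatnonzero(rec["mac"] >= rc.min_mac)
    neff_panel = study.panels[first].subset_variants(neff_idx)
    n_eff = len(ld_prune(neff_panel, rc.prune_window, rc.prune_step, rc.prune_vif))
    pooled_resid = pd.concat([adjusted[c].residuals for c in cohorts])
    pheno_corr = pooled_resid.corr().to_numpy()
    np.fill_diagonal(pheno_corr, 1.0)
    # pairwise-complete correlations need not be PSD: clip and renormalize
    evals, evecs = np.linalg.eigh(pheno_corr)
    if evals.min() < 0:
        pheno_corr = (evecs * np.clip(evals, 0, None)) @ evecs.T
        d = np.sqrt(np.diag(pheno_corr))
        pheno_corr = pheno_corr / np.outer(d, d)
        np.fill_diagonal(pheno_corr, 1.0)
    plan = significance_threshold(n_eff, pheno_corr, rc.alpha)
    counts["n_eff"] = plan.n_eff
    counts["m_eff_reported"] = plan.m_eff_reported

    # ---- stage 4: association -------------------------------------------
    fits = {c: _protein_fits(adjusted[c], grms[c]) for c in cohorts}
    assoc: dict[str, dict[str, pd.DataFrame]] = {c: {} for c in cohorts}
    lam_rows = []
    for c in cohorts:
        panel = study.panels[c]
        kept = qc[c].kept
        qpanel = panel.subset_variants(kept)
        for prot, (idx, yv, fit) in fits[c].items():
            tab = lmm_assoc(yv, qpanel.subset_samples(idx), fit)
            assoc[c][prot] = tab
            lam_rows.append(
                {"cohort": c, "protein": prot, "lambda_gc": lambda_gc(tab["p_wald"])}
            )
    lam = pd.DataFrame(lam_rows)
    lo, hi = rc.lambda_gc_band
    bad = sorted(
        lam.loc[(lam["lambda_gc"] < lo) | (lam["lambda_gc"] > hi), "protein"].unique()
    )
    if bad:
        log.info("excluding %d proteins for genomic-control inflation: %s", len(bad), bad)
    counts["proteins_lambda_excluded"] = len(bad)

    # ---- stage 5: meta-analysis -----------------------------------------
    proteins = sorted(
        set.intersection(*(set(assoc[c]) for c in cohorts)) - set(bad)
    )
    meta_tables: dict[str, pd.DataFrame] = {}
    for prot in proteins:
        harmonized = []
        for c in cohorts:
            vcf_meta = study.panels[c].variants.copy()
            vcf_meta["af"] = study.panels[c].alt_freq()
            harmonized.append(harmonize_alleles(assoc[c][prot], vcf_meta))
        meta_tables[prot] = ivw_meta(harmonized[0], harmonized[1])
    counts["proteins_meta"] = len(meta_tables)

    # ---- stage 6: peaks + COJO ------------------------------------------
    merged = _merged_panel(study.panels)
    ld = PanelLD(merged)
    hwe_fail = {
        r
        for c in cohorts
        for r in qc[c].records.loc[
            qc[c].records["hwe_p"] < rc.hwe_alpha, "rsid"
        ]
    }
    peaks: dict[str, list[Peak]] = {}
    conditional: dict[str, pd.DataFrame] = {}
    for prot, meta in meta_tables.items():
        pk = extract_peaks(
            meta,
            ld,
            rc.p_extract,
            rc.r2_drop,
            rc.group_dist,
            plan.threshold,
            rc.min_mac,
            hwe_fail,
        )
        pk = merge_adjacent_peaks(pk, ld, rc.merge_r2, rc.merge_dist)
        sig = [p for p in pk if p.significant]
        peaks[prot] = pk
        sel_frames = []
        for peak in sig:
            region = meta[
                (meta["chr"] == peak.chrom)
                & (meta["pos"] >= peak.start - rc.clump_window)
                & (meta["pos"] <= peak.end + rc.clump_window)
                & (meta["p"] < rc.p_extract)
            ]
            if region.empty:
                continue
            clumped = clump(region, ld, rc.clump_r2, rc.clump_window)
            sel = cojo_select(
                clumped, ld, plan.threshold, rc.cojo_collinearity_r2, rc.cojo_window
            )
            if not sel.empty:
                sel = sel.assign(peak_index=peak.index_rsid)
                sel_frames.append(sel)
        conditional[prot] = (
            pd.concat(sel_frames, ignore_index=True)
            if sel_frames
            else pd.DataFrame()
        )
    counts["significant_peaks"] = int(
        sum(sum(p.significant for p in v) for v in peaks.values())
    )
    counts["independent_variants"] = int(sum(len(v) for v in conditional.values()))

    # ---- stage 7: sex-stratified heterogeneity --------------------------
    het_rows = []
    if run_sex_het:
        n_tested = max(counts["independent_variants"], 1)
        for prot, sel in conditional.items():
            if sel.empty:
                continue
            for _, row in sel.iterrows():
                per_sex = {}
                for sex_code, label in ((1, "male"), (0, "female")):
                    betas, ses = [], []
                    for c in cohorts:
                        if prot not in fits[c]:
                            continue
                        idx, yv, _ = fits[c][prot]
                        sex = study.proteins[c].covariates["sex"].to_numpy()[idx]
                        sub = np.flatnonzero(sex == sex_code)
                        if sub.size < 30:
                            continue
                        jv = {
                            r: j
                            for j, r in enumerate(study.panels[c].variants["rsid"])
                        }.get(row["rsid"])
                        if jv is None:
                            continue
                        g = study.panels[c].dosages[np.ix_(idx[sub], [jv])][:, 0]
                        fit_s = fit_null_lmm(
                            yv[sub], grms[c][np.ix_(idx[sub], idx[sub])]
                        )
                        b, s, _p = assoc_single_with_covariates(
                            yv[sub], g, fit_s
                        )
                        betas.append(b)
                        ses.append(s)
                    if betas:
                        w = 1.0 / np.array(ses) ** 2
                        per_sex[label] = (
                            float((w * np.array(betas)).sum() / w.sum()),
                            float(1.0 / np.sqrt(w.sum())),
                        )
                if {"male", "female"} <= set(per_sex):
                    q, p = sex_het_test(*per_sex["male"], *per_sex["female"])
                    het_rows.append(
                        {
                            "protein": prot,
                            "rsid": row["rsid"],
                            "q": q,
                            "p_het": p,
                            "significant": p < rc.alpha / n_tested,
                        }
                    )
    sex_het = pd.DataFrame(het_rows, columns=["protein", "rsid", "q", "p_het", "significant"])

    # ---- stage 8: annotation --------------------------------------------
    gene_loc = study.truth.gene_locations.set_index("protein")
    ref = study.reference_af[["rsid", "maf"]]
    ann_rows = []
    for prot, sel in conditional.items():
        if sel.empty:
            continue
        gchrom = gene_loc.loc[prot, "chrom"] if prot in gene_loc.index else None
        gstart = gene_loc.loc[prot, "start"] if prot in gene_loc.index else None
        maf_tab = pd.DataFrame({"rsid": sel["rsid"]})
        for c in cohorts:
            maf_map = dict(
                zip(study.panels[c].variants["rsid"], study.panels[c].maf())
            )
            maf_tab[f"maf_{c}"] = sel["rsid"].map(maf_map)
        drift = ann.annotate_drift(
            maf_tab, ref, rc.drift_min_fold, rc.rare_maf
        ).set_index("rsid")
        known = (
            list(known_signals["rsid"]) if known_signals is not None else []
        )
        for _, row in sel.iterrows():
            kind = ann.classify_cis_trans(
                row["chr"], row["pos"], gchrom, gstart, int(rc.cis_window)
            )
            novelty = {"novel": None, "p_conditional": None}
            c0 = cohorts[0]
            if prot in fits[c0]:
                idx, yv, fit = fits[c0][prot]
                try:
                    novelty = ann.condition_on_known(
                        yv,
                        study.panels[c0].subset_samples(idx),
                        fit,
                        row["rsid"],
                        known,
                        plan.threshold,
                        int(rc.cis_window),
                    )
                except KeyError:
                    pass
            rec_out = {
                "protein": prot,
                "rsid": row["rsid"],
                "chrom": row["chr"],
                "pos": row["pos"],
                "cis_trans": kind,
                "novel": novelty.get("novel"),
                "p_conditional": novelty.get("p_conditional"),
            }
            if row["rsid"] in drift.index:
                d = drift.loc[row["rsid"]]
                rec_out.update(
                    {
                        "reference_maf": d["reference_maf"],
                        "rare_in_reference": bool(d["rare_in_reference"]),
                        "max_drift_fold": d["max_fold"],
                        "drifted": bool(d["drifted"]),
                    }
                )
            ann_rows.append(rec_out)
    annotations = pd.DataFrame(ann_rows)
    if replication_stats is not None and not annotations.empty:
        disc = annotations.rename(columns={"chrom": "chr"})
        disc = disc.merge(
            pd.concat(
                [t[["rsid", "beta"]] for t in meta_tables.values()],
                ignore_index=True,
            ).drop_duplicates("rsid"),
            on="rsid",
            how="left",
        )
        rep = ann.replication_lookup(
            disc, replication_stats, ld, rc.proxy_r2, rc.alpha
        )
        annotations = annotations.merge(
            rep[["rsid", "status", "proxy_rsid"]], on="rsid", how="left"
        )
    counts["annotated_signals"] = len(annotations)

    # ---- stage 9: colocalization ----------------------------------------
    coloc_rows = []
    if outcome_gwas:
        for prot, sel in conditional.items():
            if sel.empty:
                continue
            meta = meta_tables[prot]
            for _, row in sel.iterrows():
                others = [r for r in sel["rsid"] if r != row["rsid"]]
                region = meta[
                    (meta["chr"] == row["chr"])
                    & (np.abs(meta["pos"] - row["pos"]) <= rc.cis_window)
                ]
                conditioned = cojo_condition(region, ld, others, rc.cojo_window)
                conditioned = conditioned[conditioned["se_cond"].notna()]
                for trait, gwas in outcome_gwas.items():
                    joined = conditioned.merge(
                        gwas[["rsid", "beta", "se"]],
                        on="rsid",
                        suffixes=("", "_out"),
                    )
                    if joined.empty:
                        continue
                    res = cl.coloc_posteriors(
                        joined["beta_cond"].to_numpy(),
                        joined["se_cond"].to_numpy(),
                        joined["beta_out"].to_numpy(),
                        joined["se_out"].to_numpy(),
                        rc.coloc_p1,
                        rc.coloc_p2,
                        rc.coloc_p12,
                        rc.coloc_w,
                        rc.coloc_w,
                    )
                    coloc_rows.append(
                        {
                            "protein": prot,
                            "signal": row["rsid"],
                            "trait": trait,
                            **res.as_dict(),
                            "colocalized": res.pp4 > rc.coloc_posterior,
                        }
                    )
    coloc_results = pd.DataFrame(coloc_rows)

    # ---- stage 10: Mendelian randomization ------------------------------
    mr_rows = []
    if outcome_gwas:
        for prot, sel in conditional.items():
            if sel.empty:
                continue
            expo = sel.drop(columns=["beta", "se"]).rename(
                columns={"beta_joint": "beta", "se_joint": "se"}
            )[["rsid", "pos", "af", "beta", "se", "allele1", "allele0"]]
            for trait, gwas in outcome_gwas.items():
                instruments = mrmod.select_instruments(
                    expo, gwas, ld, rc.proxy_r2
                )
                est = mrmod.mr_estimate(instruments)
                if est is None:
                    log.info("no usable instruments for %s -> %s", prot, trait)
                    continue
                mr_rows.append(
                    {
                        "protein": prot,
                        "trait": trait,
                        "method": est.method,
                        "beta": est.beta,
                        "se": est.se,
                        "p": est.p,
                        "n_instruments": est.n_instruments,
                    }
                )
    mr_results = pd.DataFrame(mr_rows)
    if not mr_results.empty:
        mr_results["p_fdr"] = mrmod.fdr_adjust(mr_results["p"].to_numpy())
    counts["mr_pairs"] = len(mr_results)

    manifest = {
        "package_version": __version__,
        "seed": rc.seed,
        "parameters": rc.as_dict(),
        "significance_threshold": plan.threshold,
        "counts": counts,
    }
    result = PipelineResult(
        adjusted,
        qc,
        grms,
        assoc,
        plan,
        lam,
        bad,
        meta_tables,
        peaks,
        conditional,
        sex_het,
        annotations,
        coloc_results,
        mr_results,
        manifest,
    )
    if out_dir is not None:
        _write_outputs(result, Path(out_dir))
    return result


def _write_outputs(res: PipelineResult, out_dir: Path) -> None:
    from .io import write_json, write_tsv

    out_dir.mkdir(parents=True, exist_ok=True)
    write_json(res.manifest, out_dir / "manifest.json")
    write_tsv(res.lambda_gc, out_dir / "lambda_gc.tsv")
    peak_rows = [
        {
            "protein": prot,
            "chrom": p.chrom,
            "start": p.start,
            "end": p.end,
            "index_rsid": p.index_rsid,
            "index_p": p.index_p,
            "n_members": len(p.members),
            "significant": p.significant,
        }
        for prot, pks in res.peaks.items()
        for p in pks
    ]
    write_tsv(pd.DataFrame(peak_rows), out_dir / "peaks.tsv")
    cond = [
        df.assign(protein=prot) for prot, df in res.conditional.items() if not df.empty
    ]
    write_tsv(
        pd.concat(cond, ignore_index=True) if cond else pd.DataFrame(),
        out_dir / "conditional_variants.tsv",
    )
    write_tsv(res.sex_het, out_dir / "sex_heterogeneity.tsv")
    write_tsv(res.annotations, out_dir / "annotations.tsv")
    write_tsv(res.coloc_results, out_dir / "colocalization.tsv")
    write_tsv(res.mr_results, out_dir / "mr_results.tsv")
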