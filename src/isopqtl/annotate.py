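"""Signal annotation: cis/trans, drift, novelty, pleiotropy, replication.

Contextualizes conditionally independent pQTLs: distance-based cis/trans
classification anchored at the encoding gene's start, allele-frequency
drift of isolate cohorts against a cosmopolitan reference panel, novelty
assessment by conditioning on previously reported variants, flagging of
trans signals inside highly pleiotropic genes, and replication lookup in
an independent cohort with LD-proxy substitution.
"""

from __future__ import annotations

import logging
from importlib import resources

import numpy as np
import pandas as pd

from .association import LMMFit, assoc_single_with_covariates
from .containers import GenotypePanel
from .genostats import PanelLD

log = logging.getLogger(__name__)

#: genes repeatedly associated with many proteins plus literature evidence
PLEIOTROPIC_GENES = ("KLKB1", "ABO", "APOE", "FUT2", "F12", "VTN", "CFH", "HLA")

CIS_WINDOW = 1_000_000  # bp around the gene start


def load_drift_catalogue() -> pd.DataFrame:
    """Published catalogue of drifted novel pQTLs (cohort vs gnomAD-NFE MAF).

    Frequencies are percentages as printed; used by the drift-arithmetic
    checks and as a demonstration input for :func:`annotate_drift`.
    """
    with resources.files("isopqtl.data").joinpath(
        "drifted_pqtls_catalogue.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t")


def classify_cis_trans(
    variant_chrom: str,
    variant_pos: int,
    gene_chrom: str | None,
    gene_start: int | None,
    window: int = CIS_WINDOW,
) -> str:
    """Cis iff the variant lies within ``window`` bp of the gene start.

    The boundary is inclusive; the window is anchored at the gene start.
    Unknown gene location yields ``"unclassified"``.
    """
    if gene_chrom is None or gene_start is None or (
        isinstance(gene_start, float) and np.isnan(gene_start)
    ):
        return "unclassified"
    if str(variant_chrom) != str(gene_chrom):
        return "trans"
    return "cis" if abs(int(variant_pos) - int(gene_start)) <= window else "trans"


def annotate_drift(
    signal_mafs: pd.DataFrame,
    reference: pd.DataFrame,
    min_fold: float = 2.25,
    rare_cut: float = 0.01,
) -> pd.DataFrame:
    """Per-variant drift folds against a cosmopolitan reference.

    ``signal_mafs`` needs columns ``rsid`` plus one ``maf_<cohort>`` column
    per cohort; ``reference`` needs ``rsid, maf`` (minor-allele scale on
    the discovery minor allele).  Fold = cohort MAF / reference MAF, with
    ``inf`` when the reference MAF is zero (reported but excluded from
    finite-fold summaries).  Variants absent from the reference are
    dropped with a log entry.
    """
    ref = reference.set_index("rsid")["maf"]
    maf_cols = [c for c in signal_mafs.columns if c.startswith("maf_")]
    rows = []
    n_dropped = 0
    for _, rec in signal_mafs.iterrows():
        if rec["rsid"] not in ref.index:
            n_dropped += 1
            continue
        ref_maf = float(ref[rec["rsid"]])
        out = {"rsid": rec["rsid"], "reference_maf": ref_maf,
               "rare_in_reference": ref_maf < rare_cut}
        folds = []
        for c in maf_cols:
            maf = float(rec[c])
            fold = np.inf if ref_maf == 0 else maf / ref_maf
            out[f"fold_{c[4:]}"] = fold
            out[c] = maf
            folds.append(fold)
        finite = [f for f in folds if np.isfinite(f)]
        out["max_fold"] = max(folds) if folds else np.nan
        out["drifted"] = bool(folds) and max(folds) >= min_fold
        rows.append(out)
    if n_dropped:
        log.info("drift annotation dropped %d variants absent from reference", n_dropped)
    return pd.DataFrame(rows)


def condition_on_known(
    y: np.ndarray,
    panel: GenotypePanel,
    fit: LMMFit,
    index_rsid: str,
    known_rsids: list[str],
    study_threshold: float,
    window: int = 1_000_000,
) -> dict:
    """Novelty by conditioning the index variant on known signals.

    If no catalogued variant lies within ``window`` bp of the index the
    signal is novel outright; otherwise the index variant's association is
    re-run with the known variants' dosages as covariates of the mixed
    model, and the signal is novel iff the conditional P stays below the
    study-wide threshold.
    """
    by_rsid = {r: j for j, r in enumerate(panel.variants["rsid"])}
    ji = by_rsid.get(index_rsid)
    if ji is None:
        raise KeyError(f"index variant {index_rsid} not in panel")
    ipos = int(panel.variants["pos"].iat[ji])
    ichrom = panel.variants["chrom"].iat[ji]

    nearby = []
    for r in known_rsids:
        jk = by_rsid.get(r)
        if jk is None:
            log.info("known variant %s absent from panel; not conditionable", r)
            continue
        if (
            panel.variants["chrom"].iat[jk] == ichrom
            and abs(int(panel.variants["pos"].iat[jk]) - ipos) <= window
        ):
            nearby.append(jk)

    if not nearby:
        return {"rsid": index_rsid, "novel": True, "conditioned_on": [],
                "p_conditional": None}
    covs = panel.dosages[:, nearby]
    beta, se, p = assoc_single_with_covariates(y, panel.dosages[:, ji], fit, covs)
    return {
        "rsid": index_rsid,
        "novel": bool(p < study_threshold),
        "conditioned_on": [panel.variants["rsid"].iat[j] for j in nearby],
        "p_conditional": p,
        "beta_conditional": beta,
        "se_conditional": se,
    }


def flag_pleiotropic(
    mapped_gene: str | None,
    pleiotropic_genes: tuple[str, ...] = PLEIOTROPIC_GENES,
) -> bool:
    """True iff the trans signal's mapped gene is in the pleiotropic list."""
    if mapped_gene is None:
        return False
    return mapped_gene in set(pleiotropic_genes)


def replication_lookup(
    discovery: pd.DataFrame,
    replication: pd.DataFrame,
    ld: PanelLD,
    proxy_r2: float = 0.8,
    alpha: float = 0.05,
    proxy_window: float = 1e6,
) -> pd.DataFrame:
    """Replication of independent variants, with LD-proxy fallback.

    ``discovery`` and ``replication`` carry ``rsid, chrom/chr, pos, beta,
    se, p`` harmonized to the same alleles.  Each variant is looked up
    directly; if absent, the best proxy with ``r^2 > proxy_r2`` within
    ``proxy_window`` bp stands in (the signed LD correlation orients the
    expected effect direction).  A variant replicates iff its (proxy)
    P-value beats the Bonferroni threshold ``alpha / n_sought`` and the
    effect direction agrees.
    """
    n_sought = len(discovery)
    thresh = alpha / n_sought if n_sought else alpha
    rep_by_rsid = replication.set_index("rsid")
    rows = []
    for _, rec in discovery.iterrows():
        status, proxy, proxy_ld, p_rep, b_rep = "absent", None, np.nan, np.nan, np.nan
        sign_expect = np.sign(rec["beta"])
        if rec["rsid"] in rep_by_rsid.index:
            hit = rep_by_rsid.loc[rec["rsid"]]
            p_rep, b_rep = float(hit["p"]), float(hit["beta"])
            agree = np.sign(b_rep) == sign_expect
            status = "replicated" if (p_rep < thresh and agree) else "not_replicated"
        else:
            ji = ld.by_rsid.get(rec["rsid"])
            if ji is not None:
                best = (0.0, None)
                for r in rep_by_rsid.index:
                    jk = ld.by_rsid.get(r)
                    if jk is None:
                        continue
                    if abs(
                        int(ld.variants["pos"].iat[jk]) - int(rec["pos"])
                    ) > proxy_window:
                        continue
                    r_signed = ld.r(ji, jk)
                    if np.isfinite(r_signed) and r_signed**2 > max(proxy_r2, best[0]):
                        best = (r_signed**2, (r, r_signed))
                if best[1] is not None:
                    proxy, r_signed = best[1]
                    proxy_ld = best[0]
                    hit = rep_by_rsid.loc[proxy]
                    p_rep, b_rep = float(hit["p"]), float(hit["beta"])
                    agree = np.sign(b_rep) == sign_expect * np.sign(r_signed)
                    status = (
                        "replicated_proxy"
                        if (p_rep < thresh and agree)
                        else "not_replicated"
                    )
        rows.append(
            {
                "rsid": rec["rsid"],
                "status": status,
                "proxy_rsid": proxy,
                "proxy_r2": proxy_ld,
                "p_replication": p_rep,
                "beta_replication": b_rep,
                "threshold": thresh,
            }
        )
    return pd.DataFrame(rows)
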