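"""Two-sample Mendelian randomization of protein levels on outcome traits.

Instruments are the conditionally independent pQTLs of each protein;
variants absent from the outcome GWAS may be replaced by LD proxies
(r^2 > 0.8).  Single-instrument analyses use the Wald ratio (outcome
effect over exposure effect, first-order delta-method SE); multi-
instrument analyses use the fixed-effect inverse-variance-weighted
estimator.  P-values across all protein-trait pairs are adjusted with
Benjamini-Hochberg.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genostats import PanelLD

log = logging.getLogger(__name__)

PALINDROMIC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
#: ambiguous-frequency band within which palindromic variants are dropped
PALINDROMIC_AF_BAND = (0.42, 0.58)


@dataclass
class MREstimate:
    method: str  # "wald_ratio" | "ivw"
    beta: float
    se: float
    p: float
    n_instruments: int


def select_instruments(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    ld: PanelLD,
    proxy_r2: float = 0.8,
    proxy_window: float = 1e6,
) -> pd.DataFrame:
    """Match a protein's independent pQTLs to outcome GWAS statistics.

    ``exposure`` rows carry ``rsid, pos, af, beta, se`` (joint/conditional
    estimates); ``outcome`` is a GWAS summary table with ``rsid, beta,
    se``.  Variants without an rsid are excluded; palindromic variants
    with allele frequency in the ambiguous band are dropped; a variant
    absent from the outcome is replaced by its best LD proxy with
    ``r^2 > proxy_r2`` (exposure statistics are then taken at the proxy
    position, with the signed LD correlation orienting the effect).
    Returns one row per usable instrument; empty when none is usable.
    """
    out_by_rsid = outcome.set_index("rsid")
    rows = []
    for _, rec in exposure.iterrows():
        rsid = rec.get("rsid")
        if rsid is None or (isinstance(rsid, float) and np.isnan(rsid)) or rsid == "":
            continue
        a1, a0 = str(rec.get("allele1", "")), str(rec.get("allele0", ""))
        if (a1, a0) in PALINDROMIC:
            af = float(rec.get("af", 0.5))
            if PALINDROMIC_AF_BAND[0] <= af <= PALINDROMIC_AF_BAND[1]:
                log.info("dropping palindromic instrument %s (af %.2f)", rsid, af)
                continue
        if rsid in out_by_rsid.index:
            hit = out_by_rsid.loc[rsid]
            rows.append(
                {
                    "rsid": rsid,
                    "bx": float(rec["beta"]),
                    "se_x": float(rec["se"]),
                    "by": float(hit["beta"]),
                    "se_y": float(hit["se"]),
                    "proxy": False,
                    "proxy_r2": np.nan,
                }
            )
            continue
        ji = ld.by_rsid.get(rsid)
        if ji is None:
            continue
        best_r2, best = 0.0, None
        for r in out_by_rsid.index:
            jk = ld.by_rsid.get(r)
            if jk is None:
                continue
            if abs(int(ld.variants["pos"].iat[jk]) - int(rec["pos"])) > proxy_window:
                continue
            r_signed = ld.r(ji, jk)
            if np.isfinite(r_signed) and r_signed**2 > max(proxy_r2, best_r2):
                best_r2, best = r_signed**2, (r, r_signed)
        if best is None:
            continue
        proxy_rsid, r_signed = best
        hit = out_by_rsid.loc[proxy_rsid]
        # exposure effect re-expressed on the proxy's allele scale
        rows.append(
            {
                "rsid": proxy_rsid,
                "bx": float(rec["beta"]) * np.sign(r_signed),
                "se_x": float(rec["se"]),
                "by": float(hit["beta"]),
                "se_y": float(hit["se"]),
                "proxy": True,
                "proxy_r2": best_r2,
            }
        )
    return pd.DataFrame(
        rows, columns=["rsid", "bx", "se_x", "by", "se_y", "proxy", "proxy_r2"]
    )


def wald_ratio(bx: float, se_x: float, by: float, se_y: float) -> MREstimate:
    """Single-instrument Wald ratio: by / bx with first-order SE |se_y / bx|."""
    if bx == 0:
        raise ZeroDivisionError("instrument-exposure effect is zero")
    beta = by / bx
    se = abs(se_y / bx)
    z = beta / se
    return MREstimate(
        "wald_ratio", float(beta), float(se), float(2 * stats.norm.sf(abs(z))), 1
    )


def ivw_estimate(instruments: pd.DataFrame) -> MREstimate:
    """Fixed-effect inverse-variance-weighted estimate over >= 2 instruments.

    beta = sum(bx * by / se_y^2) / sum(bx^2 / se_y^2);
    se = 1 / sqrt(sum(bx^2 / se_y^2)); two-sided normal P.
    """
    if len(instruments) < 2:
        raise ValueError("IVW requires at least 2 instruments; use wald_ratio")
    bx = instruments["bx"].to_numpy(dtype=float)
    by = instruments["by"].to_numpy(dtype=float)
    se_y = instruments["se_y"].to_numpy(dtype=float)
    w = bx**2 / se_y**2
    beta = float((bx * by / se_y**2).sum() / w.sum())
    se = float(1.0 / np.sqrt(w.sum()))
    z = beta / se
    return MREstimate(
        "ivw", beta, se, float(2 * stats.norm.sf(abs(z))), len(instruments)
    )


def mr_estimate(instruments: pd.DataFrame) -> MREstimate | None:
    """Dispatch: Wald ratio for one instrument, IVW for several, None for none."""
    if instruments.empty:
        return None
    if len(instruments) == 1:
        r = instruments.iloc[0]
        return wald_ratio(r["bx"], r["se_x"], r["by"], r["se_y"])
    return ivw_estimate(instruments)


def fdr_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty P-value list")
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]
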