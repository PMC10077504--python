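"""Signal extraction and approximate conditional/joint analysis.

Turns meta-analysis summary statistics into association peaks and
conditionally independent variants:

* ``extract_peaks`` — greedy LD pruning of sub-threshold variants
  (ascending P, removing neighbours with r^2 above a drop threshold)
  followed by distance-based grouping; the index variant of each group is
  the one with the lowest P-value.
* ``clump`` — plink-style LD clumping (r^2 and window) to thin candidates
  before model selection.
* ``cojo_select`` / ``cojo_condition`` — stepwise summary-statistic joint
  model selection and conditioning, reconstructing the multiple-regression
  normal equations from marginal effects, allele frequencies, effective
  sample size and a reference-panel LD matrix (the GCTA-COJO algebra).
* ``merge_adjacent_peaks`` — automated surrogate for the manual merging of
  neighbouring peaks created by the extended LD of isolate cohorts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genostats import PanelLD

log = logging.getLogger(__name__)


@dataclass
class Peak:
    chrom: str
    start: int
    end: int
    index_rsid: str
    index_pos: int
    index_p: float
    members: list[str] = field(default_factory=list)
    significant: bool = True


def extract_peaks(
    meta: pd.DataFrame,
    ld: PanelLD,
    p_extract: float = 1e-6,
    r2_drop: float = 0.2,
    group_dist: float = 2e6,
    study_threshold: float | None = None,
    min_mac: int = 10,
    hwe_fail: set[str] | None = None,
) -> list[Peak]:
    """Greedy LD-and-distance signal extraction from summary statistics.

    Variants with ``p < p_extract`` are sorted by increasing P; walking the
    list, each variant removes all remaining variants on the same
    chromosome in LD at ``r^2 > r2_drop``.  Survivors within
    ``group_dist`` of each other are grouped; the index is the lowest-P
    member.  Candidate index variants must have MAC >= ``min_mac`` and
    pass HWE (``hwe_fail`` lists failing rsids).  Peaks whose index P is
    not below ``study_threshold`` are flagged non-significant.
    """
    hwe_fail = hwe_fail or set()
    cand = meta[meta["p"] < p_extract].copy()
    if "mac" in cand.columns:
        cand = cand[cand["mac"].fillna(np.inf) >= min_mac]
    cand = cand[~cand["rsid"].isin(hwe_fail)]
    if cand.empty:
        return []
    cand = cand.sort_values(["p", "chr", "pos"], kind="stable").reset_index(drop=True)

    removed = np.zeros(len(cand), dtype=bool)
    selected: list[int] = []
    for i in range(len(cand)):
        if removed[i]:
            continue
        selected.append(i)
        ri = cand["rsid"].iat[i]
        ji = ld.by_rsid.get(ri)
        if ji is None:
            continue
        for k in range(i + 1, len(cand)):
            if removed[k] or cand["chr"].iat[k] != cand["chr"].iat[i]:
                continue
            jk = ld.by_rsid.get(cand["rsid"].iat[k])
            if jk is None:
                continue
            r2 = ld.r2(ji, jk)
            if np.isfinite(r2) and r2 > r2_drop:
                removed[k] = True

    surv = cand.iloc[selected].sort_values(["chr", "pos"]).reset_index(drop=True)
    peaks: list[Peak] = []
    group: list[int] = []

    def _flush(group_idx: list[int]) -> None:
        g = surv.iloc[group_idx]
        best = g["p"].idxmin()
        p_index = float(g.loc[best, "p"])
        peaks.append(
            Peak(
                chrom=str(g["chr"].iat[0]),
                start=int(g["pos"].min()),
                end=int(g["pos"].max()),
                index_rsid=str(g.loc[best, "rsid"]),
                index_pos=int(g.loc[best, "pos"]),
                index_p=p_index,
                members=list(g["rsid"]),
                significant=(
                    True if study_threshold is None else p_index < study_threshold
                ),
            )
        )

    for i in range(len(surv)):
        if group and (
            surv["chr"].iat[i] != surv["chr"].iat[group[-1]]
            or surv["pos"].iat[i] - surv["pos"].iat[group[-1]] >= group_dist
        ):
            _flush(group)
            group = []
        group.append(i)
    if group:
        _flush(group)
    return peaks


def clump(
    meta: pd.DataFrame,
    ld: PanelLD,
    r2: float = 0.1,
    window: float = 1e6,
) -> pd.DataFrame:
    """Plink-style greedy LD clumping by ascending P-value.

    A retained variant absorbs all remaining candidates within ``window``
    base pairs and in LD at ``r^2 > r2``; absorbed variants leave
    candidacy.  Returns the retained rows with a ``clumped`` column
    listing absorbed rsids.
    """
    cand = meta.sort_values(["p", "chr", "pos"], kind="stable").reset_index(drop=True)
    removed = np.zeros(len(cand), dtype=bool)
    kept_rows = []
    for i in range(len(cand)):
        if removed[i]:
            continue
        ji = ld.by_rsid.get(cand["rsid"].iat[i])
        absorbed = []
        for k in range(i + 1, len(cand)):
            if removed[k] or cand["chr"].iat[k] != cand["chr"].iat[i]:
                continue
            if abs(cand["pos"].iat[k] - cand["pos"].iat[i]) > window:
                continue
            jk = ld.by_rsid.get(cand["rsid"].iat[k])
            if ji is None or jk is None:
                continue
            r2_ik = ld.r2(ji, jk)
            if np.isfinite(r2_ik) and r2_ik > r2:
                removed[k] = True
                absorbed.append(cand["rsid"].iat[k])
        row = cand.iloc[i].copy()
        row["clumped"] = ",".join(absorbed)
        kept_rows.append(row)
    return pd.DataFrame(kept_rows).reset_index(drop=True)


# ---------------------------------------------------------------------------
# summary-statistic joint regression (COJO algebra)


def _prepare(sub: pd.DataFrame, ld: PanelLD) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Per-variant genotype variances, positions, effective n and implied y'y."""
    var_x = np.empty(len(sub))
    for a, rsid in enumerate(sub["rsid"]):
        j = ld.by_rsid.get(rsid)
        if j is not None:
            var_x[a] = ld.dosage_variance(j)
        else:  # fall back to the HWE variance implied by the allele frequency
            p = float(sub["af"].iat[a])
            var_x[a] = 2 * p * (1 - p)
    n = float(np.median(sub["n"]))
    b = sub["beta"].to_numpy(dtype=float)
    se = sub["se"].to_numpy(dtype=float)
    # y'y implied per variant by the marginal fit; median across variants
    yy = np.median(n * var_x * b**2 + se**2 * (n - 2) * n * var_x)
    return var_x, sub["pos"].to_numpy(dtype=float), n, yy


def _joint_fit(
    sub: pd.DataFrame, ld: PanelLD, window: float = 1e7
) -> pd.DataFrame:
    """Joint regression of all variants in ``sub`` from summary statistics.

    Reconstructs X'X from reference LD correlations and allele-frequency
    variances (correlations beyond ``window`` bp are taken as zero), X'y
    from the marginal effects, and the phenotypic sum of squares from the
    implied per-variant residual variances.
    """
    k = len(sub)
    var_x, pos, n, yy = _prepare(sub, ld)
    b = sub["beta"].to_numpy(dtype=float)

    idx = [ld.by_rsid.get(r) for r in sub["rsid"]]
    R = np.eye(k)
    for a in range(k):
        for c in range(a + 1, k):
            if abs(pos[a] - pos[c]) > window or idx[a] is None or idx[c] is None:
                r = 0.0
            else:
                r = ld.r(idx[a], idx[c])
                if not np.isfinite(r):
                    r = 0.0
            R[a, c] = R[c, a] = r

    sd = np.sqrt(var_x)
    XtX = n * R * np.outer(sd, sd)
    Xty = n * var_x * b
    try:
        beta_j = np.linalg.solve(XtX, Xty)
    except np.linalg.LinAlgError:
        beta_j, *_ = np.linalg.lstsq(XtX, Xty, rcond=None)
    df = max(n - k - 1, 1.0)
    sigma2 = max(float(yy - beta_j @ Xty) / df, 1e-30)
    try:
        cov = sigma2 * np.linalg.inv(XtX)
    except np.linalg.LinAlgError:
        cov = sigma2 * np.linalg.pinv(XtX)
    se_j = np.sqrt(np.clip(np.diag(cov), 1e-60, None))
    t = beta_j / se_j
    p = np.maximum(2 * stats.t.sf(np.abs(t), df=df), 5e-324)
    out = sub.copy().reset_index(drop=True)
    out["beta_joint"] = beta_j
    out["se_joint"] = se_j
    out["p_joint"] = p
    return out


def _max_r2_with(ld: PanelLD, rsid: str, selected: list[str]) -> float:
    j = ld.by_rsid.get(rsid)
    if j is None:
        return 0.0
    vals = []
    for r in selected:
        js = ld.by_rsid.get(r)
        if js is None:
            continue
        v = ld.r2(j, js)
        if np.isfinite(v):
            vals.append(v)
    return max(vals) if vals else 0.0


def cojo_select(
    meta: pd.DataFrame,
    ld: PanelLD,
    entry_p: float,
    collinearity_r2: float = 0.9,
    window: float = 1e7,
) -> pd.DataFrame:
    """Stepwise forward selection of conditionally independent variants.

    Starts from the lowest marginal P; at each step computes the
    approximate conditional association of every remaining candidate given
    the selected set and admits the best one if its conditional P is below
    ``entry_p`` and its maximum r^2 with the selected set is below
    ``collinearity_r2``.  Finishes with a joint fit of the selected set and
    removes any variant whose joint P rises above ``entry_p``.
    """
    usable = meta[meta["rsid"].map(lambda r: r in ld.by_rsid)].copy()
    skipped = len(meta) - len(usable)
    if skipped:
        log.info("cojo: %d candidates absent from the LD reference; skipped", skipped)
    if usable.empty:
        return usable.assign(beta_joint=[], se_joint=[], p_joint=[])
    cand = usable.sort_values(["p", "chr", "pos"], kind="stable").reset_index(drop=True)
    if float(cand["p"].iat[0]) >= entry_p:
        return cand.iloc[0:0].assign(beta_joint=[], se_joint=[], p_joint=[])

    selected = [0]
    while True:
        best_i, best_p, best_row = None, entry_p, None
        sel_rsids = [cand["rsid"].iat[s] for s in selected]
        for i in range(len(cand)):
            if i in selected:
                continue
            rsid = cand["rsid"].iat[i]
            if _max_r2_with(ld, rsid, sel_rsids) >= collinearity_r2:
                continue
            trial = cand.iloc[selected + [i]]
            fit = _joint_fit(trial, ld, window)
            p_cond = float(fit["p_joint"].iloc[-1])
            if p_cond < best_p:
                best_i, best_p = i, p_cond
        if best_i is None:
            break
        selected.append(best_i)

    # backward elimination on the joint model
    while True:
        fit = _joint_fit(cand.iloc[selected], ld, window)
        worst = int(np.argmax(fit["p_joint"].to_numpy()))
        if float(fit["p_joint"].iat[worst]) < entry_p or len(selected) == 1:
            break
        del selected[worst]
    final = _joint_fit(cand.iloc[selected], ld, window)
    return final.sort_values(["chr", "pos"]).reset_index(drop=True)


def cojo_condition(
    meta: pd.DataFrame,
    ld: PanelLD,
    condition_on: list[str],
    window: float = 1e7,
) -> pd.DataFrame:
    """Approximate conditional association given a set of conditioning variants.

    For each remaining variant the joint model {variant} + condition_on is
    fitted from summary statistics and the variant's coefficient reported
    as its conditional effect.  An empty conditioning set returns the
    marginal statistics unchanged.
    """
    out = meta.copy().reset_index(drop=True)
    if not condition_on:
        out["beta_cond"] = out["beta"]
        out["se_cond"] = out["se"]
        out["p_cond"] = out["p"]
        return out
    cond_rows = meta[meta["rsid"].isin(condition_on)]
    missing = set(condition_on) - set(cond_rows["rsid"])
    if missing:
        log.info("cojo_condition: conditioning variants missing from stats: %s", missing)
    res = {"beta_cond": [], "se_cond": [], "p_cond": []}
    for _, row in out.iterrows():
        if row["rsid"] in set(cond_rows["rsid"]):
            res["beta_cond"].append(0.0)
            res["se_cond"].append(np.nan)
            res["p_cond"].append(1.0)
            continue
        trial = pd.concat([row.to_frame().T, cond_rows], ignore_index=True)
        trial = trial.astype({"beta": float, "se": float, "af": float, "pos": float, "n": float})
        fit = _joint_fit(trial, ld, window)
        res["beta_cond"].append(float(fit["beta_joint"].iat[0]))
        res["se_cond"].append(float(fit["se_joint"].iat[0]))
        res["p_cond"].append(float(fit["p_joint"].iat[0]))
    for k, v in res.items():
        out[k] = v
    return out


def merge_adjacent_peaks(
    peaks: list[Peak],
    ld: PanelLD,
    merge_r2: float = 0.1,
    merge_dist: float = 1e6,
) -> list[Peak]:
    """Merge neighbouring peaks whose index variants are close or in LD.

    Automated surrogate for the manual review of split peaks in long-LD
    isolate cohorts: peaks merge when their index variants are within
    ``merge_dist`` bp or in LD at r^2 > ``merge_r2``; the merged index is
    the lowest-P index.  Idempotent.
    """
    merged = list(peaks)
    changed = True
    while changed:
        changed = False
        merged.sort(key=lambda p: (p.chrom, p.index_pos))
        out: list[Peak] = []
        for pk in merged:
            if out and out[-1].chrom == pk.chrom:
                prev = out[-1]
                close = abs(pk.index_pos - prev.index_pos) <= merge_dist
                ji = ld.by_rsid.get(prev.index_rsid)
                jk = ld.by_rsid.get(pk.index_rsid)
                r2 = ld.r2(ji, jk) if ji is not None and jk is not None else 0.0
                linked = np.isfinite(r2) and r2 > merge_r2
                if close or linked:
                    best, other = (
                        (prev, pk) if prev.index_p <= pk.index_p else (pk, prev)
                    )
                    out[-1] = Peak(
                        chrom=prev.chrom,
                        start=min(prev.start, pk.start),
                        end=max(prev.end, pk.end),
                        index_rsid=best.index_rsid,
                        index_pos=best.index_pos,
                        index_p=best.index_p,
                        members=sorted(set(prev.members) | set(pk.members)),
                        significant=prev.significant or pk.significant,
                    )
                    changed = True
                    continue
            out.append(pk)
        merged = out
    return merged
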