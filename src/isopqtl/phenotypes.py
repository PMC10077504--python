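"""Olink NPX phenotype QC and transformation to analysis-ready residuals.

Pipeline order is fixed: censor below-LOD values -> protein / sample
filters -> joint covariate regression -> rank-based inverse normal
transformation (INT).  The covariate model regresses each protein on
intercept, age, age^2, sex, plate indicators, season and the per-sample
mean NPX across all assays; residuals are mapped to standard-normal
quantiles via (rank - 0.5)/n with average ranks for ties.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .containers import AdjustedPhenotypes, ProteinMatrix

log = logging.getLogger(__name__)


def censor_below_lod(matrix: ProteinMatrix) -> ProteinMatrix:
    """Set NPX values strictly below each protein's LOD to missing.

    Values equal to the LOD are retained (only values that *fall below*
    the detection limit are unreliable).  Censoring counts are logged.
    """
    out = matrix.copy()
    for prot in out.proteins:
        lod = out.lod[prot]
        if pd.isna(lod):
            raise ValueError(f"no LOD defined for protein {prot}")
        below = out.values[prot] < lod
        n_below = int(below.sum())
        if n_below:
            out.values.loc[below, prot] = np.nan
            log.info("censored %d values below LOD for %s", n_below, prot)
    return out


def filter_proteins(
    matrix: ProteinMatrix, max_missing: float = 0.40
) -> tuple[ProteinMatrix, list[str]]:
    """Drop proteins whose missing/below-LOD proportion exceeds ``max_missing``.

    The threshold is exclusive: a protein at exactly ``max_missing`` is
    retained.  Samples with missing covariates are also dropped and logged.
    Returns the filtered matrix and the list of excluded proteins.
    """
    miss = matrix.missing_fraction()
    excluded = sorted(miss.index[miss > max_missing])
    kept = [p for p in matrix.proteins if p not in excluded]
    if excluded:
        log.info("excluded %d proteins for missingness: %s", len(excluded), excluded)

    cov_ok = matrix.covariates[["age", "sex", "plate", "season"]].notna().all(axis=1)
    n_dropped = int((~cov_ok).sum())
    if n_dropped:
        log.info("excluded %d samples with missing covariates", n_dropped)
    out = ProteinMatrix(
        matrix.values.loc[cov_ok, kept].copy(),
        matrix.lod[kept].copy(),
        matrix.covariates.loc[cov_ok].copy(),
    )
    return out, excluded


def inverse_normal_transform(x: pd.Series) -> pd.Series:
    """Rank-based INT: Phi^-1((rank - 0.5)/n), average ranks for ties."""
    mask = x.notna()
    ranks = x[mask].rank(method="average")
    q = stats.norm.ppf((ranks - 0.5) / mask.sum())
    out = pd.Series(np.nan, index=x.index, dtype=float)
    out[mask] = q
    return out


def _design_matrix(covs: pd.DataFrame, sample_mean: pd.Series) -> pd.DataFrame:
    X = pd.DataFrame(index=covs.index)
    X["intercept"] = 1.0
    X["age"] = covs["age"].astype(float)
    X["age2"] = X["age"] ** 2
    X["sex"] = covs["sex"].astype(float)
    plates = pd.get_dummies(covs["plate"], prefix="plate", drop_first=True)
    X = pd.concat([X, plates.astype(float)], axis=1)
    X["season"] = covs["season"].astype(float)
    X["sample_mean"] = sample_mean
    return X


def _drop_aliased(X: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str], list[str]]:
    """Remove columns that are linearly dependent on earlier ones.

    Plate and season can be exactly confounded when samples are plated in
    collection order; the aliased column is dropped rather than failing.
    """
    keep: list[int] = []
    dropped: list[str] = []
    for j in range(X.shape[1]):
        trial = X[:, keep + [j]]
        if np.linalg.matrix_rank(trial) > len(keep):
            keep.append(j)
        else:
            dropped.append(names[j])
    return X[:, keep], [names[j] for j in keep], dropped


def adjust_and_int(
    matrix: ProteinMatrix, sample_mean: pd.Series | None = None
) -> AdjustedPhenotypes:
    """Regress out covariates per protein, then inverse-normal transform.

    ``sample_mean`` is the per-sample mean NPX across all assays; pass the
    mean computed on the pre-filter (censored) matrix to adjust using all
    assays that passed vendor QC, before protein-level exclusion.  When
    omitted it is computed from the supplied matrix.  Rank-deficient
    designs (e.g. plate exactly aliased with season) drop the aliased
    column with a log entry instead of failing.
    """
    if sample_mean is None:
        sample_mean = matrix.values.mean(axis=1)
    sample_mean = sample_mean.reindex(matrix.values.index)
    X_full = _design_matrix(matrix.covariates, sample_mean)
    residuals = pd.DataFrame(
        np.nan, index=matrix.values.index, columns=matrix.proteins, dtype=float
    )
    n_retained = pd.Series(0, index=matrix.proteins, dtype=int)
    dropped_cols: dict[str, list[str]] = {}

    for prot in matrix.proteins:
        y = matrix.values[prot]
        mask = y.notna()
        n = int(mask.sum())
        n_retained[prot] = n
        if n < 3:
            continue
        Xs = X_full.loc[mask].to_numpy(dtype=float)
        Xs, kept_names, dropped = _drop_aliased(Xs, list(X_full.columns))
        if dropped:
            dropped_cols[prot] = dropped
            log.info("protein %s: dropped aliased columns %s", prot, dropped)
        coef, *_ = np.linalg.lstsq(Xs, y[mask].to_numpy(dtype=float), rcond=None)
        resid = y[mask].to_numpy(dtype=float) - Xs @ coef
        residuals.loc[mask, prot] = resid
        residuals[prot] = inverse_normal_transform(residuals[prot])
    return AdjustedPhenotypes(residuals, n_retained, dropped_cols)
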