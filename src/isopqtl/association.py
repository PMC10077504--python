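"""Linear mixed-model association for pre-adjusted protein phenotypes.

The model is ``y = mu + u + e`` with ``u ~ N(0, lambda * sigma^2 * K)`` for
a genomic relatedness matrix K.  The null variance ratio ``lambda`` is
estimated once per protein by REML on the eigendecomposition of K, then a
Wald test of each variant's dosage effect is carried out in the rotated
(eigenbasis-whitened) model with ``lambda`` held fixed — the classic
EMMA/GEMMA strategy.  Phenotypes arrive covariate-adjusted and
INT-transformed, so only an intercept is fitted alongside the dosage.

P-values use the t reference distribution with ``n - p`` degrees of
freedom rather than the normal, which matters at modest sample sizes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .containers import ASSOC_COLUMNS, GenotypePanel

log = logging.getLogger(__name__)

MIN_SAMPLES = 30


@dataclass
class LMMFit:
    """Null-model REML fit: variance ratio and rotation of the phenotype."""

    lmbda: float
    log_reml: float
    sigma2: float
    eigvals: np.ndarray
    eigvecs: np.ndarray
    yt: np.ndarray  # rotated phenotype U'y

    @property
    def h2(self) -> float:
        """Narrow-sense heritability implied by the variance ratio."""
        return self.lmbda / (1.0 + self.lmbda)


def _reml_neg_loglik(log_lambda: float, s: np.ndarray, yt: np.ndarray) -> float:
    lam = np.exp(log_lambda)
    d = lam * s + 1.0
    w = 1.0 / d
    n = len(yt)
    sw = w.sum()
    beta = (w * yt).sum() / sw
    r = yt - beta
    rss = (w * r * r).sum()
    nc = n - 1
    # profiled REML (constants dropped); sigma2_hat = rss / (n - 1)
    return 0.5 * (nc * np.log(rss / nc) + np.log(d).sum() + np.log(sw))


def fit_null_lmm(y: np.ndarray, K: np.ndarray) -> LMMFit:
    """REML fit of the null (no-variant) mixed model.

    Eigendecomposes K once and maximizes the restricted likelihood over
    ``log(lambda)`` in [-10, 10] to an absolute tolerance of 1e-6.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < MIN_SAMPLES:
        raise ValueError(f"refusing to fit mixed model with n = {n} < {MIN_SAMPLES}")
    if K.shape != (n, n):
        raise ValueError("GRM does not match phenotype length")
    s, U = np.linalg.eigh((K + K.T) / 2.0)
    if s.min() < -1e-6 * max(1.0, s.max()):
        raise ValueError("GRM is not positive semi-definite within tolerance")
    s = np.clip(s, 0.0, None)
    yt = U.T @ y

    res = optimize.minimize_scalar(
        _reml_neg_loglik,
        bounds=(-10.0, 10.0),
        args=(s, yt),
        method="bounded",
        options={"xatol": 1e-6},
    )
    lam = float(np.exp(res.x))
    d = lam * s + 1.0
    w = 1.0 / d
    beta = (w * yt).sum() / w.sum()
    r = yt - beta
    sigma2 = float((w * r * r).sum() / (n - 1))
    const = -0.5 * (n - 1) * (np.log(2 * np.pi) + 1.0)
    return LMMFit(lam, float(-res.fun + const), sigma2, s, U, yt)


def _rotated_wald(
    yt: np.ndarray, Xt: np.ndarray, w: np.ndarray, test_col: int
) -> tuple[float, float, float]:
    """GLS Wald test of one column in the rotated model.

    Returns (beta, se, p) with a t reference on n - p degrees of freedom.
    """
    n, p = Xt.shape
    Xw = Xt * w[:, None]
    XtX = Xw.T @ Xt
    Xty = Xw.T @ yt
    XtX_inv = np.linalg.pinv(XtX)
    coef = XtX_inv @ Xty
    resid = yt - Xt @ coef
    rss = float((w * resid * resid).sum())
    df = n - p
    sigma2 = rss / df
    se = float(np.sqrt(sigma2 * XtX_inv[test_col, test_col]))
    beta = float(coef[test_col])
    if se == 0:
        return beta, se, 1.0
    tstat = beta / se
    pval = float(2 * stats.t.sf(abs(tstat), df=df))
    return beta, se, max(pval, 5e-324)


def lmm_assoc(
    y: np.ndarray,
    panel: GenotypePanel,
    fit: LMMFit,
) -> pd.DataFrame:
    """Per-variant Wald association with lambda fixed at the null REML fit.

    Missing dosages are mean-imputed per variant; monomorphic variants are
    skipped with a log entry.  Effects are reported per alternate allele
    (``allele1``), in the GEMMA-style column order.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if panel.n_samples != n:
        raise ValueError("panel does not match phenotype length")

    G = panel.dosages.copy()
    af = np.nanmean(G, axis=0) / 2.0
    mac = panel.mac()
    idx = np.where(np.isnan(G))
    G[idx] = np.take(2 * af, idx[1])
    poly = G.std(axis=0) > 0
    n_skip = int((~poly).sum())
    if n_skip:
        log.info("skipping %d monomorphic variants", n_skip)

    U = fit.eigvecs
    w = 1.0 / (fit.lmbda * fit.eigvals + 1.0)
    yt = fit.yt
    ones_t = U.T @ np.ones(n)
    Gt = U.T @ G

    # closed-form weighted simple regression with intercept, vectorized
    sw = w.sum()
    s1y = (w * ones_t * yt).sum()
    s11 = (w * ones_t * ones_t).sum()
    sxy = Gt.T @ (w * yt)
    sx1 = Gt.T @ (w * ones_t)
    sxx = np.einsum("ij,i,ij->j", Gt, w, Gt)

    denom = s11 * sxx - sx1 * sx1
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = (s11 * sxy - sx1 * s1y) / denom
        alpha = (s1y - sx1 * beta) / s11
        # weighted RSS via sufficient statistics
        syy = (w * yt * yt).sum()
        rss = (
            syy
            - 2 * alpha * s1y
            - 2 * beta * sxy
            + alpha**2 * s11
            + 2 * alpha * beta * sx1
            + beta**2 * sxx
        )
        sigma2 = rss / (n - 2)
        var_beta = sigma2 * s11 / denom
        se = np.sqrt(var_beta)
        tstat = beta / se
    pval = 2 * stats.t.sf(np.abs(tstat), df=n - 2)

    out = pd.DataFrame(
        {
            "chr": panel.variants["chrom"],
            "pos": panel.variants["pos"],
            "rsid": panel.variants["rsid"],
            "allele1": panel.variants["alt"],
            "allele0": panel.variants["ref"],
            "af": af,
            "beta": beta,
            "se": se,
            "p_wald": np.maximum(pval, 5e-324),
            "n": n,
        }
    )[ASSOC_COLUMNS]
    out["mac"] = mac
    return out[poly].reset_index(drop=True)


def assoc_single_with_covariates(
    y: np.ndarray,
    g: np.ndarray,
    fit: LMMFit,
    covariates: np.ndarray | None = None,
) -> tuple[float, float, float]:
    """Wald test of one dosage vector with optional extra covariates.

    Used for conditioning on known variants: the known variants' dosages
    enter as covariates of the mixed model.  Returns (beta, se, p).
    """
    n = len(y)
    g = np.asarray(g, dtype=float)
    g = np.where(np.isnan(g), np.nanmean(g), g)
    cols = [np.ones(n), g]
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != n:
            C = C.T
        for k in range(C.shape[1]):
            ck = C[:, k]
            cols.append(np.where(np.isnan(ck), np.nanmean(ck), ck))
    X = np.column_stack(cols)
    # dosage exactly in the span of the covariates (e.g. conditioning a
    # variant on itself): the signal is fully absorbed
    others = np.delete(X, 1, axis=1)
    coef, *_ = np.linalg.lstsq(others, X[:, 1], rcond=None)
    resid = X[:, 1] - others @ coef
    if resid.var() <= 1e-10 * max(X[:, 1].var(), 1e-30):
        return 0.0, float("nan"), 1.0
    U = fit.eigvecs
    w = 1.0 / (fit.lmbda * fit.eigvals + 1.0)
    return _rotated_wald(U.T @ y, U.T @ X, w, test_col=1)


def sex_stratified_assoc(
    y: np.ndarray,
    panel: GenotypePanel,
    K: np.ndarray,
    sex: np.ndarray,
) -> tuple[pd.DataFrame | None, pd.DataFrame | None]:
    """Independent LMM association runs in males (sex == 1) and females.

    Each stratum refits the null model on the corresponding GRM
    sub-matrix; strata smaller than 30 samples are skipped with a log
    entry and returned as ``None``.
    """
    sex = np.asarray(sex)
    results: list[pd.DataFrame | None] = []
    for label, code in (("male", 1), ("female", 0)):
        idx = np.flatnonzero(sex == code)
        if idx.size < MIN_SAMPLES:
            log.info("stratum %s too small (n = %d); skipped", label, idx.size)
            results.append(None)
            continue
        sub_panel = panel.subset_samples(idx)
        sub_K = K[np.ix_(idx, idx)]
        fit = fit_null_lmm(y[idx], sub_K)
        results.append(lmm_assoc(y[idx], sub_panel, fit))
    return results[0], results[1]
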