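"""Mixed-model association against OLS oracles and simulator ground truth."""

import numpy as np
import pytest
from scipy import stats

from isopqtl.association import (
    assoc_single_with_covariates,
    fit_null_lmm,
    lmm_assoc,
    sex_stratified_assoc,
)
from isopqtl.config import SimConfig
from isopqtl.genostats import compute_grm, lambda_gc
from isopqtl.simulate import simulate_cohorts

from conftest import make_panel


def ols_oracle(y, g):
    X = np.column_stack([np.ones(len(g)), g])
    coef, rss, *_ = np.linalg.lstsq(X, y, rcond=None)
    sigma2 = rss[0] / (len(g) - 2)
    se = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
    t = coef[1] / se
    return coef[1], se, 2 * stats.t.sf(abs(t), len(g) - 2)


@pytest.fixture(scope="module")
def polygenic_study():
    cfg = SimConfig(
        n_samples_per_cohort=1000,
        n_variants=4000,
        n_proteins=3,
        polygenic_h2=0.5,
        drift_fst=0.0,  # keep the planted variant common in the cohort
        ld_rho=0.0,
        n_cis_effects=1,
        n_trans_effects=0,
        effect_betas=[1.0],
        genotype_missing_rate=0.0,
        seed=21,
    )
    study = simulate_cohorts(cfg)
    panel = study.panels["cohortA"]
    K = compute_grm(panel.subset_variants(np.flatnonzero(panel.maf() > 0.05)))
    return study, panel, K


class TestNullFit:
    def test_identity_grm_collapses_to_ols(self, rng):
        n, m = 200, 50
        y = rng.standard_normal(n)
        d = (rng.random((n, m)) < 0.3).astype(float) + (rng.random((n, m)) < 0.3)
        panel = make_panel(d)
        fit = fit_null_lmm(y, np.eye(n))
        tab = lmm_assoc(y, panel, fit)
        for _, row in tab.iterrows():
            j = int(row["pos"] // 1000 - 1)
            b, se, p = ols_oracle(y, d[:, j])
            assert row["beta"] == pytest.approx(b, abs=1e-8)
            assert row["se"] == pytest.approx(se, abs=1e-8)
            assert row["p_wald"] == pytest.approx(p, abs=1e-8)

    def test_heritability_recovered(self, polygenic_study):
        """Planted polygenic h2 = 0.5: REML lambda/(1+lambda) within 0.1."""
        study, panel, K = polygenic_study
        resid = study.proteins["cohortA"].values["PROT001"]  # no planted pQTL
        y = (resid - resid.mean()) / resid.std()
        fit = fit_null_lmm(y.to_numpy(), K)
        assert fit.h2 == pytest.approx(0.5, abs=0.1)

    def test_permuted_phenotype_loses_heritability(self, polygenic_study, rng):
        study, panel, K = polygenic_study
        resid = study.proteins["cohortA"].values["PROT001"].to_numpy()
        y = rng.permutation(resid)
        fit = fit_null_lmm((y - y.mean()) / y.std(), K)
        assert fit.h2 < 0.1

    def test_small_sample_refused(self):
        with pytest.raises(ValueError, match="n = 10"):
            fit_null_lmm(np.zeros(10), np.eye(10))

    def test_non_psd_grm_rejected(self, rng):
        n = 50
        K = -np.eye(n)
        with pytest.raises(ValueError, match="positive semi-definite"):
            fit_null_lmm(rng.standard_normal(n), K)


class TestAssoc:
    def test_planted_effect_recovered_with_relatedness(self, polygenic_study):
        study, panel, K = polygenic_study
        truth = study.truth.pqtls.iloc[0]
        y = study.proteins["cohortA"].values[truth["protein"]].to_numpy()
        y = (y - y.mean()) / y.std()
        fit = fit_null_lmm(y, K)
        tab = lmm_assoc(y, panel, fit)
        row = tab[tab["rsid"] == truth["rsid"]].iloc[0]
        # phenotype standardized: planted beta shrinks by the phenotype sd
        target = truth["beta"] / study.proteins["cohortA"].values[
            truth["protein"]
        ].std()
        assert abs(row["beta"] - target) < 3 * row["se"]
        assert row["p_wald"] < 1e-8

    def test_allele_relabeling_flips_beta_only(self, rng):
        n = 300
        g = (rng.random(n) < 0.4).astype(float) + (rng.random(n) < 0.4)
        y = 0.3 * g + rng.standard_normal(n)
        panel = make_panel(np.column_stack([g, 2 - g]))
        fit = fit_null_lmm(y, np.eye(n))
        tab = lmm_assoc(y, panel, fit)
        assert tab["beta"].iloc[0] == pytest.approx(-tab["beta"].iloc[1], rel=1e-9)
        assert tab["p_wald"].iloc[0] == pytest.approx(tab["p_wald"].iloc[1], rel=1e-9)

    def test_null_panel_lambda_gc_in_band(self, rng):
        """No planted effects, unrelated samples: genomic control within the
        QC band used to exclude misbehaving proteins."""
        n, m = 800, 20_000
        p = rng.uniform(0.05, 0.5, m)
        d = (rng.random((n, m)) < p).astype(float) + (rng.random((n, m)) < p)
        y = rng.standard_normal(n)
        fit = fit_null_lmm(y, np.eye(n))
        tab = lmm_assoc(y, make_panel(d), fit)
        assert 0.97 <= lambda_gc(tab["p_wald"]) <= 1.05

    def test_conditioning_on_near_perfect_proxy_absorbs_signal(self, rng):
        n = 500
        g = (rng.random(n) < 0.3).astype(float) + (rng.random(n) < 0.3)
        proxy = g.copy()
        flip = rng.choice(n, size=5, replace=False)
        proxy[flip] = rng.integers(0, 3, size=5)  # r^2 ~ 0.99
        y = 0.8 * g + rng.standard_normal(n)
        fit = fit_null_lmm(y, np.eye(n))
        b_marg, _, p_marg = assoc_single_with_covariates(y, g, fit)
        b_cond, se_cond, p_cond = assoc_single_with_covariates(
            y, g, fit, covariates=proxy
        )
        assert p_marg < 1e-10
        # the proxy carries essentially the whole signal
        assert p_cond > 1e-3
        assert abs(b_cond) < 3 * se_cond + 0.3


class TestSexStratified:
    def test_identical_strata_identical_tables(self, rng):
        n = 120
        d = (rng.random((n, 20)) < 0.4).astype(float)
        y_half = rng.standard_normal(n // 2)
        y = np.concatenate([y_half, y_half])
        dd = np.vstack([d[: n // 2], d[: n // 2]])
        panel = make_panel(dd)
        sex = np.array([1] * (n // 2) + [0] * (n // 2))
        male, female = sex_stratified_assoc(y, panel, np.eye(n), sex)
        np.testing.assert_allclose(male["beta"], female["beta"], atol=1e-10)

    def test_small_stratum_skipped(self, rng):
        n = 100
        panel = make_panel((rng.random((n, 5)) < 0.4).astype(float))
        sex = np.array([1] * 10 + [0] * 90)
        male, female = sex_stratified_assoc(
            rng.standard_normal(n), panel, np.eye(n), sex
        )
        assert male is None and female is not None

    def test_sex_specific_effect_recovered(self, rng):
        """beta = 1 in males, 0 in females: stratum estimates within 3 SE."""
        n = 1200
        g = (rng.random(n) < 0.3).astype(float) + (rng.random(n) < 0.3)
        sex = rng.integers(0, 2, n)
        y = np.where(sex == 1, 1.0 * g, 0.0) + rng.standard_normal(n)
        panel = make_panel(g[:, None])
        male, female = sex_stratified_assoc(y, panel, np.eye(n), sex)
        assert abs(male["beta"].iloc[0] - 1.0) < 3 * male["se"].iloc[0]
        assert abs(female["beta"].iloc[0]) < 3 * female["se"].iloc[0]
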