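"""Variant statistics against independent oracles: the exact HWE test vs
full enumeration, VIF pruning vs exhaustive subset search, the GRM vs
pedigree expectations, and the significance-threshold arithmetic."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from isopqtl.config import SimConfig
from isopqtl.genostats import (
    compute_grm,
    hwe_exact_test,
    lambda_gc,
    ld_prune,
    ld_r2,
    significance_threshold,
    variant_qc,
)
from isopqtl.simulate import simulate_cohorts

from conftest import make_panel


def hwe_enumeration_oracle(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Direct enumeration of the conditional heterozygote distribution."""
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n_bb + n_ab

    def prob(het: int):
        hom_a = (n_a - het) // 2
        hom_b = (n_b - het) // 2
        if hom_a < 0 or hom_b < 0 or (n_a - het) % 2:
            return Fraction(0)
        return Fraction(
            2**het
            * math.factorial(n)
            * math.factorial(n_a)
            * math.factorial(n_b),
            math.factorial(het)
            * math.factorial(hom_a)
            * math.factorial(hom_b)
            * math.factorial(2 * n),
        )

    probs = {h: prob(h) for h in range(min(n_a, n_b) + 1)}
    total = sum(probs.values())
    p_obs = probs[n_ab]
    return float(sum(p for p in probs.values() if p <= p_obs) / total)


class TestHweExact:
    def test_monomorphic_returns_one(self):
        assert hwe_exact_test(50, 0, 0) == 1.0
        assert hwe_exact_test(0, 0, 7) == 1.0

    @pytest.mark.parametrize(
        "counts", [(0, 2, 0), (25, 50, 25), (10, 5, 10), (1, 1, 1), (0, 10, 0)]
    )
    def test_matches_enumeration(self, counts):
        assert hwe_exact_test(*counts) == pytest.approx(
            hwe_enumeration_oracle(*counts), rel=1e-10
        )

    @given(
        st.integers(0, 20), st.integers(0, 20), st.integers(0, 20)
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_equals_enumeration_up_to_n50(self, a, h, b):
        if a + h + b == 0:
            return
        assert hwe_exact_test(a, h, b) == pytest.approx(
            hwe_enumeration_oracle(a, h, b), rel=1e-9
        )

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 2, 3)


class TestVariantQC:
    def test_mac_boundary(self, rng):
        n = 200
        d = np.zeros((n, 2))
        d[:9, 0] = 1.0  # MAC 9: fails
        d[:10, 1] = 1.0  # MAC 10: passes
        res = variant_qc(make_panel(d))
        assert list(res.kept) == [1]

    def test_missingness_boundary(self, rng):
        n = 200
        d = rng.integers(0, 2, size=(n, 2)).astype(float) + rng.integers(
            0, 2, size=(n, 2)
        )
        d[:3, 0] = np.nan  # 1.5% missing: fails
        d[:2, 1] = np.nan  # 1.0% missing: passes (boundary is ">1%")
        res = variant_qc(make_panel(d))
        assert 1 in res.kept and 0 not in res.kept

    def test_constructed_failure_count(self, rng):
        n = 400
        m = 100
        p = rng.uniform(0.2, 0.5, m)
        d = (rng.random((n, m)) < p).astype(float) + (rng.random((n, m)) < p)
        # 3 variants fail missingness, 2 fail MAC, 2 fail HWE
        for j in range(3):
            d[: int(0.02 * n), j] = np.nan
        for j in range(3, 5):
            d[:, j] = 0.0
            d[:5, j] = 1.0
        for j in range(5, 7):
            d[:, j] = 1.0  # all heterozygous: gross HWE violation
        res = variant_qc(make_panel(d))
        assert len(res.kept) == 93


class TestLdR2:
    def test_identical_columns(self, rng):
        g = rng.integers(0, 3, 100).astype(float)
        panel = make_panel(np.column_stack([g, g]))
        assert ld_r2(panel, 0, 1) == pytest.approx(1.0)

    def test_complement_is_sign_invariant(self, rng):
        g = rng.integers(0, 3, 100).astype(float)
        panel = make_panel(np.column_stack([g, 2 - g]))
        assert ld_r2(panel, 0, 1) == pytest.approx(1.0)

    def test_independent_variants_near_zero(self, rng):
        n = 10_000
        d = (rng.random((n, 2)) < 0.3).astype(float) + (rng.random((n, 2)) < 0.3)
        panel = make_panel(d)
        assert ld_r2(panel, 0, 1) < 0.01

    def test_too_few_pairs_undefined(self):
        d = np.array([[0.0, 1.0], [np.nan, 0.0], [1.0, np.nan]])
        panel = make_panel(d)
        assert np.isnan(ld_r2(panel, 0, 1))


def vif_prune_oracle(dosages: np.ndarray, vif_cap: float, maf: np.ndarray):
    """Exhaustive search: largest subset (fewest removals) whose members all
    have VIF <= cap; ties resolved toward the greedy tie-break order."""
    m = dosages.shape[1]
    Z = dosages - dosages.mean(axis=0)
    Z = Z / Z.std(axis=0)
    R_full = Z.T @ Z / len(Z)

    def ok(subset):
        if len(subset) < 2:
            return True
        R = R_full[np.ix_(subset, subset)]
        vifs = np.diag(np.linalg.inv(R + 1e-8 * np.eye(len(subset))))
        return vifs.max() <= vif_cap

    best = None
    for size in range(m, 0, -1):
        for subset in itertools.combinations(range(m), size):
            if ok(list(subset)):
                best = set(subset)
                break
        if best is not None:
            break
    return best


class TestLdPrune:
    def test_independent_all_kept(self, rng):
        d = (rng.random((500, 20)) < 0.4).astype(float) + (
            rng.random((500, 20)) < 0.4
        )
        kept = ld_prune(make_panel(d), window=10, step=2, vif=2.0)
        assert len(kept) == 20

    def test_duplicate_column_removes_exactly_one(self, rng):
        g = (rng.random(300) < 0.4).astype(float) + (rng.random(300) < 0.4)
        others = (rng.random((300, 4)) < 0.3).astype(float)
        d = np.column_stack([g, others[:, :2], g, others[:, 2:]])
        kept = ld_prune(make_panel(d), window=6, step=1, vif=2.0)
        assert ({0, 3} & set(kept)) != {0, 3}
        assert len(kept) == 5

    def test_matches_exhaustive_oracle_on_small_windows(self, rng):
        """Greedy removal achieves the exhaustive-search optimum (size of the
        kept set) on correlated blocks of <= 8 variants."""
        for seed in range(5):
            r = np.random.default_rng(seed)
            n, m = 400, 7
            base = r.standard_normal((n, 2))
            lat = base[:, r.integers(0, 2, m)] + 0.9 * r.standard_normal((n, m))
            d = (lat > 0).astype(float) + (lat > 0.8)
            panel = make_panel(d)
            kept = ld_prune(panel, window=m, step=m, vif=2.0)
            oracle = vif_prune_oracle(d, 2.0, panel.maf())
            assert len(kept) == len(oracle)

    def test_invariant_to_input_variant_order(self, rng):
        n, m = 300, 12
        lat = rng.standard_normal((n, 3))
        d = (
            (lat[:, rng.integers(0, 3, m)] + rng.standard_normal((n, m))) > 0
        ).astype(float)
        panel = make_panel(d)
        kept = ld_prune(panel, window=6, step=2, vif=2.0)
        perm = rng.permutation(m)
        panel_p = make_panel(d[:, perm], positions=(perm + 1) * 1000)
        kept_p = ld_prune(panel_p, window=6, step=2, vif=2.0)
        pos_kept = {(j + 1) * 1000 for j in kept}
        pos_kept_p = {int(panel_p.variants["pos"].iat[j]) for j in kept_p}
        assert pos_kept == pos_kept_p


class TestGrm:
    def test_unrelated_off_diagonal_small(self, rng):
        n, m = 150, 10_000
        p = rng.uniform(0.1, 0.5, m)
        d = (rng.random((n, m)) < p).astype(float) + (rng.random((n, m)) < p)
        K = compute_grm(make_panel(d))
        off = K[~np.eye(n, dtype=bool)]
        assert abs(off.mean()) < 0.01
        assert np.abs(off).max() < 0.1
        assert np.trace(K) / n == pytest.approx(1.0, abs=0.05)
        assert np.linalg.eigvalsh(K).min() > -1e-8

    def test_duplicate_samples_unit_relatedness(self, rng):
        m = 2000
        p = rng.uniform(0.1, 0.5, m)
        d = (rng.random((40, m)) < p).astype(float) + (rng.random((40, m)) < p)
        d[1] = d[0]
        K = compute_grm(make_panel(d))
        assert K[0, 1] == pytest.approx(K[0, 0], rel=0.05)

    def test_full_sibs_half_relatedness(self):
        cfg = SimConfig(
            n_samples_per_cohort=200,
            n_variants=4000,
            n_proteins=2,
            ld_rho=0.0,
            n_cis_effects=0,
            n_trans_effects=0,
            relatedness_block_size=2,
            genotype_missing_rate=0.0,
            seed=9,
        )
        study = simulate_cohorts(cfg)
        panel = study.panels["cohortA"]
        maf = panel.maf()
        K = compute_grm(panel.subset_variants(np.flatnonzero(maf > 0.05)))
        sib_vals = [K[2 * b, 2 * b + 1] for b in range(100)]
        assert np.mean(sib_vals) == pytest.approx(0.5, abs=0.05)


class TestLambdaGc:
    def test_single_median_p(self):
        assert lambda_gc([0.5]) == pytest.approx(1.0, abs=1e-12)

    def test_uniform_null_calibrated(self, rng):
        p = rng.uniform(size=1_000_000)
        assert 0.99 < lambda_gc(p) < 1.01

    def test_scale_equivariance(self, rng):
        from scipy import stats as sps

        chi = sps.chi2.rvs(1, size=5000, random_state=123)
        lam1 = lambda_gc(sps.chi2.sf(chi, 1))
        lam2 = lambda_gc(sps.chi2.sf(2 * chi, 1))
        assert lam2 == pytest.approx(2 * lam1, rel=1e-6)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            lambda_gc([])


class TestSignificanceThreshold:
    def test_identity_correlation(self):
        plan = significance_threshold(1000, np.eye(20), alpha=0.05)
        assert plan.m_eff_reported == 20
        assert plan.threshold == pytest.approx(0.05 / (1000 * 20))

    def test_perfect_correlation_collapses_to_one(self):
        C = np.ones((6, 6))
        plan = significance_threshold(100, C)
        assert plan.m_eff_reported == 1

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            significance_threshold(10, np.ones((2, 3)))
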