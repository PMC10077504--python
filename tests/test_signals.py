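"""Peak extraction, clumping, conditional/joint selection vs brute oracles.

The peak-extraction oracle re-implements the published selection rule
directly (sort by P, drop r^2 > threshold neighbours, group survivors by
distance) in the most literal O(n^2) form; the COJO checks compare
summary-statistic joint fits against multiple regression on the raw
individual-level genotypes."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from isopqtl.genostats import PanelLD
from isopqtl.signals import (
    Peak,
    clump,
    cojo_condition,
    cojo_select,
    extract_peaks,
    merge_adjacent_peaks,
)

from conftest import make_panel


def peaks_oracle(meta, r2_of, p_extract, r2_drop, group_dist):
    """Literal re-implementation: independent of the library code path."""
    cand = meta[meta["p"] < p_extract].sort_values(
        ["p", "chr", "pos"], kind="stable"
    )
    alive = list(cand.index)
    survivors = []
    while alive:
        top = alive.pop(0)
        survivors.append(top)
        alive = [
            k
            for k in alive
            if cand.loc[k, "chr"] != cand.loc[top, "chr"]
            or not (r2_of(cand.loc[top, "rsid"], cand.loc[k, "rsid"]) > r2_drop)
        ]
    surv = cand.loc[survivors].sort_values(["chr", "pos"])
    groups = []
    for idx, row in surv.iterrows():
        if (
            groups
            and groups[-1][-1][1]["chr"] == row["chr"]
            and row["pos"] - groups[-1][-1][1]["pos"] < group_dist
        ):
            groups[-1].append((idx, row))
        else:
            groups.append([(idx, row)])
    out = []
    for g in groups:
        rows = pd.DataFrame([r for _, r in g])
        best = rows.loc[rows["p"].idxmin()]
        out.append(
            (best["rsid"], int(rows["pos"].min()), int(rows["pos"].max()),
             sorted(rows["rsid"])),
        )
    return out


def _random_instance(seed, n=300, m=40):
    rng = np.random.default_rng(seed)
    # blocky LD: variants share latent factors
    k = max(2, m // 8)
    factors = rng.standard_normal((n, k))
    assign = rng.integers(0, k, m)
    lat = factors[:, assign] + rng.uniform(0.3, 1.5, m) * rng.standard_normal((n, m))
    d = (lat > rng.uniform(-0.5, 0.5, m)).astype(float) + (lat > 0.9).astype(float)
    pos = np.sort(rng.choice(np.arange(1, 8_000_000, 1000), m, replace=False))
    panel = make_panel(d, positions=pos)
    meta = pd.DataFrame(
        {
            "chr": "1",
            "pos": pos,
            "rsid": panel.variants["rsid"],
            "p": 10.0 ** (-rng.uniform(0, 15, m)),
            "mac": 50,
        }
    )
    return panel, meta


class TestExtractPeaks:
    def test_single_significant_variant(self, rng):
        panel, meta = _random_instance(1, m=10)
        meta["p"] = 0.5
        meta.loc[3, "p"] = 1e-12
        ld = PanelLD(panel)
        peaks = extract_peaks(meta, ld, study_threshold=1e-10)
        assert len(peaks) == 1
        assert peaks[0].index_rsid == meta.loc[3, "rsid"]
        assert peaks[0].significant

    def test_hand_traced_ld_and_distance_rules(self, rng):
        """Three variants: 1.0 Mb (p 1e-20), 1.1 Mb (p 1e-15, r2 0.5 with the
        first), 5.0 Mb (p 1e-9, independent) -> two peaks, the second
        variant removed by LD."""
        n = 2000
        g1 = (rng.random(n) < 0.4).astype(float) + (rng.random(n) < 0.4)
        g2 = g1.copy()
        flip = rng.random(n) < 0.25  # partial shuffle: r2 ~ 0.5
        g2[flip] = rng.integers(0, 3, flip.sum())
        g3 = (rng.random(n) < 0.3).astype(float) + (rng.random(n) < 0.3)
        panel = make_panel(
            np.column_stack([g1, g2, g3]),
            positions=[1_000_000, 1_100_000, 5_000_000],
        )
        ld = PanelLD(panel)
        assert 0.2 < ld.r2(0, 1) < 0.9
        meta = pd.DataFrame(
            {
                "chr": "1",
                "pos": [1_000_000, 1_100_000, 5_000_000],
                "rsid": ["v0", "v1", "v2"],
                "p": [1e-20, 1e-15, 1e-9],
                "mac": 50,
            }
        )
        peaks = extract_peaks(meta, ld)
        assert [p.index_rsid for p in peaks] == ["v0", "v2"]
        assert peaks[0].members == ["v0"]

    def test_mac_filter_applies_to_index_candidates(self, rng):
        panel, meta = _random_instance(2, m=6)
        meta["p"] = 1e-12
        meta["mac"] = [50, 5, 50, 50, 50, 50]
        ld = PanelLD(panel)
        peaks = extract_peaks(meta, ld)
        members = {r for p in peaks for r in p.members}
        assert meta.loc[1, "rsid"] not in members

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_brute_force_oracle(self, seed):
        panel, meta = _random_instance(seed)
        ld = PanelLD(panel)

        def r2_of(r1, r2):
            return ld.r2(ld.by_rsid[r1], ld.by_rsid[r2])

        got = extract_peaks(meta, ld, p_extract=1e-6, r2_drop=0.2, group_dist=2e6)
        expected = peaks_oracle(meta, r2_of, 1e-6, 0.2, 2e6)
        assert len(got) == len(expected)
        for pk, (rsid, start, end, members) in zip(got, expected):
            assert pk.index_rsid == rsid
            assert (pk.start, pk.end) == (start, end)
            assert sorted(pk.members) == members


def clump_oracle(meta, r2_of, r2, window):
    cand = meta.sort_values(["p", "chr", "pos"], kind="stable")
    alive = list(cand.index)
    kept = []
    while alive:
        top = alive.pop(0)
        kept.append(top)
        alive = [
            k
            for k in alive
            if cand.loc[k, "chr"] != cand.loc[top, "chr"]
            or abs(cand.loc[k, "pos"] - cand.loc[top, "pos"]) > window
            or not (r2_of(cand.loc[top, "rsid"], cand.loc[k, "rsid"]) > r2)
        ]
    return sorted(cand.loc[kept, "rsid"])


class TestClump:
    def test_independent_variants_all_retained(self, rng):
        n, m = 500, 8
        d = (rng.random((n, m)) < 0.4).astype(float) + (rng.random((n, m)) < 0.4)
        panel = make_panel(d)
        meta = pd.DataFrame(
            {
                "chr": "1",
                "pos": panel.variants["pos"],
                "rsid": panel.variants["rsid"],
                "p": rng.uniform(1e-10, 1e-7, m),
            }
        )
        out = clump(meta, PanelLD(panel))
        assert len(out) == m

    def test_correlated_pair_keeps_lower_p(self, rng):
        n = 800
        g = (rng.random(n) < 0.4).astype(float) + (rng.random(n) < 0.4)
        g2 = g.copy()
        g2[rng.random(n) < 0.1] = 0
        panel = make_panel(np.column_stack([g, g2]), positions=[1000, 201_000])
        meta = pd.DataFrame(
            {
                "chr": "1",
                "pos": [1000, 201_000],
                "rsid": ["v0", "v1"],
                "p": [1e-8, 1e-12],
            }
        )
        out = clump(meta, PanelLD(panel))
        assert list(out["rsid"]) == ["v1"]

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_oracle(self, seed):
        panel, meta = _random_instance(seed + 100, m=50)
        ld = PanelLD(panel)

        def r2_of(r1, r2):
            return ld.r2(ld.by_rsid[r1], ld.by_rsid[r2])

        got = sorted(clump(meta, ld, r2=0.1, window=1e6)["rsid"])
        assert got == clump_oracle(meta, r2_of, 0.1, 1e6)


def _locus_with_causals(rng, n=2000, m=30, causal_idx=(5, 20), betas=(0.6, 0.5),
                        rho=0.0):
    """Simulated locus: marginal OLS summary stats + the raw genotypes."""
    if rho > 0:
        k = rng.standard_normal((n, 1))
        lat = rho * k + np.sqrt(1 - rho**2) * rng.standard_normal((n, m))
    else:
        lat = rng.standard_normal((n, m))
    thresh = stats.norm.ppf(rng.uniform(0.2, 0.8, m))
    d = (lat < thresh).astype(float) + (rng.standard_normal((n, m)) < thresh)
    y = rng.standard_normal(n)
    for j, b in zip(causal_idx, betas):
        y = y + b * d[:, j]
    rows = []
    for j in range(m):
        g = d[:, j]
        X = np.column_stack([np.ones(n), g])
        coef, rss, *_ = np.linalg.lstsq(X, y, rcond=None)
        sigma2 = rss[0] / (n - 2)
        se = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
        t = coef[1] / se
        rows.append(
            {
                "chr": "1",
                "pos": (j + 1) * 1000,
                "rsid": f"v{j}",
                "allele1": "G",
                "allele0": "A",
                "af": g.mean() / 2,
                "beta": coef[1],
                "se": se,
                "p": 2 * stats.t.sf(abs(t), n - 2),
                "n": n,
                "mac": 50,
            }
        )
    return make_panel(d), pd.DataFrame(rows), y


class TestCojo:
    def test_single_causal_joint_equals_marginal(self, rng):
        panel, meta, _ = _locus_with_causals(rng, causal_idx=(5,), betas=(0.6,))
        ld = PanelLD(panel)
        sel = cojo_select(meta, ld, entry_p=1e-8)
        assert len(sel) == 1
        row = sel.iloc[0]
        assert row["beta_joint"] == pytest.approx(row["beta"], abs=1e-6)

    def test_two_independent_causals_match_individual_level_ols(self, rng):
        panel, meta, y = _locus_with_causals(rng)
        ld = PanelLD(panel)
        sel = cojo_select(meta, ld, entry_p=1e-8)
        assert sorted(sel["rsid"]) == ["v20", "v5"]
        # oracle: two-covariate OLS on the raw genotypes
        X = np.column_stack([np.ones(len(y)), panel.dosages[:, 5], panel.dosages[:, 20]])
        coef, rss, *_ = np.linalg.lstsq(X, y, rcond=None)
        sigma2 = rss[0] / (len(y) - 3)
        cov = sigma2 * np.linalg.inv(X.T @ X)
        for rsid, k in (("v5", 1), ("v20", 2)):
            row = sel[sel["rsid"] == rsid].iloc[0]
            assert abs(row["beta_joint"] - coef[k]) < 3 * np.sqrt(cov[k, k])

    def test_collinearity_cap_blocks_near_duplicates(self, rng):
        n = 1500
        g = (rng.random(n) < 0.4).astype(float) + (rng.random(n) < 0.4)
        g2 = g.copy()
        g2[rng.choice(n, 10, replace=False)] = 0  # r2 ~ 0.97
        y = 0.7 * g + rng.standard_normal(n)
        panel = make_panel(np.column_stack([g, g2]))
        ld = PanelLD(panel)
        assert ld.r2(0, 1) > 0.9
        rows = []
        for j, gg in enumerate([g, g2]):
            X = np.column_stack([np.ones(n), gg])
            coef, rss, *_ = np.linalg.lstsq(X, y, rcond=None)
            se = np.sqrt(rss[0] / (n - 2) * np.linalg.inv(X.T @ X)[1, 1])
            rows.append(
                {"chr": "1", "pos": (j + 1) * 1000, "rsid": f"v{j}",
                 "af": gg.mean() / 2, "beta": coef[1], "se": se,
                 "p": 2 * stats.norm.sf(abs(coef[1] / se)), "n": n}
            )
        sel = cojo_select(pd.DataFrame(rows), ld, entry_p=1e-4,
                          collinearity_r2=0.9)
        assert len(sel) == 1

    def test_condition_on_nothing_is_identity(self, rng):
        panel, meta, _ = _locus_with_causals(rng, causal_idx=(5,), betas=(0.6,))
        out = cojo_condition(meta, PanelLD(panel), condition_on=[])
        np.testing.assert_allclose(out["beta_cond"], meta["beta"])
        np.testing.assert_allclose(out["p_cond"], meta["p"])

    def test_conditioning_on_second_causal_recovers_first(self, rng):
        panel, meta, _ = _locus_with_causals(rng, betas=(0.6, 0.5))
        ld = PanelLD(panel)
        out = cojo_condition(meta, ld, condition_on=["v20"])
        row = out[out["rsid"] == "v5"].iloc[0]
        assert abs(row["beta_cond"] - 0.6) < 3 * row["se_cond"]
        # and the conditioned variant itself is absorbed
        assert out[out["rsid"] == "v20"]["beta_cond"].iloc[0] == 0.0

    def test_recovers_number_of_planted_causals(self):
        """k <= 3 planted independent causals, n = 2000, effects >= 0.5 SD:
        the selected-set size is within +-1 of k in >= 90% of replicates."""
        hits = 0
        n_rep = 100
        for rep in range(n_rep):
            rng = np.random.default_rng(10_000 + rep)
            k = int(rng.integers(1, 4))
            idx = tuple(rng.choice(25, k, replace=False))
            betas = tuple(rng.uniform(0.5, 0.9, k))
            panel, meta, _ = _locus_with_causals(
                rng, n=2000, m=25, causal_idx=idx, betas=betas, rho=0.3
            )
            sel = cojo_select(meta, PanelLD(panel), entry_p=5e-8)
            if abs(len(sel) - k) <= 1:
                hits += 1
        assert hits >= 0.9 * n_rep


class TestMergePeaks:
    def _peak(self, rsid, pos, p):
        return Peak("1", pos - 1000, pos + 1000, rsid, pos, p, [rsid])

    def test_distant_independent_peaks_untouched(self, rng):
        panel, _ = _random_instance(3, m=4)
        ld = PanelLD(panel)
        pks = [
            self._peak(panel.variants["rsid"].iat[0], 1_000_000, 1e-12),
            self._peak(panel.variants["rsid"].iat[1], 6_000_000, 1e-9),
        ]
        out = merge_adjacent_peaks(pks, ld, merge_r2=0.99, merge_dist=1e6)
        assert len(out) == 2

    def test_close_peaks_merged_to_lowest_p(self, rng):
        panel, _ = _random_instance(4, m=4)
        ld = PanelLD(panel)
        pks = [
            self._peak(panel.variants["rsid"].iat[0], 1_000_000, 1e-9),
            self._peak(panel.variants["rsid"].iat[1], 1_500_000, 1e-12),
        ]
        out = merge_adjacent_peaks(pks, ld)
        assert len(out) == 1
        assert out[0].index_p == 1e-12
        assert out[0].start == 999_000 and out[0].end == 1_501_000

    def test_idempotent(self, rng):
        panel, _ = _random_instance(5, m=6)
        ld = PanelLD(panel)
        pks = [
            self._peak(panel.variants["rsid"].iat[j], int(1e6 + j * 4e5), 1e-10 / (j + 1))
            for j in range(4)
        ]
        once = merge_adjacent_peaks(pks, ld)
        twice = merge_adjacent_peaks(once, ld)
        assert [(p.index_rsid, p.start, p.end) for p in once] == [
            (p.index_rsid, p.start, p.end) for p in twice
        ]
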