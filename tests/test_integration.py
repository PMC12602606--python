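"""Spearman correlation and the promoter anti-correlation screen."""

from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pannetsub import anticorrelation_screen, promoter_probe_pairs, spearman


def brute_force_spearman_p(x, y):
    """Independent enumeration oracle: two-sided permutation p using
    scipy's spearmanr for each permutation of y."""
    rho_obs = stats.spearmanr(x, y).statistic
    hits = total = 0
    for perm in permutations(y):
        r = stats.spearmanr(x, perm).statistic
        total += 1
        if abs(r) >= abs(rho_obs) - 1e-12:
            hits += 1
    return rho_obs, hits / total


class TestSpearman:
    def test_perfect_anticorrelation(self):
        rho, p = spearman([1, 2, 3, 4, 5], [10, 8, 6, 4, 2])
        assert rho == -1.0
        assert p == pytest.approx(2 / 120)  # only the two extreme orderings

    def test_worked_example(self):
        # d^2 = (1,1,1,1): rho = 1 - 6*4/(4*15) = 0.6
        rho, _ = spearman([1, 2, 3, 4], [2, 1, 4, 3])
        assert rho == pytest.approx(0.6)

    @pytest.mark.parametrize("n", [4, 5, 6, 7])
    def test_exact_p_matches_enumeration(self, n, rng):
        for _ in range(3):
            x = rng.integers(0, n - 1, size=n).astype(float)  # with ties
            y = rng.integers(0, n - 1, size=n).astype(float)
            if len(set(x)) < 2 or len(set(y)) < 2:
                continue
            rho, p = spearman(x, y)
            rho_ref, p_ref = brute_force_spearman_p(x, y)
            assert rho == pytest.approx(rho_ref, abs=1e-12)
            assert p == pytest.approx(p_ref, abs=1e-12)

    def test_t_approximation_large_n(self, rng):
        x = rng.normal(size=30)
        y = x + rng.normal(size=30)
        rho, p = spearman(x, y)
        ref = stats.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_missing_pairs_removed(self):
        rho, _ = spearman([1, 2, 3, 4, np.nan], [5, 4, 3, 2, 1])
        assert rho == -1.0  # the 4 complete pairs are strictly decreasing

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            spearman([1, 2, 3], [3, 2, 1])


def toy_manifest_and_degs():
    manifest = pd.DataFrame(
        {
            "probe_id": ["pr1", "pr2", "pr3", "en1"],
            "chrom": "chr1",
            "pos": [100, 200, 300, 400],
            "state": ["active_promoter", "weak_promoter", "active_promoter",
                      "enhancer"],
            "gene": ["gA", "gA", "gB", np.nan],
        }
    )
    deg = pd.DataFrame(
        {
            "log2_fold_change": [2.0, -1.5, 0.1],
            "significant": [True, False, True],
        },
        index=["gA", "gB", "gC"],
    )
    return manifest, deg


class TestPromoterProbePairs:
    def test_multi_probe_gene_yields_multiple_pairs(self):
        manifest, deg = toy_manifest_and_degs()
        pairs = promoter_probe_pairs(manifest, deg)
        assert pairs == [("gA", "pr1"), ("gA", "pr2")]

    def test_non_deg_excluded(self):
        manifest, deg = toy_manifest_and_degs()
        pairs = promoter_probe_pairs(manifest, deg)
        assert all(g != "gB" for g, _ in pairs)

    def test_no_degs_empty_with_warning(self):
        manifest, deg = toy_manifest_and_degs()
        deg["significant"] = False
        with pytest.warns(UserWarning):
            assert promoter_probe_pairs(manifest, deg) == []


class TestAnticorrelationScreen:
    def make_matrices(self, rng, n=30, coupled=True):
        m = pd.DataFrame(rng.normal(size=(2, n)),
                         index=["pr1", "pr2"],
                         columns=[f"S{i}" for i in range(n)])
        expr = pd.DataFrame(rng.normal(size=(2, n)),
                            index=["gA", "gB"], columns=m.columns)
        if coupled:
            expr.loc["gA"] = -m.loc["pr1"] + rng.normal(0, 0.1, n)
        return m, expr

    def test_coupled_pair_passes(self, rng):
        m, expr = self.make_matrices(rng)
        table = anticorrelation_screen(
            m, expr, [("gA", "pr1"), ("gB", "pr2")]
        )
        t = table.set_index(["gene_id", "probe_id"])
        assert bool(t.loc[("gA", "pr1"), "passes"])
        assert not bool(t.loc[("gB", "pr2"), "passes"])

    def test_invariant_under_monotone_expr_transform(self, rng):
        m, expr = self.make_matrices(rng)
        pairs = [("gA", "pr1"), ("gB", "pr2")]
        a = anticorrelation_screen(m, expr, pairs)
        b = anticorrelation_screen(m, np.exp(expr / 3.0), pairs)
        np.testing.assert_allclose(a["rho"], b["rho"], atol=1e-12)
        np.testing.assert_allclose(a["p_value"], b["p_value"], atol=1e-12)

    def test_bh_monotonicity_extra_null_pair(self, rng):
        # adding a pair with p ~ 1 never turns a failing pair into passing
        m, expr = self.make_matrices(rng)
        m.loc["pr3"] = expr.loc["gB"].to_numpy()  # rho=+1 pair, p tiny but positive
        base = anticorrelation_screen(m, expr, [("gA", "pr1"), ("gB", "pr2")])
        more = anticorrelation_screen(
            m, expr, [("gA", "pr1"), ("gB", "pr2"), ("gB", "pr3")]
        )
        base_pass = set(map(tuple, base.loc[base["passes"], ["gene_id", "probe_id"]].to_numpy()))
        more_pass = set(map(tuple, more.loc[more["passes"], ["gene_id", "probe_id"]].to_numpy()))
        assert more_pass - base_pass <= {("gB", "pr3")}

    def test_misaligned_matrices_rejected(self, rng):
        m, expr = self.make_matrices(rng)
        with pytest.raises(ValueError, match="align"):
            anticorrelation_screen(m, expr.iloc[:, ::-1], [("gA", "pr1")])

    def test_empty_pairs_empty_table(self, rng):
        m, expr = self.make_matrices(rng)
        table = anticorrelation_screen(m, expr, [])
        assert table.empty
        assert table.attrs["summary"] == {"up": 0, "down": 0}

    def test_summary_counts_distinct_genes(self, rng):
        # gene gA coupled through two probes counts once
        m, expr = self.make_matrices(rng)
        m.loc["pr2"] = m.loc["pr1"] + rng.normal(0, 0.05, m.shape[1])
        deg = pd.DataFrame({"log2_fold_change": [2.0, -1.0],
                            "significant": [True, True]}, index=["gA", "gB"])
        table = anticorrelation_screen(
            m, expr, [("gA", "pr1"), ("gA", "pr2")], deg_table=deg
        )
        assert table["passes"].sum() == 2
        assert table.attrs["summary"] == {"up": 1, "down": 0}
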