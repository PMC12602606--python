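"""Differential methylation, state ORA and structural-region statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import pannetsub as ps
from pannetsub import (
    chromatin_state_ora,
    define_structural_regions,
    dmp_test,
    region_group_test,
    region_medians,
)
from pannetsub.diffmeth import PERICENTROMERIC, SUBTELOMERIC


def beta_frame(values, samples=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    samples = samples or [f"S{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=[f"p{i}" for i in range(values.shape[0])],
                        columns=samples)


def labels_for(samples, n_ref):
    return pd.Series(
        ["alpha_like"] * n_ref + ["ADM"] * (len(samples) - n_ref), index=samples
    )


class TestDmpTest:
    def test_matches_two_sample_t(self, rng):
        # OLS on a group indicator is the pooled-variance two-sample t
        y = rng.random((20, 10))
        beta = beta_frame(y)
        lab = labels_for(beta.columns, 5)
        table = dmp_test(beta, lab, reference="alpha_like")
        t_ref, p_ref = stats.ttest_ind(y[:, 5:], y[:, :5], axis=1)
        np.testing.assert_allclose(table["t_statistic"], t_ref, atol=1e-10)
        np.testing.assert_allclose(table["p_value"], p_ref, atol=1e-10)
        np.testing.assert_allclose(
            table["delta_beta"], y[:, 5:].mean(1) - y[:, :5].mean(1), atol=1e-12
        )

    def test_separated_groups_highly_significant(self, rng):
        base = np.concatenate([np.full(5, 0.2), np.full(5, 0.8)])
        y = base + rng.normal(0, 0.005, size=(50, 10))
        beta = beta_frame(np.clip(y, 0, 1))
        table = dmp_test(beta, labels_for(beta.columns, 5),
                         reference="alpha_like")
        assert (table["delta_beta"] > 0.55).all()
        assert (table["p_adjusted"] < 1e-6).all()
        assert table["significant"].all()

    def test_missing_values_handled_per_probe(self, rng):
        y = rng.random((5, 12))
        beta = beta_frame(y)
        beta.iloc[0, 0] = np.nan
        table = dmp_test(beta, labels_for(beta.columns, 6))
        assert np.isfinite(table.loc["p0", "p_value"])

    def test_all_missing_group_dropped(self, rng):
        beta = beta_frame(rng.random((3, 8)))
        beta.iloc[1, :4] = np.nan
        with pytest.warns(UserWarning, match="all-missing"):
            table = dmp_test(beta, labels_for(beta.columns, 4))
        assert "p1" not in table.index

    def test_singular_covariate_rejected(self, rng):
        beta = beta_frame(rng.random((3, 8)))
        lab = labels_for(beta.columns, 4)
        cov = pd.DataFrame({"dup": (lab == "ADM").astype(float)},
                           index=beta.columns)
        with pytest.raises(ValueError, match="singular|collinear"):
            dmp_test(beta, lab, covariates=cov)

    def test_needs_two_groups(self, rng):
        beta = beta_frame(rng.random((2, 4)))
        with pytest.raises(ValueError):
            dmp_test(beta, pd.Series(["A"] * 4, index=beta.columns))


class TestChromatinStateOra:
    def manifest(self, states):
        return pd.DataFrame(
            {
                "probe_id": [f"p{i}" for i in range(len(states))],
                "chrom": "chr1",
                "pos": np.arange(1, len(states) + 1),
                "state": states,
                "gene": np.nan,
            }
        )

    def test_enrichment_detected(self):
        states = ["enhancer"] * 10 + ["other"] * 10
        man = self.manifest(states)
        dmps = {f"p{i}" for i in range(8)}  # 8 enhancer DMPs of 10
        table = chromatin_state_ora(dmps, man).set_index("state")
        assert table.loc["enhancer", "odds_ratio"] > 1
        assert table.loc["enhancer", "p_value"] < 0.05

    def test_dmp_outside_universe_rejected(self):
        man = self.manifest(["other"] * 5)
        with pytest.raises(ValueError):
            chromatin_state_ora({"zz"}, man)


class TestStructuralRegions:
    def test_classification_boundaries(self):
        genome = ps.default_genome()
        length = genome.chromosomes[0][1]
        man = pd.DataFrame(
            {
                "probe_id": ["tel_lo", "tel_hi", "near_cen", "mid", "both_na"],
                "chrom": "chr1",
                "pos": [1, length, 24_000_000 - 1, 10_000_000, 15_000_000],
                "state": "other",
                "gene": np.nan,
            }
        )
        regions = define_structural_regions(genome, 2_000_000, 2_000_000,
                                            manifest=man)
        assert regions["tel_lo"] == SUBTELOMERIC
        assert regions["tel_hi"] == SUBTELOMERIC
        assert regions["near_cen"] == PERICENTROMERIC
        assert regions["mid"] is None

    def test_window_too_large_rejected(self):
        genome = ps.default_genome()
        with pytest.raises(ValueError):
            define_structural_regions(genome, 30_000_000, 1_000_000,
                                      manifest=pd.DataFrame(
                                          {"probe_id": [], "chrom": [],
                                           "pos": [], "state": [], "gene": []}))


class TestRegionMedians:
    def test_even_count_midpoint(self):
        beta = beta_frame([[0.1], [0.9]])
        regions = pd.Series({"p0": SUBTELOMERIC, "p1": SUBTELOMERIC})
        out = region_medians(beta, regions)
        assert out.loc[0, "median_beta"] == pytest.approx(0.5)

    def test_probe_and_sample_order_invariant(self, rng):
        beta = beta_frame(rng.random((10, 6)))
        regions = pd.Series(
            {f"p{i}": SUBTELOMERIC if i < 5 else PERICENTROMERIC
             for i in range(10)}
        )
        a = region_medians(beta, regions)
        b = region_medians(beta.iloc[::-1, ::-1], regions)
        merged = a.merge(b, on=["sample_id", "region_class", "chromosome"])
        np.testing.assert_allclose(merged["median_beta_x"], merged["median_beta_y"])

    def test_empty_region_omitted_with_warning(self):
        beta = beta_frame([[0.5]])
        regions = pd.Series({"p0": SUBTELOMERIC})
        with pytest.warns(UserWarning, match="no probes"):
            out = region_medians(beta, regions)
        assert set(out["region_class"]) == {SUBTELOMERIC}


class TestRegionGroupTest:
    def test_equal_groups_t_zero(self):
        rows = pd.DataFrame(
            {
                "sample_id": [f"S{i}" for i in range(8)],
                "region_class": SUBTELOMERIC,
                "chromosome": "all",
                "median_beta": [0.5, 0.6, 0.5, 0.6] * 2,
            }
        )
        lab = labels_for([f"S{i}" for i in range(8)], 4)
        out = region_group_test(rows, lab, reference="alpha_like")
        assert out.loc[0, "t_statistic"] == 0.0
        assert out.loc[0, "p_value"] == 1.0

    def test_power_at_large_shift(self, rng):
        n = 20
        vals = np.concatenate([rng.normal(0.7, 0.02, n), rng.normal(0.55, 0.02, n)])
        rows = pd.DataFrame(
            {
                "sample_id": [f"S{i}" for i in range(2 * n)],
                "region_class": PERICENTROMERIC,
                "chromosome": "all",
                "median_beta": vals,
            }
        )
        lab = labels_for([f"S{i}" for i in range(2 * n)], n)
        out = region_group_test(rows, lab, reference="alpha_like")
        assert out.loc[0, "p_value"] < 0.01
        assert out.loc[0, "mean_difference"] == pytest.approx(-0.15, abs=0.02)

    def test_null_p_uniform(self):
        # permuted labels: p-values roughly uniform
        rng = np.random.default_rng(0)
        ps_ = []
        vals = rng.normal(0.6, 0.05, 30)
        rows = pd.DataFrame(
            {
                "sample_id": [f"S{i}" for i in range(30)],
                "region_class": SUBTELOMERIC,
                "chromosome": "all",
                "median_beta": vals,
            }
        )
        for _ in range(200):
            lab = pd.Series(rng.permutation(["alpha_like"] * 15 + ["ADM"] * 15),
                            index=rows["sample_id"])
            ps_.append(region_group_test(rows, lab).loc[0, "p_value"])
        assert stats.kstest(ps_, "uniform").pvalue > 0.01
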