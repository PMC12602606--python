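"""Synthetic cohort generator: determinism, planted effects, truth ledger."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import pannetsub as ps
from pannetsub.synthetic import ConfigurationError, MethylationEffects


class TestMakeManifest:
    def test_state_fractions_approximately_respected(self, toy_manifest):
        _, manifest = toy_manifest
        n = len(manifest)
        frac = (manifest["state"] == "enhancer").mean()
        # binomial(2000, 0.2): 4 sd band
        assert abs(frac - 0.2) < 4 * np.sqrt(0.2 * 0.8 / n)

    def test_identical_seeds_byte_identical(self):
        g = ps.default_genome()
        m1 = ps.make_manifest(g, 500, seed=3)
        m2 = ps.make_manifest(g, 500, seed=3)
        pd.testing.assert_frame_equal(m1, m2)

    def test_fraction_sum_violation_rejected(self):
        g = ps.default_genome()
        with pytest.raises(ConfigurationError, match="sum"):
            ps.make_manifest(g, 500, {"enhancer": 0.5, "other": 0.4})

    def test_promoter_probes_have_exactly_one_gene(self, toy_manifest):
        _, manifest = toy_manifest
        prom = manifest[manifest["state"].isin(
            {"active_promoter", "weak_promoter"})]
        assert prom["gene"].notna().all()
        assert manifest.loc[~manifest.index.isin(prom.index), "gene"].isna().all()

    def test_positions_inside_chromosomes(self, toy_manifest):
        genome, manifest = toy_manifest
        lengths = {c[0]: c[1] for c in genome.chromosomes}
        assert (manifest["pos"] >= 1).all()
        assert all(p <= lengths[c] for c, p in zip(manifest["chrom"],
                                                   manifest["pos"]))


class TestToyGenome:
    def test_invalid_centromere_rejected(self):
        with pytest.raises(ConfigurationError):
            ps.ToyGenome((("chr1", 100, 60, 50), ("chr2", 100, 40, 60)))

    def test_sex_chromosome_rejected(self):
        with pytest.raises(ConfigurationError):
            ps.ToyGenome((("chr1", 100, 40, 60), ("chrX", 100, 40, 60)))


class TestSimulateMethylation:
    def setup_method(self):
        self.genome = ps.default_genome()
        self.manifest = ps.make_manifest(self.genome, 2000, seed=5)

    def test_null_region_effect_only_noise(self):
        eff = MethylationEffects(
            n_dmp=0,
            region_effect_delta={"subtelomeric": 0.0, "pericentromeric": 0.0},
        )
        beta, truth = ps.simulate_methylation(
            self.manifest, {"alpha_like": 10, "ADM1": 10}, eff, seed=2,
            genome=self.genome,
        )
        regions = ps.define_structural_regions(self.genome, manifest=self.manifest)
        med = ps.region_medians(beta, regions)
        lab = pd.Series(truth.sample_subtype).map(
            lambda s: "ADM" if s != "alpha_like" else s)
        out = ps.region_group_test(med, lab, reference="alpha_like")
        assert out["mean_difference"].abs().max() < 0.05

    def test_planted_delta_recovered_in_group_means(self):
        eff = MethylationEffects(
            n_dmp=500, dmp_delta_beta=0.3, dmp_up_fraction=1.0,
            region_effect_delta={"subtelomeric": 0.0, "pericentromeric": 0.0},
        )
        beta, truth = ps.simulate_methylation(
            self.manifest, {"alpha_like": 20, "ADM1": 20}, eff,
            noise_sd=0.05, seed=4, genome=self.genome,
        )
        sub = beta.loc[sorted(truth.dmp_probes)]
        adm = [s for s, st in truth.sample_subtype.items() if st != "alpha_like"]
        alpha = [s for s in beta.columns if s not in adm]
        diff = (sub[adm].mean(axis=1) - sub[alpha].mean(axis=1)).mean()
        assert diff == pytest.approx(0.3, abs=0.02)

    def test_fixed_seed_reproducible(self):
        eff = MethylationEffects(n_dmp=50)
        a, _ = ps.simulate_methylation(self.manifest, {"alpha_like": 5, "ADM1": 5},
                                       eff, seed=9, genome=self.genome)
        b, _ = ps.simulate_methylation(self.manifest, {"alpha_like": 5, "ADM1": 5},
                                       eff, seed=9, genome=self.genome)
        pd.testing.assert_frame_equal(a, b)

    def test_values_in_unit_interval(self):
        eff = MethylationEffects(n_dmp=100)
        beta, _ = ps.simulate_methylation(self.manifest,
                                          {"alpha_like": 5, "ADM1": 5}, eff,
                                          seed=1, genome=self.genome)
        assert ((beta.to_numpy() >= 0) & (beta.to_numpy() <= 1)).all()

    def test_small_group_rejected(self):
        with pytest.raises(ConfigurationError):
            ps.simulate_methylation(self.manifest, {"alpha_like": 1, "ADM1": 5},
                                    MethylationEffects(), seed=0,
                                    genome=self.genome)


class TestSimulateExpression:
    def make_sheet(self, truth, groups):
        samples, subtypes = [], []
        i = 0
        for g, n in groups.items():
            for _ in range(n):
                samples.append(f"S{i:03d}")
                subtypes.append(g)
                i += 1
        truth.sample_subtype = dict(zip(samples, subtypes))
        return pd.DataFrame({"sample_id": samples}, index=samples)

    def test_null_fold_changes_near_one(self):
        truth = ps.GroundTruth()
        sheet = self.make_sheet(truth, {"ADM1": 15, "ADM2": 15})
        genes = [f"G{i}" for i in range(300)]
        counts, _ = ps.simulate_expression(genes, sheet, truth, seed=3)
        a = counts.iloc[:, :15].mean(axis=1)
        b = counts.iloc[:, 15:].mean(axis=1)
        ratio = np.log2((a + 1) / (b + 1))
        assert ratio.abs().median() < 0.2

    def test_poisson_limit_variance_equals_mean(self):
        truth = ps.GroundTruth()
        sheet = self.make_sheet(truth, {"ADM1": 400})
        counts, _ = ps.simulate_expression(["G0"], sheet, truth,
                                           nb_dispersion=0.0, seed=5,
                                           base_mean_range=(100, 101))
        x = counts.iloc[0]
        assert x.var() / x.mean() == pytest.approx(1.0, abs=0.3)

    def test_planted_fold_change_shifts_target_group(self):
        truth = ps.GroundTruth()
        sheet = self.make_sheet(truth, {"ADM1": 20, "ADM2": 20})
        truth.de_genes = {"ADM1": [("G0", 2.0)]}
        counts, _ = ps.simulate_expression(["G0", "G1"], sheet, truth, seed=6)
        adm1 = [s for s, st in truth.sample_subtype.items() if st == "ADM1"]
        rest = [s for s in counts.columns if s not in adm1]
        lfc = np.log2(counts.loc["G0", adm1].mean() / counts.loc["G0", rest].mean())
        assert lfc == pytest.approx(2.0, abs=0.5)

    def test_counts_are_nonnegative_integers(self):
        truth = ps.GroundTruth()
        sheet = self.make_sheet(truth, {"ADM1": 10})
        counts, _ = ps.simulate_expression([f"G{i}" for i in range(50)], sheet,
                                           truth, seed=7)
        assert (counts.to_numpy() >= 0).all()
        assert counts.dtypes.eq(np.int64).all()


class TestSimulateSurvival:
    def make_sheet(self, n_per_group):
        rows = []
        i = 0
        for g, n in n_per_group.items():
            for _ in range(n):
                rows.append({"sample_id": f"S{i}", "epigenetic_subtype": g})
                i += 1
        return pd.DataFrame(rows).set_index("sample_id", drop=False)

    def test_censor_rate_zero_all_events(self):
        sheet = self.make_sheet({"A": 30, "B": 30})
        out = ps.simulate_survival(sheet, {"A": 0.1, "B": 0.1},
                                   censor_rate=0.0, seed=1)
        assert (out["dfs_event"] == 1).all()

    def test_equal_hazards_null_p_uniform(self):
        pvals = []
        for seed in range(200):
            sheet = self.make_sheet({"A": 20, "B": 20})
            out = ps.simulate_survival(sheet, {"A": 0.1, "B": 0.1},
                                       censor_rate=0.2, seed=seed)
            pvals.append(ps.logrank_test(out["dfs_time"], out["dfs_event"],
                                         out["epigenetic_subtype"])[2])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_hazard_ratio_three_power(self):
        hits = 0
        for seed in range(40):
            sheet = self.make_sheet({"A": 50, "B": 50})
            out = ps.simulate_survival(sheet, {"A": 0.1, "B": 0.3},
                                       censor_rate=0.2, seed=seed)
            p = ps.logrank_test(out["dfs_time"], out["dfs_event"],
                                out["epigenetic_subtype"])[2]
            hits += p < 0.05
        assert hits >= 0.8 * 40

    def test_invalid_censor_rate(self):
        sheet = self.make_sheet({"A": 5})
        with pytest.raises(ConfigurationError):
            ps.simulate_survival(sheet, {"A": 0.1}, censor_rate=1.0, seed=0)


class TestCohortTruth:
    def test_coupled_genes_are_de_genes(self, small_cohort):
        truth = small_cohort.truth
        de_all = {g for lst in truth.de_genes.values() for g, _ in lst}
        assert all(g in de_all for g, _, _ in truth.coupled_pairs)

    def test_dmp_probes_subset_of_manifest(self, small_cohort):
        assert small_cohort.truth.dmp_probes <= set(
            small_cohort.manifest["probe_id"])

    def test_realized_coupling_strongly_negative(self, small_cohort):
        co = small_cohort
        m = ps.beta_to_m(co.beta)
        expr = ps.vst_like(co.counts, ps.size_factors(
            ps.filter_low_counts(co.counts))).reindex(co.counts.index)
        adm = [s for s, st in co.truth.sample_subtype.items()
               if st != "alpha_like"]
        rhos = []
        for gene, probe, _target in co.truth.coupled_pairs:
            rho, _ = ps.spearman(m.loc[probe, adm], expr.loc[gene, adm])
            rhos.append(rho)
        assert np.median(rhos) < -0.6

    def test_cohort_roundtrip_files(self, small_cohort, tmp_path):
        ps.write_cohort(small_cohort, tmp_path)
        from pannetsub import io as pio
        from pannetsub.synthetic import read_genome
        beta = pio.read_matrix(tmp_path / "beta.tsv", "beta")
        counts = pio.read_matrix(tmp_path / "counts.tsv", "counts")
        sheet = pio.read_sample_sheet(tmp_path / "sample_sheet.tsv")
        genome = read_genome(tmp_path / "genome.tsv")
        assert beta.shape == small_cohort.beta.shape
        pd.testing.assert_frame_equal(counts, small_cohort.counts)
        assert list(sheet.index) == list(small_cohort.sheet.index)
        assert genome == small_cohort.genome
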