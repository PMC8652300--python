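import numpy as np
import pandas as pd
import pytest

from bdnfnet import eprs, network, simulate
from bdnfnet.genio import GenotypeMatrix
from bdnfnet.growth import FIXED_TERMS, design_matrix
from bdnfnet.simulate import (AdversitySpec, FusionSpec, GenotypeSpec,
                              GrowthSpec, NetworkSpec, SimulationSpec,
                              gen_adversity_records, gen_cohort,
                              gen_fusion_data, gen_genotypes,
                              gen_reference_tables)


class TestGenotypeGenerator:
    def test_same_seed_is_bitwise_identical(self):
        spec = GenotypeSpec(n_snps=50)
        G1, _ = gen_genotypes(spec, 40, seed=3)
        G2, _ = gen_genotypes(spec, 40, seed=3)
        np.testing.assert_array_equal(G1.dosage, G2.dosage)

    def test_within_block_r2_decays_with_distance(self):
        spec = GenotypeSpec(n_snps=100, block_size=10, rho=0.9)
        G, truth = gen_genotypes(spec, 400, seed=4)
        d = G.dosage.astype(float)
        r2_adjacent, r2_far = [], []
        for b in range(10):
            j = b * 10
            r2_adjacent.append(np.corrcoef(d[:, j], d[:, j + 1])[0, 1] ** 2)
            r2_far.append(np.corrcoef(d[:, j], d[:, j + 9])[0, 1] ** 2)
        assert np.mean(r2_adjacent) > np.mean(r2_far) + 0.1

    def test_block_size_one_is_independent(self):
        spec = GenotypeSpec(n_snps=40, block_size=1)
        G, _ = gen_genotypes(spec, 500, seed=5)
        d = G.dosage.astype(float)
        r2 = [np.corrcoef(d[:, j], d[:, j + 1])[0, 1] ** 2 for j in range(39)]
        assert np.mean(r2) < 0.02

    def test_realized_maf_near_target_at_large_n(self):
        spec = GenotypeSpec(n_snps=60)
        G, truth = gen_genotypes(spec, 400, seed=6)
        realized = G.effect_allele_freq()
        np.testing.assert_allclose(realized, truth["target_freq"], atol=0.05)


@pytest.fixture(scope="module")
def ref():
    return gen_reference_tables(NetworkSpec(), seed=7)


class TestReferenceTables:

    def test_coexpression_filter_recovers_planted_count(self, ref):
        sel = network.select_coexpressed(ref["coexpression"], rmin=0.5)
        assert len(sel) == ref["truth"]["n_coexpressed"]
        assert sorted(sel["gene"]) == sorted(ref["truth"]["coexpressed_mouse"])

    def test_signs_preserved_through_pipeline_tables(self, ref):
        sel = network.select_coexpressed(ref["coexpression"], rmin=0.5)
        mapped, _ = network.map_to_homologs(sel, ref["homolog"])
        truth_signs = ref["truth"]["coexpr_signs"]
        back = dict(zip(ref["homolog"]["human"], ref["homolog"]["mouse"]))
        for _, row in mapped.iterrows():
            assert row["coexpr_sign"] == truth_signs[back[row["gene"]]]

    def test_stage_filter_recovers_planted_enrichment(self, ref):
        sel = network.select_coexpressed(ref["coexpression"], rmin=0.5)
        mapped, _ = network.map_to_homologs(sel, ref["homolog"])
        kept, _ = network.filter_stage_enrichment(mapped, ref["stage_expression"])
        assert sorted(kept["gene"]) == ref["truth"]["enriched_human"]

    def test_decoy_snps_excluded_by_assignment(self, ref):
        sel = network.select_coexpressed(ref["coexpression"], rmin=0.5)
        mapped, _ = network.map_to_homologs(sel, ref["homolog"])
        kept, _ = network.filter_stage_enrichment(mapped, ref["stage_expression"])
        net = network.annotate_intervals(kept, ref["annotation"], flank=500)
        G, _ = gen_genotypes(GenotypeSpec(), 30, seed=8,
                             variants=ref["variant_plan"])
        table = eprs.assign_snps(G, net, ref["weights_ref"])
        assert set(table["id"]).isdisjoint(ref["truth"]["decoy_snps"])
        assert len(table) > 0


class TestCohortGenerator:
    def test_zero_noise_outcome_is_exact_polynomial(self):
        spec = SimulationSpec(n_children=20, growth=GrowthSpec(
            sd_age=0.0, sd_age2=0.0, phi=0.0, sigma=0.0))
        data, truth = gen_cohort(spec, seed=9)
        beta = np.array([truth["beta"][t] for t in FIXED_TERMS])
        np.testing.assert_allclose(data["cognition"], design_matrix(data) @ beta,
                                   atol=1e-9)

    def test_imaging_subsample_splits_23_24(self):
        from bdnfnet.adversity import split_adversity_groups

        data, truth = gen_cohort(SimulationSpec(), seed=10)
        labels, rep = split_adversity_groups(truth["imaging_adversity"])
        assert (rep["n_high"], rep["n_low"]) == (23, 24)

    def test_visit_structure(self):
        data, _ = gen_cohort(SimulationSpec(n_children=30), seed=11)
        counts = data.groupby("child_id")["age"].agg(["size", "nunique"])
        assert (counts["size"] == 4).all()
        assert (counts["nunique"] == 4).all()

    def test_residual_autocorrelation_matches_phi(self):
        spec = SimulationSpec(n_children=2000, growth=GrowthSpec(
            sd_age=0.0, sd_age2=0.0, phi=0.5, sigma=5.0))
        data, truth = gen_cohort(spec, seed=12)
        beta = np.array([truth["beta"][t] for t in FIXED_TERMS])
        resid = (data["cognition"] - design_matrix(data) @ beta).to_numpy()
        resid = resid.reshape(-1, 4)
        r = np.corrcoef(resid[:, 0], resid[:, 1])[0, 1]
        assert r == pytest.approx(0.5, abs=0.06)


class TestAdversityGenerator:
    def test_rubric_totals_reproduce_planted_draws(self):
        from bdnfnet.adversity import score_cohort

        tab, truth = gen_adversity_records(AdversitySpec(), 300, seed=13)
        scored = score_cohort(tab)
        np.testing.assert_array_equal(scored["adversity"].to_numpy(),
                                      truth["totals"])

    def test_mean_total_matches_cohort_calibration(self):
        tab, truth = gen_adversity_records(AdversitySpec(), 2000, seed=14)
        assert truth["totals"].mean() == pytest.approx(1.3, abs=0.15)


class TestFusionGenerator:
    def test_linked_pair_sample_correlation_is_exact(self):
        _, _, truth = gen_fusion_data(FusionSpec(n_subjects=60), seed=15)
        r = np.corrcoef(truth["A1"][:, 0], truth["A2"][:, 0])[0, 1]
        assert r == pytest.approx(0.6, abs=1e-12)

    def test_infinite_snr_perfect_rho_gives_identical_columns(self):
        spec = FusionSpec(n_subjects=30, rho=1.0 - 1e-12, snr=1e12)
        X1, V, truth = gen_fusion_data(spec, seed=16)
        a, b = truth["A1"][:, 0], truth["A2"][:, 0]
        a = (a - a.mean()) / a.std()
        b = (b - b.mean()) / b.std()
        np.testing.assert_allclose(np.abs(np.corrcoef(a, b)[0, 1]), 1.0, atol=1e-9)

    def test_voxel_modality_lives_in_mask(self):
        X1, V, truth = gen_fusion_data(FusionSpec(n_subjects=20), seed=17)
        assert V.data.shape == (20, int(V.mask.sum()))
        assert V.mask.shape == (8, 8, 8)

    def test_null_rho_gives_small_max_cross_correlation(self):
        from bdnfnet.pica import fit_parallel_ica

        spec = FusionSpec(n_subjects=60, rho=0.0)
        X1, V, _ = gen_fusion_data(spec, seed=18)
        res = fit_parallel_ica(X1, V.data, 2, 2, lam=0.0, seed=18)
        # permutation null for max |r| over 4 column pairs at n=60
        rng = np.random.default_rng(0)
        null = []
        A1, A2 = res.loadings
        for _ in range(200):
            perm = rng.permutation(60)
            C = np.corrcoef(np.c_[A1[perm], A2].T)[:2, 2:]
            null.append(np.abs(C).max())
        assert np.abs(res.loading_corr).max() < np.quantile(null, 0.95) + 0.15
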