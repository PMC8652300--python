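from math import factorial

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bdnfnet import eprs
from bdnfnet.genio import MISSING
from bdnfnet.network import GeneNetwork

from conftest import make_genotypes


def hwe_enumeration_oracle(n_hom1, n_het, n_hom2):
    """Direct combinatorial enumeration over heterozygote counts."""
    n = n_hom1 + n_het + n_hom2
    na = 2 * n_hom1 + n_het
    nb = 2 * n_hom2 + n_het
    if na == 0 or nb == 0:
        return 1.0
    rare = min(na, nb)

    def prob(h):
        ra = (rare - h) // 2
        ca = (2 * n - rare - h) // 2
        return (factorial(n) / (factorial(ra) * factorial(h) * factorial(ca))
                * 2 ** h * factorial(rare) * factorial(2 * n - rare)
                / factorial(2 * n))

    ps = {h: prob(h) for h in range(rare % 2, min(rare, 2 * n - rare) + 1, 2)}
    po = ps[n_het]
    return min(1.0, sum(p for p in ps.values() if p <= po * (1 + 1e-12)))


class TestHWEExactTest:
    def test_monomorphic_convention(self):
        assert eprs.hwe_exact_test(5, 0, 0) == 1.0
        assert eprs.hwe_exact_test(0, 0, 7) == 1.0

    def test_matches_enumeration_oracle_up_to_n50(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            n = int(rng.integers(1, 51))
            a = int(rng.integers(0, n + 1))
            b = int(rng.integers(0, n - a + 1))
            c = n - a - b
            assert eprs.hwe_exact_test(a, b, c) == pytest.approx(
                hwe_enumeration_oracle(a, b, c), abs=1e-12)

    @settings(derandomize=True, max_examples=80)
    @given(st.integers(0, 60), st.integers(0, 60), st.integers(0, 60))
    def test_p_value_always_in_unit_interval(self, a, b, c):
        if a + b + c == 0:
            return
        p = eprs.hwe_exact_test(a, b, c)
        assert 0 < p <= 1

    def test_extreme_disequilibrium_fails_default_floor(self):
        # all-heterozygote genotypes at a large sample: p far below 1e-40
        p = eprs.hwe_exact_test(0, 200, 0)
        assert p < 1e-40


class TestQC:
    def test_clean_matrix_passes_unchanged(self):
        rng = np.random.default_rng(0)
        d = rng.choice([0, 1, 2], p=[0.49, 0.42, 0.09], size=(200, 20))
        G = make_genotypes(d)
        Gq, rep = eprs.qc_genotypes(G)
        assert Gq.n_variants == 20 and Gq.n_samples == 200
        assert rep.n_variants_out == 20

    def test_low_call_rate_variant_removed(self):
        rng = np.random.default_rng(1)
        d = rng.choice([0, 1, 2], p=[0.25, 0.5, 0.25], size=(100, 20))
        d[:6, 0] = MISSING  # 6% missing < 95% call rate; samples keep 19/20
        G = make_genotypes(d)
        Gq, rep = eprs.qc_genotypes(G)
        assert rep.samples_removed_call_rate == 0
        assert rep.variants_removed_call_rate == 1
        assert "rs0" not in Gq.variant_ids()

    def test_maf_boundary_exactly_5_percent_kept(self):
        # 100 samples: 10 effect alleles -> freq 0.05 exactly
        d = np.zeros((100, 1), dtype=np.int8)
        d[:10, 0] = 1
        G = make_genotypes(d)
        Gq, rep = eprs.qc_genotypes(G, hwe_floor=0.0)
        assert rep.variants_removed_maf == 0
        d2 = np.zeros((100, 1), dtype=np.int8)
        d2[:9, 0] = 1
        with pytest.raises(ValueError, match="empty after QC"):
            eprs.qc_genotypes(make_genotypes(d2), hwe_floor=0.0)

    def test_sample_reordering_commutes_with_filters(self):
        rng = np.random.default_rng(5)
        d = rng.choice([0, 1, 2, MISSING], p=[0.4, 0.35, 0.2, 0.05], size=(60, 15))
        G = make_genotypes(d)
        perm = rng.permutation(60)
        Gp = G.subset(sample_idx=perm)
        q1, _ = eprs.qc_genotypes(G)
        q2, _ = eprs.qc_genotypes(Gp)
        assert q1.variant_ids() == q2.variant_ids()


def toy_network():
    table = pd.DataFrame({
        "gene": ["gA", "gB"],
        "coexpr_sign": [1, -1],
        "chrom": ["1", "1"],
        "start": [9_500, 19_500],   # flank 500 already applied to 10k-20k / 20k-30k
        "end": [20_500, 30_500],
    })
    return GeneNetwork(table, flank=500)


class TestAssignSnps:
    def weights(self, rows):
        return pd.DataFrame(rows, columns=["id", "gene", "effect_allele",
                                           "slope", "assoc_p"])

    @pytest.mark.parametrize("pos,included", [(9_500, True), (9_499, False)])
    def test_flank_boundary(self, pos, included):
        G = make_genotypes(np.ones((4, 1), dtype=np.int8), positions=[pos])
        w = self.weights([("rs0", "gA", "A", 0.1, 0.5)])
        tab = eprs.assign_snps(G, toy_network(), w)
        assert (len(tab) == 1) is included

    def test_overlapping_genes_resolved_by_lower_assoc_p(self):
        # position 20_000 is inside both flanked intervals
        G = make_genotypes(np.ones((4, 1), dtype=np.int8), positions=[20_000])
        w = self.weights([("rs0", "gA", "A", 0.1, 0.5),
                          ("rs0", "gB", "A", 0.2, 0.01)])
        tab = eprs.assign_snps(G, toy_network(), w)
        assert len(tab) == 1
        assert tab.iloc[0]["gene"] == "gB"
        assert tab.iloc[0]["coexpr_sign"] == -1


def brute_force_clump(G, table, r2_max, window):
    """Exhaustive re-application of the clumping rule for small instances."""
    ranked = table.sort_values(["assoc_p", "pos", "id"], kind="stable")
    col = {v.id: j for j, v in enumerate(G.variants)}
    kept, removed = [], set()
    for _, row in ranked.iterrows():
        if row["id"] in removed:
            continue
        kept.append(row["id"])
        for _, other in ranked.iterrows():
            if other["id"] in removed or other["id"] in [row["id"], *kept[:-1]]:
                continue
            if other["id"] == row["id"] or other["chrom"] != row["chrom"]:
                continue
            if abs(int(other["pos"]) - int(row["pos"])) > window:
                continue
            a = G.dosage[:, col[row["id"]]].astype(float)
            b = G.dosage[:, col[other["id"]]].astype(float)
            ok = (a != MISSING) & (b != MISSING)
            if ok.sum() < 2 or a[ok].std() == 0 or b[ok].std() == 0:
                continue
            if np.corrcoef(a[ok], b[ok])[0, 1] ** 2 > r2_max:
                removed.add(other["id"])
    return kept


def random_clump_instance(seed, n_snps=12, n_samples=40):
    rng = np.random.default_rng(seed)
    base = rng.integers(0, 3, size=(n_samples, n_snps)).astype(np.int8)
    # induce LD by copying some columns with noise
    for j in range(1, n_snps):
        if rng.random() < 0.5:
            src = int(rng.integers(0, j))
            mask = rng.random(n_samples) < 0.85
            base[mask, j] = base[mask, src]
    pos = np.sort(rng.integers(1, 2_000_000, size=n_snps))
    chrom = rng.choice(["1", "2"], size=n_snps)
    G = make_genotypes(base, positions=pos, chroms=chrom)
    table = pd.DataFrame({
        "id": G.variant_ids(), "chrom": chrom, "pos": pos,
        "effect_allele": "A", "other_allele": "G",
        "gene": "g", "slope": 0.1,
        "assoc_p": rng.random(n_snps), "coexpr_sign": 1,
    })
    return G, table


class TestLDClump:
    def test_perfect_ld_trio_keeps_lowest_p(self):
        col = np.random.default_rng(0).integers(0, 3, size=(50, 1))
        d = np.repeat(col, 3, axis=1).astype(np.int8)
        G = make_genotypes(d, positions=[1000, 5000, 9000])
        table = pd.DataFrame({
            "id": ["rs0", "rs1", "rs2"], "chrom": "1",
            "pos": [1000, 5000, 9000], "effect_allele": "A",
            "other_allele": "G", "gene": "g", "slope": 0.1,
            "assoc_p": [0.5, 0.001, 0.2], "coexpr_sign": 1,
        })
        out = eprs.ld_clump(G, table)
        assert list(out["id"]) == ["rs1"]

    def test_outside_window_both_survive(self):
        col = np.random.default_rng(1).integers(0, 3, size=(50, 1))
        d = np.repeat(col, 2, axis=1).astype(np.int8)
        G = make_genotypes(d, positions=[1000, 601_000])
        table = pd.DataFrame({
            "id": ["rs0", "rs1"], "chrom": "1", "pos": [1000, 601_000],
            "effect_allele": "A", "other_allele": "G", "gene": "g",
            "slope": 0.1, "assoc_p": [0.01, 0.02], "coexpr_sign": 1,
        })
        out = eprs.ld_clump(G, table, window=500_000)
        assert sorted(out["id"]) == ["rs0", "rs1"]

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_oracle(self, seed):
        G, table = random_clump_instance(seed)
        got = list(eprs.ld_clump(G, table, r2_max=0.2, window=300_000)["id"])
        want = brute_force_clump(G, table, 0.2, 300_000)
        assert got == want

    def test_row_order_invariance(self):
        G, table = random_clump_instance(99)
        shuffled = table.sample(frac=1, random_state=1).reset_index(drop=True)
        a = list(eprs.ld_clump(G, table)["id"])
        b = list(eprs.ld_clump(G, shuffled)["id"])
        assert a == b


class TestComputeEprs:
    def weight_table(self, slopes, signs, ids=None):
        ids = ids or [f"rs{j}" for j in range(len(slopes))]
        return pd.DataFrame({
            "id": ids, "chrom": "1", "pos": range(1000, 1000 + len(ids)),
            "effect_allele": "A", "other_allele": "G", "gene": "g",
            "slope": slopes, "assoc_p": 0.1, "coexpr_sign": signs,
        })

    def test_all_zero_dosages_score_zero(self):
        G = make_genotypes(np.zeros((3, 2), dtype=np.int8))
        out = eprs.compute_eprs(G, self.weight_table([0.3, -0.2], [1, -1]),
                                standardize=False)
        assert out["eprs"].tolist() == [0.0, 0.0, 0.0]

    def test_hand_computed_weighted_sum(self):
        G = make_genotypes(np.array([[1, 2]], dtype=np.int8))
        out = eprs.compute_eprs(G, self.weight_table([0.3, -0.2], [1, -1]),
                                standardize=False)
        # 1*0.3*1 + 2*(-0.2)*(-1) = 0.7
        assert out["eprs"].iloc[0] == pytest.approx(0.7)

    def test_linear_in_slopes(self):
        rng = np.random.default_rng(2)
        G = make_genotypes(rng.integers(0, 3, size=(10, 4)))
        t1 = self.weight_table([0.1, -0.2, 0.3, 0.05], [1, -1, 1, 1])
        t2 = t1.assign(slope=t1["slope"] * 3.0)
        s1 = eprs.compute_eprs(G, t1, standardize=False)["eprs"]
        s2 = eprs.compute_eprs(G, t2, standardize=False)["eprs"]
        np.testing.assert_allclose(s2, 3.0 * s1)

    def test_allele_flip_shifts_scores_by_constant(self):
        rng = np.random.default_rng(3)
        G = make_genotypes(rng.integers(0, 3, size=(20, 2)))
        table = self.weight_table([0.3, -0.2], [1, -1])
        s = eprs.compute_eprs(G, table)
        flipped = table.copy()
        flipped.loc[0, "effect_allele"] = "G"
        flipped.loc[0, "slope"] = -table.loc[0, "slope"]
        s2 = eprs.compute_eprs(G, flipped)
        shift = s2["eprs"] - s["eprs"]
        np.testing.assert_allclose(shift, shift.iloc[0])
        np.testing.assert_allclose(s["eprs_z"], s2["eprs_z"], atol=1e-12)

    def test_unknown_snp_raises_with_id(self):
        G = make_genotypes(np.zeros((3, 1), dtype=np.int8))
        table = self.weight_table([0.1], [1], ids=["rs_unknown"])
        with pytest.raises(KeyError, match="rs_unknown"):
            eprs.compute_eprs(G, table)


class TestStratificationPCA:
    def test_divergent_populations_separate_on_pc1(self):
        rng = np.random.default_rng(11)
        n, m = 120, 80
        f1 = rng.uniform(0.1, 0.4, m)
        f2 = np.clip(f1 + rng.choice([-1, 1], m) * 0.35, 0.05, 0.95)
        pop = np.r_[np.zeros(n // 2), np.ones(n // 2)]
        d = np.empty((n, m), dtype=np.int8)
        for i in range(n):
            f = f1 if pop[i] == 0 else f2
            d[i] = rng.binomial(2, f)
        G = make_genotypes(d, positions=(np.arange(m) + 1) * 200_000)
        res = eprs.stratification_pca(G, k=3)
        r = np.corrcoef(res.scores[:, 0], pop)[0, 1]
        assert abs(r) > 0.9

    def test_components_orthogonal(self, small_genotypes):
        res = eprs.stratification_pca(small_genotypes, k=3)
        gram = res.scores.T @ res.scores
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8 * np.abs(np.diag(gram)).max()

    def test_duplicated_samples_share_coordinates(self):
        rng = np.random.default_rng(4)
        d = rng.integers(0, 3, size=(15, 20)).astype(np.int8)
        G = make_genotypes(np.vstack([d, d]))
        res = eprs.stratification_pca(G, k=2)
        np.testing.assert_allclose(res.scores[:15], res.scores[15:], atol=1e-8)
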