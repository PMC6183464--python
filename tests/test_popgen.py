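"""Population-genetic statistics against hand values and independent oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hatchtrace.genotypes import GenotypeTable
from hatchtrace.popgen import (
    allele_frequencies, hwe_test, pairwise_fst, pcoa,
    probability_of_identity, summarize_diversity, unbiased_heterozygosity,
)

from conftest import make_table, pool_from_freqs


# ---------------------------------------------------------------------------
# allele frequencies
# ---------------------------------------------------------------------------

class TestAlleleFrequencies:
    def test_monomorphic(self):
        t = make_table([[[101, 101]], [[101, 101]]], loci=["L1"])
        pf = allele_frequencies(t)
        assert pf.freqs["pop1"]["L1"] == {101: 1.0}

    def test_direct_gene_count(self):
        # 4 AA, 4 AB, 2 BB -> p(A)=0.6, p(B)=0.4, n = 20 gene copies
        rows = [[[101, 101]]] * 4 + [[[101, 103]]] * 4 + [[[103, 103]]] * 2
        pf = allele_frequencies(make_table(rows, loci=["L1"]))
        assert pf.freqs["pop1"]["L1"] == pytest.approx({101: 0.6, 103: 0.4})
        assert pf.n_copies["pop1"]["L1"] == 20

    def test_missing_calls_excluded(self):
        t = make_table([[[101, 103]], [[0, 0]]], loci=["L1"])
        pf = allele_frequencies(t)
        assert pf.n_copies["pop1"]["L1"] == 2

    def test_empty_locus_flagged(self):
        t = make_table([[[0, 0]]], loci=["L1"])
        pf = allele_frequencies(t)
        assert pf.freqs["pop1"]["L1"] == {} and pf.n_copies["pop1"]["L1"] == 0
        assert ("pop1", "L1") in pf.empty_loci

    def test_frequencies_normalized(self):
        rng = np.random.default_rng(0)
        rows = rng.choice([101, 103, 105, 107], size=(40, 5, 2))
        t = make_table(rows.tolist(), loci=[f"L{j}" for j in range(5)],
                       pops=["a"] * 20 + ["b"] * 20)
        pf = allele_frequencies(t)
        for pop in pf.populations:
            for locus in pf.loci:
                assert sum(pf.freqs[pop][locus].values()) == pytest.approx(
                    1.0, abs=1e-12
                )


# ---------------------------------------------------------------------------
# diversity
# ---------------------------------------------------------------------------

class TestDiversity:
    def test_monomorphic_population(self):
        t = make_table([[[101, 101]] * 3] * 4, loci=["L1", "L2", "L3"])
        d = summarize_diversity(t)
        assert d.loc["pop1", "H_E"] == 0.0
        assert d.loc["pop1", "N_A"] == 1.0

    def test_unbiased_he_worked_value(self):
        # 1 locus, 2 alleles at 0.5, n = 10 individuals (20 copies):
        # He = (20/19)(1 - 0.5) = 0.52631...
        rows = [[[101, 103]]] * 10
        d = summarize_diversity(make_table(rows, loci=["L1"]))
        assert d.loc["pop1", "H_E"] == pytest.approx(20 / 19 * 0.5, abs=1e-6)
        assert unbiased_heterozygosity({1: 0.5, 2: 0.5}, 20) == pytest.approx(
            0.526315789, abs=1e-8
        )

    def test_he_bounds_random_tables(self):
        rng = np.random.default_rng(1)
        rows = rng.choice([101, 103, 105], size=(30, 4, 2))
        d = summarize_diversity(
            make_table(rows.tolist(), loci=list("ABCD"))
        )
        assert 0.0 <= d["H_E"].iloc[0] <= 1.0


# ---------------------------------------------------------------------------
# Hardy-Weinberg
# ---------------------------------------------------------------------------

class TestHWE:
    def _table(self, n_aa, n_ab, n_bb):
        rows = ([[[101, 101]]] * n_aa + [[[101, 103]]] * n_ab
                + [[[103, 103]]] * n_bb)
        return make_table(rows, loci=["L1"])

    def test_exact_proportions_give_p_one(self):
        res = hwe_test(self._table(25, 50, 25), "pop1")
        assert res.loc["L1", "chi2"] == pytest.approx(0.0, abs=1e-12)
        assert res.loc["L1", "p_value"] == pytest.approx(1.0)

    def test_all_heterozygote_excess(self):
        # expected (12.5, 25, 12.5) under p=q=0.5 -> chi2 = 50, df = 1
        res = hwe_test(self._table(0, 50, 0), "pop1")
        assert res.loc["L1", "chi2"] == pytest.approx(50.0)
        assert res.loc["L1", "df"] == 1
        assert res.loc["L1", "p_value"] == pytest.approx(1.5e-12, rel=0.05)

    def test_bonferroni_threshold(self):
        res = hwe_test(self._table(25, 50, 25), "pop1", alpha=0.05, n_tests=24)
        assert res["bonferroni_threshold"].iloc[0] == pytest.approx(
            0.05 / 24, abs=1e-12
        )
        assert res["bonferroni_threshold"].iloc[0] == pytest.approx(
            0.00208, abs=5e-6
        )

    def test_monomorphic_not_applicable(self):
        t = make_table([[[101, 101]]] * 5, loci=["L1"])
        res = hwe_test(t, "pop1")
        assert np.isnan(res.loc["L1", "chi2"])


# ---------------------------------------------------------------------------
# FST
# ---------------------------------------------------------------------------

def _indicator_anova_theta(calls_a, calls_b):
    """Independent Weir-Cockerham oracle via a three-level ANOVA on allele
    indicator variables (pops / individuals-within-pops / copies), following
    the method-of-moments mean-square route rather than the closed-form
    variance components."""
    num = den = 0.0
    for l in range(calls_a.shape[1]):
        groups = []
        for calls in (calls_a, calls_b):
            typed = calls[:, l, :]
            typed = typed[(typed != 0).all(axis=1)]
            groups.append(typed)
        alleles = np.unique(np.concatenate([g.reshape(-1) for g in groups]))
        n_i = np.array([g.shape[0] for g in groups], dtype=float)
        r = 2
        nbar = n_i.mean()
        nc = (r * nbar - (n_i**2).sum() / (r * nbar)) / (r - 1)
        for a in alleles:
            # indicator value per copy
            x = [np.mean(g == a, axis=1) for g in groups]  # per-individual freq
            y = [(g == a).astype(float) for g in groups]
            # mean squares
            grand = np.concatenate([yy.reshape(-1) for yy in y]).mean()
            p_i = np.array([yy.mean() for yy in y])
            msp = sum(
                2 * n_i[k] * (p_i[k] - grand) ** 2 for k in range(r)
            ) / (r - 1)
            msi = sum(
                2 * ((x[k] - p_i[k]) ** 2 * 1).sum() for k in range(r)
            ) / (n_i.sum() - r)
            msg = sum(
                ((y[k] - x[k][:, None]) ** 2).sum() for k in range(r)
            ) / n_i.sum()
            a_comp = (msp - msi) / (2 * nc)
            b_comp = (msi - msg) / 2
            c_comp = msg
            num += a_comp
            den += a_comp + b_comp + c_comp
    return num / den


class TestPairwiseFst:
    def test_identical_compositions_near_zero(self):
        rng = np.random.default_rng(2)
        block = rng.choice([101, 103, 105], size=(100, 6, 2))
        rows = np.concatenate([block, block])
        t = make_table(rows.tolist(), loci=[f"L{j}" for j in range(6)],
                       pops=["a"] * 100 + ["b"] * 100)
        m, _ = pairwise_fst(t)
        # theta of two copies of the same sample is slightly negative
        assert abs(m.loc["a", "b"]) < 0.01

    def test_fixed_difference_is_exactly_one(self):
        rows = [[[101, 101]] * 3] * 30 + [[[103, 103]] * 3] * 30
        t = make_table(rows, loci=["L1", "L2", "L3"],
                       pops=["a"] * 30 + ["b"] * 30)
        m, _ = pairwise_fst(t)
        assert m.loc["a", "b"] == pytest.approx(1.0, abs=1e-12)

    def test_matches_indicator_anova_oracle(self):
        rng = np.random.default_rng(7)
        rows_a = rng.choice([101, 103], size=(50, 1, 2), p=[0.7, 0.3])
        rows_b = rng.choice([101, 103], size=(50, 1, 2), p=[0.3, 0.7])
        rows = np.concatenate([rows_a, rows_b])
        t = make_table(rows.tolist(), loci=["L1"],
                       pops=["a"] * 50 + ["b"] * 50)
        m, _ = pairwise_fst(t)
        oracle = _indicator_anova_theta(rows_a, rows_b)
        assert m.loc["a", "b"] == pytest.approx(oracle, abs=1e-10)

    def test_oracle_agreement_multilocus_with_missing(self):
        rng = np.random.default_rng(8)
        rows = rng.choice([101, 103, 105], size=(60, 4, 2))
        rows[rng.random(rows.shape[:2]) < 0.1] = 0
        t = make_table(rows.tolist(), loci=list("ABCD"),
                       pops=["a"] * 30 + ["b"] * 30)
        m, _ = pairwise_fst(t)
        oracle = _indicator_anova_theta(rows[:30], rows[30:])
        assert m.loc["a", "b"] == pytest.approx(oracle, abs=1e-10)

    def test_matrix_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(3)
        rows = rng.choice([101, 103, 105], size=(60, 3, 2))
        t = make_table(rows.tolist(), loci=["L1", "L2", "L3"],
                       pops=["a"] * 20 + ["b"] * 20 + ["c"] * 20)
        m, _ = pairwise_fst(t)
        assert np.allclose(m, m.T) and np.allclose(np.diag(m), 0)

    def test_small_population_reported_missing(self):
        rows = [[[101, 101]]] * 5 + [[[103, 103]]]
        t = make_table(rows, loci=["L1"], pops=["a"] * 5 + ["b"])
        m, _ = pairwise_fst(t)
        assert np.isnan(m.loc["a", "b"])

    def test_permutation_pvalue_significant_for_fixed_difference(self):
        rows = [[[101, 101]] * 3] * 20 + [[[103, 103]] * 3] * 20
        t = make_table(rows, loci=["L1", "L2", "L3"],
                       pops=["a"] * 20 + ["b"] * 20)
        _, p = pairwise_fst(t, n_permutations=49, seed=0)
        assert p.loc["a", "b"] == pytest.approx(1 / 50)

    def test_nei_estimator_orders_like_theta(self):
        rows = [[[101, 101]]] * 30 + [[[103, 103]]] * 30
        t = make_table(rows, loci=["L1"], pops=["a"] * 30 + ["b"] * 30)
        m, _ = pairwise_fst(t, estimator="nei")
        assert m.loc["a", "b"] > 0.9


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------

class TestPcoa:
    def test_equilateral_triangle_splits_variance(self):
        D = np.ones((3, 3)) - np.eye(3)
        coords, pct, _ = pcoa(D)
        assert pct == pytest.approx([50.0, 50.0], abs=1e-9)

    def test_gower_reconstruction_identity(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(5, 3))
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        coords, pct, _ = pcoa(D)
        rec = np.sqrt(
            ((coords[:, None] - coords[None]) ** 2).sum(-1)
        )
        assert np.allclose(rec, D, atol=1e-8)
        assert pct.sum() == pytest.approx(100.0, abs=1e-9)

    def test_matches_skbio(self):
        skbio_ord = pytest.importorskip("skbio.stats.ordination")
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(6, 2))
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        coords, pct, _ = pcoa(D)
        ref = skbio_ord.pcoa(D, number_of_dimensions=2)
        ref_pct = 100 * ref.proportion_explained.to_numpy()[:2]
        assert pct[:2] == pytest.approx(ref_pct, abs=1e-6)
        assert np.abs(coords[:, 0]) == pytest.approx(
            np.abs(ref.samples.iloc[:, 0].to_numpy()), abs=1e-6
        )

    def test_rejects_asymmetric(self):
        with pytest.raises(ValueError, match="symmetric"):
            pcoa(np.array([[0.0, 1.0], [2.0, 0.0]]))

    def test_truncates_negative_distances(self):
        D = np.array([[0.0, -0.01], [-0.01, 0.0]])
        coords, pct, ev = pcoa(D)
        assert coords.shape[1] == 0 or np.allclose(coords, 0)


# ---------------------------------------------------------------------------
# probability of identity
# ---------------------------------------------------------------------------

def _pid_enumeration(freq):
    """Oracle: sum over HWE genotype frequencies squared."""
    alleles = sorted(freq)
    total = 0.0
    for i, a in enumerate(alleles):
        for b in alleles[i:]:
            g = freq[a] ** 2 if a == b else 2 * freq[a] * freq[b]
            total += g * g
    return total


class TestPID:
    def test_monomorphic_locus(self):
        assert probability_of_identity(
            pool_from_freqs({"L1": {101: 1.0}})
        ) == pytest.approx(1.0)

    def test_biallelic_half(self):
        pf = pool_from_freqs({"L1": {101: 0.5, 103: 0.5}})
        assert probability_of_identity(pf) == pytest.approx(0.375, abs=1e-12)
        assert probability_of_identity(pf) == pytest.approx(
            _pid_enumeration({101: 0.5, 103: 0.5}), abs=1e-12
        )

    def test_product_rule(self):
        pf = pool_from_freqs({
            "L1": {101: 0.5, 103: 0.5}, "L2": {101: 0.5, 103: 0.5}
        })
        assert probability_of_identity(pf) == pytest.approx(0.140625, abs=1e-12)

    @settings(deadline=None, max_examples=30)
    @given(st.lists(st.floats(0.05, 1.0), min_size=2, max_size=6))
    def test_enumeration_oracle_any_spectrum(self, weights):
        p = np.array(weights) / np.sum(weights)
        freq = {101 + 2 * i: float(v) for i, v in enumerate(p)}
        pf = pool_from_freqs({"L1": freq})
        assert probability_of_identity(pf) == pytest.approx(
            _pid_enumeration(freq), abs=1e-12
        )

    def test_non_increasing_in_loci(self):
        f = {101: 0.6, 103: 0.4}
        one = probability_of_identity(pool_from_freqs({"L1": f}))
        two = probability_of_identity(pool_from_freqs({"L1": f, "L2": f}))
        assert two <= one

    def test_empty_locus_rejected(self):
        pf = pool_from_freqs({"L1": {}})
        with pytest.raises(ValueError, match="no allele frequencies"):
            probability_of_identity(pf)
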