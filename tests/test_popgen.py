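"""Summary statistics against hand computations and independent oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from deintrogress.genotype_io import CollectionMeta
from deintrogress.popgen import (
    allele_freqs,
    expected_heterozygosity,
    fdr_adjust,
    g_test_differentiation,
    hwe_exact,
    pca,
    per_locus_theta,
    rank_discriminating_loci,
    wc_theta,
)

from conftest import make_freqs, make_gm


# ---------------------------------------------------------------------------
# Allele frequencies & heterozygosity
# ---------------------------------------------------------------------------

class TestAlleleFreqs:
    def test_single_het_gives_half(self):
        gm = make_gm([[1]])
        af = allele_freqs(gm, groups={"g": gm.individuals})["g"]
        assert af.freq[0] == pytest.approx(0.5)

    def test_all_hom_ref_gives_one(self):
        gm = make_gm([[2], [2]])
        af = allele_freqs(gm, groups={"g": gm.individuals})["g"]
        assert af.freq[0] == pytest.approx(1.0)

    def test_masking_matches_hand_count(self):
        missing = np.array([[False, True], [False, False], [True, False]])
        gm = make_gm([[2, 1], [1, 0], [0, 2]], missing)
        af = allele_freqs(gm, groups={"g": gm.individuals})["g"]
        # locus 0: dosages 2,1 over 4 copies; locus 1: 0,2 over 4 copies
        assert af.freq[0] == pytest.approx(3 / 4)
        assert af.freq[1] == pytest.approx(2 / 4)
        assert list(af.n_alleles) == [4, 4]

    def test_empty_group_errors(self, tiny_gm):
        with pytest.raises(ValueError, match="empty group"):
            allele_freqs(tiny_gm, groups={"g": []})


class TestExpectedHeterozygosity:
    def test_half_frequency_large_n(self):
        assert expected_heterozygosity(make_freqs([0.5], n_per_locus=10**9)) == pytest.approx(0.5)

    def test_fixed_locus_zero(self):
        assert expected_heterozygosity(make_freqs([1.0])) == 0.0

    def test_three_locus_hand_computation(self):
        freqs = make_freqs([0.5, 0.2, 1.0])
        freqs.n_alleles = np.array([10, 20, 8])
        by_hand = np.mean(
            [
                2 * 0.5 * 0.5 * 10 / 9,
                2 * 0.2 * 0.8 * 20 / 19,
                0.0,
            ]
        )
        assert expected_heterozygosity(freqs) == pytest.approx(by_hand)


# ---------------------------------------------------------------------------
# HWE exact test
# ---------------------------------------------------------------------------

def _hwe_enumeration_oracle(n_het, n_ref, n_ind):
    """Exact two-sided HWE p by direct enumeration of genotype tables."""
    from math import comb

    n_alt = 2 * n_ind - n_ref
    rare = min(n_ref, n_alt)
    probs = {}
    for h in range(rare % 2, rare + 1, 2):
        hom_ref = (n_ref - h) // 2
        hom_alt = (n_alt - h) // 2
        if hom_ref < 0 or hom_alt < 0:
            continue
        # multinomial count of genotype configurations x 2^het phase factor
        from math import factorial

        w = (
            factorial(n_ind)
            / (factorial(hom_ref) * factorial(h) * factorial(hom_alt))
            * 2**h
        )
        probs[h] = w
    total = sum(probs.values())
    obs = probs[n_het] / total
    return sum(p / total for p in probs.values() if p / total <= obs * (1 + 1e-12))


class TestHweExact:
    def test_monomorphic_flagged_p_one(self):
        gm = make_gm([[2], [2], [2]])
        df = hwe_exact(gm, groups={"g": gm.individuals})
        assert df.iloc[0]["p_value"] == 1.0
        assert bool(df.iloc[0]["monomorphic"])

    @pytest.mark.parametrize(
        "dosages",
        [
            [2, 2, 2, 0, 0],      # 0 hets, allele counts 6/4
            [1, 1, 1, 1, 1],      # all het
            [2, 1, 1, 0, 1],
            [2, 2, 1, 1, 0, 0, 1, 2],
        ],
    )
    def test_matches_enumeration_oracle(self, dosages):
        gm = make_gm(np.array(dosages)[:, None])
        df = hwe_exact(gm, groups={"g": gm.individuals})
        n_het = sum(d == 1 for d in dosages)
        n_ref = sum(dosages)
        expected = _hwe_enumeration_oracle(n_het, n_ref, len(dosages))
        assert df.iloc[0]["p_value"] == pytest.approx(expected, abs=1e-12)

    def test_perfect_hwe_proportions_high_p(self):
        # 25 hom-ref, 50 het, 25 hom-alt: exactly HWE at p=0.5
        dosages = [2] * 25 + [1] * 50 + [0] * 25
        gm = make_gm(np.array(dosages)[:, None])
        df = hwe_exact(gm, groups={"g": gm.individuals})
        assert df.iloc[0]["p_value"] > 0.5

    def test_super_uniform_under_null(self):
        # simulated HWE genotypes: exact-test p-values are conservative
        rng = np.random.default_rng(5)
        pvals = []
        for _ in range(300):
            p = rng.uniform(0.2, 0.8)
            gm = make_gm(rng.binomial(2, p, 30)[:, None])
            df = hwe_exact(gm, groups={"g": gm.individuals})
            pvals.append(df.iloc[0]["p_value"])
        pvals = np.array(pvals)
        for alpha in (0.05, 0.1, 0.25):
            assert (pvals <= alpha).mean() <= alpha + 0.03


# ---------------------------------------------------------------------------
# Weir-Cockerham theta
# ---------------------------------------------------------------------------

def _wc_oracle_two_pops(geno_a, geno_b):
    """Independent per-locus Weir-Cockerham (1984) implementation.

    Literal transcription of the two-allele estimator: sample sizes n_i,
    frequencies p_i, observed heterozygosities h_i; returns (a, b, c) sums
    over loci and the multi-locus ratio.
    """
    geno_a = np.asarray(geno_a, float)
    geno_b = np.asarray(geno_b, float)
    r = 2
    A = B = C = 0.0
    per_locus = []
    for j in range(geno_a.shape[1]):
        ga, gb = geno_a[:, j], geno_b[:, j]
        n1, n2 = len(ga), len(gb)
        p1, p2 = ga.sum() / (2 * n1), gb.sum() / (2 * n2)
        h1, h2 = np.mean(ga == 1), np.mean(gb == 1)
        nbar = (n1 + n2) / 2
        nc = (n1 + n2 - (n1**2 + n2**2) / (n1 + n2)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (n1 + n2)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        A += a
        B += b
        C += c
        per_locus.append(a / (a + b + c) if (a + b + c) != 0 else np.nan)
    return A / (A + B + C), np.array(per_locus)


class TestWcTheta:
    def test_identical_populations_near_zero(self):
        rng = np.random.default_rng(6)
        geno = rng.binomial(2, rng.uniform(0.2, 0.8, 100), size=(40, 100))
        gm = make_gm(geno)
        pops = {"a": gm.individuals[:20], "b": gm.individuals[20:]}
        res = wc_theta(gm, pops, n_bootstrap=0)
        assert abs(res.theta_multilocus) < 0.02

    def test_fixed_differences_give_one(self):
        geno = np.vstack([np.full((4, 5), 2), np.full((4, 5), 0)])
        gm = make_gm(geno)
        res = wc_theta(gm, {"a": gm.individuals[:4], "b": gm.individuals[4:]}, n_bootstrap=0)
        assert res.theta_multilocus == pytest.approx(1.0)
        np.testing.assert_allclose(res.theta_per_locus, 1.0)

    def test_toy_matches_independent_oracle(self):
        # 2 pops x 2 individuals x 2 loci, mixed genotypes
        geno_a = np.array([[2, 1], [1, 0]])
        geno_b = np.array([[0, 2], [1, 2]])
        gm = make_gm(np.vstack([geno_a, geno_b]))
        res = wc_theta(gm, {"a": gm.individuals[:2], "b": gm.individuals[2:]}, n_bootstrap=0)
        multi, per_locus = _wc_oracle_two_pops(geno_a, geno_b)
        assert res.theta_multilocus == pytest.approx(multi, abs=1e-12)
        np.testing.assert_allclose(res.theta_per_locus, per_locus, atol=1e-12)

    def test_invariant_to_locus_and_individual_order(self):
        rng = np.random.default_rng(7)
        geno = rng.binomial(2, rng.uniform(0.1, 0.9, 30), size=(24, 30))
        gm = make_gm(geno)
        pops = {"a": gm.individuals[:12], "b": gm.individuals[12:]}
        base = wc_theta(gm, pops, n_bootstrap=0).theta_multilocus
        perm_loci = list(rng.permutation(gm.locus_ids))
        shuffled = gm.subset(loci=perm_loci)
        pops_shuf = {"a": list(rng.permutation(pops["a"])), "b": list(rng.permutation(pops["b"]))}
        assert wc_theta(shuffled, pops_shuf, n_bootstrap=0).theta_multilocus == pytest.approx(base)

    def test_bootstrap_ci_brackets_estimate_and_shrinks(self):
        rng = np.random.default_rng(8)
        p_w = rng.uniform(0.2, 0.8, 60)
        p_h = np.clip(p_w + rng.normal(0, 0.15, 60), 0.05, 0.95)

        def dataset(n):
            geno = np.vstack([
                rng.binomial(2, p_w, size=(n, 60)),
                rng.binomial(2, p_h, size=(n, 60)),
            ])
            gm = make_gm(geno)
            return gm, {"a": gm.individuals[:n], "b": gm.individuals[n:]}

        gm_s, pops_s = dataset(12)
        gm_l, pops_l = dataset(120)
        small = wc_theta(gm_s, pops_s, n_bootstrap=200, seed=1)
        large = wc_theta(gm_l, pops_l, n_bootstrap=200, seed=1)
        assert small.ci_low <= small.theta_multilocus <= small.ci_high
        assert (large.ci_high - large.ci_low) < (small.ci_high - small.ci_low)

    def test_single_individual_population_errors(self, tiny_gm):
        with pytest.raises(ValueError, match="fewer than 2"):
            wc_theta(tiny_gm, {"a": tiny_gm.individuals[:1], "b": tiny_gm.individuals[1:]})


# ---------------------------------------------------------------------------
# G test
# ---------------------------------------------------------------------------

class TestGTest:
    def test_hand_computed_g_statistic(self):
        # allele table 12/8 vs 4/16 -> G = 2 * sum O ln(O/E)
        geno_a = np.array([2] * 6 + [0] * 4)[:, None]  # 12 ref / 8 alt
        geno_b = np.array([2] * 2 + [0] * 8)[:, None]  # 4 ref / 16 alt
        gm = make_gm(np.vstack([geno_a, geno_b]))
        table, _ = g_test_differentiation(
            gm, gm.individuals[:10], gm.individuals[10:], n_perm=10, seed=0
        )
        obs = np.array([12, 8, 4, 16], dtype=float)
        row = np.array([20, 20])
        col = np.array([16, 24])
        exp = np.array([row[0] * col[0], row[0] * col[1], row[1] * col[0], row[1] * col[1]]) / 40
        g_hand = 2 * np.sum(obs * np.log(obs / exp))
        assert table.iloc[0]["g_stat"] == pytest.approx(g_hand)

    def test_fixed_difference_minimal_p(self):
        geno = np.vstack([np.full((20, 1), 2), np.full((20, 1), 0)])
        gm = make_gm(geno)
        table, combined = g_test_differentiation(
            gm, gm.individuals[:20], gm.individuals[20:], n_perm=200, seed=1
        )
        assert table.iloc[0]["p_value"] == pytest.approx(1 / 201)
        assert combined < 0.01

    def test_null_calibration(self):
        # identical sampling distributions: per-dataset combined p roughly uniform
        rng = np.random.default_rng(9)
        rejections = 0
        n_datasets = 100
        for _ in range(n_datasets):
            geno = rng.binomial(2, rng.uniform(0.3, 0.7, 6), size=(24, 6))
            gm = make_gm(geno)
            _, combined = g_test_differentiation(
                gm, gm.individuals[:12], gm.individuals[12:], n_perm=150,
                seed=int(rng.integers(2**31)),
            )
            rejections += combined < 0.05
        assert rejections / n_datasets < 0.14

    def test_monomorphic_locus_excluded_from_combination(self):
        geno = np.column_stack([np.full(10, 2), np.r_[np.full(5, 2), np.full(5, 0)]])
        gm = make_gm(geno)
        table, combined = g_test_differentiation(
            gm, gm.individuals[:5], gm.individuals[5:], n_perm=50, seed=2
        )
        assert not bool(table.iloc[0]["polymorphic"])
        assert np.isfinite(combined)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

class TestPca:
    def test_duplicated_groups_separate_on_pc1(self):
        a = [0, 2, 0, 2, 1]
        b = [2, 0, 2, 0, 1]
        gm = make_gm([a, a, a, b, b, b])
        res = pca(gm)
        pc1 = res.coordinates[:, 0]
        assert (pc1[:3] > 0).all() != (pc1[3:] > 0).all()
        # duplicates within groups leave no within-group variance
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_variance_ratios_sum_to_one_full_rank(self):
        rng = np.random.default_rng(10)
        gm = make_gm(rng.integers(0, 3, size=(6, 10)))
        res = pca(gm)
        assert res.explained_variance_ratio.sum() == pytest.approx(1.0)

    def test_matches_eigendecomposition_oracle(self):
        geno = np.array([[0, 1, 2], [2, 1, 0], [1, 2, 1], [2, 0, 2]])
        gm = make_gm(geno)
        res = pca(gm)
        x = geno - geno.mean(axis=0)
        eigvals, eigvecs = np.linalg.eigh(x @ x.T)
        order = np.argsort(eigvals)[::-1]
        for k in range(2):
            expected = eigvecs[:, order[k]] * np.sqrt(eigvals[order[k]])
            got = res.coordinates[:, k]
            assert np.allclose(got, expected, atol=1e-9) or np.allclose(
                got, -expected, atol=1e-9
            )


# ---------------------------------------------------------------------------
# Locus ranking + FDR
# ---------------------------------------------------------------------------

class TestRanking:
    def test_fixed_difference_ranked_first(self):
        rng = np.random.default_rng(11)
        neutral = rng.binomial(2, 0.5, size=(20, 9))
        fixed = np.r_[np.full(10, 2), np.full(10, 0)][:, None]
        gm = make_gm(np.column_stack([neutral[:, :4], fixed, neutral[:, 4:]]))
        top = rank_discriminating_loci(gm, gm.individuals[:10], gm.individuals[10:], 0.1)
        assert top[0] == "L4"

    def test_top_frac_one_returns_all(self, tiny_gm):
        got = rank_discriminating_loci(
            tiny_gm, tiny_gm.individuals[:2], tiny_gm.individuals[2:], 1.0
        )
        assert sorted(got) == sorted(tiny_gm.locus_ids)

    def test_matches_sort_oracle(self):
        rng = np.random.default_rng(12)
        gm = make_gm(rng.integers(0, 3, size=(30, 20)))
        a, b = gm.individuals[:15], gm.individuals[15:]
        theta = per_locus_theta(gm, a, b)
        expected = [
            gm.locus_ids[j]
            for j in np.argsort(-np.where(np.isnan(theta), -np.inf, theta), kind="stable")[:5]
        ]
        assert rank_discriminating_loci(gm, a, b, 0.25) == expected

    def test_bad_top_frac_errors(self, tiny_gm):
        with pytest.raises(ValueError, match="top_frac"):
            rank_discriminating_loci(tiny_gm, tiny_gm.individuals[:2], tiny_gm.individuals[2:], 0.0)


class TestFdr:
    def test_single_p_unchanged(self):
        assert fdr_adjust([0.037])[0] == pytest.approx(0.037)

    def test_hand_stepup(self):
        np.testing.assert_allclose(
            fdr_adjust([0.01, 0.02, 0.5]), [0.03, 0.03, 0.5], atol=1e-12
        )

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.2])

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    def test_properties(self, pvals):
        adj = fdr_adjust(pvals)
        assert np.all((adj >= np.asarray(pvals) - 1e-12) & (adj <= 1 + 1e-12))
        order = np.argsort(pvals)
        assert np.all(np.diff(adj[order]) >= -1e-12)
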