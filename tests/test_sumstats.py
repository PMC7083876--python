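"""Diversity statistics against hand computations and brute-force oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from demosat.dataset import MISSING, GenotypeDataset
from demosat.sumstats import (abc_summary_vector, m_ratio, pairwise_fst,
                              per_locus_diversity, private_alleles,
                              prop_low_freq_alleles, rarefied_allelic_richness,
                              subsample_statistic)

from conftest import make_dataset


def locus_dataset(copies, pops=None):
    """One-locus dataset from an explicit list of gene copies (paired)."""
    copies = list(copies)
    assert len(copies) % 2 == 0
    genos = [[[copies[2 * i], copies[2 * i + 1]]] for i in range(len(copies) // 2)]
    return make_dataset(genos, pops=pops)


class TestPerLocusDiversity:
    def test_hand_example(self):
        # genotypes (A,B),(A,A): Ho=1/2; He = 4/3*(1 - 9/16 - 1/16) = 1/2; Fis=0
        d = make_dataset([[[10, 12]], [[10, 10]]])
        div = per_locus_diversity(d)
        row = div.per_locus.iloc[0]
        assert row["Ho"] == pytest.approx(0.5)
        assert row["He_unbiased"] == pytest.approx(0.5)
        assert row["Fis"] == pytest.approx(0.0)

    def test_monomorphic_locus(self):
        d = make_dataset([[[10, 10]], [[10, 10]]])
        row = per_locus_diversity(d).per_locus.iloc[0]
        assert (row["Ho"], row["He_unbiased"], row["Fis"]) == (0.0, 0.0, 0.0)

    def test_unbiased_he_at_least_plugin(self):
        rng = np.random.default_rng(0)
        copies = rng.integers(10, 15, size=40)
        d = locus_dataset(copies)
        he = per_locus_diversity(d).per_locus.iloc[0]["He_unbiased"]
        f = np.unique(copies, return_counts=True)[1] / copies.size
        plugin = 1 - np.sum(f**2)
        assert he >= plugin
        mono = locus_dataset([7] * 10)
        assert per_locus_diversity(mono).per_locus.iloc[0]["He_unbiased"] == 0.0

    def test_all_missing_locus_flagged_and_excluded(self):
        d = make_dataset([[[10, 12], [MISSING, MISSING]],
                          [[10, 10], [MISSING, MISSING]]])
        div = per_locus_diversity(d)
        assert not div.per_locus.iloc[1]["usable"]
        assert div.means["Ho"] == pytest.approx(0.5)  # mean over usable loci only


class TestRarefiedRichness:
    def test_three_copy_example(self):
        # copies A,A,B at g=2: subsamples {AA,AB,AB} -> (1+2+2)/3 = 5/3
        d = locus_dataset([10, 10, 11, 11])  # need even copies; use A,A,B,B below
        d = locus_dataset([10, 10, 10, 11])
        ar, _ = rarefied_allelic_richness(d, g=2)
        # brute force over the actual 4 copies {A,A,A,B}
        combos = list(itertools.combinations([10, 10, 10, 11], 2))
        expected = np.mean([len(set(c)) for c in combos])
        assert ar[0] == pytest.approx(expected)

    def test_brute_force_enumeration(self):
        rng = np.random.default_rng(1)
        copies = rng.integers(20, 24, size=12).tolist()
        d = locus_dataset(copies)
        for g in (2, 5, 8):
            ar, _ = rarefied_allelic_richness(d, g=g)
            expected = np.mean([len(set(c))
                                for c in itertools.combinations(copies, g)])
            assert ar[0] == pytest.approx(expected)

    def test_monomorphic_and_full_sample(self):
        mono = locus_dataset([9] * 8)
        assert rarefied_allelic_richness(mono, g=3)[0][0] == pytest.approx(1.0)
        copies = [10, 10, 11, 12, 12, 13]
        d = locus_dataset(copies)
        ar, _ = rarefied_allelic_richness(d, g=6)
        assert ar[0] == pytest.approx(len(set(copies)))

    def test_monotone_in_g(self):
        d = locus_dataset([10, 10, 11, 12, 12, 13, 14, 14])
        vals = [rarefied_allelic_richness(d, g=g)[1] for g in range(2, 9)]
        assert np.all(np.diff(vals) >= 0)

    def test_error_names_locus(self):
        d = make_dataset([[[10, 12], [MISSING, 20]], [[10, 10], [21, 20]]],
                         locus_names=["good", "thin"])
        with pytest.raises(ValueError, match="thin"):
            rarefied_allelic_richness(d, g=4)


class TestMRatio:
    @pytest.mark.parametrize("copies,expected", [
        ([10, 12, 13, 10], 3 / 4),    # k=3, range 3
        ([10, 10, 10, 10], 1.0),      # monomorphic
        ([10, 11, 12, 11], 1.0),      # contiguous ladder
    ])
    def test_examples(self, copies, expected):
        arr, mean = m_ratio(locus_dataset(copies))
        assert arr[0] == pytest.approx(expected)
        assert mean == pytest.approx(expected)

    def test_base_pair_conversion_error(self):
        d = locus_dataset([100, 103, 104, 100])
        with pytest.raises(ValueError, match="motif"):
            m_ratio(d, repeat_unit_bp=np.array([2]))


class TestLowFreqAlleles:
    def test_one_of_three_below_threshold(self):
        copies = [1] * 45 + [2] * 3 + [3] * 2  # freqs 0.90, 0.06, 0.04
        arr, _ = prop_low_freq_alleles(locus_dataset(copies))
        assert arr[0] == pytest.approx(1 / 3)

    def test_exact_five_percent_not_low(self):
        copies = [1] * 19 + [2]  # freq exactly 1/20
        arr, _ = prop_low_freq_alleles(locus_dataset(copies))
        assert arr[0] == 0.0

    def test_equifrequent_and_singletons(self):
        assert prop_low_freq_alleles(locus_dataset([1] * 5 + [2] * 5))[0][0] == 0.0
        copies = list(range(100))  # 100 singletons in 100 copies
        assert prop_low_freq_alleles(locus_dataset(copies))[0][0] == 1.0


class TestPrivateAlleles:
    def test_one_private_each(self):
        d = locus_dataset([10, 11, 10, 11, 11, 12, 11, 12],
                          pops=["a", "a", "b", "b"])
        counts = private_alleles(d)
        assert counts["a"] == 1 and counts["b"] == 1

    def test_identical_populations(self):
        d = locus_dataset([10, 11, 10, 11] * 2, pops=["a", "a", "b", "b"])
        assert private_alleles(d).sum() == 0

    def test_disjoint_allele_sets(self):
        d = locus_dataset([1, 2, 3, 1, 8, 9, 8, 9], pops=["a", "a", "b", "b"])
        counts = private_alleles(d)
        assert counts["a"] == 3 and counts["b"] == 2

    def test_single_population_error(self):
        with pytest.raises(ValueError):
            private_alleles(locus_dataset([1, 2, 1, 2]))


def _wc_theta_biallelic(n1, n2, p1, p2, h1, h2):
    """Independent textbook Weir-Cockerham theta for one biallelic locus,
    two populations (coded directly from the published variance components)."""
    total = 0.0
    num = 0.0
    for pA, pB, hA, hB in [(p1, p2, h1, h2), (1 - p1, 1 - p2, h1, h2)]:
        n_bar = (n1 + n2) / 2
        nc = 2 * n_bar - (n1**2 + n2**2) / (2 * n_bar)
        p_bar = (n1 * pA + n2 * pB) / (2 * n_bar)
        s2 = (n1 * (pA - p_bar) ** 2 + n2 * (pB - p_bar) ** 2) / n_bar
        h_bar = (n1 * hA + n2 * hB) / (2 * n_bar)
        a = (n_bar / nc) * (s2 - (p_bar * (1 - p_bar) - s2 / 2 - h_bar / 4) / (n_bar - 1))
        b = (n_bar / (n_bar - 1)) * (p_bar * (1 - p_bar) - s2 / 2
                                     - (2 * n_bar - 1) / (4 * n_bar) * h_bar)
        c = h_bar / 2
        num += a
        total += a + b + c
    return num / total


class TestPairwiseFst:
    def test_toy_biallelic_matches_textbook_evaluation(self):
        # pop a: 4 ind with genotypes AA, AA, AB, BB; pop b: AB, BB, BB, BB
        d = make_dataset(
            [[[1, 1]], [[1, 1]], [[1, 2]], [[2, 2]],
             [[1, 2]], [[2, 2]], [[2, 2]], [[2, 2]]],
            pops=["a"] * 4 + ["b"] * 4)
        res = pairwise_fst(d)
        p1, h1 = 5 / 8, 1 / 4   # freq of allele 1 and het fraction in pop a
        p2, h2 = 1 / 8, 1 / 4
        expected = _wc_theta_biallelic(4, 4, p1, p2, h1, h2)
        assert res.fst.loc["a", "b"] == pytest.approx(expected)

    def test_fixed_differences_give_one(self):
        d = make_dataset([[[1, 1], [5, 5]], [[1, 1], [5, 5]],
                          [[2, 2], [6, 6]], [[2, 2], [6, 6]]],
                         pops=["a", "a", "b", "b"])
        assert pairwise_fst(d).fst.loc["a", "b"] == pytest.approx(1.0)

    def test_panmictic_split_near_zero(self):
        rng = np.random.default_rng(5)
        copies = rng.integers(10, 16, size=(60, 12, 2))
        d = GenotypeDataset(copies, np.array(["a"] * 30 + ["b"] * 30, dtype=object),
                            [f"l{i}" for i in range(12)])
        res = pairwise_fst(d, n_bootstrap=200, seed=6)
        width = res.ci_high.loc["a", "b"] - res.ci_low.loc["a", "b"]
        assert abs(res.fst.loc["a", "b"]) < max(3 * width, 0.02)

    def test_small_population_excluded_with_warning(self):
        d = locus_dataset([1, 2, 1, 2, 1, 1, 2, 2, 1, 2],
                          pops=["a", "b", "b", "c", "c"])
        with pytest.warns(UserWarning, match="excluded"):
            res = pairwise_fst(d)
        assert list(res.fst.index) == ["b", "c"]


class TestSummaryVector:
    def test_monomorphic_dataset(self):
        d = make_dataset([[[10, 10], [20, 20]], [[10, 10], [20, 20]]])
        sv = abc_summary_vector(d)
        assert sv.as_array() == pytest.approx([1.0, 0.0, 1.0])

    def test_first_component_is_mean_allele_count(self, bottleneck_dataset):
        sv = abc_summary_vector(bottleneck_dataset)
        ks = [np.unique(bottleneck_dataset.gene_copies(l)).size
              for l in range(bottleneck_dataset.n_loci)]
        assert sv.mean_allelic_richness == pytest.approx(np.mean(ks))

    def test_multi_population_rejected(self):
        d = locus_dataset([1, 2, 1, 2], pops=["a", "b"])
        with pytest.raises(ValueError):
            abc_summary_vector(d)


class TestInvariances:
    @given(offset=st.integers(min_value=-5, max_value=40), seed=st.integers(0, 50))
    def test_translation_and_order_invariance(self, offset, seed):
        rng = np.random.default_rng(seed)
        alleles = rng.integers(10, 18, size=(12, 4, 2))
        d = GenotypeDataset(alleles, np.array(["p"] * 12, dtype=object),
                            [f"l{i}" for i in range(4)])
        base = abc_summary_vector(d).as_array()
        shifted = abc_summary_vector(d.translated(offset)).as_array()
        perm = d.subset(rng.permutation(12))
        permuted = abc_summary_vector(perm).as_array()
        assert np.allclose(base, shifted)
        assert np.allclose(base, permuted)


class TestSubsampling:
    def test_monomorphic_statistic_constant(self):
        d = locus_dataset([5] * 20)
        vals = subsample_statistic(
            d, lambda s: rarefied_allelic_richness(s, g=2)[1],
            n_ind=4, n_rep=20, seed=1)
        assert np.all(vals == 1.0)

    def test_full_size_subset_equals_plain_statistic(self):
        d = locus_dataset([10, 11, 12, 13, 10, 11])
        stat = lambda s: abc_summary_vector(s).mean_allelic_richness
        vals = subsample_statistic(d, stat, n_ind=3, n_rep=1, seed=2)
        assert vals[0] == stat(d)

    def test_oversized_subset_rejected(self):
        d = locus_dataset([1, 2, 1, 2])
        with pytest.raises(ValueError):
            subsample_statistic(d, lambda s: 0.0, n_ind=5, n_rep=1, seed=3)

    def test_mean_subsampled_k_matches_rarefaction(self):
        rng = np.random.default_rng(7)
        copies = rng.integers(30, 40, size=24).tolist()
        d = locus_dataset(copies)
        stat = lambda s: float(np.unique(s.gene_copies(0)).size)
        vals = subsample_statistic(d, stat, n_ind=4, n_rep=4000, seed=8)
        # exact expectation over individual subsets by enumeration
        pairs = [copies[2 * i:2 * i + 2] for i in range(12)]
        exact = np.mean([len(set(sum((pairs[i] for i in c), [])))
                         for c in itertools.combinations(range(12), 4)])
        se = vals.std(ddof=1) / np.sqrt(vals.size)
        assert abs(vals.mean() - exact) < 4 * se
        # rarefaction over gene copies approximates the individual-level
        # expectation; the two differ slightly because subsampling whole
        # individuals keeps gene copies paired
        expected = rarefied_allelic_richness(d, g=8)[1]
        assert expected == pytest.approx(exact, abs=0.25)
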