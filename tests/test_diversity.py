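import itertools
import math

import numpy as np
import pytest

from conftest import make_dataset
from introsel.diversity import (count_haplotypes, dxy, fst_hudson, fst_wc,
                                haplotype_diversity, nucleotide_diversity,
                                permutation_test, whole_locus_fst)


def haploid_pair_oracle(gt, idxA, idxB=None):
    """All-pairs allele-comparison mismatch rate, per site, by enumeration."""
    mism = comp = 0
    for i in range(gt.shape[0]):
        allelesA = [al for j in idxA for al in ([0] * (2 - gt[i, j]) + [1] * gt[i, j])]
        if idxB is None:
            pairs = list(itertools.combinations(allelesA, 2))
        else:
            allelesB = [al for j in idxB
                        for al in ([0] * (2 - gt[i, j]) + [1] * gt[i, j])]
            pairs = list(itertools.product(allelesA, allelesB))
        mism += sum(a != b for a, b in pairs)
        comp += len(pairs)
    return mism, comp


class TestPi:
    def test_two_haploid_sequences_hand_case(self):
        # one diploid = two haploid sequences; heterozygous at 3 of 100 sites
        gt = np.zeros((100, 2), np.int8)
        gt[[4, 40, 77], 0] = 1
        gt[:, 1] = 1  # second sample only satisfies the per-site call invariant
        ds = make_dataset(gt, {"X": [0], "Y": [1]})
        stats = nucleotide_diversity(ds, "X", [("1", 0, 100)],
                                     denominator="sites")
        assert stats[0].value == pytest.approx(0.03)

    def test_monomorphic_window_zero(self):
        ds = make_dataset(np.full((10, 3), 2, np.int8), {"X": [0, 1, 2]})
        stats = nucleotide_diversity(ds, "X", [("1", 0, 10)])
        assert stats[0].value == 0.0

    def test_invariant_under_sample_reordering(self):
        rng = np.random.default_rng(1)
        gt = rng.integers(0, 3, (30, 4)).astype(np.int8)
        a = nucleotide_diversity(make_dataset(gt, {"X": [0, 1, 2, 3]}),
                                 "X", [("1", 0, 30)])[0].value
        b = nucleotide_diversity(make_dataset(gt[:, ::-1], {"X": [0, 1, 2, 3]}),
                                 "X", [("1", 0, 30)])[0].value
        assert a == pytest.approx(b)

    def test_unknown_population_fatal(self):
        ds = make_dataset(np.ones((2, 2), np.int8), {"X": [0, 1]})
        with pytest.raises(ValueError):
            nucleotide_diversity(ds, "NOPE", [("1", 0, 2)])


class TestDxy:
    def test_fixed_difference_one_of_ten_sites(self):
        gt = np.zeros((10, 4), np.int8)
        gt[0, 2:] = 2  # popB fixed alt at first site
        ds = make_dataset(gt, {"A": [0, 1], "B": [2, 3]})
        stats = dxy(ds, "A", "B", [("1", 0, 10)], denominator="sites")
        assert stats[0].value == pytest.approx(0.1)

    def test_identical_populations_equal_within_mismatch(self):
        gt = np.array([[0, 1, 0, 1], [2, 0, 2, 0], [1, 1, 1, 1],
                       [0, 2, 0, 2], [2, 2, 2, 2]], np.int8)
        ds = make_dataset(gt, {"A": [0, 1], "B": [2, 3]})
        val = dxy(ds, "A", "B", [("1", 0, 5)], denominator="sites")[0].value
        mism, comp = haploid_pair_oracle(gt, [0, 1], [2, 3])
        assert val == pytest.approx(mism / comp)

    def test_random_masking_unbiased(self):
        rng = np.random.default_rng(7)
        gt = rng.integers(0, 3, (400, 12)).astype(np.int8)
        pops = {"A": list(range(6)), "B": list(range(6, 12))}
        base = dxy(make_dataset(gt, pops), "A", "B", [("1", 0, 400)],
                   denominator="sites")[0].value
        shifts = []
        for _ in range(50):
            m = gt.copy()
            mask = rng.random(m.shape) < 0.2
            m[mask] = -1
            keep = (m != -1).any(axis=1)  # validation requires a call per site
            masked = dxy(make_dataset(m[keep], pops), "A", "B",
                         [("1", 0, 400)], denominator="sites")[0].value
            shifts.append(masked - base)
        se = np.std(shifts) / math.sqrt(len(shifts))
        assert abs(np.mean(shifts)) < 2 * se + 1e-4


@pytest.mark.parametrize("n_samp,n_sites", [(2, 5), (3, 12), (5, 20)])
def test_brute_force_equivalence_pi_dxy(n_samp, n_sites):
    """Frequency-based pi/d_xy equal explicit all-pairs allele comparison."""
    rng = np.random.default_rng(n_samp * 100 + n_sites)
    gt = rng.integers(0, 3, (n_sites, 2 * n_samp)).astype(np.int8)
    pops = {"A": list(range(n_samp)), "B": list(range(n_samp, 2 * n_samp))}
    ds = make_dataset(gt, pops)
    win = [("1", 0, n_sites)]
    pi = nucleotide_diversity(ds, "A", win, denominator="sites")[0]
    mism, comp = haploid_pair_oracle(gt, pops["A"])
    assert pi.value * pi.n_snps == pytest.approx(
        sum(haploid_pair_oracle(gt[[i]], pops["A"])[0]
            / haploid_pair_oracle(gt[[i]], pops["A"])[1]
            for i in range(n_sites)))
    d = dxy(ds, "A", "B", win, denominator="sites")[0].value
    mism, comp = haploid_pair_oracle(gt, pops["A"], pops["B"])
    assert d == pytest.approx(mism / comp)


class TestFst:
    def test_fixed_difference_approaches_one(self):
        gt = np.zeros((50, 40), np.int8)
        gt[:, 20:] = 2
        ds = make_dataset(gt, {"A": list(range(20)), "B": list(range(20, 40))})
        for fun in (fst_hudson, fst_wc):
            v = fun(ds, "A", "B", [("1", 0, 50)])[0].value
            assert v == pytest.approx(1.0, abs=0.03)

    def test_equal_frequencies_centred_on_zero(self):
        rng = np.random.default_rng(11)
        p = rng.uniform(0.1, 0.9, 1000)
        gt = rng.binomial(2, p[:, None], (1000, 30)).astype(np.int8)
        ds = make_dataset(gt, {"A": list(range(15)), "B": list(range(15, 30))})
        v = fst_hudson(ds, "A", "B", [("1", 0, 1000)])[0].value
        assert abs(v) < 0.05

    def test_swap_symmetry(self):
        rng = np.random.default_rng(2)
        gt = rng.integers(0, 3, (200, 10)).astype(np.int8)
        ds = make_dataset(gt, {"A": list(range(5)), "B": list(range(5, 10))})
        for fun in (fst_hudson, fst_wc):
            ab = fun(ds, "A", "B", [("1", 0, 200)])[0].value
            ba = fun(ds, "B", "A", [("1", 0, 200)])[0].value
            assert ab == pytest.approx(ba)

    def test_wc_close_to_hudson_on_balanced_data(self, pulse_dataset):
        _, ds, _ = pulse_dataset
        win = [("1", 0, int(ds.sequence_length["1"]))]
        h = fst_hudson(ds, "W1", "W2", win)[0].value
        w = fst_wc(ds, "W1", "W2", win)[0].value
        assert abs(h - w) < 0.02

    def test_pseudo_split_centred_on_zero(self, neutral_dataset):
        _, ds = neutral_dataset
        idx = ds.populations["W1"]
        from introsel.io import GenotypeDataset
        pops = {k: v for k, v in ds.populations.items() if k != "W1"}
        pops.update({"H1": idx[:2], "H2": idx[2:]})
        ds2 = GenotypeDataset(ds.samples, ds.chrom, ds.pos, ds.ref, ds.alt,
                              ds.gt, pops, ds.sequence_length)
        win = [("1", 0, int(ds.sequence_length["1"]))]
        assert abs(fst_wc(ds2, "H1", "H2", win)[0].value) < 0.05


class TestHaplotypeDiversity:
    def test_all_identical_zero(self):
        assert haplotype_diversity([9])[0] == 0.0

    def test_all_distinct_exactly_one(self):
        h, _ = haplotype_diversity([1] * 6)
        assert h == pytest.approx(1.0, abs=1e-12)

    def test_published_mouflon_values(self):
        assert round(haplotype_diversity([5, 2])[0], 5) == 0.47619
        assert round(haplotype_diversity([6, 1])[0], 5) == 0.28571

    def test_too_few_sequences_fatal(self):
        with pytest.raises(ValueError):
            haplotype_diversity([1])

    def test_count_haplotypes_round_trip(self):
        from introsel.simulate import make_haplotype_fixture
        seqs = make_haplotype_fixture([5, 2], 30, seed=3)
        assert count_haplotypes(seqs) == [5, 2]


class TestPermutationTest:
    def test_minimum_attainable_p_separated_pops(self):
        gt = np.zeros((30, 24), np.int8)
        gt[:, 12:] = 2
        ds = make_dataset(gt, {"A": list(range(12)), "B": list(range(12, 24))})
        obs, p, flag = permutation_test(ds, "fst_wc", "A", "B",
                                        n_perm=999, seed=0)
        assert p == pytest.approx(1 / 1000)
        assert obs > 0.9 and flag == ""

    def test_p_never_zero(self):
        rng = np.random.default_rng(0)
        gt = rng.integers(0, 3, (20, 8)).astype(np.int8)
        ds = make_dataset(gt, {"A": list(range(4)), "B": list(range(4, 8))})
        _, p, _ = permutation_test(ds, "fst_hudson", "A", "B", n_perm=50, seed=1)
        assert p > 0

    def test_type_one_error_calibrated(self):
        """Identically-drawn populations reject at ~alpha."""
        rng = np.random.default_rng(42)
        rejections = 0
        n_rep = 200
        for i in range(n_rep):
            p = rng.uniform(0.2, 0.8, 40)
            gt = rng.binomial(2, p[:, None], (40, 10)).astype(np.int8)
            keep = (gt != -1).any(axis=1)
            ds = make_dataset(gt[keep], {"A": list(range(5)),
                                         "B": list(range(5, 10))})
            _, pval, _ = permutation_test(ds, "fst_hudson", "A", "B",
                                          n_perm=99, seed=i)
            rejections += pval < 0.05
        assert 0.02 <= rejections / n_rep <= 0.08


def test_hudson_fst_monotone_in_split_time():
    """Window F_ST ranks with divergence time on two-population simulations."""
    import msprime
    from scipy.stats import spearmanr

    split_times = [200, 600, 1800, 5400, 16000]
    pairs = []
    seed = 1
    for t in split_times:
        for _ in range(8):
            dem = msprime.Demography()
            dem.add_population(name="A", initial_size=5000)
            dem.add_population(name="B", initial_size=5000)
            dem.add_population(name="ANC", initial_size=5000)
            dem.add_population_split(time=t, derived=["A", "B"], ancestral="ANC")
            ts = msprime.sim_ancestry({"A": 5, "B": 5}, demography=dem,
                                      sequence_length=3e5,
                                      recombination_rate=1e-8, random_seed=seed)
            ts = msprime.sim_mutations(ts, rate=1e-8, random_seed=seed)
            seed += 1
            gt = np.array([[g[2 * i] + g[2 * i + 1] for i in range(10)]
                           for g in (v.genotypes for v in ts.variants()
                                     if len(v.alleles) == 2)], np.int8)
            pos0 = [int(v.site.position) for v in ts.variants()
                    if len(v.alleles) == 2]
            uniq = np.concatenate([[True], np.diff(pos0) > 0])
            ds = make_dataset(gt[uniq], {"A": list(range(5)),
                                         "B": list(range(5, 10))},
                              pos=np.array(pos0)[uniq])
            v = fst_hudson(ds, "A", "B", [("1", 0, 300_000)])[0].value
            pairs.append((t, v))
    rho = spearmanr([a for a, _ in pairs], [b for _, b in pairs]).statistic
    assert rho > 0.9


def test_whole_locus_fst_finite(pulse_dataset):
    _, ds, _ = pulse_dataset
    v = whole_locus_fst(ds, "W1", "W2", estimator="hudson")
    assert np.isfinite(v) and -0.1 < v < 1
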