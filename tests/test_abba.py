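import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_freqs
from introsel.abba import (TrioSpec, call_introgressed_windows, d_statistic,
                           f4_ratio, fdm_windows, jackknife)
from introsel.io import polarize, split_donor
from introsel.simulate import truth_regions
from introsel.windows import WindowStat

TRIO = TrioSpec("P1", "P2", "P3", "O")


class TestDStatistic:
    def test_single_abba_site(self):
        assert d_statistic(make_freqs([(0, 1, 1, 0)]), TRIO) == 1.0

    def test_symmetric_abba_baba_cancel(self):
        ft = make_freqs([(0, 0.5, 0.5, 0), (0.5, 0, 0.5, 0)])
        assert d_statistic(ft, TRIO) == pytest.approx(0.0)

    def test_numerator_vanishes_when_p1_equals_p2(self):
        rng = np.random.default_rng(0)
        rows = rng.uniform(0, 1, (30, 3))
        ft = make_freqs(np.column_stack([rows[:, 0], rows[:, 0],
                                         rows[:, 1], rows[:, 2]]))
        assert d_statistic(ft, TRIO) == pytest.approx(0.0)

    def test_swapping_p1_p2_flips_sign(self):
        rng = np.random.default_rng(1)
        ft = make_freqs(rng.uniform(0, 1, (50, 4)))
        d12 = d_statistic(ft, TRIO)
        d21 = d_statistic(ft, TrioSpec("P2", "P1", "P3", "O"))
        assert d12 == pytest.approx(-d21)

    def test_distinct_populations_required(self):
        with pytest.raises(ValueError):
            TrioSpec("P1", "P1", "P3", "O")


def pattern_count_oracle(rows):
    """(nABBA - nBABA) / (nABBA + nBABA) on 0/1-coded polarized sites."""
    abba = sum(1 for r in rows if tuple(r) == (0, 1, 1, 0))
    baba = sum(1 for r in rows if tuple(r) == (1, 0, 1, 0))
    if abba + baba == 0:
        return None
    return (abba - baba) / (abba + baba)


def test_exact_equivalence_with_pattern_counting_oracle():
    """On fixed-difference polarized data (outgroup ancestral by definition)
    the frequency form of D equals ABBA/BABA counting, for every pair of
    4-taxon patterns and random stacks of up to 8 sites."""
    patterns = [p + (0,) for p in itertools.product([0, 1], repeat=3)]
    for a, b in itertools.product(patterns, repeat=2):
        expected = pattern_count_oracle([a, b])
        if expected is None:
            continue
        d = d_statistic(make_freqs([a, b]), TRIO)
        assert d == pytest.approx(expected)
    rng = np.random.default_rng(5)
    for _ in range(200):
        rows = [patterns[i] for i in rng.integers(0, len(patterns),
                                                  rng.integers(1, 9))]
        expected = pattern_count_oracle(rows)
        if expected is None:
            continue
        assert d_statistic(make_freqs(rows), TRIO) == pytest.approx(expected)


class TestJackknife:
    def test_identical_blocks_zero_se_flagged(self):
        ft = make_freqs([(0, 1, 1, 0)] * 40)
        res = jackknife(ft, TRIO, n_blocks=4)
        assert res.flag == "zero_variance" and res.se == 0.0

    def test_pulse_dataset_significant(self, pulse_dataset):
        _, ds, _ = pulse_dataset
        freqs = polarize(ds, "OUT")
        res = jackknife(freqs, TrioSpec("MEN", "C1", "W2", "OUT"))
        assert res.d > 0 and res.z == pytest.approx(res.d / res.se)
        assert res.p < 0.05
        assert -1 <= res.d <= 1 and res.n_blocks == 20

    def test_control_candidate_not_significant(self, pulse_dataset):
        _, ds, _ = pulse_dataset
        freqs = polarize(ds, "OUT")
        res = jackknife(freqs, TrioSpec("MEN", "C2", "W2", "OUT"))
        assert abs(res.z) < 3

    def test_needs_two_blocks(self):
        with pytest.raises(ValueError):
            jackknife(make_freqs([(0, 1, 1, 0)]), TRIO, n_blocks=1)


class TestF4Ratio:
    def _with_split(self, rows):
        ft = make_freqs([r[:4] for r in rows])
        a = np.array(rows, float)
        ft.split_freq = {"P3a": a[:, 4], "P3b": a[:, 5]}
        return ft

    def test_p2_equals_p3b_gives_one(self):
        rng = np.random.default_rng(2)
        rows = []
        for _ in range(20):
            p1, p2, p3, po, p3a = rng.uniform(0, 1, 5)
            rows.append((p1, p2, p3, po, p3a, p2))
        assert f4_ratio(self._with_split(rows), TRIO) == pytest.approx(1.0)

    def test_p2_equals_p1_gives_zero(self):
        rng = np.random.default_rng(3)
        rows = []
        for _ in range(20):
            p1, p3, po, p3a, p3b = rng.uniform(0, 1, 5)
            rows.append((p1, p1, p3, po, p3a, p3b))
        assert f4_ratio(self._with_split(rows), TRIO) == pytest.approx(0.0)

    def test_printed_form_equals_quartet_form(self, pulse_dataset):
        """The printed ratio is the standard quartet f4-ratio in disguise."""
        _, ds, _ = pulse_dataset
        ia, ib = split_donor(ds, "W2", seed=4)
        freqs = polarize(ds, "OUT", extra_groups={"P3a": ia, "P3b": ib})
        trio = TrioSpec("MEN", "C1", "W2", "OUT")
        printed = f4_ratio(freqs, trio, form="printed")
        alt = f4_ratio(freqs, trio, form="f4")
        assert printed == pytest.approx(alt)
        assert printed > 0.1  # sees the f=0.3 pulse


class TestFdm:
    def test_single_site_abba_is_one(self):
        stats = fdm_windows(make_freqs([(0, 1, 1, 0)]), TRIO, 1, 1)
        assert stats[0].value == 1.0

    def test_single_site_p1_p3_sharing_is_minus_one(self):
        stats = fdm_windows(make_freqs([(1, 0, 1, 0)]), TRIO, 1, 1)
        assert stats[0].value == -1.0

    def test_p3_zero_gives_zero(self):
        rng = np.random.default_rng(4)
        rows = np.column_stack([rng.uniform(0, 1, 50), rng.uniform(0, 1, 50),
                                np.zeros(50), np.zeros(50)])
        stats = fdm_windows(make_freqs(rows), TRIO, 50, 25)
        assert stats[0].value == pytest.approx(0.0)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_bounded(self, seed):
        rng = np.random.default_rng(seed)
        rows = rng.uniform(0, 1, (50, 4))
        for s in fdm_windows(make_freqs(rows), TRIO, 25, 25):
            if s.flag == "":
                assert -1 - 1e-9 <= s.value <= 1 + 1e-9

    def test_ref_alt_orientation_invariance(self, pulse_dataset):
        from conftest import make_dataset
        _, ds, _ = pulse_dataset
        sub = ds.take_sites(np.arange(2000))
        flipped = make_dataset(2 - sub.gt,
                               {k: list(v) for k, v in sub.populations.items()},
                               pos=sub.pos)
        trio = TrioSpec("MEN", "C1", "W2", "OUT")
        f1 = fdm_windows(polarize(sub, "OUT"), trio)
        f2 = fdm_windows(polarize(flipped, "OUT"), trio)
        np.testing.assert_allclose([s.value for s in f1], [s.value for s in f2])


class TestCallWindows:
    def _stats(self, values):
        return [WindowStat("1", i * 100, i * 100 + 100, 50, "fdm", v)
                for i, v in enumerate(values)]

    def test_negative_genome_wide_d_calls_nothing(self):
        vals = list(np.linspace(0, 1, 50))
        for mode in ("ztest", "quantile"):
            assert len(call_introgressed_windows(self._stats(vals), -0.1,
                                                 mode=mode)) == 0

    def test_equal_windows_ztest_calls_nothing(self):
        assert len(call_introgressed_windows(self._stats([0.3] * 30), 0.2,
                                             mode="ztest")) == 0

    def test_quantile_needs_twenty_windows(self):
        with pytest.raises(ValueError, match="20"):
            call_introgressed_windows(self._stats([0.1] * 10), 0.2,
                                      mode="quantile")

    def test_quantile_calls_top_fraction(self):
        vals = list(np.linspace(0, 1, 100))
        rs = call_introgressed_windows(self._stats(vals), 0.2, mode="quantile",
                                       quantile=0.05)
        # top 5 windows, contiguous by construction -> merged into one region
        assert rs.total_length == 5 * 100

    def test_flagged_windows_excluded(self):
        stats = self._stats([0.1] * 30)
        stats.append(WindowStat("1", 9999, 10000, 0, "fdm", np.nan,
                                flag="undefined"))
        rs = call_introgressed_windows(stats, 0.5, mode="ztest")
        assert all(s != 9999 for _, s, _ in rs)


def test_fdm_recovers_truth_tracts(pulse_dataset):
    """Called introgressed regions overlap the known donor-ancestry tracts."""
    params, ds, tracts = pulse_dataset
    trio = TrioSpec("MEN", "C1", "W2", "OUT")
    freqs = polarize(ds, "OUT")
    stats = fdm_windows(freqs, trio)
    called = call_introgressed_windows(stats, d_statistic(freqs, trio))
    truth = truth_regions(tracts, "C1")
    assert len(called) > 0
    assert any(truth.overlaps(c, s, e) for c, s, e in called)


def test_fdm_phase_invariance(pulse_dataset):
    """A called tract is recovered regardless of a half-window offset."""
    params, ds, tracts = pulse_dataset
    trio = TrioSpec("MEN", "C1", "W2", "OUT")
    freqs = polarize(ds, "OUT")
    truth = truth_regions(tracts, "C1")
    d = d_statistic(freqs, trio)
    hits = []
    for offset in (0, 25):
        mask = np.ones(freqs.n_sites, dtype=bool)
        mask[:offset] = False
        shifted = make_freqs(
            np.column_stack([freqs.freq[p][mask]
                             for p in ("MEN", "C1", "W2", "OUT")]),
            pops=["MEN", "C1", "W2", "OUT"], pos=freqs.pos[mask])
        stats = fdm_windows(shifted, trio)
        called = call_introgressed_windows(stats, d)
        hits.append(any(truth.overlaps(c, s, e) for c, s, e in called))
    assert all(hits)
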