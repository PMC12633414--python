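import numpy as np
import pytest
from hypothesis import given, strategies as st

from aqerscan import divergence_screen as ds
from aqerscan.genome_io import GenomicInterval, ProbRow

from conftest import bh_adjust_oracle


def _prob_row(bases: str, rng=None) -> ProbRow:
    """Point-mass probabilistic row from a string of bases and '-' gaps."""
    n = len(bases)
    probs = np.zeros((n, 4))
    present = np.zeros(n, dtype=bool)
    for i, ch in enumerate(bases):
        if ch != "-":
            present[i] = True
            probs[i, "ACGT".index(ch)] = 1.0
    return ProbRow(probs=probs, present=present)


class TestCosineDistance:
    def test_identical_distributions(self):
        d = ds.cosine_distance(np.array([1.0, 0, 0, 0]), np.array([1.0, 0, 0, 0]))
        assert d == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_distributions(self):
        d = ds.cosine_distance(np.array([1.0, 0, 0, 0]), np.array([0, 1.0, 0, 0]))
        assert d == pytest.approx(1.0)

    def test_partial_overlap_below_threshold(self):
        d = ds.cosine_distance(np.array([0.5, 0.5, 0, 0]), np.array([1.0, 0, 0, 0]))
        assert d == pytest.approx(1 - 1 / np.sqrt(2), abs=1e-12)
        assert d < 0.8

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            ds.cosine_distance(np.array([0.0, 0, 0, 0]), np.array([1.0, 0, 0, 0]))


class TestSiteEvents:
    def test_substitution_labels(self):
        a = _prob_row("ACGT")
        b = _prob_row("ACCT")
        ev = ds.call_site_events(a, b)
        assert ev.substitution.tolist() == [False, False, True, False]

    def test_gap_run_counts_once_regardless_of_length(self):
        a = _prob_row("A" * 50)
        b = _prob_row("AAAAA" + "-" * 40 + "AAAAA")
        ev = ds.call_site_events(a, b)
        assert ev.gap_anchor.sum() == 1
        assert ev.gap_anchor[5]
        assert ev.substitution.sum() == 0

    def test_both_absent_columns_are_silent(self):
        a = _prob_row("A--A")
        b = _prob_row("A--A")
        ev = ds.call_site_events(a, b)
        assert ev.gap_anchor.sum() == 0
        assert ev.both_present.tolist() == [True, False, False, True]

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(0)
        n = 500
        probs_a = rng.dirichlet(np.ones(4) * 0.3, size=n)
        probs_b = rng.dirichlet(np.ones(4) * 0.3, size=n)
        a = ProbRow(probs=probs_a, present=np.ones(n, dtype=bool))
        b = ProbRow(probs=probs_b, present=np.ones(n, dtype=bool))
        counts = []
        for tau in [0.5, 0.7, 0.8, 0.95]:
            ev = ds.call_site_events(a, b, ds.ScreenConfig(cosine_threshold=tau))
            counts.append(ev.substitution.sum())
            # definition check: substitution iff distance >= tau
            np.testing.assert_array_equal(ev.substitution, ev.distance >= tau)
        assert all(y <= x for x, y in zip(counts, counts[1:]))


class TestWindowedCounts:
    def test_no_events_gives_zero_windows(self):
        a = _prob_row("A" * 100)
        ev = ds.call_site_events(a, a)
        t = ds.windowed_event_counts(ev, np.arange(100), 100,
                                     window_length=25, window_step=25)
        assert np.all(t.k == 0)
        assert np.all(t.callable_bases == 25)

    def test_planted_events_match_brute_force_scan(self):
        rng = np.random.default_rng(4)
        n = 2000
        ref = "".join(rng.choice(list("ACGT"), size=n))
        other = list(ref)
        # 20 substitutions inside [700, 1200)
        sub_pos = rng.choice(np.arange(700, 1200), size=20, replace=False)
        for p in sub_pos:
            other[p] = "ACGT"[("ACGT".index(other[p]) + 1) % 4]
        # 9 separated gap runs anchored inside the window
        gap_starts = np.arange(720, 1170, 50)
        for gs in gap_starts:
            length = int(rng.integers(1, 4))
            for q in range(gs, gs + length):
                if q not in sub_pos:
                    other[q] = "-"
        a = _prob_row(ref)
        b = _prob_row("".join(other))
        ev = ds.call_site_events(a, b)
        t = ds.windowed_event_counts(ev, np.arange(n), n,
                                     window_length=500, window_step=1)
        # brute-force column scan for window [700, 1200)
        k_brute = 0
        in_gap = False
        for col in range(700, 1200):
            ca, cb = ref[col], "".join(other)[col]
            if ca != "-" and cb != "-":
                in_gap = False
                if ca != cb:
                    k_brute += 1
            elif (ca == "-") != (cb == "-"):
                if not in_gap:
                    k_brute += 1
                in_gap = True
        w = np.flatnonzero(t.start == 700)[0]
        assert t.k[w] == k_brute

    def test_window_longer_than_chromosome_truncated_and_flagged(self):
        a = _prob_row("A" * 20)
        ev = ds.call_site_events(a, a)
        t = ds.windowed_event_counts(ev, np.arange(20), 20,
                                     window_length=25, window_step=1)
        assert len(t) == 1
        assert t.truncated.tolist() == [True]
        assert t.callable_bases[0] == 20  # clipped at the chromosome end

    def test_last_full_window_not_flagged(self):
        a = _prob_row("A" * 30)
        ev = ds.call_site_events(a, a)
        t = ds.windowed_event_counts(ev, np.arange(30), 30,
                                     window_length=25, window_step=5)
        assert t.start.tolist() == [0, 5]
        assert not t.truncated.any()


class TestCalibration:
    def _table(self, ks, callables, L=1000):
        n = len(ks)
        return ds.WindowTable(chrom="ref", start=np.arange(n) * L, length=L,
                              k_s=np.array(ks), k_g=np.zeros(n, dtype=int),
                              callable_bases=np.array(callables))

    def test_maximum_rate_selected(self):
        t = self._table([1, 2, 3], [1000, 1000, 2000])
        assert ds.calibrate_expected_rate(t) == pytest.approx(0.002)

    def test_single_window(self):
        t = self._table([5], [1000])
        assert ds.calibrate_expected_rate(t) == pytest.approx(0.005)

    def test_low_callable_windows_excluded(self):
        t = self._table([100, 1], [200, 1000])  # first window 20% callable
        assert ds.calibrate_expected_rate(t) == pytest.approx(0.001)

    def test_no_qualifying_window_errors(self):
        t = self._table([1], [100])
        with pytest.raises(ValueError):
            ds.calibrate_expected_rate(t)

    def test_neutral_simulation_rate_bound(self):
        # max of 3 binomial window rates at per-base rate 0.005 over 30 Mb:
        # the calibrated rate is the max window rate, within a few binomial
        # standard deviations (sd of a window rate = sqrt(p(1-p)/W))
        rng = np.random.default_rng(1)
        W = 10_000_000
        ks = rng.binomial(W, 0.005, size=3)
        t = self._table(ks.tolist(), [W] * 3, L=W)
        p_hat = ds.calibrate_expected_rate(t)
        assert p_hat == pytest.approx(max(ks) / W)
        sd = np.sqrt(0.005 * 0.995 / W)
        assert 0.005 - 3 * sd <= p_hat <= 0.0065


class TestLineageScaling:
    def test_equal_branches_unchanged(self):
        from aqerscan.trees import great_ape_tree
        tree = great_ape_tree()
        assert ds.scale_rate_for_lineage(0.01, tree, "HUMANanc", "HUMANanc") \
            == pytest.approx(0.01)

    def test_gorilla_over_human_ratio(self):
        from aqerscan.trees import great_ape_tree
        tree = great_ape_tree()
        scaled = ds.scale_rate_for_lineage(0.01, tree, "gorillaT2Tanc",
                                           "HUMANanc")
        assert scaled / 0.01 == pytest.approx(0.00856474 / 0.00606109)
        assert scaled / 0.01 == pytest.approx(1.413, abs=5e-3)

    def test_linearity(self):
        from aqerscan.trees import great_ape_tree
        tree = great_ape_tree()
        s1 = ds.scale_rate_for_lineage(0.01, tree, "cbaT2T", "HUMANanc")
        s2 = ds.scale_rate_for_lineage(0.02, tree, "cbaT2T", "HUMANanc")
        assert s2 == pytest.approx(2 * s1)


class TestSignificance:
    def _table(self, ks, L=500):
        n = len(ks)
        return ds.WindowTable(chrom="ref", start=np.arange(n) * L, length=L,
                              k_s=np.array(ks), k_g=np.zeros(n, dtype=int),
                              callable_bases=np.full(n, L))

    def test_zero_events_gives_p_one(self):
        t = ds.window_significance(self._table([0]), 0.005)
        assert t.raw_p[0] == pytest.approx(1.0)

    def test_small_case_enumeration(self):
        # L=3, p=0.5: P(X >= 2) = 4/8
        t = ds.window_significance(self._table([2], L=3), 0.5)
        assert t.raw_p[0] == pytest.approx(0.5, abs=1e-12)

    def test_bh_stepup_example(self):
        t = self._table([10, 20, 30, 40])
        t.raw_p = np.array([0.01, 0.02, 0.03, 0.04])
        t.adj_p = None
        from statsmodels.stats.multitest import multipletests
        adj = multipletests(t.raw_p, method="fdr_bh")[1]
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04])

    @given(st.lists(st.floats(1e-12, 1.0), min_size=1, max_size=60))
    def test_bh_matches_sort_based_oracle(self, pvals):
        from statsmodels.stats.multitest import multipletests
        adj = multipletests(np.array(pvals), method="fdr_bh")[1]
        np.testing.assert_allclose(adj, bh_adjust_oracle(pvals), atol=1e-12)

    def test_exact_tail_matches_summation_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            L = int(rng.integers(25, 2000))
            p = float(rng.uniform(1e-4, 0.05))
            k = int(rng.integers(0, min(L, 40)))
            t = ds.window_significance(self._table([k], L=L), p)
            # independent complementary-CDF via stable pmf recursion
            pmf0 = (1 - p) ** L
            cdf, pmf = pmf0, pmf0
            for j in range(1, k):
                pmf *= (L - j + 1) / j * p / (1 - p)
                cdf += pmf
            oracle = 1.0 - cdf if k > 0 else 1.0
            assert abs(t.raw_p[0] - oracle) < 1e-12


class TestCalls:
    def _sig_table(self, starts, ks, adj_ps, L=500, ref_length=10_000):
        n = len(starts)
        t = ds.WindowTable(chrom="ref", start=np.array(starts), length=L,
                           k_s=np.array(ks), k_g=np.zeros(n, dtype=int),
                           callable_bases=np.full(n, L), ref_length=ref_length)
        t.raw_p = np.array(adj_ps)
        t.adj_p = np.array(adj_ps)
        return t

    def test_no_significant_windows_empty(self):
        t = self._sig_table([0], [5], [0.5])
        assert ds.call_aqers(t) == []

    def test_overlapping_windows_merge(self):
        t = self._sig_table([100, 400], [30, 35], [1e-9, 1e-10])
        calls = ds.call_aqers(t)
        assert len(calls) == 1
        c = calls[0]
        assert (c.interval.start, c.interval.end) == (100, 900)
        assert c.peak_k == 35
        assert c.min_adj_p == pytest.approx(1e-10)

    def test_bookended_windows_merge(self):
        t = self._sig_table([0, 500], [29, 29], [1e-9, 1e-9])
        assert len(ds.call_aqers(t)) == 1

    def test_distant_windows_stay_separate(self):
        t = self._sig_table([0, 2000], [29, 29], [1e-9, 1e-9])
        assert len(ds.call_aqers(t)) == 2


class TestFilterCalls:
    def _calls(self, peaks):
        return [ds.AqerCall(GenomicInterval("ref", 1000 * i, 1000 * i + 500),
                            pk, 1e-9) for i, pk in enumerate(peaks)]

    def test_cutoff_at_minimum_keeps_all(self):
        calls = self._calls([29, 34, 40])
        assert len(ds.filter_calls(calls, min_k=29)) == 3

    def test_cutoff_39_keeps_one(self):
        calls = self._calls([29, 34, 40])
        assert len(ds.filter_calls(calls, min_k=39)) == 1

    def test_exclusion_covering_genome_empties(self):
        calls = self._calls([29, 34])
        excl = [GenomicInterval("ref", 0, 10_000_000)]
        assert ds.filter_calls(calls, exclude=excl) == []

    def test_partial_exclusion(self):
        calls = self._calls([29, 34])
        excl = [GenomicInterval("ref", 0, 600)]
        assert len(ds.filter_calls(calls, exclude=excl)) == 1


class TestConfidenceFilteredWindows:
    def test_low_confidence_columns_not_counted(self):
        n = 100
        probs_a = np.zeros((n, 4))
        probs_a[:, 0] = 1.0
        probs_b = probs_a.copy()
        # a substitution at column 10, but with a low-confidence ancestor
        probs_b[10] = [0.0, 0.7, 0.3, 0.0]
        # a confident substitution at column 20
        probs_b[20] = [0.0, 1.0, 0.0, 0.0]
        a = ProbRow(probs=probs_a, present=np.ones(n, dtype=bool))
        b = ProbRow(probs=probs_b, present=np.ones(n, dtype=bool))
        t = ds.confident_divergence_windows(a, b, np.arange(n), n,
                                            window_length=50, window_step=50,
                                            min_confident_fraction=0.9)
        assert len(t) == 2
        assert t.k_s[0] == 1  # only the confident substitution counts

    def test_windows_below_confident_fraction_dropped(self):
        n = 100
        probs = np.tile([0.7, 0.3, 0.0, 0.0], (n, 1))  # all low-confidence
        a = ProbRow(probs=probs, present=np.ones(n, dtype=bool))
        t = ds.confident_divergence_windows(a, a, np.arange(n), n,
                                            window_length=50, window_step=50)
        assert len(t) == 0
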