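import numpy as np
import pytest
from scipy import stats

from aqerscan import selection_signatures as ss
from aqerscan.genome_io import GenomicInterval, ProbRow, VariantRecord


def _prob_row(bases: str) -> ProbRow:
    n = len(bases)
    probs = np.zeros((n, 4))
    present = np.zeros(n, dtype=bool)
    for i, ch in enumerate(bases):
        if ch != "-":
            present[i] = True
            probs[i, "ACGT".index(ch)] = 1.0
    return ProbRow(probs=probs, present=present)


def _variant(pos, chrom="ref", daf=None, aa="A", n=10, alt_count=3):
    g = np.zeros(n, dtype=np.int8)
    g[:alt_count] = 1
    return VariantRecord(chrom, pos, "A", "G", g, aa=aa, daf=daf)


class TestDivergentSites:
    def test_identical_tracks_give_no_sites(self):
        a = _prob_row("ACGTACGT")
        assert ss.extract_divergent_sites(a, a, np.arange(8)) == []

    def test_gap_events_excluded(self):
        a = _prob_row("ACGTACGTAA")
        b = _prob_row("ACCTA--TAC")  # subs at 2 and 9, one gap run
        sites = ss.extract_divergent_sites(a, b, np.arange(10))
        assert [s.start for s in sites] == [2, 9]

    def test_positions_match_column_scan_on_random_fixtures(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            n = 300
            sa = "".join(rng.choice(list("ACGT-"), size=n, p=[.23, .23, .23, .23, .08]))
            sb = "".join(rng.choice(list("ACGT-"), size=n, p=[.23, .23, .23, .23, .08]))
            a, b = _prob_row(sa), _prob_row(sb)
            got = [s.start for s in ss.extract_divergent_sites(a, b, np.arange(n))]
            expected = [i for i in range(n)
                        if sa[i] != "-" and sb[i] != "-" and sa[i] != sb[i]]
            assert got == expected


class TestFixedPolymorphic:
    def test_partition_is_exhaustive(self):
        sites = [GenomicInterval("ref", p, p + 1) for p in [5, 10, 15]]
        variants = [_variant(10)]
        fixed, poly = ss.partition_fixed_polymorphic(sites, variants)
        assert len(fixed) + len(poly) == len(sites)
        assert [s.interval.start for s in poly] == [10]

    def test_independence_gives_zero_statistic(self):
        res = ss.compare_fixed_polymorphic(10, 10, 10, 10)
        assert res.chi2 == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_association_statistic_by_hand(self):
        # all expected cells are 15; sum (o-e)^2/e = 4*(25/15) = 100/15
        res = ss.compare_fixed_polymorphic(20, 10, 10, 20)
        assert res.chi2 == pytest.approx(100 / 15)

    def test_all_polymorphic_proportion_one(self):
        sites = [GenomicInterval("ref", p, p + 1) for p in [5, 10]]
        variants = [_variant(5), _variant(10)]
        fixed, poly = ss.partition_fixed_polymorphic(sites, variants)
        assert len(fixed) == 0
        res = ss.compare_fixed_polymorphic(len(fixed), len(poly), 10, 10)
        assert res.polymorphic_proportion_set == 1.0

    def test_zero_expected_cell_errors(self):
        with pytest.raises(ValueError):
            ss.compare_fixed_polymorphic(0, 0, 10, 10)

    def test_site_densities(self):
        sites = [GenomicInterval("ref", 5, 6), GenomicInterval("ref", 50, 51)]
        variants = [_variant(7)]
        regions = [GenomicInterval("ref", 0, 10)]
        div_per_base, poly_per_base = ss.site_densities(sites, variants, regions)
        assert div_per_base == pytest.approx(0.1)
        assert poly_per_base == pytest.approx(0.1)


class TestProximityBlock:
    def test_single_variant_retained(self):
        vs = [_variant(100)]
        assert ss.proximity_block(vs, seed=10) == vs

    def test_greedy_outcomes_enumerated(self):
        # {0, 5k, 12k}: whichever is drawn first, the invariant holds and the
        # outcome is one of the two maximal greedy solutions
        vs = [_variant(0), _variant(5_000), _variant(12_000)]
        for seed in range(20):
            out = ss.proximity_block(vs, min_dist=10_000, seed=seed)
            got = sorted(v.pos for v in out)
            assert got in ([0, 12_000], [5_000], [12_000], [0])
            for x, y in zip(got, got[1:]):
                assert y - x >= 10_000

    def test_published_seeds_reproducible(self):
        rng = np.random.default_rng(0)
        vs = [_variant(int(p)) for p in
              np.sort(rng.choice(2_000_000, size=400, replace=False))]
        for seed in (10, 40, 70):
            a = [v.pos for v in ss.proximity_block(vs, seed=seed)]
            b = [v.pos for v in ss.proximity_block(vs, seed=seed)]
            assert a == b
        subsets = {tuple(v.pos for v in ss.proximity_block(vs, seed=s))
                   for s in (10, 40, 70)}
        assert len(subsets) == 3

    def test_spacing_invariant_and_maximality(self):
        rng = np.random.default_rng(5)
        vs = [_variant(int(p)) for p in
              np.sort(rng.choice(300_000, size=200, replace=False))]
        out = ss.proximity_block(vs, min_dist=10_000, seed=40)
        pos = sorted(v.pos for v in out)
        assert all(b - a >= 10_000 for a, b in zip(pos, pos[1:]))
        # maximality: every rejected variant is < min_dist from a retained one
        kept = set(pos)
        for v in vs:
            if v.pos not in kept:
                assert any(abs(v.pos - p) < 10_000 for p in pos)


class TestSpectrum:
    def test_all_singletons_in_lowest_class(self):
        vs = [_variant(i * 100, daf=0.1, alt_count=1, aa="A") for i in range(5)]
        for v in vs:
            v.daf = 1 / v.n_alleles
        bins = ss.allele_frequency_spectrum(vs, polarized=True)
        assert bins[0].sites == 5
        assert sum(b.sites for b in bins[1:]) == 0

    def test_folding_maps_daf_to_maf(self):
        v = _variant(0, alt_count=7, aa="A")
        v.daf = 0.7
        polarized = ss.allele_frequency_spectrum([v], polarized=True)
        unpolarized = ss.allele_frequency_spectrum([v], polarized=False)
        assert polarized[6].sites == 1  # derived count 7
        assert unpolarized[2].sites == 1  # minor count 3 -> MAF 0.3

    def test_fold_of_polarized_equals_unpolarized(self):
        rng = np.random.default_rng(3)
        vs = []
        for i in range(50):
            ac = int(rng.integers(1, 10))
            v = _variant(i * 100, alt_count=ac, aa="A")
            v.daf = ac / v.n_alleles
            vs.append(v)
        polarized = ss.allele_frequency_spectrum(vs, polarized=True)
        folded = ss.fold_spectrum(polarized, n_alleles=10)
        unpolarized = ss.allele_frequency_spectrum(vs, polarized=False)
        assert [b.sites for b in folded] == [b.sites for b in unpolarized]

    def test_total_mass_equals_variant_count(self):
        rng = np.random.default_rng(4)
        vs = []
        for i in range(30):
            ac = int(rng.integers(1, 10))
            v = _variant(i * 50, alt_count=ac, aa="A")
            v.daf = ac / v.n_alleles
            vs.append(v)
        bins = ss.allele_frequency_spectrum(vs, polarized=True)
        assert sum(b.sites for b in bins) == 30


class TestReversionClassification:
    def _site(self, daf):
        v = _variant(1_000, daf=daf, n=20, alt_count=19)
        return v

    def test_low_daf_not_applicable(self):
        assert ss.classify_high_daf_site(self._site(0.5), np.zeros((20, 1)),
                                         []) == "not_applicable"

    def test_ancestral_context_flags_incomplete_sweep(self):
        # carrier haplotype 0 is ancestral at the focal site and at a
        # divergent site 500 b away
        near = _variant(1_500, daf=0.9, n=20)
        hap = np.ones((20, 2), dtype=int)
        hap[0, 0] = 0  # ancestral at focal
        hap[0, 1] = 0  # ancestral at the nearby divergent site
        assert ss.classify_high_daf_site(self._site(0.96), hap, [near],
                                         context_w=2_000) == "ancestral_haplotype"

    def test_derived_context_flags_reversion(self):
        near = _variant(1_500, daf=0.9, n=20)
        hap = np.ones((20, 2), dtype=int)
        hap[0, 0] = 0  # ancestral at focal, derived at the nearby site
        assert ss.classify_high_daf_site(self._site(0.96), hap, [near],
                                         context_w=2_000) == "reversion_candidate"

    def test_context_window_respected(self):
        far = _variant(200_000, daf=0.9, n=20)
        hap = np.ones((20, 2), dtype=int)
        hap[0, 0] = 0
        hap[0, 1] = 0  # ancestral, but far outside the context window
        assert ss.classify_high_daf_site(self._site(0.96), hap, [far],
                                         context_w=2_000) == "reversion_candidate"

    def test_invariant_to_haplotype_order(self):
        near = _variant(1_500, daf=0.9, n=20)
        hap = np.ones((20, 2), dtype=int)
        hap[3, 0] = 0
        hap[3, 1] = 0
        a = ss.classify_high_daf_site(self._site(0.96), hap, [near], 2_000)
        b = ss.classify_high_daf_site(self._site(0.96), hap[::-1], [near], 2_000)
        assert a == b == "ancestral_haplotype"

    def test_missing_carrier_is_data_inconsistency(self):
        hap = np.ones((20, 1), dtype=int)  # everyone derived despite DAF<1
        with pytest.raises(ValueError):
            ss.classify_high_daf_site(self._site(0.96), hap, [])


class TestMeanSignal:
    def test_constant_signal(self):
        els = [GenomicInterval("ref", 0, 10), GenomicInterval("ref", 50, 60)]
        signal = {("ref", p): 2.5 for p in range(100)}
        means, dropped = ss.mean_signal_per_element(els, signal)
        np.testing.assert_allclose(means, 2.5)
        assert dropped == 0

    def test_half_and_half_mean(self):
        el = GenomicInterval("ref", 0, 10)
        signal = {("ref", p): (1.0 if p < 5 else 3.0) for p in range(10)}
        means, _ = ss.mean_signal_per_element([el], signal)
        assert means[0] == pytest.approx(2.0)

    def test_uncovered_elements_dropped_and_counted(self):
        els = [GenomicInterval("ref", 0, 10), GenomicInterval("ref", 500, 510)]
        signal = {("ref", p): 1.0 for p in range(10)}
        means, dropped = ss.mean_signal_per_element(els, signal)
        assert len(means) == 1 and dropped == 1

    def test_all_uncovered_errors(self):
        with pytest.raises(ValueError):
            ss.mean_signal_per_element([GenomicInterval("ref", 0, 5)], {})

    def test_null_distribution_of_welch_p(self):
        # identical distributions -> p roughly uniform (KS on 200 replicates)
        rng = np.random.default_rng(8)
        ps = []
        for _ in range(200):
            a = rng.normal(1.0, 0.3, size=40)
            b = rng.normal(1.0, 0.3, size=40)
            ps.append(ss.compare_mean_signal(a, b).raw_p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_bonferroni_adjustment(self):
        rng = np.random.default_rng(1)
        a = rng.normal(1.0, 0.1, 30)
        b = rng.normal(1.2, 0.1, 30)
        res = ss.compare_mean_signal(a, b, n_comparisons=5)
        assert res.adj_p == pytest.approx(min(1.0, res.raw_p * 5))
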