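"""Population-genetic evidence layer.

Given divergent sites between two ancestral nodes and a polarized variant
set, these routines partition divergence into fixed and polymorphic
classes, build allele-frequency spectra with linkage-reducing proximity
blocking, classify high-frequency derived polymorphic divergent sites as
reversion candidates versus incomplete-sweep haplotypes, and compare
per-element signal tracks (e.g. local mutation-rate estimates) between
region sets.

The underlying logic: ancient positive selection fixes beneficial variants,
so regions shaped by it show a *low* proportion of divergent sites that
remain polymorphic, and divergence in excess of what local mutation rates
predict.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .divergence_screen import ScreenConfig, call_site_events
from .genome_io import GenomicInterval, ProbRow, VariantRecord


@dataclass(frozen=True)
class DivergentSite:
    """A single substitution position (1-base interval), fixed or polymorphic."""

    interval: GenomicInterval
    status: str  # "fixed" | "polymorphic"


@dataclass
class SpectrumBin:
    """One allele-count class (derived count 1..n-1, or folded minor count)."""

    allele_count: int
    sites: int


def extract_divergent_sites(node_a: ProbRow, node_b: ProbRow,
                            ref_coord_map: np.ndarray,
                            config: ScreenConfig | None = None,
                            chrom: str = "ref") -> list[GenomicInterval]:
    """Reference positions of substitution columns between two nodes.

    Gap events are excluded: divergence is represented by substitutions only.
    Columns inserted relative to the reference are skipped (they have no
    reference coordinate of their own).
    """
    events = call_site_events(node_a, node_b, config)
    sub_cols = np.flatnonzero(events.substitution)
    is_ref_col = np.zeros(len(events.substitution), dtype=bool)
    is_ref_col[ref_coord_map] = True
    sub_cols = sub_cols[is_ref_col[sub_cols]]
    pos = np.searchsorted(ref_coord_map, sub_cols)
    return [GenomicInterval(chrom, int(p), int(p) + 1) for p in pos]


def partition_fixed_polymorphic(div_sites: Sequence[GenomicInterval],
                                variants: Sequence[VariantRecord],
                                ) -> tuple[list[DivergentSite], list[DivergentSite]]:
    """Split divergent sites into fixed vs polymorphic against a variant set."""
    poly_pos = {(v.chrom, v.pos) for v in variants}
    fixed, poly = [], []
    for iv in div_sites:
        site = DivergentSite(iv, "polymorphic"
                             if (iv.chrom, iv.start) in poly_pos else "fixed")
        (poly if site.status == "polymorphic" else fixed).append(site)
    return fixed, poly


@dataclass
class FixedPolymorphicComparison:
    table: np.ndarray          # 2x2: {set, reference} x {fixed, polymorphic}
    chi2: float
    p_value: float
    polymorphic_proportion_set: float
    polymorphic_proportion_ref: float


def compare_fixed_polymorphic(set_fixed: int, set_poly: int,
                              ref_fixed: int, ref_poly: int,
                              ) -> FixedPolymorphicComparison:
    """Pearson chi-squared (df=1, no continuity correction) on the 2x2
    {set, reference} x {fixed, polymorphic} contingency table."""
    table = np.array([[set_fixed, set_poly], [ref_fixed, ref_poly]], float)
    expected = stats.contingency.expected_freq(table)
    if np.any(expected == 0):
        raise ValueError("expected cell count of zero; use an exact test")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return FixedPolymorphicComparison(
        table=table, chi2=float(chi2), p_value=float(p),
        polymorphic_proportion_set=set_poly / max(set_fixed + set_poly, 1),
        polymorphic_proportion_ref=ref_poly / max(ref_fixed + ref_poly, 1))


def site_densities(div_sites: Sequence[GenomicInterval],
                   variants: Sequence[VariantRecord],
                   regions: Sequence[GenomicInterval],
                   ) -> tuple[float, float]:
    """(divergent sites per base, polymorphic sites per base) over a region set."""
    total = sum(len(r) for r in regions)
    if total == 0:
        raise ValueError("empty region set")
    def in_regions(chrom: str, pos: int) -> bool:
        return any(r.chrom == chrom and r.start <= pos < r.end for r in regions)
    n_div = sum(1 for s in div_sites if in_regions(s.chrom, s.start))
    n_poly = sum(1 for v in variants if in_regions(v.chrom, v.pos))
    return n_div / total, n_poly / total


def proximity_block(variants: Sequence[VariantRecord], min_dist: int = 10_000,
                    seed: int = 10) -> list[VariantRecord]:
    """Greedy linkage-thinning: accept variants in seeded-shuffle order,
    keeping each only if every previously retained variant on the same
    chromosome is at least ``min_dist`` bases away.  Deterministic per seed."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(variants))
    kept: dict[str, list[int]] = {}
    out = []
    import bisect
    for i in order:
        v = variants[i]
        positions = kept.setdefault(v.chrom, [])
        j = bisect.bisect_left(positions, v.pos)
        ok = True
        if j > 0 and v.pos - positions[j - 1] < min_dist:
            ok = False
        if ok and j < len(positions) and positions[j] - v.pos < min_dist:
            ok = False
        if ok:
            bisect.insort(positions, v.pos)
            out.append(v)
    out.sort(key=lambda v: (v.chrom, v.pos))
    return out


def allele_frequency_spectrum(variants: Sequence[VariantRecord],
                              polarized: bool = True,
                              ) -> list[SpectrumBin]:
    """Site counts per allele-count class.

    Polarized: derived allele counts 1..n-1 (requires DAF annotations).
    Unpolarized: minor allele counts 1..n//2 (MAF in (0, 0.5])."""
    if not variants:
        return []
    n = variants[0].n_alleles
    if polarized:
        counts = np.zeros(n, dtype=np.int64)  # index = derived count, 1..n-1
        for v in variants:
            if v.daf is None:
                raise ValueError("polarized spectrum requires DAF annotations")
            d = int(round(v.daf * v.n_alleles))
            if 1 <= d <= v.n_alleles - 1:
                counts[d] += 1
        return [SpectrumBin(i, int(counts[i])) for i in range(1, n)]
    counts = np.zeros(n // 2 + 1, dtype=np.int64)
    for v in variants:
        if np.any(v.genotypes < 0):
            raise ValueError("unpolarized spectrum requires complete genotypes")
        alt = v.alt_count
        minor = min(alt, v.n_alleles - alt)
        if minor >= 1:
            counts[minor] += 1
    return [SpectrumBin(i, int(counts[i])) for i in range(1, n // 2 + 1)]


def fold_spectrum(spectrum: Sequence[SpectrumBin], n_alleles: int,
                  ) -> list[SpectrumBin]:
    """Fold a polarized (derived-count) spectrum into a minor-count one."""
    folded = np.zeros(n_alleles // 2 + 1, dtype=np.int64)
    for b in spectrum:
        folded[min(b.allele_count, n_alleles - b.allele_count)] += b.sites
    return [SpectrumBin(i, int(folded[i])) for i in range(1, n_alleles // 2 + 1)]


def classify_high_daf_site(site: VariantRecord,
                           haplotypes: np.ndarray,
                           nearby_divergent: Sequence[VariantRecord],
                           context_w: int = 2_000,
                           daf_cutoff: float = 0.95) -> str:
    """Classify a high-DAF polymorphic divergent site.

    ``haplotypes``: (n_haplotypes, n_sites) 0/1 matrix over
    ``[site] + nearby_divergent`` columns where 1 means the haplotype
    carries the *derived* allele at that site.

    Returns ``"not_applicable"`` when DAF <= cutoff.  Otherwise inspects
    haplotypes carrying the ancestral allele at the focal site: if any such
    haplotype is also ancestral at another divergent site within
    ``context_w`` bases, the ancestral allele travels with ancient context
    (``"ancestral_haplotype"``, incomplete sweep); if every carrier is
    derived at all nearby divergent sites, the site looks like a back
    mutation after fixation (``"reversion_candidate"``).
    """
    if site.daf is None:
        raise ValueError("site must carry a DAF annotation")
    if site.daf <= daf_cutoff:
        return "not_applicable"
    hap = np.asarray(haplotypes)
    carriers = np.flatnonzero(hap[:, 0] == 0)  # ancestral at the focal site
    if len(carriers) == 0:
        if site.daf < 1.0:
            raise ValueError("DAF < 1 but no ancestral-allele carrier found")
        return "not_applicable"
    near = [j + 1 for j, d in enumerate(nearby_divergent)
            if abs(d.pos - site.pos) <= context_w and d.pos != site.pos]
    for h in carriers:
        if any(hap[h, j] == 0 for j in near):
            return "ancestral_haplotype"
    return "reversion_candidate"


@dataclass
class SignalComparison:
    set_means: np.ndarray
    ref_means: np.ndarray
    n_uncovered: int
    t_statistic: float
    raw_p: float
    adj_p: float


def mean_signal_per_element(elements: Sequence[GenomicInterval],
                            signal: Mapping[tuple[str, int], float],
                            ) -> tuple[np.ndarray, int]:
    """Per-element mean of a per-position signal track.

    Positions are keyed by (chrom, position); each position's value should
    already be the total rate (e.g. the sum of the three possible
    substitution rates).  Elements with no covered position are dropped;
    their count is returned alongside the means.
    """
    means, uncovered = [], 0
    for el in elements:
        vals = [signal[(el.chrom, p)] for p in range(el.start, el.end)
                if (el.chrom, p) in signal]
        if vals:
            means.append(float(np.mean(vals)))
        else:
            uncovered += 1
    if not means:
        raise ValueError("no element overlaps the signal track")
    return np.asarray(means), uncovered


def compare_mean_signal(set_means: np.ndarray, ref_means: np.ndarray,
                        n_comparisons: int = 1,
                        n_uncovered: int = 0) -> SignalComparison:
    """Welch two-sample t-test of per-element means vs a reference set,
    Bonferroni-adjusted across ``n_comparisons`` region sets."""
    t, p = stats.ttest_ind(set_means, ref_means, equal_var=False)
    return SignalComparison(set_means=np.asarray(set_means),
                            ref_means=np.asarray(ref_means),
                            n_uncovered=n_uncovered,
                            t_statistic=float(t), raw_p=float(p),
                            adj_p=float(min(1.0, p * n_comparisons)))
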