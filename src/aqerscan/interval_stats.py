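"""Interval arithmetic, overlap-enrichment statistics, matched random
region simulation, and GC-content classification.

The enrichment null models each query element as independently and
uniformly placed (by its start) among all positions where an element of
its length fits inside the genome without touching an excluded region.
The per-element probability of hitting the annotation is computed exactly
from the union of favorable start positions, and the distribution of the
total number of overlapping elements is the Poisson-binomial distribution
of those placement indicators (exact dynamic-programming convolution up to
5,000 elements, normal approximation beyond).  Two-sided p-values are
2 * min(lower tail, upper tail, 0.5), capped at 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .genome_io import GenomicInterval


# ---------------------------------------------------------------------------
# Interval arithmetic

def merge_intervals(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping and book-ended intervals; output sorted, disjoint."""
    out: list[GenomicInterval] = []
    for iv in sorted(intervals):
        if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end:
            if iv.end > out[-1].end:
                out[-1] = GenomicInterval(iv.chrom, out[-1].start, iv.end)
        else:
            out.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return out


def subtract_intervals(a: Sequence[GenomicInterval],
                       b: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Remove every base of ``b`` from ``a``, splitting intervals as needed."""
    bm = merge_intervals(b)
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in bm:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out: list[GenomicInterval] = []
    for iv in merge_intervals(a):
        cur = iv.start
        for blk in by_chrom.get(iv.chrom, []):
            if blk.end <= cur or blk.start >= iv.end:
                continue
            if blk.start > cur:
                out.append(GenomicInterval(iv.chrom, cur, blk.start))
            cur = max(cur, blk.end)
            if cur >= iv.end:
                break
        if cur < iv.end:
            out.append(GenomicInterval(iv.chrom, cur, iv.end))
    return out


def count_overlaps(a: Sequence[GenomicInterval],
                   b: Sequence[GenomicInterval]) -> int:
    """Number of elements of ``a`` overlapping >= 1 base of ``b``
    (half-open semantics; each element counted at most once)."""
    bm = merge_intervals(b)
    starts: dict[str, np.ndarray] = {}
    ends: dict[str, np.ndarray] = {}
    for chrom in {iv.chrom for iv in bm}:
        blocks = [iv for iv in bm if iv.chrom == chrom]
        starts[chrom] = np.array([x.start for x in blocks])
        ends[chrom] = np.array([x.end for x in blocks])
    n = 0
    for iv in a:
        if iv.chrom not in starts:
            continue
        j = np.searchsorted(ends[iv.chrom], iv.start, side="right")
        if j < len(starts[iv.chrom]) and starts[iv.chrom][j] < iv.end:
            n += 1
    return n


# ---------------------------------------------------------------------------
# Overlap enrichment

@dataclass
class EnrichmentResult:
    observed: int
    expected: float
    ratio: float
    raw_p: float
    adj_p: float
    direction: str  # "enriched" | "depleted"


def _start_space(genome: Mapping[str, int], w: int,
                 excluded: Sequence[GenomicInterval] | None,
                 ) -> dict[str, list[GenomicInterval]]:
    """Valid start positions (as intervals) for an element of length w."""
    out: dict[str, list[GenomicInterval]] = {}
    for chrom, size in genome.items():
        if size < w:
            continue
        valid = [GenomicInterval(chrom, 0, size - w + 1)]
        if excluded:
            bad = [GenomicInterval(chrom, max(0, e.start - w + 1), e.end)
                   for e in excluded if e.chrom == chrom]
            valid = subtract_intervals(valid, bad)
        out[chrom] = valid
    return out


def _overlap_probability(w: int, b_merged: Sequence[GenomicInterval],
                         start_space: Mapping[str, list[GenomicInterval]],
                         ) -> float:
    """P(an element of length w, uniformly placed over its valid start
    positions, overlaps the merged annotation b)."""
    total = sum(len(iv) for ivs in start_space.values() for iv in ivs)
    if total == 0:
        raise ValueError(f"no valid placement for element of length {w}")
    favorable = 0
    for chrom, valid in start_space.items():
        hits = [GenomicInterval(chrom, max(0, blk.start - w + 1), blk.end)
                for blk in b_merged if blk.chrom == chrom]
        if not hits:
            continue
        inter = subtract_intervals(valid, subtract_intervals(valid, hits))
        favorable += sum(len(iv) for iv in inter)
    return favorable / total


def poisson_binomial_pmf(probs: np.ndarray) -> np.ndarray:
    """Exact pmf of a sum of independent Bernoulli(p_i) by DP convolution."""
    pmf = np.array([1.0])
    for p in probs:
        nxt = np.zeros(len(pmf) + 1)
        nxt[:-1] += pmf * (1 - p)
        nxt[1:] += pmf * p
        pmf = nxt
    return pmf


def overlap_enrichment(a: Sequence[GenomicInterval],
                       b: Sequence[GenomicInterval],
                       genome: Mapping[str, int],
                       excluded: Sequence[GenomicInterval] | None = None,
                       n_tests: int = 1,
                       method: str = "bonferroni",
                       exact_limit: int = 5_000) -> EnrichmentResult:
    """Two-sided binomial-based overlap enrichment of set ``a`` in ``b``."""
    if not a:
        raise ValueError("query set is empty")
    bm = merge_intervals(b)
    max_size = max(genome.values())
    probs = []
    for el in a:
        w = len(el)
        if w > max_size:
            raise ValueError(f"element of length {w} exceeds every chromosome")
        space = _start_space(genome, w, excluded)
        probs.append(_overlap_probability(w, bm, space) if bm else 0.0)
    probs = np.asarray(probs)
    expected = float(probs.sum())
    observed = count_overlaps(a, bm) if bm else 0
    if expected == 0:
        ratio = np.nan
        raw_p = 1.0
        direction = "depleted" if observed == 0 else "enriched"
    else:
        ratio = observed / expected
        if len(a) <= exact_limit:
            pmf = poisson_binomial_pmf(probs)
            cdf = np.cumsum(pmf)
            lower = float(cdf[observed])
            upper = float(pmf[observed:].sum())
        else:
            mu = expected
            sd = float(np.sqrt(np.sum(probs * (1 - probs))))
            lower = float(stats.norm.cdf(observed + 0.5, mu, sd))
            upper = float(stats.norm.sf(observed - 0.5, mu, sd))
        raw_p = min(1.0, 2.0 * min(lower, upper, 0.5))
        direction = "enriched" if observed >= expected else "depleted"
    if method == "bonferroni":
        adj_p = min(1.0, raw_p * n_tests)
    elif method == "bh":
        adj_p = raw_p  # adjusted jointly across results; see adjust_enrichments
    else:
        raise ValueError(f"unknown adjustment method {method!r}")
    return EnrichmentResult(observed=observed, expected=expected,
                            ratio=float(ratio), raw_p=raw_p, adj_p=adj_p,
                            direction=direction)


def adjust_enrichments(results: Sequence[EnrichmentResult],
                       method: str = "bh") -> list[EnrichmentResult]:
    """Joint multiple-testing adjustment over a family of enrichment tests
    (BH for GWAS-style scans, Bonferroni otherwise)."""
    from statsmodels.stats.multitest import multipletests
    raw = [r.raw_p for r in results]
    mm = {"bh": "fdr_bh", "bonferroni": "bonferroni"}[method]
    adj = multipletests(raw, method=mm)[1]
    for r, p in zip(results, adj):
        r.adj_p = float(p)
    return list(results)


# ---------------------------------------------------------------------------
# Matched random regions

def simulate_rand_regions(background: Sequence[GenomicInterval], n: int,
                          mean_len: float, seed: int,
                          max_attempts: int = 10_000) -> list[GenomicInterval]:
    """Pseudorandom region set matched in element count and mean length.

    Each element has length round(mean_len) and is placed uniformly within
    the background without crossing block boundaries or overlapping a
    previously placed element.  Deterministic per seed.
    """
    L = int(round(mean_len))
    blocks = [b for b in merge_intervals(background) if len(b) >= L]
    capacity = sum(len(b) - L + 1 for b in blocks)
    if capacity < n:
        raise ValueError("background capacity insufficient for requested set")
    rng = np.random.default_rng(seed)
    weights = np.array([len(b) - L + 1 for b in blocks], dtype=float)
    weights /= weights.sum()
    placed: list[GenomicInterval] = []
    attempts = 0
    while len(placed) < n:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(f"could not place {n} non-overlapping regions "
                               f"in {max_attempts} attempts")
        b = blocks[rng.choice(len(blocks), p=weights)]
        start = b.start + int(rng.integers(0, len(b) - L + 1))
        cand = GenomicInterval(b.chrom, start, start + L, name=f"RAND{len(placed)}")
        if any(cand.overlaps(p) for p in placed):
            continue
        placed.append(cand)
    return sorted(placed)


# ---------------------------------------------------------------------------
# GC content

def gc_content(sequence: str, rich: float = 0.75, poor: float = 0.25,
               ) -> tuple[float, str]:
    """GC fraction (Ns excluded from the denominator) and class.

    Class is "rich" for GC > ``rich``, "poor" for GC < ``poor``, else "mid".
    An all-N sequence has undefined GC content (ValueError).
    """
    s = sequence.upper()
    gc = sum(1 for ch in s if ch in "GC")
    denom = sum(1 for ch in s if ch in "ACGT")
    if denom == 0:
        raise ValueError("all-N sequence: GC content undefined")
    frac = gc / denom
    cls = "rich" if frac > rich else ("poor" if frac < poor else "mid")
    return frac, cls


def gc_class_test(set_counts: tuple[int, int],
                  genome_counts: tuple[int, int]) -> tuple[float, float]:
    """Chi-squared independence test of (in-class, out-of-class) counts for a
    region set against the genome background."""
    table = np.array([set_counts, genome_counts], dtype=float)
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


# ---------------------------------------------------------------------------
# Posterior filtering

def posterior_filter(intervals: Sequence[GenomicInterval],
                     cutoff: float) -> list[GenomicInterval]:
    """Keep intervals whose score (a posterior probability) is >= cutoff."""
    out = []
    for iv in intervals:
        if iv.score is None or not (0.0 <= iv.score <= 1.0):
            raise ValueError(f"posterior value outside [0, 1]: {iv.score}")
        if iv.score >= cutoff:
            out.append(iv)
    return out
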