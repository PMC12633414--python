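"""Sliding-window scan for rapidly diverged regions between two ancestral nodes.

Divergence between two internal nodes is counted per alignment column:

* a **substitution** is a column where both nodes carry a base and the
  cosine distance between their posterior base vectors,
  ``d = 1 - u.v / (|u||v|)``, is at least a threshold (default 0.8) —
  the distance approximates the probability that a substitution occurred
  on the branch separating the nodes, and thresholding binarizes it
  conservatively;
* a **gap event** is a maximal run of columns where exactly one node
  carries a base; it counts as a single divergence event irrespective of
  its length, anchored at its first column.

Windows (default 500 bp, sliding by 1 reference base) accumulate
``k = substitutions + gap events``.  The expected per-base event rate is
calibrated conservatively as the *maximum* rate observed in any wide
calibration window (default 10 Mb), optionally rescaled by the ratio of
branch lengths for non-reference lineages.  Window significance is an
exact binomial upper tail P(X >= k) with n = window length, adjusted by
Benjamini-Hochberg over all evaluated windows; significant windows are
merged into calls.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import binom
from statsmodels.stats.multitest import multipletests

from .genome_io import GenomicInterval, ProbRow
from .phylo_model import PhyloTree


@dataclass
class ScreenConfig:
    """Tunable parameters of the divergence screen."""

    window_length: int = 500
    window_step: int = 1
    cosine_threshold: float = 0.8
    calibration_window: int = 10_000_000
    alpha_adj: float = 3e-7
    lineage_scale: float = 1.0
    min_callable_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not (0 < self.cosine_threshold <= 1):
            raise ValueError("cosine_threshold must be in (0, 1]")
        if self.window_length < 25:
            raise ValueError("window_length must be >= 25")
        if self.calibration_window < self.window_length:
            raise ValueError("calibration_window must be >= window_length")
        if not (0 < self.alpha_adj < 1):
            raise ValueError("alpha_adj must be in (0, 1)")


@dataclass
class SiteEvents:
    """Per-column event labels between two node tracks."""

    substitution: np.ndarray   # bool per column
    gap_anchor: np.ndarray     # bool: first column of each one-sided gap run
    both_present: np.ndarray   # bool
    distance: np.ndarray       # cosine distance (nan unless both present)


@dataclass
class WindowTable:
    """Array-backed per-window statistics (one row per window)."""

    chrom: str
    start: np.ndarray          # window start, reference coords
    length: int
    k_s: np.ndarray            # substitution count
    k_g: np.ndarray            # gap-event count (anchored)
    callable_bases: np.ndarray
    raw_p: np.ndarray | None = None
    adj_p: np.ndarray | None = None
    truncated: np.ndarray | None = None
    ref_length: int | None = None

    @property
    def k(self) -> np.ndarray:
        return self.k_s + self.k_g

    def __len__(self) -> int:
        return len(self.start)

    def interval(self, i: int) -> GenomicInterval:
        return GenomicInterval(self.chrom, int(self.start[i]),
                               int(self.start[i]) + self.length)


@dataclass
class AqerCall:
    """A merged run of significant windows."""

    interval: GenomicInterval
    peak_k: int
    min_adj_p: float


def cosine_distance(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """1 - cosine similarity, rowwise over (n, 4) arrays."""
    nu = np.linalg.norm(u, axis=-1)
    nv = np.linalg.norm(v, axis=-1)
    if np.any((nu == 0) | (nv == 0)):
        raise ValueError("zero-magnitude posterior vector")
    dot = np.sum(u * v, axis=-1)
    return 1.0 - dot / (nu * nv)


def call_site_events(node_a: ProbRow, node_b: ProbRow,
                     config: ScreenConfig | None = None) -> SiteEvents:
    """Label every column as substitution, part of a gap event, or none."""
    cfg = config or ScreenConfig()
    both = node_a.present & node_b.present
    ncol = len(both)
    dist = np.full(ncol, np.nan)
    if np.any(both):
        dist[both] = cosine_distance(node_a.probs[both], node_b.probs[both])
    sub = np.zeros(ncol, dtype=bool)
    sub[both] = dist[both] >= cfg.cosine_threshold
    one_sided = node_a.present ^ node_b.present
    prev = np.concatenate([[False], one_sided[:-1]])
    gap_anchor = one_sided & ~prev
    return SiteEvents(substitution=sub, gap_anchor=gap_anchor,
                      both_present=both, distance=dist)


def _per_ref_base(events: SiteEvents, ref_coord_map: np.ndarray,
                  ref_length: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Assign column events to reference positions (insertions fold onto the
    preceding reference base) and return per-base counts."""
    ncol = len(events.substitution)
    cols = np.arange(ncol)
    pos_of_col = np.searchsorted(ref_coord_map, cols, side="right") - 1
    valid = pos_of_col >= 0
    def count(mask: np.ndarray) -> np.ndarray:
        m = mask & valid
        return np.bincount(pos_of_col[m], minlength=ref_length).astype(np.int64)
    return (count(events.substitution), count(events.gap_anchor),
            count(events.both_present))


def windowed_event_counts(events: SiteEvents, ref_coord_map: np.ndarray,
                          ref_length: int, config: ScreenConfig | None = None,
                          chrom: str = "ref",
                          window_length: int | None = None,
                          window_step: int | None = None) -> WindowTable:
    """Sliding-window event counts on reference coordinates.

    ``k_s`` counts substitution columns whose span falls in the window
    (alignment columns inserted relative to the reference are folded onto
    the preceding reference base, so insertions inside the span are
    included); ``k_g`` counts gap-event runs anchored in the window;
    ``callable_bases`` counts reference bases where both nodes are present.
    """
    cfg = config or ScreenConfig()
    L = window_length if window_length is not None else cfg.window_length
    step = window_step if window_step is not None else cfg.window_step
    subs, gaps, callab = _per_ref_base(events, ref_coord_map, ref_length)
    starts = np.arange(0, max(ref_length - L, 0) + 1, step, dtype=np.int64)
    if len(starts) == 0:  # window longer than the chromosome: truncate
        starts = np.array([0], dtype=np.int64)
    ends = np.minimum(starts + L, ref_length)
    truncated = (starts + L) > ref_length

    def wsum(per_base: np.ndarray) -> np.ndarray:
        cum = np.concatenate([[0], np.cumsum(per_base)])
        return cum[ends] - cum[starts]

    return WindowTable(chrom=chrom, start=starts, length=L,
                       k_s=wsum(subs), k_g=wsum(gaps),
                       callable_bases=wsum(callab), truncated=truncated,
                       ref_length=ref_length)


def calibrate_expected_rate(genome_windows: WindowTable,
                            config: ScreenConfig | None = None) -> float:
    """Conservative expected divergence rate: the maximum per-base event
    rate among calibration windows with sufficient callable fraction."""
    cfg = config or ScreenConfig()
    callab = genome_windows.callable_bases.astype(float)
    frac = callab / genome_windows.length
    ok = (frac >= cfg.min_callable_fraction) & (callab > 0)
    if not np.any(ok):
        raise ValueError("no calibration window with callable fraction >= "
                         f"{cfg.min_callable_fraction}")
    rates = genome_windows.k[ok] / callab[ok]
    return float(np.max(rates))


def scale_rate_for_lineage(p_hat: float, tree: PhyloTree,
                           lineage_branch: str, human_branch: str) -> float:
    """Rescale the calibrated rate by the ratio of stem branch lengths."""
    t_lineage = tree.length_of(lineage_branch)
    t_human = tree.length_of(human_branch)
    if not (t_human > 0):
        raise ValueError("reference (human) branch length must be > 0")
    if not (t_lineage > 0):
        raise ValueError("lineage branch length must be > 0")
    return p_hat * (t_lineage / t_human)


def window_significance(windows: WindowTable, p_hat: float,
                        config: ScreenConfig | None = None) -> WindowTable:
    """Exact binomial upper-tail p per window plus BH adjustment.

    raw_p = P(X >= k) for X ~ Binomial(L, p_hat); the number of trials is
    the window length regardless of insertions, so k is capped at L.
    BH m = number of evaluated windows.
    """
    cfg = config or ScreenConfig()
    if not (0 < p_hat < 1):
        raise ValueError("expected rate must be in (0, 1)")
    L = windows.length
    k = windows.k
    if np.any(k > L):
        import warnings
        warnings.warn("event count exceeds window length; clipping")
        k = np.minimum(k, L)
    # lookup table over k = 0..L: sf(k-1) = P(X >= k)
    table = binom.sf(np.arange(-1, L), L, p_hat)
    raw = table[k]
    windows.raw_p = raw
    windows.adj_p = multipletests(raw, method="fdr_bh")[1]
    return windows


def call_aqers(windows: WindowTable,
               config: ScreenConfig | None = None) -> list[AqerCall]:
    """Merge overlapping/book-ended significant windows into calls."""
    cfg = config or ScreenConfig()
    if windows.adj_p is None:
        raise ValueError("run window_significance first")
    sig = windows.adj_p < cfg.alpha_adj
    if not np.any(sig):
        return []
    starts = windows.start[sig]
    limit = windows.ref_length if windows.ref_length is not None else np.inf
    ends = np.minimum(starts + windows.length, limit).astype(np.int64)
    ks = windows.k[sig]
    ps = windows.adj_p[sig]
    order = np.argsort(starts)
    calls: list[AqerCall] = []
    cs, ce, pk, mp = None, None, 0, 1.0
    for i in order:
        s, e = int(starts[i]), int(ends[i])
        if cs is None:
            cs, ce, pk, mp = s, e, int(ks[i]), float(ps[i])
        elif s <= ce:  # overlap or book-ended
            ce = max(ce, e)
            pk = max(pk, int(ks[i]))
            mp = min(mp, float(ps[i]))
        else:
            calls.append(AqerCall(GenomicInterval(windows.chrom, cs, ce), pk, mp))
            cs, ce, pk, mp = s, e, int(ks[i]), float(ps[i])
    calls.append(AqerCall(GenomicInterval(windows.chrom, cs, ce), pk, mp))
    return calls


def filter_calls(calls: Sequence[AqerCall], min_k: int | None = None,
                 exclude: Sequence[GenomicInterval] | None = None,
                 ) -> list[AqerCall]:
    """Threshold calls by peak event count and/or drop calls overlapping an
    exclusion set (>= 1 base)."""
    out = list(calls)
    if min_k is not None:
        out = [c for c in out if c.peak_k >= min_k]
    if exclude is not None:
        out = [c for c in out
               if not any(c.interval.overlaps(e) for e in exclude)]
    return out


def run_screen(node_a: ProbRow, node_b: ProbRow, ref_coord_map: np.ndarray,
               ref_length: int, config: ScreenConfig | None = None,
               chrom: str = "ref", tree: PhyloTree | None = None,
               lineage_branch: str | None = None,
               human_branch: str | None = None,
               ) -> tuple[list[AqerCall], WindowTable, float]:
    """End-to-end screen between two reconstructed node tracks.

    Returns (calls, window table with p-values, calibrated rate).
    """
    cfg = config or ScreenConfig()
    events = call_site_events(node_a, node_b, cfg)
    calib = windowed_event_counts(events, ref_coord_map, ref_length, cfg,
                                  chrom=chrom,
                                  window_length=min(cfg.calibration_window,
                                                    ref_length),
                                  window_step=min(cfg.calibration_window,
                                                  ref_length))
    p_hat = calibrate_expected_rate(calib, cfg) * cfg.lineage_scale
    if tree is not None and lineage_branch is not None and human_branch is not None:
        p_hat = scale_rate_for_lineage(p_hat, tree, lineage_branch, human_branch)
    windows = windowed_event_counts(events, ref_coord_map, ref_length, cfg,
                                    chrom=chrom)
    windows = window_significance(windows, p_hat, cfg)
    return call_aqers(windows, cfg), windows, p_hat


# ---------------------------------------------------------------------------
# Confidence-filtered substitution windows (polymorphism/divergence scans)

def confident_divergence_windows(node_a: ProbRow, node_b: ProbRow,
                                 ref_coord_map: np.ndarray, ref_length: int,
                                 window_length: int, window_step: int,
                                 cosine_threshold: float = 0.8,
                                 posterior_min: float = 0.8,
                                 min_confident_fraction: float = 0.9,
                                 chrom: str = "ref") -> WindowTable:
    """Substitution-only window counts with posterior-confidence filtering.

    Columns count as substitutions (and as callable) only when both nodes
    are present *and* each node's maximum posterior is at least
    ``posterior_min``; windows whose confident fraction does not exceed
    ``min_confident_fraction`` are dropped.  Gap events are excluded so
    uneven gap sizes cannot skew the trend.
    """
    events = call_site_events(node_a, node_b,
                              ScreenConfig(cosine_threshold=cosine_threshold))
    conf = (events.both_present
            & (node_a.probs.max(axis=1) >= posterior_min)
            & (node_b.probs.max(axis=1) >= posterior_min))
    filtered = SiteEvents(substitution=events.substitution & conf,
                          gap_anchor=np.zeros_like(events.gap_anchor),
                          both_present=conf, distance=events.distance)
    table = windowed_event_counts(filtered, ref_coord_map, ref_length,
                                  chrom=chrom, window_length=window_length,
                                  window_step=window_step)
    frac = table.callable_bases / table.length
    keep = frac > min_confident_fraction
    return WindowTable(chrom=table.chrom, start=table.start[keep],
                       length=table.length, k_s=table.k_s[keep],
                       k_g=table.k_g[keep],
                       callable_bases=table.callable_bases[keep],
                       truncated=table.truncated[keep])
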