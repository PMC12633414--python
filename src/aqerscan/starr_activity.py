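"""Single-cell STARR-seq enhancer-activity quantification.

The assay reads out enhancer activity as reporter RNA relative to plasmid
input.  Per construct we compute

    score = (output UMIs / input reads) / mean over negative controls of
            (output UMIs / input reads)

so negative-control scores average exactly 1 within each scope (pseudobulk
pooling all cells, or one scope per cell type).  Significance comes from a
gamma distribution fitted by maximum likelihood to the negative-control
scores — the gamma supports [0, inf) and fits reporter noise better than a
normal — with right-tailed p-values per construct.  Pseudoreplicates
(random cell bins) assess the read distribution among cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats


@dataclass
class ConstructCounts:
    """UMI-deduplicated output counts plus input-library read counts.

    ``umi_counts`` is (n_constructs, n_cells); ``negative_control`` flags
    the scrambled controls used for normalization.
    """

    constructs: list[str]
    cells: list[str]
    umi_counts: np.ndarray
    input_counts: np.ndarray
    negative_control: np.ndarray

    def __post_init__(self) -> None:
        self.umi_counts = np.asarray(self.umi_counts)
        self.input_counts = np.asarray(self.input_counts, dtype=float)
        self.negative_control = np.asarray(self.negative_control, dtype=bool)
        if np.any(self.input_counts <= 0):
            raise ValueError("input counts must be > 0 for scored constructs")
        if np.any(self.umi_counts < 0):
            raise ValueError("UMI counts must be >= 0")


@dataclass
class ActivityResult:
    construct: str
    scope: str              # "pseudobulk" or a cell-type name
    score: float
    p_right: float | None = None
    p_adj: float | None = None


def dedupe_umis(records: Iterable[tuple[str, str, str]],
                constructs: Sequence[str], input_counts: Mapping[str, float],
                nc_ids: Sequence[str]) -> ConstructCounts:
    """Collapse identical (cell, UMI, construct) triples to single molecules
    and tabulate per-cell counts."""
    seen = set(records)
    cells = sorted({cell for cell, _, _ in seen})
    cell_idx = {c: i for i, c in enumerate(cells)}
    cons_idx = {c: i for i, c in enumerate(constructs)}
    mat = np.zeros((len(constructs), len(cells)), dtype=np.int64)
    for cell, _, construct in seen:
        mat[cons_idx[construct], cell_idx[cell]] += 1
    return ConstructCounts(
        constructs=list(constructs), cells=cells, umi_counts=mat,
        input_counts=np.array([input_counts[c] for c in constructs]),
        negative_control=np.array([c in set(nc_ids) for c in constructs]))


def _scope_scores(counts: ConstructCounts, cell_mask: np.ndarray,
                  scope: str, smooth_nc_zero: bool = True) -> list[ActivityResult]:
    out_counts = counts.umi_counts[:, cell_mask].sum(axis=1).astype(float)
    nc = counts.negative_control
    if np.all(out_counts[nc] == 0):
        raise ValueError(f"all negative controls have zero output in scope "
                         f"{scope!r}")
    if smooth_nc_zero and np.any(out_counts[nc] == 0):
        # add-one smoothing on NC outputs only, to keep the NC mean finite
        warnings.warn(f"zero negative-control output in scope {scope!r}; "
                      "applying add-one smoothing to NC outputs")
        out_counts = out_counts.copy()
        out_counts[nc] += 1
    ratio = out_counts / counts.input_counts
    nc_mean = ratio[nc].mean()
    scores = ratio / nc_mean
    return [ActivityResult(construct=c, scope=scope, score=float(s))
            for c, s in zip(counts.constructs, scores)]


def activity_scores(counts: ConstructCounts,
                    cell_types: Mapping[str, str] | None = None,
                    ) -> list[ActivityResult]:
    """Input- and negative-control-normalized activity scores.

    Without ``cell_types`` a single pseudobulk scope pools all cells;
    with a {cell: label} mapping, each label is scored independently with
    its own negative-control normalization.
    """
    if cell_types is None:
        mask = np.ones(len(counts.cells), dtype=bool)
        return _scope_scores(counts, mask, "pseudobulk")
    results: list[ActivityResult] = []
    labels = sorted(set(cell_types.values()))
    cell_arr = np.array([cell_types.get(c) for c in counts.cells], dtype=object)
    for label in labels:
        mask = cell_arr == label
        results.extend(_scope_scores(counts, mask, label))
    return results


def fit_gamma_null(nc_scores: np.ndarray) -> tuple[float, float]:
    """Gamma (shape, scale) by MLE on negative-control scores, with a
    method-of-moments fallback if the MLE does not converge."""
    x = np.asarray(nc_scores, dtype=float)
    if len(x) < 3:
        raise ValueError("need >= 3 negative-control scores to fit the null")
    if np.any(x <= 0):
        raise ValueError("negative-control scores must be > 0 to fit a gamma")
    try:
        shape, loc, scale = stats.gamma.fit(x, floc=0)
        if not (np.isfinite(shape) and np.isfinite(scale) and shape > 0):
            raise RuntimeError("non-finite gamma MLE")
    except Exception:
        warnings.warn("gamma MLE failed; falling back to method of moments")
        m, v = x.mean(), x.var(ddof=1)
        shape, scale = m * m / v, v / m
    return float(shape), float(scale)


def gamma_null_test(results: Sequence[ActivityResult],
                    counts: ConstructCounts,
                    adjust: bool = True) -> list[ActivityResult]:
    """Right-tailed gamma-null p-values per scope, with optional BH column."""
    nc_names = {c for c, f in zip(counts.constructs, counts.negative_control) if f}
    by_scope: dict[str, list[ActivityResult]] = {}
    for r in results:
        by_scope.setdefault(r.scope, []).append(r)
    for scope, rs in by_scope.items():
        nc_scores = np.array([r.score for r in rs if r.construct in nc_names])
        shape, scale = fit_gamma_null(nc_scores)
        for r in rs:
            r.p_right = float(stats.gamma.sf(r.score, shape, scale=scale))
    if adjust:
        from statsmodels.stats.multitest import multipletests
        ps = [r.p_right for r in results]
        adj = multipletests(ps, method="fdr_bh")[1]
        for r, p in zip(results, adj):
            r.p_adj = float(p)
    return list(results)


def pseudoreplicate_bins(counts: ConstructCounts, k: int = 5,
                         seed: int = 0) -> dict[str, int]:
    """Randomly assort cells into ``k`` bins; every bin must end up with
    more than one read of every negative-control construct."""
    if k < 2:
        raise ValueError("need at least 2 bins")
    rng = np.random.default_rng(seed)
    assignment = rng.integers(0, k, size=len(counts.cells))
    offending: list[tuple[int, str]] = []
    for b in range(k):
        mask = assignment == b
        totals = counts.umi_counts[:, mask].sum(axis=1)
        for name, flag, tot in zip(counts.constructs,
                                   counts.negative_control, totals):
            if flag and tot <= 1:
                offending.append((b, name))
    if offending:
        raise ValueError("bins with <= 1 read of a negative control: "
                         + ", ".join(f"bin {b} ({n})" for b, n in offending)
                         + "; lower k")
    return {cell: int(b) for cell, b in zip(counts.cells, assignment)}
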