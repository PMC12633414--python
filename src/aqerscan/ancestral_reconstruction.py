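"""Per-column ancestral state inference on a fixed tree.

Two separate questions are answered for every internal node and alignment
column:

* **presence** — does the node carry a base at all?  A node is present iff
  at least two of its incident lineage directions (each child subtree, and
  the complement of the node's subtree reached through its parent) contain
  at least one leaf with a base.  This treats aligned bases as sharing a
  common origin while refusing to hallucinate ancestral bases supported by
  a single lineage.

* **base posterior** — for present nodes, the marginal posterior
  probability of A, C, G and T under the Jukes-Cantor model with the
  tree's branch lengths and a uniform root prior, conditioning on present
  leaves only (absent leaves contribute no likelihood term).  The full
  vector is kept rather than a single argmax base.

Posteriors are computed with the standard inside-outside decomposition of
Felsenstein pruning, vectorized across columns and chunked so genome-scale
alignments stream through in bounded memory.
"""

from __future__ import annotations

import numpy as np

from .genome_io import BASES, BaseRow, ProbAlignment, ProbRow, VariantRecord
from .phylo_model import PhyloTree


def _leaf_presence_matrix(alignment: ProbAlignment, tree: PhyloTree,
                          sl: slice) -> tuple[np.ndarray, list[int]]:
    leaves = tree.leaves
    n = sl.stop - sl.start
    pres = np.zeros((n, len(leaves)), dtype=bool)
    for j, v in enumerate(leaves):
        row = alignment.rows[tree.names[v]]
        if isinstance(row, BaseRow):
            pres[:, j] = row.codes[sl] < 4  # gaps and Ns are absent
        else:
            pres[:, j] = row.present[sl]
    return pres, leaves


def infer_presence(leaf_presence: np.ndarray, tree: PhyloTree,
                   ) -> dict[str, np.ndarray]:
    """Presence flags for every internal node.

    ``leaf_presence``: (n_columns, n_leaves) bool in ``tree.leaves`` order.
    Returns {node name: bool array}; leaves are included for convenience
    (present iff non-gap).
    """
    leaf_presence = np.asarray(leaf_presence, dtype=bool)
    leaves = tree.leaves
    pos = {v: j for j, v in enumerate(leaves)}
    ncol = leaf_presence.shape[0]
    # leaves present in each node's subtree, counted per column
    cnt = {}
    for v in tree.postorder:
        if tree.is_leaf(v):
            cnt[v] = leaf_presence[:, pos[v]].astype(np.int32)
        else:
            cnt[v] = sum(cnt[c] for c in tree.children[v])
    total = cnt[tree.root]
    out: dict[str, np.ndarray] = {}
    for v in range(tree.n_nodes):
        if tree.is_leaf(v):
            out[tree.names[v]] = leaf_presence[:, pos[v]].copy()
            continue
        occupied = np.zeros(ncol, dtype=np.int8)
        for c in tree.children[v]:
            occupied += (cnt[c] > 0)
        if v != tree.root:
            occupied += ((total - cnt[v]) > 0)
        out[tree.names[v]] = occupied >= 2
    return out


def _leaf_partial(codes: np.ndarray, dtype=np.float64) -> np.ndarray:
    # rows 0-3: one-hot observed base; row 4 (absent): uninformative ones
    table = np.vstack([np.eye(4), np.ones(4)]).astype(dtype)
    return table[np.minimum(codes, 4)]


def compute_posteriors(alignment: ProbAlignment, tree: PhyloTree,
                       nodes: list[str] | None = None,
                       chunk: int = 500_000,
                       dtype: np.dtype = np.float64) -> dict[str, ProbRow]:
    """Marginal JC posteriors at internal nodes for every alignment column.

    Returns {node name: ProbRow} restricted to ``nodes`` (default: all
    internal nodes).  Posterior vectors are defined (and sum to 1) only
    where the node is inferred present; elsewhere they are zero.
    ``dtype=np.float32`` halves memory traffic for genome-scale scans where
    posteriors only feed a thresholded distance.
    """
    internal = [tree.names[v] for v in range(tree.n_nodes)
                if not tree.is_leaf(v)]
    wanted = internal if nodes is None else list(nodes)
    for nm in wanted:
        if tree.is_leaf(tree.index(nm)):
            raise ValueError(f"{nm!r} is a leaf, not an internal node")
    ncol = alignment.n_columns
    result = {nm: ProbRow(probs=np.zeros((ncol, 4), dtype=dtype),
                          present=np.zeros(ncol, dtype=bool))
              for nm in wanted}
    for start in range(0, ncol, chunk):
        sl = slice(start, min(start + chunk, ncol))
        _posteriors_chunk(alignment, tree, wanted, sl, result, np.dtype(dtype))
    return result


def _norm_message(part: np.ndarray, t: float) -> np.ndarray:
    """Sum-normalized JC message: psd + (pss - psd) * partial / sum(partial).

    Row sums of the JC matrix are 1, so the message's column sum equals the
    partial's; normalizing the partial first and exploiting that identity
    saves a second reduction over the array.
    """
    pss = 0.25 + 0.75 * np.exp(-4.0 * t / 3.0)
    psd = 0.25 - 0.25 * np.exp(-4.0 * t / 3.0)
    dt = part.dtype.type
    s = part.sum(axis=1, keepdims=True)
    if np.any(s == 0):  # zero-likelihood columns (conflicting zero branches)
        part = np.where(s == 0, dt(0.25), part)
        s = np.where(s == 0, dt(1.0), s)
    pn = part / s
    return dt(psd) + dt(pss - psd) * pn


def _posteriors_chunk(alignment: ProbAlignment, tree: PhyloTree,
                      wanted: list[str], sl: slice,
                      result: dict[str, ProbRow],
                      dtype: np.dtype) -> None:
    leaf_presence, leaves = _leaf_presence_matrix(alignment, tree, sl)
    presence = infer_presence(leaf_presence, tree)
    n = sl.stop - sl.start

    # inside pass: up[v] = message from v's subtree through the branch above v
    up: dict[int, np.ndarray] = {}
    partial: dict[int, np.ndarray] = {}
    for v in tree.postorder:
        if tree.is_leaf(v):
            row = alignment.rows[tree.names[v]]
            if isinstance(row, BaseRow):
                codes = np.where(row.codes[sl] >= 4, 4, row.codes[sl])
            else:
                raise ValueError("posterior computation requires concrete leaf rows")
            part = _leaf_partial(codes, dtype)
        else:
            part = None
            for c in tree.children[v]:
                part = up[c].copy() if part is None else np.multiply(part, up[c], out=part)
        partial[v] = part
        if v != tree.root:
            up[v] = _norm_message(part, float(tree.branch_length[v]))

    # outside pass, restricted to the target nodes and their ancestors:
    # out[v] = message arriving at v from the rest of the tree
    needed: set[int] = set()
    for nm in wanted:
        v = tree.index(nm)
        while v >= 0:
            needed.add(v)
            v = int(tree.parent[v])
    out: dict[int, np.ndarray] = {tree.root: np.full((n, 4), 0.25, dtype=dtype)}
    for v in reversed(tree.postorder):  # preorder
        if tree.is_leaf(v) or v not in out:
            continue
        for c in tree.children[v]:
            if c not in needed or tree.is_leaf(c):
                continue
            above = out[v].copy()
            for s_ in tree.children[v]:
                if s_ != c:
                    np.multiply(above, up[s_], out=above)
            out[c] = _norm_message(above, float(tree.branch_length[c]))

    for nm in wanted:
        v = tree.index(nm)
        post = partial[v] * out[v]
        tot = post.sum(axis=1, keepdims=True)
        good = tot[:, 0] > 0
        np.divide(post, tot, out=post, where=tot > 0)
        post[~good] = 0.25  # impossible-data guard (e.g. conflicting zero branches)
        pres = presence[nm]
        row = result[nm]
        row.present[sl] = pres
        post[~pres] = 0.0
        row.probs[sl] = post


def reconstruct(alignment: ProbAlignment, tree: PhyloTree,
                nodes: list[str] | None = None,
                chunk: int = 500_000) -> ProbAlignment:
    """Attach reconstructed internal-node rows to a copy of the alignment."""
    rows = dict(alignment.rows)
    for nm, prow in compute_posteriors(alignment, tree, nodes, chunk).items():
        rows[nm] = prow
    return ProbAlignment(alignment.reference_name, rows)


# ---------------------------------------------------------------------------
# Variant polarization

def annotate_ancestral_allele(variant: VariantRecord, ancestor: np.ndarray,
                              cutoff: float = 0.99) -> VariantRecord:
    """Set the AA field from an ancestral posterior vector.

    The most probable base is accepted as ancestral only when its posterior
    is at least ``cutoff``; otherwise AA is set to "N" so that only
    high-confidence sites enter downstream frequency analyses.
    """
    vec = np.asarray(ancestor, dtype=float)
    if vec.shape != (4,):
        raise ValueError("ancestral vector must have 4 entries")
    best = int(np.argmax(vec))
    variant.aa = BASES[best] if vec[best] >= cutoff else "N"
    return variant


def polarize_variants(variants: list[VariantRecord]) -> list[VariantRecord]:
    """Keep sites whose ancestral allele matches ref or alt; compute DAF.

    Multi-allelic records are rejected (the pipeline is biallelic-only);
    sites with AA = "N" or AA matching neither allele are dropped.
    """
    out = []
    for v in variants:
        if "," in v.alt:
            raise ValueError(f"multi-allelic record at {v.chrom}:{v.pos + 1}; "
                             "retain only biallelic substitution variants")
        if v.aa is None:
            raise ValueError("variants must be AA-annotated before polarization")
        if v.aa == "N" or v.aa not in (v.ref, v.alt):
            continue
        n = v.n_alleles
        if n == 0:
            continue
        alt_freq = v.alt_count / n
        v.daf = alt_freq if v.aa == v.ref else 1.0 - alt_freq
        out.append(v)
    return out
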