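"""Tree handling, Jukes-Cantor substitution model, fourfold-degenerate site
extraction, and maximum-likelihood branch-length fitting on a fixed topology.

The tree is stored in flat arrays (parent pointers, postorder) so the
Felsenstein pruning recursion can run vectorized over many alignment
columns or site patterns at once.  Under Jukes-Cantor the transition matrix
has the closed form

    P(same)      = 1/4 + 3/4 * exp(-4 t / 3)
    P(different) = 1/4 - 1/4 * exp(-4 t / 3)   (per target base)

with ``t`` the branch length in expected substitutions per site, and the
stationary (and root prior) distribution uniform over the four bases.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from io import StringIO
from typing import Sequence

import numpy as np
from Bio import Phylo
from scipy.optimize import minimize_scalar

from .genome_io import BASES, BaseRow, CdsFeature, ProbAlignment


class NewickError(ValueError):
    pass


class PhyloTree:
    """Rooted tree with named nodes and branch lengths, in flat-array form.

    Node 0 is the root; nodes are indexed so that ``postorder`` visits all
    children before their parent. Branch lengths are expected substitutions
    per site on the edge to the parent (nan for the root).
    """

    def __init__(self, names: list[str], parent: np.ndarray,
                 branch_length: np.ndarray):
        if len(set(names)) != len(names):
            raise ValueError("node names must be unique")
        self.names = list(names)
        self.parent = np.asarray(parent, dtype=np.int64)
        self.branch_length = np.asarray(branch_length, dtype=np.float64)
        n = len(names)
        self.children: list[list[int]] = [[] for _ in range(n)]
        roots = []
        for i in range(n):
            p = self.parent[i]
            if p < 0:
                roots.append(i)
            else:
                self.children[p].append(i)
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, found {len(roots)}")
        self.root = roots[0]
        neg = (self.branch_length < 0) & np.isfinite(self.branch_length)
        if np.any(neg):
            raise ValueError("branch lengths must be >= 0")
        # postorder via iterative DFS
        order: list[int] = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(self.children[v])
        self.postorder = order[::-1]
        self._index = {nm: i for i, nm in enumerate(self.names)}

    # -- basic queries ------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.names)

    def is_leaf(self, i: int) -> bool:
        return not self.children[i]

    @property
    def leaves(self) -> list[int]:
        return [i for i in range(self.n_nodes) if self.is_leaf(i)]

    @property
    def leaf_names(self) -> list[str]:
        return [self.names[i] for i in self.leaves]

    def index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise KeyError(f"no node named {name!r}") from None

    def length_of(self, name: str) -> float:
        return float(self.branch_length[self.index(name)])

    def with_lengths(self, lengths: np.ndarray) -> "PhyloTree":
        return PhyloTree(self.names, self.parent.copy(), np.asarray(lengths, float))

    def subtree_leaf_mask(self) -> np.ndarray:
        """(n_nodes, n_leaves) bool: which leaves descend from each node."""
        leaves = self.leaves
        pos = {v: j for j, v in enumerate(leaves)}
        mask = np.zeros((self.n_nodes, len(leaves)), dtype=bool)
        for v in self.postorder:
            if self.is_leaf(v):
                mask[v, pos[v]] = True
            else:
                for c in self.children[v]:
                    mask[v] |= mask[c]
        return mask

    # -- newick -------------------------------------------------------------
    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        return parse_newick(text)

    def to_newick(self) -> str:
        def fmt(i: int) -> str:
            label = self.names[i] if not self.names[i].startswith("_node") else ""
            if self.is_leaf(i):
                s = self.names[i]
            else:
                s = "(" + ",".join(fmt(c) for c in self.children[i]) + ")" + label
            if i != self.root and np.isfinite(self.branch_length[i]):
                s += f":{self.branch_length[i]:g}"
            return s
        return fmt(self.root) + ";"

    # -- surgery ------------------------------------------------------------
    def with_sibling(self, leaf_name: str, twin_name: str,
                     pair_name: str, eps: float = 1e-8) -> "PhyloTree":
        """Attach ``twin_name`` as a sibling of an existing leaf.

        The leaf is replaced by an internal node ``pair_name`` keeping the
        leaf's branch length; leaf and twin hang below it on branches of
        negligible length ``eps``.  Used to represent an equal-weight
        consensus haplotype (e.g. a reference sequence and its
        alternate-allele counterpart) during polarization.
        """
        i = self.index(leaf_name)
        if not self.is_leaf(i):
            raise ValueError(f"{leaf_name!r} is not a leaf")
        names = self.names + [pair_name, twin_name]
        n = self.n_nodes
        parent = np.concatenate([self.parent, [self.parent[i], i]])
        bl = np.concatenate([self.branch_length, [self.branch_length[i], eps]])
        # old leaf becomes child of the new internal node (index n)
        parent = parent.copy()
        parent[i] = n
        bl = bl.copy()
        bl[i] = eps
        # swap roles: index n is the internal pair node, n+1 the twin leaf
        names[n], names[n + 1] = pair_name, twin_name
        parent[n + 1] = n
        return PhyloTree(names, parent, bl)


def parse_newick(text: str) -> PhyloTree:
    """Parse a newick string with named internal nodes and branch lengths."""
    text = text.strip()
    if text.count("(") != text.count(")"):
        raise NewickError("unbalanced parentheses")
    if ";" in text and text.split(";", 1)[1].strip():
        raise NewickError("trailing garbage after ';'")
    try:
        clade = Phylo.read(StringIO(text), "newick").root
    except Exception as exc:
        raise NewickError(f"newick parse failed: {exc}") from exc
    names: list[str] = []
    parents: list[int] = []
    lengths: list[float] = []
    counter = [0]

    def visit(cl, parent_idx: int) -> None:
        idx = len(names)
        nm = cl.name
        if nm is None:
            nm = f"_node{counter[0]}"
            counter[0] += 1
        names.append(nm)
        parents.append(parent_idx)
        lengths.append(cl.branch_length if cl.branch_length is not None else np.nan)
        for ch in cl.clades:
            visit(ch, idx)

    visit(clade, -1)
    return PhyloTree(names, np.array(parents), np.array(lengths))


# ---------------------------------------------------------------------------
# Jukes-Cantor model

def jc_transition(t: float | np.ndarray, same: bool) -> float | np.ndarray:
    """JC transition probability after branch length ``t``.

    ``same=True`` gives P(no net change); ``same=False`` the probability of
    ending at one particular different base.
    """
    t = np.asarray(t, dtype=np.float64)
    if np.any(t < 0):
        raise ValueError("branch length must be >= 0")
    e = np.exp(-4.0 * t / 3.0)
    out = 0.25 + 0.75 * e if same else 0.25 - 0.25 * e
    return float(out) if out.ndim == 0 else out


def jc_message(partial: np.ndarray, t: float) -> np.ndarray:
    """Propagate a conditional-likelihood array (n, 4) through a JC branch."""
    pss = jc_transition(t, True)
    psd = jc_transition(t, False)
    s = partial.sum(axis=1, keepdims=True)
    return psd * s + (pss - psd) * partial


# ---------------------------------------------------------------------------
# Site patterns & pruning likelihood

@dataclass
class SitePattern:
    """Leaf-state assignment (codes 0-3, 4 = absent) with multiplicity."""

    states: tuple[int, ...]
    count: int = 1

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("multiplicity must be >= 1")


def patterns_from_columns(columns: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Collapse a (n_sites, n_leaves) state matrix to unique patterns + counts."""
    uniq, counts = np.unique(np.asarray(columns, dtype=np.int8),
                             axis=0, return_counts=True)
    return uniq, counts


def _leaf_partials(states: np.ndarray) -> np.ndarray:
    """(n_pat,) leaf states -> (n_pat, 4) conditional likelihoods.

    Absent leaves (code >= 4) contribute no information (all-ones)."""
    n = len(states)
    part = np.ones((n, 4), dtype=np.float64)
    obs = states < 4
    part[obs] = 0.0
    part[obs, states[obs]] = 1.0
    return part


def log_likelihood(tree: PhyloTree, patterns: np.ndarray,
                   counts: np.ndarray,
                   branch_length: np.ndarray | None = None) -> float:
    """JC log-likelihood of leaf patterns via Felsenstein pruning.

    ``patterns``: (n_pat, n_leaves) int codes in leaf order ``tree.leaves``;
    uniform root prior.
    """
    bl = tree.branch_length if branch_length is None else branch_length
    patterns = np.asarray(patterns, dtype=np.int8)
    counts = np.asarray(counts, dtype=np.float64)
    leaf_pos = {v: j for j, v in enumerate(tree.leaves)}
    partial: dict[int, np.ndarray] = {}
    logscale = np.zeros(patterns.shape[0])
    for v in tree.postorder:
        if tree.is_leaf(v):
            partial[v] = _leaf_partials(patterns[:, leaf_pos[v]])
        else:
            prod = None
            for c in tree.children[v]:
                msg = jc_message(partial.pop(c), float(bl[c]))
                prod = msg if prod is None else prod * msg
            # rescale to avoid underflow on deep trees
            m = prod.max(axis=1)
            m = np.where(m > 0, m, 1.0)
            logscale += np.log(m)
            partial[v] = prod / m[:, None]
    lik = partial[tree.root].mean(axis=1)  # uniform 1/4 prior
    with np.errstate(divide="ignore"):
        site_ll = np.log(lik) + logscale
    return float(np.sum(counts * site_ll))


def fit_branch_lengths(tree: PhyloTree, patterns: np.ndarray,
                       counts: np.ndarray, max_branch: float = 5.0,
                       tol: float = 1e-8, max_cycles: int = 100,
                       ) -> tuple[PhyloTree, float, list[float]]:
    """ML branch lengths on a fixed topology by cyclic 1-D optimization.

    Each branch is optimized in turn with bounded scalar maximization
    (tolerance 1e-8), cycling until the log-likelihood improves by less
    than ``tol`` or no branch moves.  On a two-leaf tree only the sum of
    the two branch lengths is identifiable; the ML sum is split equally.
    Returns (fitted tree, log-likelihood, trajectory).
    """
    patterns = np.asarray(patterns, dtype=np.int8)
    counts = np.asarray(counts, dtype=np.float64)
    informative = np.any(patterns < 4, axis=1)
    if not np.all(informative):
        warnings.warn("excluding all-absent site patterns")
        patterns, counts = patterns[informative], counts[informative]
    if patterns.shape[0] == 0:
        raise ValueError("no informative site patterns")
    bl = np.where(np.isfinite(tree.branch_length), 0.01, np.nan)
    branches = [i for i in range(tree.n_nodes) if i != tree.root]
    ll = log_likelihood(tree, patterns, counts, bl)
    trajectory = [ll]
    for _ in range(max_cycles):
        max_move = 0.0
        for b in branches:
            def neg(t: float, b=b) -> float:
                trial = bl.copy()
                trial[b] = t
                return -log_likelihood(tree, patterns, counts, trial)
            current = neg(float(bl[b]))
            res = minimize_scalar(neg, bounds=(0.0, max_branch),
                                  method="bounded",
                                  options={"xatol": 1e-8})
            if res.fun <= current:  # never step downhill in likelihood
                max_move = max(max_move, abs(float(res.x) - float(bl[b])))
                bl[b] = res.x
        ll_new = log_likelihood(tree, patterns, counts, bl)
        trajectory.append(ll_new)
        converged = (ll_new - ll < tol) or (max_move < 1e-9)
        ll = ll_new
        if converged:
            break
    else:
        raise RuntimeError(f"branch-length fit did not converge; last ll={ll}")
    # near-zero estimates snap to zero for the no-divergence case
    bl[np.isfinite(bl) & (bl < 1e-7)] = 0.0
    if len(branches) == 2 and all(tree.is_leaf(b) for b in branches):
        total = bl[branches[0]] + bl[branches[1]]
        bl[branches[0]] = bl[branches[1]] = total / 2.0
    return tree.with_lengths(bl), ll, trajectory


# ---------------------------------------------------------------------------
# Fourfold-degenerate site extraction

def _fourfold_prefixes() -> set[str]:
    """Dinucleotide prefixes whose codons encode one amino acid regardless
    of the third base (standard genetic code)."""
    from Bio.Data.CodonTable import standard_dna_table
    table = standard_dna_table.forward_table
    stops = set(standard_dna_table.stop_codons)
    out = set()
    for b1 in BASES:
        for b2 in BASES:
            codons = [b1 + b2 + b3 for b3 in BASES]
            if any(c in stops for c in codons):
                continue
            if len({table[c] for c in codons}) == 1:
                out.add(b1 + b2)
    return out


FOURFOLD_PREFIXES = _fourfold_prefixes()
_STOPS = {"TAA", "TAG", "TGA"}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def extract_4d_sites(alignment: ProbAlignment,
                     cds_features: Sequence[CdsFeature]) -> list[int]:
    """Alignment columns of fourfold-degenerate third codon positions.

    Degeneracy is judged on the reference sequence only; minus-strand CDS
    are reverse-complemented before codon reading.  Codons containing a
    reference gap/N are skipped, as are reference codons that are internal
    stops (with a warning).
    """
    ref = alignment.rows[alignment.reference_name]
    assert isinstance(ref, BaseRow)
    ref_seq = ref.to_string()
    coord = alignment.ref_coord_map
    ref_len = len(coord)
    columns: list[int] = []
    for cds in cds_features:
        positions = list(range(cds.start, min(cds.end, ref_len)))
        if cds.strand == "-":
            positions = positions[::-1]
        positions = positions[cds.frame:]
        for k in range(0, len(positions) - 2, 3):
            codon_pos = positions[k:k + 3]
            bases = []
            ok = True
            for p in codon_pos:
                ch = ref_seq[coord[p]]
                if cds.strand == "-":
                    ch = _COMP.get(ch, "N")
                if ch not in BASES:
                    ok = False
                    break
                bases.append(ch)
            if not ok:
                continue
            codon = "".join(bases)
            if codon in _STOPS:
                warnings.warn(f"internal stop codon on reference at {codon_pos[0]}")
                continue
            if codon[:2] in FOURFOLD_PREFIXES:
                columns.append(int(coord[codon_pos[2]]))
    return columns


def patterns_at_columns(alignment: ProbAlignment, tree: PhyloTree,
                        columns: Sequence[int],
                        require_all_present: bool = False,
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Leaf state matrix at the given alignment columns, collapsed to
    unique patterns with counts.  Gaps and Ns are coded as absent."""
    cols = np.asarray(columns, dtype=np.int64)
    mat = np.empty((len(cols), len(tree.leaves)), dtype=np.int8)
    for j, v in enumerate(tree.leaves):
        row = alignment.rows[tree.names[v]]
        if not isinstance(row, BaseRow):
            raise ValueError(f"leaf row {tree.names[v]!r} is not concrete")
        codes = row.codes[cols]
        codes = np.where(codes >= 4, 4, codes)
        mat[:, j] = codes
    if require_all_present:
        mat = mat[np.all(mat < 4, axis=1)]
    return patterns_from_columns(mat)


def branch_length_standard_errors(tree: PhyloTree, patterns: np.ndarray,
                                  counts: np.ndarray) -> np.ndarray:
    """Per-branch standard errors from the observed information.

    The curvature of the log-likelihood is taken numerically along each
    branch at the fitted lengths (other branches held fixed);
    SE = 1/sqrt(-d2l/dt2).  nan for the root.
    """
    patterns = np.asarray(patterns, dtype=np.int8)
    counts = np.asarray(counts, dtype=np.float64)
    bl = tree.branch_length
    se = np.full(tree.n_nodes, np.nan)
    for b in range(tree.n_nodes):
        if b == tree.root:
            continue
        t0 = float(bl[b])
        h = max(1e-5, 0.05 * t0)
        lls = []
        for t in (t0 - h, t0, t0 + h):
            trial = bl.copy()
            trial[b] = max(t, 0.0)
            lls.append(log_likelihood(tree, patterns, counts, trial))
        d2 = (lls[0] - 2 * lls[1] + lls[2]) / h ** 2
        se[b] = 1.0 / np.sqrt(-d2) if d2 < 0 else np.inf
    return se
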