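import itertools

import numpy as np
import pytest
from hypothesis import settings

from aqerscan.phylo_model import PhyloTree, jc_transition

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def three_leaf_tree() -> PhyloTree:
    """((h:0.1,c:0.1)hc:0.1,g:0.2)r;"""
    return PhyloTree(
        names=["r", "hc", "h", "c", "g"],
        parent=np.array([-1, 0, 1, 1, 0]),
        branch_length=np.array([np.nan, 0.1, 0.1, 0.1, 0.2]))


def random_tree(rng: np.random.Generator, n_leaves: int,
                max_bl: float = 0.5) -> PhyloTree:
    """Random rooted binary topology with uniform branch lengths."""
    next_id = [0]

    def build(k: int) -> dict:
        if k == 1:
            next_id[0] += 1
            return {"name": f"L{next_id[0]}"}
        split = int(rng.integers(1, k))
        return {"name": None, "children": [build(split), build(k - split)]}

    names, parents, lengths = [], [], []

    def flatten(node: dict, parent: int) -> None:
        idx = len(names)
        nm = node["name"] or f"I{idx}"
        names.append(nm)
        parents.append(parent)
        lengths.append(np.nan if parent < 0 else float(rng.uniform(0.01, max_bl)))
        for ch in node.get("children", []):
            flatten(ch, idx)

    flatten(build(n_leaves), -1)
    return PhyloTree(names, np.array(parents), np.array(lengths))


def _enumerate_assignment_likelihoods(tree: PhyloTree,
                                      leaf_states: dict[str, int],
                                      ) -> tuple[np.ndarray, dict[int, int]]:
    """Likelihood of every internal-state assignment, by explicit
    enumeration (uniform root prior; absent leaves marginalized out)."""
    internal = [v for v in range(tree.n_nodes) if not tree.is_leaf(v)]
    col = {v: j for j, v in enumerate(internal)}
    n_assign = 4 ** len(internal)
    grid = np.array(list(itertools.product(range(4), repeat=len(internal))),
                    dtype=np.int8).reshape(n_assign, len(internal))
    lik = np.full(n_assign, 0.25)
    for v in range(tree.n_nodes):
        if v == tree.root:
            continue
        t = float(tree.branch_length[v])
        p_same, p_diff = jc_transition(t, True), jc_transition(t, False)
        parent_states = grid[:, col[tree.parent[v]]]
        if tree.is_leaf(v):
            s = leaf_states.get(tree.names[v], 4)
            if s >= 4:
                continue
            child_states = np.full(n_assign, s, dtype=np.int8)
        else:
            child_states = grid[:, col[v]]
        lik *= np.where(child_states == parent_states, p_same, p_diff)
    return lik, col | {"grid": grid}  # type: ignore[operator]


def brute_force_likelihood(tree: PhyloTree, leaf_states: dict[str, int],
                           ) -> float:
    lik, _ = _enumerate_assignment_likelihoods(tree, leaf_states)
    return float(lik.sum())


def brute_force_posterior(tree: PhyloTree, leaf_states: dict[str, int],
                          node: str) -> np.ndarray:
    """Marginal posterior at one internal node by state enumeration."""
    v = tree.index(node)
    lik, col = _enumerate_assignment_likelihoods(tree, leaf_states)
    grid = col.pop("grid")
    joint = np.bincount(grid[:, col[v]], weights=lik, minlength=4)
    return joint / joint.sum()


def bh_adjust_oracle(pvals: np.ndarray) -> np.ndarray:
    """Independent sort-based Benjamini-Hochberg step-up adjustment."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj
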