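"""Seeded generators for synthetic inputs with the statistical structure the
analysis assumes: alignments evolved under a fixed tree with planted
high-divergence windows and indels, biallelic variants with
derived-allele frequencies under a scaled selection parameter, and
single-cell STARR-seq count matrices with planted active constructs.

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .genome_io import BASES, BaseRow, GenomicInterval, ProbAlignment, VariantRecord
from .phylo_model import PhyloTree, jc_transition
from .starr_activity import ConstructCounts


@dataclass
class SimulationTruth:
    """What the generator planted, for downstream validation."""

    seed: int
    planted: list[tuple[int, int, float]] = field(default_factory=list)
    target_branch: str | None = None
    indel_rate: float = 0.0
    gamma: float | None = None
    active_constructs: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Alignment simulation

def simulate_alignment(tree: PhyloTree, length: int,
                       indel_rate: float = 0.05,
                       planted: Sequence[tuple[int, int, float]] = (),
                       target_branch: str | None = None,
                       seed: int = 0,
                       reference: str | None = None,
                       indel_mean_len: float = 5.0,
                       ) -> tuple[ProbAlignment, SimulationTruth]:
    """Evolve sequences down the tree under Jukes-Cantor.

    The root sequence is uniform over {A,C,G,T}.  On each branch every
    site substitutes with probability 3/4*(1-exp(-4t/3)); inside planted
    intervals on ``target_branch`` the branch length is multiplied by the
    planted factor.  Deletions arrive as a Poisson number of events per
    branch (rate ``indel_rate`` events per substitution-unit branch length
    per base) with geometric lengths (mean ``indel_mean_len``), toggling
    presence; once absent in an ancestor a site stays absent below it.
    No insertions are generated, so alignment columns equal reference
    coordinates.

    Returns the leaf alignment (rows in tree leaf order, reference first)
    and the simulation truth.
    """
    for s, e, m in planted:
        if m < 1:
            raise ValueError("planted multipliers must be >= 1")
        if not (0 <= s < e <= length):
            raise ValueError(f"planted interval [{s}, {e}) outside sequence")
    iv = sorted(planted)
    for (s1, e1, _), (s2, _, _) in zip(iv, iv[1:]):
        if s2 < e1:
            raise ValueError("planted intervals overlap")
    if planted and target_branch is None:
        raise ValueError("planted intervals require a target branch")
    rng = np.random.default_rng(seed)
    target_idx = tree.index(target_branch) if target_branch else -1

    mult = np.ones(length)
    for s, e, m in planted:
        mult[s:e] = m

    root_seq = rng.integers(0, 4, size=length, dtype=np.int8)
    root_pres = np.ones(length, dtype=bool)
    leaf_rows: dict[str, BaseRow] = {}

    def evolve(node: int, seq: np.ndarray, pres: np.ndarray) -> None:
        for child in tree.children[node]:
            t = float(tree.branch_length[child])
            cseq = seq.copy()
            if t > 0:
                if child == target_idx and planted:
                    p_sub = 3.0 * jc_transition(t * mult, False)
                else:
                    p_sub = 3.0 * jc_transition(t, False)
                hit = rng.random(length) < p_sub
                n_hit = int(hit.sum())
                if n_hit:
                    offsets = rng.integers(1, 4, size=n_hit, dtype=np.int8)
                    cseq[hit] = (cseq[hit] + offsets) % 4
            cpres = pres.copy()
            if indel_rate > 0 and t > 0:
                n_events = rng.poisson(indel_rate * t * length)
                if n_events:
                    starts = rng.integers(0, length, size=n_events)
                    lens = rng.geometric(1.0 / indel_mean_len, size=n_events)
                    for s, l in zip(starts, lens):
                        cpres[s:s + l] = False
            if tree.is_leaf(child):
                codes = cseq.copy()
                codes[~cpres] = 4
                leaf_rows[tree.names[child]] = BaseRow(codes)
            else:
                evolve(child, cseq, cpres)

    evolve(tree.root, root_seq, root_pres)
    leaf_order = tree.leaf_names
    ref_name = reference if reference is not None else leaf_order[0]
    ordered = {ref_name: leaf_rows[ref_name]}
    for nm in leaf_order:
        if nm != ref_name:
            ordered[nm] = leaf_rows[nm]
    aln = ProbAlignment(ref_name, ordered)
    truth = SimulationTruth(seed=seed, planted=list(planted),
                            target_branch=target_branch,
                            indel_rate=indel_rate)
    return aln, truth


# ---------------------------------------------------------------------------
# Variant simulation

def stationary_daf_weights(gamma: float, n_alleles: int) -> np.ndarray:
    """Unnormalized stationary density of derived-allele frequencies at
    counts 1..n-1 under a scaled selection coefficient gamma.

    f(x) proportional to (1 - exp(-gamma (1-x))) / ((1 - exp(-gamma)) x (1-x))
    for gamma != 0, and 1/x under neutrality (gamma = 0).
    """
    if abs(gamma) > 100:
        raise ValueError("selection parameter magnitude > 100 is numerically "
                         "unsafe; rescale the model")
    i = np.arange(1, n_alleles)
    x = i / n_alleles
    if gamma == 0:
        return 1.0 / x
    num = -np.expm1(-gamma * (1.0 - x))
    den = -np.expm1(-gamma) * x * (1.0 - x)
    return num / den


def simulate_variants(n_sites: int, gamma: float = 0.0,
                      n_alleles: int = 1_002,
                      region: Sequence[GenomicInterval] | None = None,
                      chrom: str = "ref", region_length: int = 10_000_000,
                      seed: int = 0,
                      ) -> tuple[list[VariantRecord], SimulationTruth]:
    """Biallelic variants with derived-allele counts drawn from the
    stationary frequency density, placed uniformly (without replacement)
    in the given region.  The ancestral allele equals the reference
    allele, so DAF is the alternate-allele frequency."""
    if n_sites < 1:
        raise ValueError("need at least one site")
    rng = np.random.default_rng(seed)
    if region is None:
        region = [GenomicInterval(chrom, 0, region_length)]
    capacity = sum(len(r) for r in region)
    if capacity < n_sites:
        raise ValueError("region capacity below requested site count")
    weights = stationary_daf_weights(gamma, n_alleles)
    probs = weights / weights.sum()
    derived_counts = rng.choice(np.arange(1, n_alleles), size=n_sites, p=probs)
    # flat position index over the region blocks, sampled without replacement
    block_sizes = np.array([len(r) for r in region])
    flat = rng.choice(capacity, size=n_sites, replace=False)
    flat.sort()
    starts = np.cumsum(np.concatenate([[0], block_sizes]))
    out: list[VariantRecord] = []
    for j, (f, d) in enumerate(zip(flat, derived_counts)):
        b = int(np.searchsorted(starts, f, side="right")) - 1
        pos = region[b].start + int(f - starts[b])
        ref_i = int(rng.integers(0, 4))
        alt_i = int((ref_i + rng.integers(1, 4)) % 4)
        gts = np.zeros(n_alleles, dtype=np.int8)
        gts[rng.choice(n_alleles, size=int(d), replace=False)] = 1
        out.append(VariantRecord(
            chrom=region[b].chrom, pos=pos, ref=BASES[ref_i], alt=BASES[alt_i],
            genotypes=gts, vid=f"sim{j}", aa=BASES[ref_i],
            daf=float(d) / n_alleles))
    truth = SimulationTruth(seed=seed, gamma=gamma)
    return out, truth


# ---------------------------------------------------------------------------
# STARR-seq count simulation

def simulate_starr_counts(n_constructs: int,
                          active: Mapping[str, float] | None = None,
                          n_cells: int = 500,
                          nc_ids: Sequence[str] | None = None,
                          seed: int = 0,
                          mean_input: float = 1_000.0,
                          input_sigma: float = 0.4,
                          base_umi_rate: float = 0.2,
                          dispersion: float = 2.0,
                          n_cell_types: int = 1,
                          ) -> tuple[ConstructCounts, dict[str, str],
                                     SimulationTruth]:
    """Synthetic scSTARR-seq counts.

    Constructs are named ``cons000``...; negative controls default to the
    first four.  Input read counts are lognormal around ``mean_input``;
    per-cell output UMIs are negative-binomial (gamma-Poisson, shape
    ``dispersion``) with mean proportional to input x fold-effect, where
    fold-effects come from ``active`` (1.0 elsewhere, and always 1.0 for
    negative controls).  Cells are labeled round-robin with
    ``n_cell_types`` types.
    """
    rng = np.random.default_rng(seed)
    constructs = [f"cons{i:03d}" for i in range(n_constructs)]
    if nc_ids is None:
        nc_ids = constructs[:4]
    active = dict(active or {})
    for cid, fold in active.items():
        if cid not in constructs:
            raise ValueError(f"unknown active construct {cid!r}")
        if fold < 1:
            raise ValueError("fold effects must be >= 1")
        if cid in set(nc_ids):
            raise ValueError("negative controls cannot be active")
    folds = np.array([active.get(c, 1.0) for c in constructs])
    input_counts = np.exp(rng.normal(np.log(mean_input), input_sigma,
                                     size=n_constructs))
    mean_per_cell = base_umi_rate * (input_counts / mean_input) * folds
    lam = rng.gamma(dispersion,
                    mean_per_cell[:, None] / dispersion,
                    size=(n_constructs, n_cells))
    umis = rng.poisson(lam)
    cells = [f"cell{i:04d}" for i in range(n_cells)]
    labels = {c: f"type{i % n_cell_types}" for i, c in enumerate(cells)}
    counts = ConstructCounts(
        constructs=constructs, cells=cells, umi_counts=umis,
        input_counts=input_counts,
        negative_control=np.array([c in set(nc_ids) for c in constructs]))
    truth = SimulationTruth(seed=seed, active_constructs=dict(active))
    return counts, labels, truth
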