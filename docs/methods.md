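# Methods

## Model and procedure

### Substitution model

All likelihood computations use the Jukes–Cantor model: a single rate,
uniform stationary distribution, transition probabilities
P(same) = 1/4 + 3/4·e^(−4t/3) and P(per different base) = 1/4 − 1/4·e^(−4t/3),
with branch length t in expected substitutions per site. The root prior
is uniform (1/4 each) — with JC stationarity this is the canonical
choice, and it makes the likelihood independent of root placement on the
unrooted tree. Richer models (HKY, GTR, rate heterogeneity) are out of
scope: the screen consumes only a thresholded distance between posterior
vectors and is insensitive to refinements of this order at great-ape
divergence levels (~1% per stem branch).

### Branch-length fitting

`phylo_model.fit_branch_lengths` maximizes the pruning likelihood of
site patterns (fourfold-degenerate third codon positions in the intended
use) over branch lengths on a fixed topology, by cyclic bounded scalar
maximization (one branch at a time, SciPy bounded Brent, xatol 1e-8).
Convergence is declared when a full cycle improves the log-likelihood by
less than 1e-8 *or* moves no branch by more than 1e-9; the scalar
optimizer re-jiggles each coordinate by about its own tolerance per
cycle, so demanding much smaller likelihood increments would never
terminate on flat ridges. A two-leaf tree identifies only the sum of the
two branch lengths; the fitted sum is split equally and this is
documented behavior. Per-branch standard errors come from the numerical
curvature of the profile log-likelihood at the optimum.

Fourfold-degenerate status is judged on the reference annotation only
(the standard genetic code; codons whose first two bases fix the amino
acid). Leaves with gaps or Ns at a 4D column are coded *absent* and
marginalized out of the likelihood; requiring presence in all rows is
available as a flag (`patterns_at_columns(..., require_all_present=True)`)
but off by default, since short human-scale branches leave most patterns
informative even with a few absent rows.

### Ancestral presence and posteriors

A base exists at an internal node, per column, iff at least two of the
node's incident lineage directions — each child subtree, plus the
complement of the node's subtree reached through its parent — contain at
least one leaf with an aligned base. The root has no parent direction.
This is the "common origin" rule: one isolated leaf cannot conjure an
ancestral base. Ambiguity codes (N) count as absent (conservative).

Posteriors at present nodes are marginal probabilities under JC with the
fitted branch lengths, conditioning on present leaves only; absent
leaves contribute no likelihood term rather than acting as a fifth
state. The implementation is the standard inside–outside decomposition
of Felsenstein pruning, vectorized across columns, chunked (default
500,000 columns) for bounded memory, with per-column message
normalization for numerical stability. The outside pass is computed only
along root-to-target paths, since genome scans need two nodes, not all.
For genome-scale scans a float32 mode halves memory traffic; posteriors
agree with the float64 path to ~1e-7, far below the 0.8 decision
threshold they feed. Columns whose observed data has likelihood zero
under the model (possible only with hard-zero branch lengths and
conflicting leaves) fall back to an uninformative uniform message.

### Divergence screen

Between two node tracks: substitution iff both present and cosine
distance ≥ τ (default 0.8); one-sided presence runs count as single gap
events anchored at their first column. Windows are laid on *reference*
coordinates (default 500 bp, step 1); alignment columns inserted
relative to the reference fold onto the preceding reference base, so
events inside insertions are counted in the covering window. The
binomial trial count is the window length regardless of insertions, and
k is capped there.

Calibration tiles the reference with non-overlapping windows of width W
(default 10 Mb, clamped to the chromosome), drops windows with callable
fraction < 0.5 (callable = both nodes present), and takes the **maximum**
k/callable as p̂ — deliberately conservative, so that the screen's null
is anchored to the most divergent neutral neighborhood rather than the
genome average. For a non-reference lineage the rate is multiplied by
the ratio of that lineage's stem branch length to the reference stem.
Raw p-values are exact binomial upper tails (a lookup table over
k = 0..L); adjustment is Benjamini–Hochberg with m = number of evaluated
windows (overlapping windows by default; tiled windows via step = L).
Significant windows (p_adj < 3e-7 by default) merge when overlapping or
book-ended, recording peak event count and minimum adjusted p.

The separate distribution-analysis scan
(`confident_divergence_windows`) counts substitutions only, restricts to
columns where both posteriors have maximum ≥ 0.8, and keeps windows with
confident fraction > 0.9. These confidence filters apply *only* there;
the main screen counts every both-present column as callable.

### Population-genetic layer

Divergent sites are substitution columns mapped to reference
coordinates (gap events excluded, so uneven gap sizes cannot skew
proportions). Fixed/polymorphic partitioning intersects them with a
variant set; the 2×2 set-vs-reference table uses Pearson χ², df = 1,
without Yates correction — the intended regimes have large counts, and
the uncorrected statistic matches the worked 2×2 arithmetic exactly.
Proximity blocking accepts variants in seeded-shuffle order, keeping a
variant only if every retained same-chromosome variant is ≥ 10 kb away;
the output is maximal for its greedy order and deterministic per seed
(seeds 10/40/70 are the conventional replicate trio). Polarized spectra
bin derived-allele counts 1..n−1; unpolarized spectra fold to minor
counts. Reversion classification applies to polymorphic divergent sites
with DAF > 0.95: carriers of the ancestral allele are inspected at other
divergent sites within a context window (default 2,000 bp — the choice
is genuinely open; sensitivity is linear in the window only through the
density of nearby divergent sites, and the classification is invariant
to haplotype ordering); any ancestral-allele context ⇒ incomplete-sweep
haplotype, none ⇒ reversion candidate. Signal comparisons (e.g. local
mutation-rate tracks, with per-position totals precomputed as the sum of
the three substitution rates) use per-element means, Welch's t-test, and
Bonferroni across region sets.

### Overlap enrichment

Each query element of length w is modeled as independently uniformly
placed over all start positions where it fits inside a chromosome
without touching the excluded set. The per-element hit probability is
computed from the exact union of favorable start intervals (a naive sum
of per-block favorable spans would double-count starts when annotation
blocks sit closer than w). The total overlap count is then
Poisson-binomial; its pmf is computed by exact O(n²) dynamic-programming
convolution up to 5,000 elements and by normal approximation with
continuity correction beyond. Two-sided p = 2·min(lower tail, upper
tail, 0.5), capped at 1; Bonferroni by default, BH for GWAS-style
many-trait scans. The null is validated against a 20,000-placement
Monte-Carlo oracle and is super-uniform on elements drawn uniformly from
the background (placement without self-overlap induces slight negative
dependence, making the independent-placement null conservative).
Matched random region sets ("RAND") use the rounded mean length for
every element — only count and mean length are matched — placed without
crossing background block boundaries or overlapping each other.

### STARR-seq activity

UMI triples (cell, UMI, construct) are deduplicated by set cardinality.
score = (output UMIs / input reads) normalized by the mean such ratio
over negative controls, per scope (pseudobulk, or per cell-type label
supplied by the caller — clustering is out of scope). Negative-control
scores average exactly 1 per scope by construction, and scores are
invariant to uniform rescaling of all inputs or all outputs. If some
(not all) negative controls have zero output in a scope, add-one
smoothing is applied to negative-control outputs only, with a warning.
Significance: a gamma is fitted to negative-control scores by maximum
likelihood (method-of-moments fallback), and each construct gets the
right tail of the fitted gamma; raw and BH-adjusted columns are both
reported, since per-construct raw tails are the convention for small
construct panels. Pseudoreplicate binning assigns cells to k bins
(default 5) and errors, listing offending bins, if any bin has ≤ 1 read
of any negative control.

**Calibration caveat:** with the assay's 4-control design the gamma is
fitted to 4 points, which underestimates tail spread; the measured raw
false-positive rate at p < 0.05 is ~15% rather than the nominal 5%,
relaxing toward nominal as the control panel grows (~8% at 8 controls,
~7% at 20 in our simulations). The test suite asserts exactly this
behavior. Effect sizes of interest (≥ several-fold) are unaffected:
8-fold planted actives are detected in ≥ 95% of runs.

## Synthetic data: what it emulates, and what it does not

`simulate_alignment` evolves a uniform root sequence down the tree under
JC, with geometric-length deletions (mean 5 bp, rate 0.05 events per
substitution-unit branch length per base) toggling presence, and planted
intervals multiplying the substitution rate on one branch. It captures
exactly the statistical structure the screen consumes — column-wise
substitutions, one-event-per-gap-run counting, presence patterns — but
not alignment error, paralogy, context-dependent mutation (CpG),
insertions (columns equal reference coordinates except for deletions in
the reference row), or rate variation beyond the planted windows. A
passing screen therefore demonstrates correct inference *given* a sound
alignment, not robustness to misalignment.

`simulate_variants` draws derived-allele counts on n = 1,002 alleles
from the Wright–Fisher stationary density
f(x) ∝ (1 − e^(−γ(1−x))) / ((1 − e^(−γ)) x (1−x)) for γ ≠ 0 (1/x when
γ = 0) — the standard Poisson-random-field form for a scaled selection
coefficient — with uniform unique positions and ancestral = reference.
It has no linkage, demography, or mutation-rate heterogeneity; spectra
are exchangeable across sites.

`simulate_starr_counts` uses lognormal input depths (σ = 0.4 around a
mean of 1,000 reads) and gamma-Poisson (negative binomial, shape 2)
per-cell output UMIs with mean 0.2·(input/mean input)·fold per cell.
Negative controls always have fold 1. These defaults give each control
~100 UMIs across 500 cells, comparable variability to a well-powered
reporter screen, and are fixed study conditions, not tuning knobs.

## Problem sizes used in validation

Chosen to exercise every guarantee on one CPU in minutes, and stated
here as the package's own test design: posterior-vs-enumeration checks
on trees of 2–6 leaves × 200 columns (|Δ| < 1e-10); branch-length
recovery from 50,000 simulated 4D sites under the bundled 20-taxon tree
(each branch within 15% relative error or 3 SE); the planted screen on
one 20-Mb alignment (seed 7, five 500-bp windows at 15× the human-stem
rate, ~42 expected events each) plus twenty neutral 2-Mb replicates with
a 1-Mb calibration window (zero calls required); 1,000-instance oracle
checks for binomial tails (L ≤ 2,000, |Δ| < 1e-12) and BH; a
20,000-placement permutation band and 500 null replicates for
enrichment; 5,000 neutral variants for the 1/i spectrum; 100 seeded
STARR power runs at 500 cells.

## Numerical and design choices

- Coordinates are 0-based half-open throughout; VCF positions convert at
  the I/O boundary. Gap-event anchoring to the run's first column
  prevents double-counting across windows.
- "One minus the cosine distance" appears in some descriptions of this
  family of screens where "cosine distance" is meant; we use
  d = 1 − cosine similarity, substitution iff d ≥ 0.8.
- The pFASTA dialect (FASTA headers; per-column tokens `-`, a base, or
  four 6-decimal comma-separated floats) is this package's own
  serialization: human-diffable and bit-stable at desk scale.
- BH m counts evaluated windows; with the default step of 1 these are
  overlapping windows (maximal sensitivity), with step = L a tiling.
  Both are supported because the convention is genuinely ambiguous.
- The consensus-haplotype trick for polarization (a reference row and
  its alternate-allele counterpart attached as sibling branches of
  length 1e-8 under a pair node) is exposed generally:
  `PhyloTree.with_sibling(leaf, twin, pair_name, eps)`.
- Enrichment placement is uniform over the whole background, not
  conditioned on chromosome of origin; conditioning would need a
  per-chromosome capacity model the data does not obviously demand.
- N50 is the largest L with cumulative length of contigs ≥ L at least
  half the total.

## Known limitations

- The screen assumes the fixed species topology everywhere; incomplete
  lineage sorting regions violate this and are handled only downstream
  (enrichment against ILS-state annotations), not in the model.
- JC is a deliberate floor: no transition/transversion bias, no CpG
  hypermutability. Divergence thresholds inherit its scale.
- Gap events are presence toggles; no attempt is made to reconstruct
  indel history or distinguish insertion from deletion.
- The Poisson-binomial enrichment null treats elements as independent;
  real query sets with strong internal clustering will be slightly
  anti-conservative in the depletion direction.
- Branch lengths below ~1/(sites) are at the resolution floor of the
  fitter; they are reported but dominated by sampling error (hence the
  3-SE acceptance alternative).
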