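# Methods

This note records the models and procedures cladelink implements, the choices
made where the design was genuinely open, and what the synthetic data used in
the tests does and does not establish about real data.

## Tree substrate

Trees are rooted, with pre-order node ids assigned at parse time so every
enumeration (tables, layouts, resolved states) is deterministic. The Newick
reader is a strict recursive-descent parser: it reports the character offset
of the first error, rejects duplicate leaf labels and multi-tree files, keeps
underscores literal (no underscore-to-space conversion, matching FASTA-id
usage), supports single-quoted labels with `''` escaping, and distinguishes an
*absent* branch length from one equal to 0. Unrooted (basal-trifurcation)
input is accepted as a rooted polytomy; no rerooting is performed. Writing
formats lengths with `%.10g`, which makes write∘parse∘write byte-stable.
Distance operations (patristic distance, clade diameters) refuse to run over
an absent length rather than treating it as 0.

Per-clade statistics (leaf count, deepest-leaf depth, diameter, sum and
pairwise sum of leaf distances) are computed in one post-order pass; the
pairwise sums combine child aggregates in O(children²) per node instead of
building an O(n²) distance matrix. Tests verify the aggregates against an
all-pairs shortest-path oracle on the node graph.

## Metadata linking

The join is exact, case-sensitive string equality between leaf label and key
value — an automated join should not guess. Two documented accommodations:
`split_labels=True` matches on the label's first whitespace-delimited token
(the FASTA-header convention), and duplicate table keys are non-fatal (first
row wins, all duplicates listed in the link report). At most 9 fields may be
linked per pass; the cap is a named constant (`MAX_LINKED_FIELDS`) kept for
compatibility with the desktop lineage of this tool. Classification assigns
every leaf its field value or the reserved category `unlinked`, with a
lexicographically ordered legend, so the category sets always partition the
leaf set. Cross-reference search runs over the linked data only, never over
leaf labels.

## Clade clustering

The clustering concretises "group the tree by the evolutionary distance of
its branches" as: *the coarsest partition of the leaves into monophyletic
clades whose divergence is ≤ t*. Two divergence summaries are provided
because the choice is a genuine modelling degree of freedom:

* `max` (default) — clade diameter, the maximum within-clade patristic
  distance. Guarantees every pair inside a cluster is within t.
* `mean` — mean within-clade pairwise distance; more tolerant of single
  outlier tips.

The top-down pass gives maximality by construction (a cluster's parent clade
always exceeds t) and, for `max` linkage, provably yields the unique
minimum-cardinality qualifying partition — the property the tests check
against a brute-force enumeration of all monophyletic partitions on small
trees. Ties at the threshold qualify (≤). The default threshold is
0.25 × tree diameter; both the linkage and the effective threshold are echoed
in every output. With a relative threshold on a zero-diameter tree the
threshold is 0 and every leaf becomes a singleton — degenerate but
well-defined.

Collapsing a cluster replaces its clade by a leaf whose branch length is the
clade's stem length plus the mean clade-root-to-leaf depth, preserving the
members' average depth in the simplified tree. The alternative (keeping only
the stem length) was rejected because it discards all within-clade depth.

Purity (majority-category fraction, leaf-weighted overall) validates a
clustering against any linked categorical field; it is a validation statistic
only and plays no role in the algorithm.

## Parsimony reconstruction

`fitch` computes the minimum number of changes of an unordered character with
Hartigan's counting downpass, which handles polytomies exactly. `sankoff`
runs the general cost-matrix dynamic program; `CostMatrix.linear` builds the
ordered-character cost `|i − j|` from numeric state labels, and unit costs
reproduce the Fitch score (checked on every fixture). The per-node set of
*all* states attained by some minimum-cost reconstruction is computed by an
inside/outside pass (subtree cost + rest-of-tree cost == total score); both
scores and sets are verified against exhaustive enumeration of internal
assignments on small instances.

ACCTRAN/DELTRAN are implemented as a pre-order traceback: at each node the
candidate states minimise (cost from the parent's resolved state) + (subtree
cost), which preserves the optimal total; DELTRAN keeps the parent's state
whenever it is a candidate (changes drift tipward), ACCTRAN switches whenever
a differing candidate exists (changes are pulled rootward). The classic
definitions assume binary trees; the same per-child rule is applied
unchanged at polytomies, a documented generalization. All ties, including
the root's, break lexicographically by state label, so outputs are
bit-reproducible. Note the rules are local: with an ambiguous *root* the
lexicographic root choice, not the transformation rule, decides which
equally-parsimonious history is reported.

## Brownian-motion reconstruction

For a continuous character the ML ancestral values under Brownian motion
jointly maximise the Gaussian likelihood of all node values; this is the
weighted least-squares problem in which each edge pulls its endpoints
together with weight 1/length. The implementation solves the internal-node
Laplacian system directly (dense, fine for the tree sizes this package
targets), which makes every internal estimate a weighted average of its
neighbours and therefore confined to the observed leaf range. The root
estimate coincides with the GLS mean μ̂ = (1ᵀC⁻¹y)/(1ᵀC⁻¹1) where C is the
shared-path-length covariance; σ̂² = (y − μ̂1)ᵀC⁻¹(y − μ̂1)/n is the ML rate
(the 1/n estimator, biased low by (n−1)/n; with the 64-leaf trees used in
validation the bias is ~1.6 % and irrelevant next to sampling noise).
Conditional variances are σ̂² × the diagonal of the inverse internal-node
precision matrix. Zero-length branches are floored at 1e-9 × tree diameter
with a warning, since the edge weights diverge otherwise. The two-leaf closed
form ((1/ℓ_A)·x_A + (1/ℓ_B)·x_B)/(1/ℓ_A + 1/ℓ_B) and the star-tree arithmetic
mean are asserted exactly, and the general solver is cross-checked against
direct numerical likelihood maximisation.

## Phylogeography export

A resolved reconstruction is tabulated per edge: parent/child ids and states,
t_start/t_end as cumulative root-to-node path lengths (t_end − t_start is
exactly the child's branch length), and a change flag. Times are
branch-length units; no calendar calibration is attempted because none is
inferable from a tree alone. A gazetteer (`state,lat,lon`) geocodes both
endpoints; states without coordinates are listed as warnings, never fatal.
The GeoJSON export writes one LineString per flagged, fully geocoded
transition with the time bounds as properties — the static, reproducible
artifact behind animated map views.

## Rendering

Rectangular phylogram only: x = cumulative branch length (unit lengths if the
tree has none), leaf y = leaf index, internal y = mean of children. The SVG
writer is a pure function — no timestamps, no randomness — so identical
inputs are byte-identical; each leaf yields exactly one text element and each
edge one path, plus a root stub. Classification uses a fixed 9-colour
qualitative palette (cycling with a warning past 9 categories, consistent
with the 9-field cap); clusters are drawn as labelled boxes; cross-reference
hits as highlight circles.

## Synthetic data

The generators are pure functions of (config, seed) via numpy's `default_rng`
(no global state). Topologies are Yule (uniform random leaf split) or
balanced, with iid exponential branch lengths at scale 0.1
substitutions/site — a typical magnitude for intra-species viral trees.
Discrete characters evolve by an at-most-one-jump-per-edge process (change
probability 1 − exp(−rate·t), new state uniform among the others); continuous
characters by exact Brownian increments. The clustered fixture hangs k star
clades (pendants uniform in [d_in/4, d_in/2], so within-clade diameter ≤
d_in) on stems of length separation/2, guaranteeing between-clade distances
≥ separation: any threshold in (d_in, separation) recovers exactly k clusters
with purity 1 — the synthetic analogue of subtype discovery in a viral tree.
Dummy sequences are deterministic label-hash 60-mers; sequence *content* is
irrelevant to extraction, which is label-driven.

What passing on these fixtures does **not** show: robustness to real-data
messiness (label/key mismatches beyond the whitespace rule, rate variation
across lineages, non-Brownian trait evolution, clusters that are not cleanly
separated, unresolved or support-annotated trees). The estimators are exact
given their models; the fixtures only probe the models' own assumptions.

## Validation problem sizes

The test-suite and acceptance-script scales are the package's chosen
desk-scale validation conditions: 200 random trees (2–64 leaves) for
round-trip stability; 100 exhaustive-oracle parsimony instances (≤ 8 leaves,
≤ 3 states — enumeration is exact there); 100 brute-force clustering
instances (≤ 10 leaves, where all monophyletic partitions can be enumerated);
200 Brownian-motion replicates on a fixed 64-leaf Yule tree (root estimator
unbiased within 2 standard errors; σ̂² median relative error < 30 %, the
expected order of √(2/(n−1)) ≈ 18 % sampling noise at n = 64); and the
k = 5 × 8-leaf clustered fixture for recovery.
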