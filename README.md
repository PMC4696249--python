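# cladelink

Link tabular metadata and sequence files to phylogenetic trees, and work with
the result programmatically: classify and search leaves by data attributes,
partition a tree into its divergent clades and collapse them into a simplified
tree, reconstruct ancestral character states by parsimony or Brownian-motion
likelihood, export phylogeographic transition tables and GeoJSON, and render
deterministic SVG views.

It is aimed at the kind of analysis common in viral molecular epidemiology —
an HIV-1 gene tree whose leaves carry country, subtype and sampling metadata —
but nothing in it is virus-specific: any rooted Newick tree with branch
lengths plus a CSV keyed on the leaf labels works.

## What it computes

**Data linking.** A CSV table is joined onto the leaves by exact,
case-sensitive equality between the leaf label and a key column (up to 9
attribute fields per pass). The join produces a full report (matched leaves,
unmatched leaves, unmatched keys, duplicate keys), a per-leaf classification
by any categorical field, and exact-value cross-reference search. FASTA files
link the same way; the sequence subset under any clade can be extracted in
tree order.

**Clade clustering.** The tree is partitioned into the *maximal monophyletic
clades whose internal divergence is below a threshold t*: a single top-down
pass makes a node a cluster root iff its clade divergence ≤ t while its
parent's exceeds t. Divergence is summarised as the clade diameter
(max within-clade patristic distance, default) or the mean pairwise distance;
t is absolute or a fraction of the tree diameter (default 0.25). Each
cluster's clade can be collapsed to a single leaf `cluster_<id>_n<size>`
whose branch length preserves the members' mean root-to-leaf depth, and the
partition can be validated against any linked categorical field via purity.

**Ancestral reconstruction.** Discrete characters: Fitch parsimony
(Hartigan's generalization on polytomies) and Sankoff parsimony with an
arbitrary cost matrix — linear parsimony (cost `|i − j|`) for ordered numeric
states — with ACCTRAN/DELTRAN resolution of ambiguity and per-node sets of
all optimal states. Continuous characters: maximum-likelihood states under
Brownian motion, i.e. the 1/branch-length-weighted-average (GLS) solution,
with the ML rate estimate σ̂² and a conditional variance per node. A resolved
discrete reconstruction exports a per-edge transition table with
root-relative times, optionally geocoded through a `state,lat,lon` gazetteer
and written as GeoJSON LineStrings.

## Worked example

No input files are needed — the `fixtures` subcommand writes a synthetic
demo dataset (5 well-separated clades of 8 leaves each, with the matching
metadata table and dummy sequences):

```bash
$ cladelink fixtures --preset clustered --seed 1 --out-dir fix
wrote clustered fixture to fix
$ cladelink cluster --tree fix/tree.nwk --threshold 1.0 --out-prefix out
5 clusters at threshold 1 (linkage=max)
$ cladelink link --tree fix/tree.nwk --data fix/data.csv --key id --fields subtype --out report.csv
matched 40/40 leaves; 0 unmatched keys; 0 duplicate keys
$ head -3 out.clusters.csv
leaf,cluster,divergence,cluster_size
t1,1,0.19495565718,8
t2,1,0.19495565718,8
```

The clustering recovers exactly the 5 generating clades (each cluster's
divergence — here its clade diameter, ≈ 0.195 — sits below the 1.0
threshold while any parent clade exceeds it); `out.simplified.nwk` is the
5-leaf collapsed tree and `out.svg` the boxed visualization. The same
library calls are available in Python:

```python
from cladelink import (parse_newick, DataTable, link_dataset, classify,
                       cluster_tree, ClusterConfig, cluster_purity)

tree = parse_newick(open("fix/tree.nwk").read())
table = DataTable.from_csv("fix/data.csv", key_column="id")
ann = link_dataset(tree, table, ["subtype"])
clustering = cluster_tree(tree, ClusterConfig(threshold=1.0))
purity = cluster_purity(clustering, classify(ann, "subtype"))
print(clustering.n_clusters, purity.overall)   # 5 1.0
```

Ancestral reconstruction and phylogeography run the same way:

```bash
cladelink fixtures --preset discrete --seed 4 --out-dir fix2
cladelink asr --tree fix2/tree.nwk --data fix2/data.csv --key id \
    --field country --method fitch --resolve deltran --out-prefix asr
```

which writes per-node states, the per-edge transition table and the GeoJSON
export (when a `--gazetteer` is given).

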