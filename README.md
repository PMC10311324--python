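# l2unifrac

Phylogeny-aware beta-diversity with averages that stay biologically valid.

The classical (L1) UniFrac distance is the 1-Wasserstein distance between
two community profiles on a tree. Taking medians of profiles in
L1-aggregated space and projecting back can produce **negative
abundances** — so representative "average" samples cannot be formed under
that metric. This package implements the **L2 variant**: profiles are
pushed rootward in one post-order pass, each node's entry scaled by the
square root of its branch length, and distances are plain Euclidean norms
in the aggregated space. Under this metric the barycenter of a cohort is
exactly the component-wise mean of the profiles, hence always a valid
probability distribution.

Included:

- **`l2unifrac.tree`** — Newick parsing (via dendropy), taxonomic trees
  from lineage tables with reciprocal (1/depth) branch lengths, and the
  dense subtree-indicator matrix used as a brute-force oracle.
- **`l2unifrac.profiles`** — sample × feature TSV tables aligned to the
  tree's node order; mass on internal nodes is supported.
- **`l2unifrac.metric`** — O(N) streaming aggregation, its exact inverse,
  L1/L2 UniFrac distances, and pairwise distance matrices.
- **`l2unifrac.barycenter`** — L2 barycenters (environment
  representatives) and the L1-median construction that demonstrates the
  negativity failure.
- **`l2unifrac.diffabund`** — signed per-edge differential-abundance
  (flow) vectors whose L2 norm equals the distance, plus top-k summaries
  at a taxonomic rank.
- **`l2unifrac.analysis`** — k-means clustering directly in aggregated
  space (no pairwise matrix), PAM k-medoids on distance matrices,
  Fowlkes–Mallows evaluation, stratified splits, and
  nearest-representative classification.
- **`l2unifrac.synthetic`** — seeded generators for random trees and
  Dirichlet environment cohorts; everything is testable offline.

## CLI

All subcommands are deterministic given inputs and `--seed`; logs go to
stderr, results to files.

```sh
l2unifrac simulate --leaves 64 --envs 4 --per-env 50 --seed 0 --out-dir fixtures/
l2unifrac dist --tree fixtures/tree.nwk --profiles fixtures/profiles.tsv \
    --metric l2 --out dmat.tsv
l2unifrac aggregate --tree fixtures/tree.nwk --profiles fixtures/profiles.tsv \
    --p 2 --out agg.tsv
l2unifrac barycenter --tree fixtures/tree.nwk --profiles fixtures/profiles.tsv \
    --labels fixtures/labels.tsv --out reps.tsv
l2unifrac diffabund --tree fixtures/tree.nwk --profiles fixtures/profiles.tsv \
    --labels fixtures/labels.tsv --env-a env1 --env-b env2 \
    --rank leaf --rank-map ranks.tsv --top 10 --out flows.tsv
l2unifrac cluster --mode l2-space --k 4 --seed 0 --tree ... --profiles ... \
    --labels ... --out clusters
l2unifrac classify --train-frac 0.8 --seed 0 --tree ... --profiles ... \
    --labels ... --out classified
```

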