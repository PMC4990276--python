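# dhm — dendritic heat maps

A traditional heat map of clustered sequences commits to a single
clustering cutoff, and the story it tells can flip when that cutoff
changes. A **dendritic heat map (DHM)** instead shows the *same*
sequence set clustered at a whole ladder of fractional-identity cutoffs
(0.75, 0.76, …, 1.00 by default) as concentric rings of a radial
figure: the innermost ring is the most lenient cutoff, each ring
outward is 0.01 stricter, and because each cluster's angular range is
conserved in the clusters it splits into, the figure reads like a
dendrogram. Each cluster is coloured by the relative abundance of two
phenotype groups among its members, so you can see at which depth of
genotype divergence a phenotype imbalance appears, strengthens, or
flips sign.

The package is for anyone who wants to visualise group inequity across
clustering specificity levels — e.g. habitat or treatment preference
across taxonomic depth in amplicon data — and for studying how
clustering algorithms themselves shape such figures.

## What it computes

- **Grouping.** Each sequence belongs to `GROUP1` (GC ≤ 50%) or
  `GROUP2` (GC > 50%) by default — GC content is a convenient stand-in
  phenotype that correlates with genotype — or to a group given in a
  two-column `id<TAB>{1,2}` table. Identical sequences are dereplicated
  into one record with an abundance count.
- **Cluster ladders.** Four methods produce nested partitions over the
  cutoff range: bottom-up agglomerative clustering under *min* (single),
  *max* (complete) or *avg* (UPGMA) linkage, cut from one merge tree at
  every cutoff; or top-down *centroid* clustering, where greedy
  UCLUST-style assignment at the lowest cutoff is refined stepwise —
  each cluster re-clustered at the next cutoff — up to 1.0. Sequences
  are processed in a *staggered* order (alternating the two ends of a
  deterministic UPGMA guide order) so the most mutually distant
  sequences seed the centroids.
- **Bin response.** Each cluster's heat-map value is
  `r = log10((Group1 + 1)/(Group2 + 1))`; a global symmetric scale
  `M = max |r|` (shared across panels of a figure set) maps `r` into 23
  colour categories — 11 reds (GROUP1 excess), 11 blues (GROUP2
  excess), and white for exact neutrality.
- **Geometry.** Per ring, cluster wedge widths are proportional to
  abundance; children divide their parent's angular span exactly. A key
  wedge at the 0° (12 o'clock) position shows the two darkest palette
  extremes and separates the circle's two ends, which are the most
  distantly related clusters.
- **Simulators.** Two artificial datasets exercise the whole pipeline:
  a *mutation lineage* (100 sequences × 100 bp, one random substitution
  per sequence per iteration, 15 iterations, from an ancestor with
  exactly 50% GC) and *population growth* (each sequence duplicated
  once unchanged and once with a substitution per generation, 2^15
  sequences at generation 15). Both keep the two GC groups even by
  rejection sampling: a run is regenerated unless
  |Group1 − Group2| ≤ 20 sequences (lineage) or ≤ 5% of the total
  (growth) at the checked snapshot.

## Worked example

```python
from dhm import *

gs = simulate_mutation_lineage(seed=1)          # 16 snapshots, 100 x 100 bp
recs = dereplicate(gs.snapshots[5])             # mutation step 5
m = identity_matrix(recs)
order = guide_order(m)
ladder = build_divisive_ladder(recs, order=order, matrix=m)
layout = build_layout(ladder, order)
colours, M = colour_ladder(ladder)
render_svg(layout, colours, "dhm_step5.svg")
```

With seed 1 this prints/produces:

```
restarts used: 0
iteration 15 groups: GROUP1=54 GROUP2=46
mutation step 5: 100 unique sequences
clusters at 0.75: 1, at 1.00: 100
colour scale M = 0.6021
base cluster: 100 members, g1=56, g2=44, r=+0.1027, category=+2
```

i.e. after five substitutions all 100 sequences still cluster together
at identity 0.75 (innermost ring: one pale-red wedge, category +2 of
11, a mild GROUP1 excess of 56:44), while at identity 1.00 every
sequence is its own cluster; `dhm_step5.svg` shows the divergence
between those extremes ring by ring. `M = 0.6021` means the darkest
hue anywhere in this panel corresponds to |log10 ratio| = 0.6021.

The same pipeline is available from the shell:

```
dhm simulate lineage --seed 1 --out-prefix out/lineage
dhm cluster --fasta out/lineage_5.fasta --method centroid \
    --ladder-out out/ladder.tsv --order-out out/order.txt
dhm render --ladder out/ladder.tsv --order out/order.txt \
    --svg-out out/dhm_step5.svg --circos-out out/circos
```

`dhm pipeline --config cfg.yaml` runs all three stages for a set of
snapshots with a shared colour scale. Circos input files (karyotype +
one heat-map track per ring + conf template) are emitted for users who
prefer Circos rendering; the tool itself is never invoked.

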