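# Methods

## The model

A dendritic heat map (DHM) joins two classical displays. Clustering a
sequence set at a single identity cutoff and colouring each cluster by
the relative abundance of two groups gives one heat map; repeating this
at every cutoff of a ladder and stacking the results as concentric
rings — with each cluster's angular range conserved in the clusters it
splits into — recovers the branching structure of a dendrogram while
keeping a heat map at every level. The displayed quantity per cluster
is the *bin response*

    r = log10((Group1 + 1) / (Group2 + 1))

over the cluster's group abundances. The +1 smoothing keeps r finite
for one-sided clusters; the log keeps small, strongly skewed clusters
visible next to large ones and makes the scale antisymmetric under
swapping the groups. A global scale M = max |r| maps responses into 23
categories (±11 hues plus white); only r = 0 is white, |r| = M is the
darkest hue, and when several panels form a figure set M is taken over
all of them so equal hues mean equal responses across panels.

## Clustering methods

All four methods consume fractional identities — matching positions /
length for equal-length sequences; for unequal lengths, matching
columns over alignment columns of a global alignment with fixed scores
(match +1, mismatch −1, gap −2, no end-gap discount, traceback ties
preferring diagonal then vertical). The cutoff ladder defaults to
0.75–1.00 in steps of 0.01 (26 levels); identity-vs-cutoff comparisons
use ≥ semantics (meeting the cutoff joins) with a 1e-9 slack that
absorbs float rounding in averaged linkage values without conflating
genuinely distinct ratios of small integers.

**Bottom-up.** One agglomerative merge tree per linkage — *min*
(single: highest cross-pair identity), *max* (complete: lowest), *avg*
(UPGMA: unweighted mean over all cross pairs, maintained exactly by the
size-weighted recurrence) — is cut at each cutoff by applying exactly
the merges whose linkage identity meets it. Since all three linkages
are monotone, cutting one tree at 26 thresholds is equivalent to 26
independent per-cutoff runs (the tests verify this against a naive
reference that regrows each partition from scratch) and guarantees that
the partitions nest, which the radial figure requires.

**Top-down.** Greedy centroid clustering processes sequences in order:
the first founds a cluster and becomes its centroid; each later
sequence joins the centroid of highest identity if that identity meets
the cutoff (ties to the earliest-founded cluster) or founds a new
cluster. Level 0 clusters the whole set at the lowest cutoff; each
subsequent level independently re-clusters every cluster at the next
cutoff, so nesting holds by construction. The processing order is the
*staggered* order — alternating ends of the guide order — so the most
mutually distant sequences are seen first and become centroids before
any sequence could be attached to the wrong side of a future split.
Within a parent cluster the staggered order is the full-dataset
staggered order restricted to the members; recomputing a per-cluster
order from a per-cluster matrix would re-introduce the all-pairs cost
the top-down method exists to avoid, and experiments during development
showed no structural difference on the simulated data.

**Guide order.** Where the original workflow ordered sequences by a
multiple-alignment tree output, this package computes a UPGMA leaf
order on 1 − identity directly: the data the package targets is
ungapped and equal-length, and the order's only role is arranging
clusters within rings (membership never depends on it). Tie-breaks are
fully deterministic: merge the pair with the highest identity, ties to
the lexicographically smallest pair of smallest original indices, and
each internal node places the child containing the smallest original
index first — so an all-tie matrix preserves input order, and repeated
runs are bit-identical.

A deliberate consequence of determinism everywhere (tie-breaks, greedy
ordering, restart seeding): fixed inputs and seed give byte-identical
FASTA, TSV and SVG outputs.

## Simulators

Two generators produce the study datasets. Both draw substitutions by
choosing a position uniformly and replacing its base with one of the
other three uniformly, so repeat hits and reversions are possible, and
both label sequences GROUP1/GROUP2 by GC ≤ 50% / > 50% evaluated in
integer arithmetic (2·GC vs length), making the boundary exact.

* *Mutation lineage* — n_seqs = 100 sequences of length 100, identical
  at iteration 0 to an ancestor with exactly 50 G/C positions; each of
  15 iterations applies one substitution to every sequence, so events
  per sequence equal the iteration index.
* *Population growth* — one ancestor; each of 15 generations replaces
  every sequence by an unchanged copy plus a once-substituted copy
  (2^g sequences at generation g). The ancestor defaults to exact 50%
  GC: with the GC random walk centred on the boundary the two groups
  are near-even on average, whereas an off-boundary random ancestor
  makes the 5% evening bound effectively unreachable.

**Group evening** is rejection sampling: a run that violates its bound
(absolute |Δ| ≤ 20 for the lineage set; fractional |Δ| ≤ 5% of total
for growth; equality passes, only strictly exceeding restarts) is
discarded and regenerated with seed + restart-index, up to 1000
attempts. The bound is checked at the final snapshot by default. A
per-snapshot check cannot be the operative rule for these datasets: at
iteration 0 the lineage set has all 100 sequences in GROUP1 (imbalance
100), and the ≤-boundary asymmetry keeps early iterations far above
the bound (the boundary mass stays in GROUP1), so `EVERY_SNAPSHOT`
(which starts at snapshot 1) is available but not default. Measured
pass rates at the defaults are ≈ 76% per lineage attempt and ≈ 19%
per 15-generation growth attempt, so the 1000-attempt budget is
conservative by orders of magnitude.

For a fixed length n over b bases, unbounded mutation saturates at
exactly b^n distinct sequences — the theoretical endpoint cluster
distribution, exposed as an exact big-integer computation.

## Geometry and rendering

Angles are degrees clockwise from 12 o'clock. The key wedge (default
12°, configurable) is centred at 0°; the remaining 360° − wedge is
divided per ring proportionally to cluster abundance (or unique count,
via `width_by`), children exactly partitioning their parent's span.
Rings have uniform thickness between an inner radius (default 15% of
the outer) and the rim, innermost = lowest cutoff. Geometry is exact in
the data model; sectors thinner than 0.25 px receive a minimum stroke
at render time only. The wedge is drawn radially split into the two
darkest palette extremes (inner = deepest red, outer = deepest blue).

The default palette interpolates linearly in RGB from near-white to
#67001F (reds) and to #053061 (blues) — Brewer-inspired endpoints; the
published figures used unpublished RGB values, so these defaults are
explicit substitutes and any 2×11 ramp can be supplied in the config.
The log base is 10; category assignment depends only on r/M, so the
base affects exported values, not colours.

## Numerical and degenerate cases

* Ambiguity codes and gaps are rejected, not coerced — identity
  semantics for them are undefined here.
* An all-neutral map (M = 0) renders white rather than erroring.
* A single-sequence input yields one singleton cluster per ring and a
  full-arc figure.
* `category_of` uses half-open bins `sign(r)·min(11, ⌊|r|/M·11⌋ + 1)`:
  only exact zero is white; a dense sweep of [−M, M] containing 0
  realises all 23 categories.

## What the tests do and do not show

The simulated data is equal-length, ungapped, substitution-only
(no indels, selection, recombination or realistic substitution-model
rates), with a phenotype — GC class — forced to correlate with
genotype. Passing tests therefore demonstrate the correctness of the
clustering/geometry/colour machinery and the simulators' stated
guarantees, not that real amplicon or transcript datasets will produce
informative DHMs; real data enters through FASTA plus an external
group table and inherits only the machinery's guarantees. Problem
sizes in the suite: full-size lineage runs (100 × 100 bp, 15
iterations), growth clustered at generation 12 (4096 sequences,
~4000 unique) for the top-down ladder, and 200 random ≤10-sequence
instances for oracle equivalence against naive re-implementations —
sizes chosen as the smallest that exercise every code path at depth.

One ordering claim common in informal descriptions is deliberately not
asserted: average-linkage partitions do not in general refine, nor are
they refined by, complete-linkage partitions at the same cutoff — both
directions fail on small counterexamples. What is provable and tested
is that single linkage is coarsest: every avg- or max-linkage merge at
identity ≥ c implies a cross edge ≥ c, hence single-linkage
connectivity at c.

## Known limitations

* All-pairs identity and the O(n²)-per-merge agglomeration make the
  bottom-up methods and the guide order impractical beyond ~10^4
  unique sequences; the top-down method avoids the matrix for
  clustering but currently still uses it for the guide order.
* The SVG renderer draws geometry only (no labels or legends beyond
  the key wedge); the Circos export is a functional template, not a
  replica of any particular published configuration.
* Unequal-length identity uses one fixed scoring scheme; it is a
  documented internal definition, not an emulation of any external
  tool's identity formula.
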