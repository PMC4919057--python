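# Methods

## Coordinates and overlap

Every interval in the package is 0-based half-open `[start, end)`, the
BED convention, normalized at the readers. Overlap means sharing at
least one base: bookended intervals (`[100,200)` and `[200,300)`) do
not overlap and do not merge (a `merge_bookended` flag relaxes this for
node construction). Variants are 1-bp intervals `[pos, pos+1)`, so a
variant sitting exactly on a node's `end` coordinate misses it.
Chromosome names are compared as exact strings; `normalize_chrom`
converts between `chr1` and `1` styles when inputs are mixed.

## Network construction

Input interactions are anchor pairs with a PET (paired-end tag) support
count; anchors are canonically ordered on read, and inter-chromosomal
(trans) interactions are retained and flagged rather than dropped.

Two node definitions:

1. **Anchor merging** — nodes are the maximal unions of overlapping
   anchors. Every anchor is then contained in exactly one node.
2. **Peak-defined nodes** — an open-chromatin peak set is merged into
   disjoint intervals; each merged peak overlapping at least one anchor
   becomes a node. Anchors overlapping no peak are unmapped, and their
   interactions are filtered — the peak set acts as a false-positive
   filter. An anchor spanning several peaks fans out to all of them:
   the interaction contributes an edge for every (node of anchor 1) ×
   (node of anchor 2) pair of distinct nodes. We chose the fan-out
   (permissive) reading over best-overlap assignment because nothing in
   the data says which peak the contact belongs to; the choice only
   matters for anchors wider than the peak spacing.

Edges aggregate all interactions landing on one node pair:
`interaction_count` (+1 per interaction) and `pet_count` (+PET). The
stored graph is simple — interactions with both anchors in one node are
*self-loops*, dropped from the edge set but tallied, because the
downstream centralities and hop-distance semantics presuppose a simple
graph. A `min_pet` threshold (default 1, i.e. no filtering, since
upstream callers differ in how much filtering they already did) is
applied before node definition.

Construction bookkeeping satisfies the conservation identity

    input = used + pet_filtered + self_loop + unmapped

which the test suite asserts under every combination of approach and
filter. Connected components are labelled by BFS, numbered by their
smallest node id for determinism.

## Centralities

All distances are hop counts; PET weights are evidence, not metric
lengths, so they never enter shortest-path computations.

* **degree** — incident edge count.
* **betweenness** — Brandes shortest-path betweenness with fractional
  credit among tied shortest paths, each unordered pair counted once.
  Reported unnormalized (raw path counts match the verbal definition);
  an optional normalization divides by `(k−1)(k−2)/2` within each
  component of size k.
* **closeness** — `(k−1)/Σd` within the node's component; isolated
  nodes score 0. Component scoping keeps the measure comparable inside
  each connected piece of a highly fragmented chromatin network.
* **harmonic** — `(1/(N−1))·Σ_{u≠v} 1/d(v,u)` over the whole network
  with `1/∞ = 0`; this is the standard well-defined closeness analogue
  on disconnected graphs.

The graph routines behind these are networkx's; the test suite checks
them against an independent exhaustive BFS/path-enumeration oracle on
random graphs (n ≤ 12), where full enumeration is feasible.

## Target discovery

Sources are nodes carrying a source annotation (typically variants);
targets are nodes carrying gene promoters. The promoter of a gene is
`[TSS − flank, TSS + flank + 1)` with flank = 2000 bp by default — "2 kb
up/downstream" read as symmetric about the TSS base, with the +1
keeping the TSS base itself inside the window on both strands. The
window convention is a documented constant, not an inference.

For every source–target pair within `max_dist` hops (default 4) we keep
*all* tied shortest paths (memory-guarded by a per-pair cap of 1000
with a warning). A gene's distance is the minimum hop distance over all
its promoter-bearing nodes and all sources; genes at ≤ 1 hop are
**direct** targets (including distance 0, gene in the variant's own
node), genes at 2–4 hops **indirect**, genes farther are excluded. The
2–4 band is a parameter; 4 is the default upper bound. Counting each
gene once at its minimum distance (rather than once per node or per
path) avoids double-counting genes with several annotated promoters.

The **nearest-TSS baseline** assigns each variant to the gene(s)
minimizing `|pos − TSS|` on its chromosome, reporting all ties; it is
the linear-genome comparator for the network-based target lists.

## Enrichment statistics

For two annotation classes A and B on the nodes, the observed statistic
is the number of edges with one endpoint in A and the other in B (each
edge counted once; A = B counts within-A edges).

**Theoretical null.** Each edge is treated as an independent uniform
draw of an unordered node pair. The per-edge probability of an A–B pair
is exact enumeration:

    p = (n_a·n_b − o − C(o,2)) / C(N,2),   o = |A ∩ B|

which reduces to `n_a·n_b/C(N,2)` for disjoint sets and `C(n_a,2)/C(N,2)`
for A = B. The one-tailed p-value is the exact binomial upper tail
P(X ≥ observed), X ~ Bin(|E|, p). This ignores the degree structure of
the real graph — it is the simplest expected-frequency model, stated
here as *this package's* null; degree-preserving nulls are out of scope.

**Permutation null.** Annotation labels are pushed through a uniform
random permutation of the node ids — preserving |A|, |B| and |A ∩ B|,
never rewiring edges — and the statistic recounted; the p-value is the
add-one estimator `(1 + #{permuted ≥ observed})/(n_perms + 1)`, bounded
below by `1/(n_perms+1)` so it is never 0. The add-one estimator is
slightly conservative when the discrete count statistic has heavy ties;
the calibration suite therefore uses conditions where the statistic has
enough spread (ER(100, 0.2) graphs, two disjoint 50-node label sets,
count sd ≈ 15) for the p-value distribution to be indistinguishable
from uniform by a KS test over 500 replicates of 200 permutations.

When several annotation pairs are tested together, Benjamini–Hochberg
FDR columns are added; multiple-testing correction across pairs is an
extension of the single-pair tests.

**Gene-list enrichment.** Discovered target genes versus a curated
reference list over a gene universe, one-tailed (greater) Fisher's
exact test. The universe defaults in callers to all genes annotated
onto the network and is always explicit, because the background choice
dominates the result.

## Synthetic data

The generator emulates desk-scale versions of the study inputs: BEDPE
interactions with geometric PET counts (heavy-tailed tag support),
open-chromatin peaks, variant tables, refGene-style gene tables, gene
lists and gene-pair lists. Layout: 1 kb node loci on a 6 kb pitch
across three toy chromosomes, so a ±2 kb promoter cannot straddle two
loci. Anchors are random sub-intervals of a locus constrained to
contain its midpoint, which guarantees that anchor merging reconstructs
exactly one node per locus and that both construction approaches yield
the same topology. Random components are spanning trees plus
density-controlled extra edges; planted variant→gene paths get
dedicated path-graph components, so their hop distances are exact by
construction. Background variants and genes are placed at inter-locus
gap centers, overlapping no node: planted target counts are exact.

Defaults (4 random components of 3–6 nodes, edge density 0.3, geometric
PET p = 0.4, anchor widths 200–800 bp, 10 background variants, 15
background genes, 5 decoy peaks, two planted paths at hops 1 and 3) are
a realistic miniature of a sparse ChIA-PET network: most components are
small, most node pairs are unconnected, and PET support is dominated by
low counts. What the fixture does **not** emulate: genomic distance
decay of contact frequency, anchor density heterogeneity, trans
contacts, and shared promoters between genes — so passing tests
demonstrate algorithmic correctness, not biological fidelity on real
libraries.

The acceptance script scales this to 30 random components of 4–8 nodes
plus 8 planted paths (two each at hops 1–4, ~190 nodes), with 1000
permutations for the enrichment test and a 200-replicate null
calibration — sizes chosen to exercise every code path at interactive
runtimes.

## Numerical and degeneracy choices

* Empty networks (everything filtered) are valid and warn rather than
  raise; empty peak sets likewise.
* A missing PET column defaults to 1 with a warning (dialects differ).
* Betweenness/closeness/harmonic are exactly 0 for isolated nodes; a
  single-node network has harmonic 0 by convention.
* Component labels, node ids, overlap results and CSV row orders are
  all deterministically sorted; identical seeds give byte-identical
  generator output.
* Binomial and hypergeometric tails are computed by scipy's exact
  routines; the test suite cross-checks them against direct summation.

## Known limitations

* The theoretical enrichment null is degree-blind; hub-heavy networks
  will show inflated binomial significance relative to the permutation
  test (which conditions on the observed graph and is the safer
  default).
* Fan-out of wide anchors across multiple peaks can inflate edge counts
  for coarse peak sets; use `min_pet` or tighter peaks if this matters.
* Shortest-path enumeration is exponential in the number of ties; the
  per-pair cap truncates pathological cases (with a warning) rather
  than exhausting memory.
* Interaction *calling* (from raw reads) and Hi-C matrix normalization
  are upstream concerns and out of scope.
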