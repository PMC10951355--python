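# Methods

## Scope and model

`icdomain` analyses protein-directed chromatin-conformation (HiChIP) data
at the level of a binned interaction graph.  The genome is tiled into
fixed-size bins (10 kb by default); every bin involved in at least one
significant loop call is a node, and two nodes are joined by an edge when
their regions interact, weighted by the pair's *connectivity* — the number
of times the pair was sequenced in a contact.  All coordinates are 0-based
half-open (BED convention), enforced by validators at parse time.  Loop
tables are consumed in a FitHiChIP-style BEDPE dialect already filtered (or
filterable) to significant interactions; loop calling itself is out of
scope.

Two vocabularies attach to nodes:

* **Element class.**  Promoters are windows from 2.5 kb upstream to 100 bp
  downstream of the TSS (mirrored on the minus strand:
  `[tss − down, tss + up)`).  Regulatory elements (enhancers) are
  accessibility peaks that do not fall within a 1.5 kb window of any
  promoter; the window extends the peak symmetrically before the overlap
  test, which is equivalent to extending the promoter for a binary overlap
  decision.  A bin overlapping both a promoter and an enhancer is classed
  P (precedence P > E > other), consistent with promoter-overlapping peaks
  being excluded from the enhancer class in the element definition.
* **Chromatin state.**  Each bin receives exactly one of eleven states by
  a fixed precedence hierarchy: SuperEnhancer ≻ BroadPeak ≻ ActivePromoter
  ≻ ActiveEnhancer ≻ WeakPromoter ≻ WeakEnhancer ≻ InactivePoisedPromoter
  ≻ Insulator ≻ PolycombRepressed ≻ Heterochromatin ≻ Others.  Ties within
  a rank (several same-rank segments overlapping one bin) are resolved by
  the largest overlap and logged; bins overlapping nothing are Others.

## Degree statistics

Degree is the unweighted number of connections of a node; weighted degree
is reserved for gene connectivity (below), keeping "degree" and
"connectivity" distinct.  Contact-class subnetworks (P-P, E-E, P-E) keep
only edges whose endpoint classes match the pair; nodes of class "other"
remain in the full network (they contribute to average degree and
components) but are excluded from the class reports.  Distributions are
compared with the Kruskal–Wallis test (omnibus) and pairwise two-sided
Mann–Whitney U tests, both asymptotic with tie correction; exact
small-sample p-values are not needed at network scale.

## CRE-removal permutation test

To ask whether the nodes containing cis-regulatory elements of interest
contribute disproportionately to connectivity, the observed statistic is
the average degree 2|E|/|N| after removing every CRE-overlapping node (the
average is taken over remaining nodes; this convention is recorded in the
output metadata).  The null removes an equal number of nodes sampled
uniformly without replacement from all nodes — the CRE nodes themselves
are not excluded from the pool — 1000 times by default.  The empirical
p-value is the fraction of permutations whose average degree falls
*strictly below* the observed value; ties are not counted and no +1
smoothing is applied, so p = 0 is reportable and logged as "< 1/n_perm"
(a `count_ties` flag provides the conservative at-or-below variant).  An
`exhaustive` mode enumerates all C(|N|, k) removal sets; the sampled
p-value converges to the exhaustive one, which the test suite checks on a
hand-enumerable four-node network.

## Connectivity–expression integration

Gene connectivity sums contact counts over all edges incident to any bin
carrying the gene's promoter.  Genes absent from the network are dropped
rather than assigned zero (a documented choice; isolated promoter bins do
score 0).  Genes are ranked into ten connectivity deciles — ties broken by
gene id so the split is deterministic, with near-equal bin sizes — and for
each decile the probability that a gene's transcript count exceeds the
population mean (taken over the binned gene set) is computed twice: as the
direct conditional frequency and through Bayes' theorem
P(count>mean | perc) = P(perc | count>mean)·P(count>mean)/P(perc).  The
two must agree to numerical precision (the decomposition is an identity;
the dual computation is an internal consistency check, asserted to 1e-12
in the tests), and the direct value is reported.

Consensus k-means (default k = 3, 10 repeats) clusters per-gene z-scored
expression rows: each repeat runs seeded k-means from one initialization; a
majority co-assignment matrix defines the consensus and, among repeats
agreeing with it on at least half of all gene pairs, the lowest-inertia
partition is returned with labels renumbered by ascending cluster mean of
the first sample.  The consensus rule is this package's own deterministic
construction.  Zero-variance rows are dropped with a warning before
z-scoring.

Single-cell signature enrichment is the per-cell median expression over a
gene set (default: the 150 genes most expressed in the re-stimulated
primed condition per response class), and signatures are compared by
Pearson correlation over cells.

## Memory classification and iCDs

Nascent RNA across three conditions (naive vehicle, naive stimulated,
primed stimulated) is spike-in normalized (raw / per-sample factor),
replicates are averaged per condition, and two log2 fold changes are
formed with a pseudocount (default 0.1): the naive response
lfc_r = log2((naive_stim+ps)/(naive_veh+ps)) and the primed amplification
lfc_m = log2((primed_stim+ps)/(naive_stim+ps)).  A gene is responsive when
lfc_r > 0.5 and memory when additionally lfc_m > 0.5; the two-threshold
rule makes the cut-off explicit and parameterizable.

An iCD is the connected component containing a gene's promoter bin,
restricted to the promoter's chromosome, with nodes carried in genomic
order.  iCD community structure is computed by seeded Louvain modularity
optimization on a layered graph: the iCD's weighted edges plus a chain
linking genomically adjacent bins (default chain weight 1, the minimum
contact count), realizing the two information layers (interaction
structure and sequential genomic order).  A nested two-level output is
produced by re-clustering interaction edges within each coarse community;
bins connected inside their community only through the adjacency chain are
merged with a chain neighbour rather than split off.  Louvain replaces a
nested stochastic block model here because a seeded, library-independent
deterministic contract was prioritized over posterior equivalence with any
particular SBM implementation; nodes are relabelled to genomic-order
integers before community detection so results do not depend on the
interpreter's hash randomization.

## Erosion and chromatin-state strength

Thresholds are the 10th–90th percentiles (nearest rank, no interpolation —
contact counts are integers) of the global multiset of pair
connectivities.  At each threshold, edges with weight below it are removed
from every iCD; a region (node) survives if it keeps at least one incident
edge (a node isolated already in the unfiltered iCD has nothing to lose
and is retained vacuously), and a promoter survives if its bin does.
Fractions are pooled across each gene group relative to the unfiltered
iCDs (per-iCD averaging is a flag-level variant the API permits by calling
per group).  Survival fractions are non-increasing in the threshold by
construction.

Chromatin-state strength at a threshold (default the 90th percentile) is,
per group and state, the fraction of that state among surviving nodes
divided by its fraction among all nodes — the state's resilience to
erosion.  Both fractions, the ratio and its reciprocal are reported, since
the two orientations are both in circulation; the resilience orientation
(filtered/unfiltered) is the primary column.

## Synthetic data

The generator emits every input the pipeline reads, in the same dialects
the readers parse, from a single seeded generator (identical seed ⇒
byte-identical files).  Structure and defaults:

* **Genome.**  One chromosome, 10 kb bins, one 16-bin *territory* per gene
  (300 genes ⇒ 48 Mb).  Territories keep each promoter's domain a distinct
  component; on a genome small enough that partners must be shared, every
  iCD collapses into one giant component and group comparisons become
  vacuous.  The TSS sits mid-bin so the promoter window stays inside one
  bin.
* **Wiring.**  Memory promoters receive Poisson(8) edges at low contact
  counts (shifted Poisson, mean 2); responsive promoters Poisson(2) edges
  at high counts (mean 8); background genes Poisson(3)/mean 4.  Weights
  are integers ≥ 1.  Partner bins are marked SuperEnhancer with
  probability 0.6 for memory genes and 0.1 otherwise, and SE partners of
  one promoter are chained to each other at high contact counts —
  super-enhancer elements cluster into densely interacting hubs — which is
  what lets the SE state resist erosion inside memory domains while the
  memory promoter itself (only weak promoter edges) is lost.
* **Hubs.**  10 planted hub CREs each gain 20 extra edges within a ±2
  territory window, so hub removal depresses average degree without fusing
  distant territories.
* **Expression.**  log-mean = log(20) + 1.0·log1p(connectivity), Poisson
  counts with lognormal rate noise (σ = 0.1).  Setting the coupling slope
  to 0 flattens the decile gradient (tested).
* **Nascent design.**  Condition means per class: memory (10, 25, 60),
  responsive (10, 25, 27), background (10, 10, 10); two replicates per
  condition; spike-in factors (1.0, 1.1, 0.9, 1.05, 1.2, 0.8); pseudocount
  0.1.  At σ = 0.1 these separate the classes with recall and precision
  above 0.9 at 100 genes per class.
* **Decoys.**  10% extra loop rows with q-values above the significance
  threshold exercise the reader's filter.
* **Broad promoter domains.**  H3K4me3-like peaks over the TSS, ~4 kb wide
  at memory promoters and ~1 kb elsewhere, support breadth comparisons.

What the generator does *not* emulate: genomic distance–decay of contact
frequency, restriction-fragment structure, read-level noise, overlapping
gene models, trans contacts, and the marginal distributions of any real
dataset.  Passing tests therefore demonstrate correctness of the graph
algorithms and the recoverability of planted effects at realistic effect
sizes — not performance on real sequencing data.

## Numerical choices and degenerate inputs

* Duplicate loop rows merge by summing contact counts (smallest q kept);
  self-loops and inter-chromosomal pairs are rejected (the latter behind a
  flag), and bins must align to the scheme.
* Genes with several TSS records keep the most upstream TSS by default
  (`dedup="all"` keeps all).
* Promoter windows clip at position 0 and the chromosome end; a window
  that clips to nothing is an error.
* Empty deciles report missing probabilities; a group with no surviving
  nodes reports missing strengths; an empty gene group is omitted from the
  erosion curve with a warning.
* All-tied samples short-circuit the Kruskal–Wallis test to H = 0, p = 1
  (the rank test is undefined on zero variance).
* Percentiles use nearest rank; empirical p-values use strict inequality.
* The CLI derives per-stage seeds as `(seed + crc32(stage)) mod 2^31`, so
  stages are independently reproducible and the full chain is
  byte-deterministic under a fixed seed.

## Problem sizes

Default analyses run on the 300-gene bundle (~1,700 network nodes, ~1,900
edges), with 1000 permutations for the removal test and ten deciles of 30
genes; the test suite completes in well under a minute and the acceptance
script in a few seconds.  These sizes were chosen so that decile and
permutation statistics are stable while iteration stays interactive.

## Known limitations

* Erosion pools nodes over iCDs with multiplicity: bins shared by several
  iCDs of a group count once per iCD.
* The two-level community structure is a deterministic Louvain construction,
  not a posterior over nested block models; modularity is reported but no
  uncertainty is attached.
* `breadth_at_tss` considers only the single base of the TSS, and ties go
  to the widest peak (the conservative upper envelope for breadth).
* Readers target the specific TSV/BED/BEDPE dialects documented in
  `genome_io`; `.hic`/`.cool` matrices and GTF gene models are not parsed.
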