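# icdomain

Graph-based analysis of HiChIP-derived regulatory interactomes and
interconnected chromatin domains (iCDs).

HiChIP measures pairwise chromatin contacts among regions carrying a
histone mark of interest (e.g. H3K27ac).  `icdomain` turns significant
loop calls into an annotated bin-level network and asks the questions a
regulatory-genomics study asks of such a network:

* Which bins are promoters (P), enhancers (E), or neither, and how do
  degree distributions differ between P-P, E-E and P-E contact classes?
* Do the nodes containing cis-regulatory elements of interest carry more
  of the network's connectivity than random nodes?  (node-removal
  permutation test on the average degree 2|E|/|N|)
* Does a gene's promoter connectivity — the summed contact counts at its
  promoter bin — predict its expression?  (decile-wise
  P(count > mean | percentile), computed directly and via Bayes' theorem
  as an internal consistency check)
* Which genes show transcriptional *memory* — an amplified nascent-RNA
  response to restimulation in primed versus naive cells (log2FC > 0.5 at
  both steps) — and how do their iCDs behave under *erosion*, the
  progressive removal of edges below rising connectivity percentiles?
* Which chromatin states (an 11-level hierarchy topped by super-enhancers
  and broad promoter domains) resist erosion?  (state *strength*: the
  state's node fraction among survivors over its overall fraction)

The package is usable on real FitHiChIP-style inputs (BEDPE loops, BED
peaks and segmentations, TSV expression tables) and ships a seeded
synthetic-data generator that emulates all of them with planted structure,
so the whole pipeline is testable end to end without downloads.

## Worked example

```python
from icdomain import (SimulationParams, simulate, classify_response,
                      cre_removal_test, build_network, truth_evaluation)
from icdomain.annotation import (annotate_bins, assign_states,
                                 classify_elements, make_promoters)
from icdomain.network import average_degree
from icdomain.icd import collect_global_weights, erosion_analysis, extract_icd

bundle = simulate(SimulationParams(seed=1))
promoters = make_promoters(bundle.tss, chrom_sizes=bundle.scheme.chrom_sizes)
elements = classify_elements(bundle.atac_peaks, promoters)
annotation = annotate_bins(bundle.scheme, bundle.loops, elements,
                           cre_set=bundle.cre_set)
annotation = assign_states(annotation, bundle.states,
                           bundle.super_enhancers, bundle.broad_peaks)
net = build_network(bundle.loops, annotation)
print(f"network: {net.n_nodes} nodes, {net.n_edges} edges, "
      f"average degree {average_degree(net):.3f}")

result = cre_removal_test(net, bundle.hub_bins, n_perm=1000, seed=17)
print(f"hub-CRE removal: observed degree {result.observed:.3f}, "
      f"p = {result.p_value:.4g}")

response = classify_response(bundle.nascent, lfc_cut=0.5)
ev = truth_evaluation(bundle, response)
print(f"memory genes: {len(response.genes('memory'))} "
      f"(recall {ev['memory']['recall']:.2f}, "
      f"precision {ev['memory']['precision']:.2f})")

groups = {lab: [extract_icd(net, g) for g in response.genes(lab)]
          for lab in ("memory", "responsive")}
curve = erosion_analysis(groups, collect_global_weights(net))
wide = curve.pivot(index="percentile", columns="group",
                   values="promoter_fraction")
print(wide.loc[[30, 60, 90]])
```

prints

```
network: 1736 nodes, 1881 edges, average degree 2.167
hub-CRE removal: observed degree 1.937, p = 0
memory genes: 100 (recall 1.00, precision 1.00)
group       memory  responsive
percentile
30            0.99        1.00
60            0.55        0.98
90            0.01        0.66
```

Removing the ten planted hub CREs depresses the average degree from 2.167
to 1.937; none of 1000 random same-size removals goes that low (p = 0,
i.e. < 0.001).  All 100 planted memory genes are recovered from the
nascent three-condition design.  The erosion curve shows the planted
wiring contrast: memory promoters, held by many weak contacts, are almost
all lost by the 90th connectivity percentile (1% survive) while responsive
promoters, held by few strong contacts, largely persist (66%).

## Command line

The same pipeline runs as subcommands sharing a working directory:

```bash
icdomain simulate    --workdir run --seed 1
icdomain build-net   --workdir run
icdomain degrees     --workdir run
icdomain perturb     --workdir run --seed 1
icdomain memory      --workdir run
icdomain erode       --workdir run
icdomain strength    --workdir run
icdomain report      --workdir run
```

(`hubs`, `link-expr`, `cluster-expr`, `icd`, `score-cells` fill in the
remaining stages.)  Stages read one another's TSV outputs; a missing
prerequisite produces an error naming the subcommand to run first.  A YAML
config file (`--config`) can override any default (bin size, q-value
threshold, promoter window, permutation count, fold-change cut, ...); each
random stage derives its own seed from the global one, and the whole chain
is byte-deterministic under a fixed seed.

## Layout

```
src/icdomain/genome_io.py   formats, coordinates, bin scheme
src/icdomain/annotation.py  promoters, enhancers, states, bin annotation
src/icdomain/network.py     network construction, degree statistics
src/icdomain/perturb.py     CRE-removal permutation test
src/icdomain/expression.py  connectivity-expression coupling, clustering,
                            signatures
src/icdomain/icd.py         memory classification, iCDs, erosion, strength
src/icdomain/simulate.py    synthetic-data generator with planted truth
src/icdomain/cli.py         subcommand orchestration
src/icdomain/plots.py       basic figures
docs/methods.md             model, assumptions, parameter choices
```
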