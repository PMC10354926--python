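# Methods

## Model and assumptions

`pacsi` treats phenotype association as a network-proximity problem. The
working assumptions are:

- The genes most characteristic of a cell or a bulk sample are those with
  the highest *relative abundance* — a high cross-column rank — rather than
  the highest absolute expression. Rank signatures make single-cell and
  bulk profiles comparable without joint normalisation, because ranks are
  invariant to any monotone per-gene rescaling.
- Genes driving the same phenotype cluster in the interactome. A cell whose
  signature module lies a short shortest-path distance from the modules of
  the phenotype-1 bulk samples is likely associated with that phenotype.
- Hop counts on the unweighted LCC are an adequate distance: edges carry no
  confidence weights, and restricting to the largest connected component
  keeps every distance finite (with curated PPI networks the LCC typically
  retains nearly all edges).

The pipeline is transductive on the cell side: ranks are computed across
the whole cell population passed to `score_cells`, so adding or removing
cells changes every cell's signature slightly.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `signature_size` (k) | 150 | genes per cell/sample signature. Too small and the signature under-determines the cell's transcriptional state; too large and noise genes dilute the module. 150 was the best-performing size on simulated data and is the default. |
| `n_permutations` | 100 | random modules per null distribution; P-value resolution is 1/n. |
| `alpha` | 0.05 | empirical-P selection threshold (strict inequality). |
| `coexpression_alpha` | 0.05 | raw Pearson-p edge threshold of the fallback network; no multiple-testing correction, by construction. |
| `null_size_mode` | `in_network` | random modules match the cell module size after LCC intersection; `signature` matches the pre-intersection size instead. |
| `cache_nulls` | `True` | cells sharing a module size share one null distribution, cutting permutation cost from O(cells × n_perm) to O(distinct sizes × n_perm) field lookups. |
| `random_state` | `None` | seeds the permutation draws; everything else is deterministic. |

## Numerical and design choices

- **Bulk z-score**: per *sample* (column) across genes, population
  (divide-by-N) standard deviation; a zero-variance sample is an error
  naming the sample. Bulk ranks are taken on the z-scored matrix. Note the
  z-score is monotone within each column but changes cross-column order, so
  this is a substantive choice; the raw-rank alternative is a one-line
  change and is flagged for sensitivity analysis.
- **Ranks**: midrank (average) tie handling; zero-expression genes
  participate (their ties resolve to the midrank); no expression floor.
- **Signature cutoff ties**: descending rank value, then lexicographic
  gene id — deterministic across runs and platforms, and makes the k-gene
  signature a prefix of the k′-gene signature for k′ > k.
- **Distance fields**: one multi-source BFS (min-only Dijkstra on the
  unweighted CSR adjacency) per phenotype-1 sample module. Because both
  averages in the proximity definition are arithmetic, the phenotype
  distance of any node set is the mean over its nodes of the per-node
  average field; random-module distances reuse the cached field and are
  mathematically identical to recomputation.
- **Null modules** are drawn uniformly without replacement from LCC nodes —
  no degree matching. Degree-preserving nulls are a possible extension, off
  by default.
- **Empirical P** counts *strictly* lower null distances, so P = 0 is
  representable and no +1 smoothing is applied. No multiple-testing
  correction across cells by default; `--bh-correction` adds a
  Benjamini–Hochberg column without changing selection.
- **Degenerate inputs**: sample modules with empty LCC intersection are
  dropped with a warning (an error only if none remain); cells with empty
  modules are reported with NA distance/P, never selected, and excluded
  from evaluation; equal-size LCC ties keep the component containing the
  lexicographically smallest node.
- **Co-expression fallback** computes Pearson p-values via the
  t-transform with N−2 degrees of freedom, excludes zero-variance genes,
  and is restricted to the union of all cell and sample signature genes —
  only signature genes can ever enter a module, and the restriction bounds
  the quadratic cost.
- **Evaluation**: ROC-AUC via the Mann–Whitney identity (midrank under
  ties), PR area as step-wise average precision; cells are ranked by
  negative phenotype distance, which is finer-grained than the
  100-permutation P value.

## Synthetic data

The simulator emulates the standard Splatter generative model: gene means
Gamma(shape 0.6, rate 0.3); per-group DE factors exp|N(location 1.0,
scale 0.4)|, inverted with probability 1/2, applied to a Bernoulli(0.1)
subset of genes per group; per-cell library sizes LogNormal(11, 0.2)
(≈ 60k counts); Poisson count sampling; optional Bernoulli dropout (off by
default). Counts become TPM by column closure with unit gene lengths
(simulated genes have no length model; FPKM would differ only by a column
scale). Pseudobulk case samples average 100 cells drawn with replacement
from cluster 1, controls from the pooled remaining clusters; the default
cohort is 250 + 250 samples over 5,000 cells × 10,000 genes in 10
equal-probability groups.

The DE-factor location is a documented constant chosen once to give
clearly separable groups at DE probability 0.1. What the simulation does
*not* reproduce: over-dispersion beyond Poisson (no BCV layer), outlier
genes, batch effects, trajectories, and realistic dropout. Passing
benchmarks on this generator therefore demonstrate correctness of the
pipeline and strong recovery under clean group structure, not performance
on real tissues, where noise, ambient RNA and annotation error will lower
accuracy.

## Problem sizes used by the checks

The test suite and `scripts/acceptance.py` run the benchmark at 1,000
cells × 2,000 genes with 100 + 100 pseudobulk samples, averaged over three
seeds — a scale chosen so a full run completes in minutes on a laptop
while preserving the design (group count, probabilities, DE rate,
cells-per-sample). Null calibration uses 500 random cell modules at 100
permutations; oracle-equivalence checks use 50 random connected graphs of
at most 30 nodes against a pure-Python Floyd–Warshall implementation.

## Known limitations

- Uniform (degree-agnostic) null modules can be anti-conservative for
  high-degree-biased signatures on scale-free PPI networks.
- The co-expression fallback inherits all caveats of thresholding raw
  correlation p-values at scale; it is a fallback, not a replacement for a
  curated interactome.
- Cells are scored independently given the fields; no spatial or clonal
  structure is modelled.
- With 100 permutations the smallest non-zero P is 0.01; raise
  `n_permutations` if you need finer resolution or BH correction across
  many cells.
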