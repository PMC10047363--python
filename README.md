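# grnkit

Reconstruction of transcription-factor regulatory networks from time-course
expression data, with bootstrap consensus, curated-prior overlay,
differential-expression contextualization, hub topology, and integration of
promoter chromatin accessibility — plus a synthetic-data generator with
known ground truth so every stage can be validated end to end.

## Who this is for

Computational biologists analyzing bulk RNA-seq time courses (for example,
stem-cell differentiation under a control and a cytokine-treated condition)
who want to move from a gene × sample expression matrix to a signed,
high-confidence TF–TF network and its regulatory hubs, and to ask whether
changes in expression are mirrored by changes in promoter accessibility
from matched ATAC-seq.

## The method

**Edge inference.** For each target gene *t*, an ensemble of randomized
regression trees predicts the standardized expression of *t* from the
expression of candidate regulators across samples (the GENIE3 approach).
The importance *w(r → t)* of regulator *r* is the total variance reduction
attributed to splits on *r*, summed over trees and normalized so that
Σ<sub>r</sub> *w(r → t)* = 1. Ranking all ordered pairs by importance gives
a directed weighted network.

**Bootstrap consensus.** Inference is repeated on *B* resamples of the
samples (drawn with replacement, stratified by (timepoint, condition) so
each run sees the full design). An edge is retained iff its importance is
positive in strictly more than a fraction τ (default 0.5) of runs, and
carries its support and mean importance.

**Prior overlay.** The consensus network is intersected with a curated
signed regulator→target edge list: weights from inference, activation /
repression signs from the prior.

**Contextualization.** Given differential-expression calls for a contrast
(each gene up / down / unchanged), a node's change must be *justified* by a
sign-consistent, differentially expressed regulator:
direction(target) = sign(edge) × direction(regulator). Unjustified nodes
are removed simultaneously, and removal is iterated to a fixed point;
declared input nodes, unchanged nodes and network roots are exempt.

**Topology.** Hubs are ranked by out-degree with directed shortest-path
betweenness as tiebreak; networks across time points and conditions are
compared by exact node/edge set arithmetic; TF sets are annotated by
upper-tail hypergeometric over-representation with Benjamini–Hochberg
adjustment.

**Accessibility concordance.** ATAC peaks are assigned to the gene with the
nearest TSS within a promoter window (default ±2 kb). Genes that are
differentially expressed (adjusted p < 0.05) and carry a significant
promoter peak (FDR < 0.05) enter a Pearson correlation of expression
log₂FC against accessibility log₂FC — published genome-wide comparisons
report R ≈ 0.4–0.6 — and each gene is classified as concordant (>2-fold
expression change with sign-consistent accessibility), discordant, or
unclassified.

## Worked example

```python
from grnkit import (sample_truth_network, simulate_timecourse, SimulationDesign,
                    concat_expression, InferenceParams, bootstrap_consensus,
                    corrupt_prior, overlay_prior, contextualize,
                    derive_differential_tables, compute_hubs)

truth = sample_truth_network(n_tf=30, mean_out_degree=2.0, seed=1)
design = SimulationDesign(replicates=7)
mats = simulate_timecourse(truth, design)
expr = concat_expression([mats[c] for c in design.conditions])

params = InferenceParams(n_trees=100, seed=1)
consensus, support = bootstrap_consensus(expr, list(truth.gene_ids),
                                         params, B=20, tau=0.5)
prior = corrupt_prior(truth, false_negative_rate=0.2,
                      false_positive_rate=0.2, seed=1)
overlaid = overlay_prior(consensus, prior, mode="intersect")

de = derive_differential_tables(expr, [(("24h", "treated"), ("24h", "control"))])
result = contextualize(overlaid, next(iter(de.values())).calls(),
                       input_nodes=truth.treatment_module)
hubs = compute_hubs(result.pruned, top_k=5)
print(hubs.head(5))
```

This prints (abridged):

```
simulated 30 TFs x 42 samples; true network has 55 edges
consensus network: 870 edges with support > 0.5
after curated-prior overlay: 51 signed edges
       out_degree  in_degree  betweenness  hub_rank  is_hub
node
TF013           7          1   103.833333         1    True
TF027           5          2   155.000000         2    True
TF020           4          2    78.666667         3    True
```

The bootstrap support filter alone is permissive (tree importances are
rarely exactly zero over 20 runs); it is the intersection with the curated
prior that produces the high-confidence signed network (51 edges here, of
which most are true edges of the planted 55-edge network), and TF013 — the
planted master regulator — tops the hub ranking.

The same pipeline runs from the shell:

```bash
grnkit run-all --config examples/config.yaml --outdir out/
```

writing one consensus / overlaid / contextualized network per (timepoint,
condition), hub and comparison tables, an accessibility-concordance
scatter table, and a `manifest.json` with the config hash and row counts
of every output. Identical config and seed reproduce every output byte for
byte.

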