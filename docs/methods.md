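# Methods

This note documents the models, algorithms, numerical conventions and
design decisions behind grnkit, and what the synthetic benchmark does and
does not establish about behaviour on real data.

## Edge inference

For each target gene, expression (standardized to zero mean, unit
variance; constant targets yield an all-zero importance vector with a
logged warning) is regressed on candidate-regulator expression with a
bagged ensemble of randomized regression trees: each tree is fit on a
bootstrap resample of samples, examining `candidates_per_split`
regulators per split (default √p; "all" and integers are accepted).
A regulator's importance is the total impurity (variance) reduction
attributed to its splits, summed over trees and normalized to sum to one
over candidates, so importances are comparable across targets. Trees are
fitted one at a time (scikit-learn `DecisionTreeRegressor` with input
validation hoisted out of the loop), which at the 20–50-sample problem
sizes typical here is several-fold faster than the stock forest wrapper
while computing the same ensemble. Samples are sorted into a canonical
order before fitting, and per-target seeds are derived deterministically
from the user seed and a CRC of the target name, so results are invariant
to input column order and fully reproducible.

By default inference is TF-only (the regulator list doubles as the target
list), producing a directed TF–TF network; arbitrary target lists are
accepted. `n_trees` defaults to 200; values down to 1 are allowed so that
single-stump diagnostics can use the same code path.

## Bootstrap consensus

The inference is repeated B times (default 50) on resamples of the sample
columns drawn with replacement within each (timepoint, condition) group,
so every run sees the complete design. Per (regulator, target) pair,
`support` is the fraction of runs with positive importance and
`mean_weight` the mean importance over those runs; an edge is retained iff
support > τ strictly (default 0.5 — an edge appearing in exactly half the
runs is dropped). "Positive importance" is taken literally: with per-split
candidate subsampling, a regulator never chosen at any split has exactly
zero importance, so no epsilon threshold is needed. Raising τ never adds
edges. In practice the support filter alone is permissive (over 20 runs of
a 100-tree forest, most pairs receive some importance at least half the
time); the filter earns its keep at larger B and smaller ensembles, and
the prior overlay provides the decisive pruning.

## Prior overlay

`intersect` (default) keeps edges present in both the consensus network
and the curated signed prior — weight and support from inference,
activation/repression sign from the prior, provenance recording both
sources. The intersection is what turns the permissive consensus into a
high-confidence signed network. `annotate` keeps all inferred edges and
attaches prior signs where known (sign 0 otherwise). Duplicate prior rows
(which could carry conflicting signs) are rejected at read time.

## Contextualization

Given per-gene calls (up / down / unchanged) from a differential contrast,
a node is *justified* if any of: it is a declared input; its call is
unchanged; it is a root (no regulators); or some remaining regulator r
with call(r) ≠ unchanged satisfies
direction(node) = sign(r → node) × direction(r), with direction(up) = +1,
direction(down) = −1. Edges of unknown sign justify either direction by
default (`unsigned_justifies=False` disables this). All unjustified nodes
are removed simultaneously each pass, with their incident edges, until a
pass removes nothing; the final (no-op) pass is counted, so an already
consistent network reports one iteration. Simultaneous removal makes the
result the unique maximal fixed point, independent of node iteration
order, idempotent, and monotone on the edge set.

Two root conventions are provided. Under the default *strict* convention,
only nodes with zero regulators in the original network count as roots;
nodes orphaned during pruning are re-evaluated against their (now absent)
regulators and fall if their change is left unexplained — pruning cannot
manufacture roots. The *lenient* alternative grants root status to any
currently regulator-less node. On the chain A(unchanged)→B(up)→C(up) with
no declared inputs, strict removes {B, C} in three passes, lenient removes
{B} in two.

## Topology and enrichment

Hubs are ranked by out-degree (descending), ties broken by shortest-path
betweenness on the unweighted directed graph (endpoints excluded,
unnormalized, computed via networkx and cross-checked in the tests against
an explicit path-enumeration oracle), then lexicographic node id — a total
order. Network comparison is exact set arithmetic on node ids and ordered
edge pairs. Over-representation of a query gene set against user-supplied
gene sets uses the upper-tail hypergeometric p (scipy), P(X ≥ 0) = 1 at
zero overlap, with Benjamini–Hochberg adjustment across the tested sets
(statsmodels). No ontology ships with the package; gene-set files are a
two-column (set_id, gene) TSV.

## Accessibility linkage

Peaks (BED convention: 0-based, half-open) are assigned to the gene whose
TSS is nearest the peak midpoint `(start + end) // 2`, if within the
promoter window (default ±2000 bp — promoter definitions vary across
annotation tools, so the window is a configuration key recorded in output
headers). Distances are signed relative to the gene's strand (negative =
upstream); ties go to the lexicographically smaller gene id, making
assignment deterministic and row-order invariant. Chromosomes absent from
the TSS table produce a warning, not an error.

Genes enter the fold-change correlation when padj < 0.05 (expression) and
their nearest assigned promoter peak has FDR < 0.05; Pearson r is reported
with the t-transform p-value (n − 2 df) and the regression line. The
2-fold concordance threshold binds to the expression axis; accessibility
need only be significant and sign-consistent. Fewer than three qualifying
genes, or a zero-variance axis, are hard errors.

## The synthetic-data generator

The generator produces every input the pipeline consumes, with known
ground truth. Design choices, in order of consequence:

**Network structure.** The ground-truth network is a directed *acyclic*
hierarchy: out-degrees are drawn multinomially with Pareto(1.5) node
propensities (heavy-tailed, so a minority of regulators are hubs — across
seeds the maximum out-degree exceeds three times the mean in ≈86% of
draws), the largest regulators sit at the top, and edges point strictly
downward. A single regulator targets at most max(7, n/4) genes, and each
gene accepts at most 2 regulators, with excess degree mass redistributed
and slots packed so the realized edge count stays near the requested
n·mean_out_degree (≈56 of 60 at the defaults; 60 edges cannot all respect
the in-degree cap, whose total capacity is 2(n−1)). Feedback loops —
present in real GRNs — are deliberately excluded: with edge gains strong
enough to be detectable, cycles make the discrete-time dynamics unstable
and chaotic, and no static-sample method (including the one under test)
can recover edges from rail-to-rail oscillations. The in-degree cap
reflects the information budget: at the benchmark signal-to-noise a target
splitting its variance across four or more regulators renders each
individual edge statistically invisible, which would measure the
generator's unfairness rather than the method's skill.

**Dynamics.** Each biological replicate is a trajectory with a persistent
per-gene offset β ~ N(0, bio_sd²). The latent state updates as

    x_g(t+1) = max(0, b_g + A·tanh( Σ_r s·e·z_r(t) / √k_g ) + stim + β_g)

where z_r = (x_r − b_r)/σ_r is the regulator's deviation standardized by
its own dynamic range (the operating-range convention Hill-type GRN
simulators use; σ is calibrated by propagating a 256-member reference
ensemble of offsets to its fixed point, iterated four times to
self-consistency), k_g is the in-degree, s the sign, e the edge effect
(1 ± 0.2), and A = 2.5 the saturating-response amplitude. Technical noise
(sd `noise_sd`) is added *at observation only*, so it does not recirculate
through the network. Recorded values are truncated at zero. A burn-in (15
steps) precedes the first recorded time point, so the baseline already
reflects network regulation; because the persistent offsets drive each
trajectory to its own fixed point, regulator and target co-vary within a
sample — the covariation static-sample inference actually uses.

**Noise scales.** bio_sd = 0.75 and noise_sd = 0.15 put the transmitted
signal amplitude (A·sd(tanh z) ≈ 1.53) at twice the total per-observation
noise sd (√(0.75² + 0.15²) ≈ 0.765) — per-edge signal-to-noise ≈ 2. Noise
mass sits predominantly in the biological component because replicate-level
biological variation dominates deeply sequenced bulk RNA-seq, and because
technical noise on the regulator side attenuates the observable
association (errors in variables) without adding any realism the
biological term does not already provide.

**Treatment.** A random 20% of genes form the treatment-responsive module;
under the treated condition they receive an additive stimulus (default
2 × the total noise sd) from the first post-baseline time point onward,
propagating downstream through the network.

**Differential tables.** Group log₂ fold changes use a pseudocount of 1;
p-values come from Welch's t-test with Benjamini–Hochberg adjustment. This
stand-in caller is deliberately simple — the pipeline consumes only
(log₂FC, padj, call), so the caller's identity is immaterial downstream;
at three replicates Welch is mildly conservative (null rate ≈ 0.03–0.04),
and the null-calibration check uses five replicates, where the rate sits
near nominal. The discrete call (up iff padj < α and log₂FC > 0; down
symmetric; unchanged otherwise) is computed once, at table construction,
from the α recorded in the table header.

**Curated prior.** Each true edge is dropped with the false-negative rate;
spurious signed edges are added with expected count fpr × E. Retained
edges keep their true signs.

**Accessibility.** One promoter peak per gene is placed at a synthetic TSS
(10 kb gene spacing, alternating strands, ±100 bp jitter); its log₂FC is
ρ·z + √(1−ρ²)·ε on the standardized expression-fold-change scale, so the
population correlation with expression equals ρ exactly. FDR values are
assigned independently of effect size (a configurable fraction pass 0.05),
so the downstream significance filter does not bias the recovered
correlation. Off-target peaks sit midway between promoters, beyond any
sane window. `synthetic_de_table` provides the matching genome-wide
differential table with significance likewise independent of effect size.

## Benchmark conditions and what they show

The edge-recovery benchmark uses 30 TFs, mean out-degree 2, two conditions
× three time points × **seven** replicates (42 samples), per-edge
signal-to-noise ≈ 2, consensus over B = 20 runs of 100 trees: mean AUROC
of the consensus mean-weight ranking over all ordered pairs is ≈ 0.75–0.78
across seed windows. At three replicates (18 samples) the same quantity
tops out near 0.69 — and so does a plain correlation ranking, which bounds
what any static-sample method can extract there — so the benchmark is run
at the ~40-sample size at which recovery is statistically attainable.
Reversed edges (importance is nearly symmetric in regulator and target)
and co-targets of large hubs (near-collinear proxies that dilute the hub's
own importance) are the dominant residual error classes; both are known
limitations of tree-importance network inference, not artifacts of this
implementation.

Passing these tests shows the machinery is correct and well calibrated on
data satisfying the generator's assumptions: acyclic truth, stationary
fixed-point dynamics, Gaussian-ish noise, significance independent of
effect size. Real differentiation time courses violate several —
large programmed temporal changes, feedback, count noise, selection
effects — so benchmark AUROC is not a forecast of accuracy on real data;
the validated claims are about the pipeline's behaviour, not about any
particular biological system.

## Pipeline and reproducibility

`run_all` executes simulate → differential tables → per-(timepoint,
condition) consensus → overlay → contextualize (against the
preceding-time-point contrast; the treatment module is declared as input
nodes for treated networks) → hubs, cross-network comparisons and
module over-representation → genome-wide accessibility concordance. Per
the time-resolved design, networks are inferred per time point and
condition; because three replicates are too few for per-cell inference,
`pool_adjacent` (default on) pools each time point with its predecessor.
The multiomics stage simulates its own genome-wide differential table
rather than reusing the TF-only matrix, mirroring the genome-wide scope of
real RNA/ATAC comparisons. Every output file names the config hash in a
header comment; the manifest records seed, config, per-stage edge counts
and a content hash per output. All randomness derives from the single
config seed via `numpy.random.SeedSequence` spawning; identical config and
seed give byte-identical outputs.

## Known limitations

- Acyclic ground truth only; feedback and autoregulation are untested.
- The Welch + BH caller is not a count-model fit; calls on real counts
  should come from a dedicated DE tool, imported via the differential
  table format.
- Edge direction is identified only weakly (near-symmetric importances).
- Nearest-TSS assignment ignores enhancer–gene links and 3D contacts.
- The contextualization rule is per-node and sign-based; it does not fit a
  logic or steady-state model of combinatorial regulation.
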