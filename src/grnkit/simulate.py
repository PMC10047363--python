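"""Ground-truth networks and synthetic pipeline inputs.

The generators here produce every input the reconstruction pipeline consumes
— time-course expression driven by a known signed transcription-factor
network, differential tables, a noisy "curated prior", and promoter
accessibility fold changes correlated with expression fold changes at a
tunable coefficient — so that every downstream stage can be tested against
a known answer.

Every generator is a pure function of its parameters and an explicit seed;
no global random state is touched.

Expression model
----------------
The ground-truth network is a regulatory hierarchy (a directed acyclic
graph with hub-dominated out-degrees). For gene ``g`` with basal level
``b_g``, the latent regulatory state in trajectory ``k`` (one biological
replicate under one condition) evolves as

    x_g(t+1) = max(0, b_g + A·sat( Σ_r s_{rg} e_{rg} z_r(t) / √k_g )
                      + stim·1[g ∈ module, treated, t ≥ post-baseline]
                      + β_gk)

where ``z_r = (x_r − b_r)/σ_r`` is the regulator's deviation standardized
by its own dynamic range σ_r (each regulatory input operates relative to
the regulator's operating scale, the convention Hill-type GRN simulators
use), ``k_g`` is the in-degree, ``s`` the edge sign, ``e`` the edge effect
magnitude, ``sat`` a unit-scale tanh and ``A`` the saturating response
amplitude — so the transmitted regulatory signal has comparable amplitude
at every depth of the hierarchy instead of accumulating, and indirect
(grand-regulator) influence attenuates multiplicatively. σ_r is
calibrated once per ground truth by propagating a reference ensemble of
biological offsets to its fixed point. ``β_gk`` is a persistent
per-trajectory biological offset (sd ``bio_sd``); the recorded value is
``max(0, x_g(t) + ε_g(t))`` with i.i.d. technical noise
ε ~ N(0, noise_sd²). The persistent offset drives the dynamics to a
trajectory-specific fixed point, so regulator and target co-vary *within*
a sample — which is what static-sample network inference needs; technical
noise enters only at observation, so it does not recirculate through the
network. A burn-in precedes the first recorded time point so the baseline
already reflects network regulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import (
    AccessibilityTable,
    DifferentialTable,
    ExpressionMatrix,
    Network,
    TssTable,
)

__all__ = [
    "GroundTruth",
    "SimulationDesign",
    "sample_truth_network",
    "simulate_timecourse",
    "derive_differential_tables",
    "corrupt_prior",
    "simulate_accessibility",
    "synthetic_de_table",
    "benjamini_hochberg",
]


def _rng(seed: int, *key: int) -> np.random.Generator:
    """Derive an independent stream from (seed, stage key)."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


@dataclass(frozen=True)
class GroundTruth:
    """A known signed regulatory network plus its simulation parameters."""

    network: Network                      # signs strictly in {+1, −1}
    basal: pd.Series                      # per-gene basal expression
    edge_effect: Mapping[tuple[str, str], float]
    noise_sd: float                       # technical noise sd per observation
    bio_sd: float                         # persistent per-trajectory offset sd
    treatment_module: frozenset
    seed: int
    saturation: float = 2.5               # amplitude A of the saturating response

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if not self.treatment_module <= set(self.basal.index):
            raise ValueError("treatment_module must be a subset of the gene set")
        signs = set(self.network.edges["sign"])
        if not signs <= {-1, 1}:
            raise ValueError("ground-truth edges must be signed +1 or -1")

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(self.basal.index)


@dataclass(frozen=True)
class SimulationDesign:
    """Study design: time points, conditions, replication, thresholds.

    Defaults mirror a three-point differentiation time course (0h / 24h /
    72h) under a control and a cytokine-treated condition with 3 biological
    replicates each.
    """

    timepoints: tuple[str, ...] = ("0h", "24h", "72h")
    conditions: tuple[str, ...] = ("control", "treated")
    replicates: int = 3
    alpha: float = 0.05
    accessibility_rho: float = 0.45
    stimulus: float | None = None  # default: 2 × total noise sd at simulation time
    burn_in: int = 15

    def __post_init__(self) -> None:
        if len(self.timepoints) < 2:
            raise ValueError("need ≥ 2 timepoints")
        if self.replicates < 2:
            raise ValueError("need ≥ 2 replicates")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not -1 < self.accessibility_rho < 1:
            raise ValueError("accessibility_rho must be in (-1, 1)")


def sample_truth_network(
    n_tf: int,
    mean_out_degree: float,
    activation_fraction: float = 0.7,
    seed: int = 0,
    *,
    module_fraction: float = 0.2,
    max_in_degree: int = 2,
    max_out_degree: int | None = None,
    pareto_shape: float = 1.5,
    effect_scale: float = 1.0,
    effect_jitter: float = 0.2,
    noise_sd: float = 0.15,
    bio_sd: float = 0.75,
    basal_range: tuple[float, float] = (2.0, 6.0),
) -> GroundTruth:
    """Draw a random signed, acyclic TF–TF network with hub topology.

    Out-degrees are allocated multinomially with Pareto-distributed node
    propensities, so a minority of regulators account for a large share of
    edges (the hub structure real regulatory networks show); the largest
    regulators are placed at the top of a random hierarchy and every edge
    points downward, making the network a DAG (master regulators upstream,
    effectors downstream). Each edge is activating (+1) with probability
    ``activation_fraction``, repressing (−1) otherwise. ``effect_scale``
    multiplies the standardized regulator deviation in the transmission
    function; at the defaults the amplitude of the transmitted regulatory
    signal is ≈ 2 × the total per-observation noise sd (per-edge
    signal-to-noise ≈ 2).

    A random ``module_fraction`` of genes form the treatment-responsive
    module stimulated under the treated condition.
    """
    if n_tf < 5:
        raise ValueError("n_tf must be ≥ 5")
    if not 0 < activation_fraction <= 1:
        raise ValueError("activation_fraction must be in (0, 1]")
    if mean_out_degree < 0:
        raise ValueError("mean_out_degree must be ≥ 0")
    if not 0 <= module_fraction <= 1:
        raise ValueError("module_fraction must be in [0, 1]")
    rng = _rng(seed, 1)
    width = max(3, len(str(n_tf)))
    genes = [f"TF{i + 1:0{width}d}" for i in range(n_tf)]

    n_edges = int(round(n_tf * mean_out_degree))
    records = []
    edge_effect: dict[tuple[str, str], float] = {}
    if n_edges > 0:
        propensity = rng.pareto(pareto_shape, size=n_tf) + 1.0
        probs = propensity / propensity.sum()
        degrees = rng.multinomial(n_edges, probs)
        # a single regulator targets at most ~a quarter of the network;
        # excess degree mass is redistributed so the total edge count holds
        out_cap = max_out_degree if max_out_degree is not None else max(
            7, int(round(n_tf / 4))
        )
        degrees = np.minimum(degrees, out_cap)
        room = out_cap - degrees
        deficit = n_edges - int(degrees.sum())
        while deficit > 0 and room.sum() > 0:
            w = probs * (room > 0)
            extra = np.minimum(rng.multinomial(deficit, w / w.sum()), room)
            degrees += extra
            room -= extra
            deficit = n_edges - int(degrees.sum())
        # hierarchy: largest out-degrees on top so each regulator has
        # enough downstream targets; edges point strictly downward.
        # Target choice prefers lightly regulated genes and caps in-degree,
        # so no target drowns in regulators it cannot resolve.
        ranked = sorted(range(n_tf), key=lambda i: (-degrees[i], i))
        layered = [genes[i] for i in ranked]
        indeg = dict.fromkeys(genes, 0)
        wanted = {layered[pos]: int(degrees[ranked[pos]]) for pos in range(n_tf)}

        def add_edge(reg: str, tgt: str) -> None:
            indeg[tgt] += 1
            wanted[reg] -= 1
            sign = 1 if rng.random() < activation_fraction else -1
            eff = effect_scale * (1.0 + effect_jitter * (2 * rng.random() - 1))
            records.append(
                {
                    "regulator": reg,
                    "target": tgt,
                    "weight": eff,
                    "sign": sign,
                    "provenance": frozenset(),
                }
            )
            edge_effect[(reg, tgt)] = eff

        # allocation order: the top hub claims its targets first (it can
        # reach anything below), then bottom-up so regulators with few
        # reachable targets claim scarce slots before mid-level ones —
        # dense packing under the in-degree cap without starving the hub
        order = [0] + list(reversed(range(1, n_tf)))
        for pos in order:
            reg = layered[pos]
            avail = [g for g in layered[pos + 1 :] if indeg[g] < max_in_degree]
            deg = min(wanted[reg], len(avail))
            if deg <= 0:
                continue
            slack = np.array([max_in_degree - indeg[g] for g in avail], dtype=float)
            targets = rng.choice(
                len(avail), size=deg, replace=False, p=slack / slack.sum()
            )
            for j in targets:
                add_edge(reg, avail[j])
    network = Network.from_records(records, extra_nodes=genes)

    basal = pd.Series(
        rng.uniform(basal_range[0], basal_range[1], size=n_tf),
        index=pd.Index(genes, name="gene_id"),
    )
    n_module = int(round(module_fraction * n_tf))
    module = frozenset(
        genes[i] for i in rng.choice(n_tf, size=n_module, replace=False)
    )
    return GroundTruth(
        network=network,
        basal=basal,
        edge_effect=edge_effect,
        noise_sd=noise_sd,
        bio_sd=bio_sd,
        treatment_module=module,
        seed=seed,
    )


def simulate_timecourse(
    truth: GroundTruth, design: SimulationDesign
) -> dict[str, ExpressionMatrix]:
    """Simulate one expression matrix per condition.

    Under the treated condition, genes in the treatment module receive an
    additive stimulus (default 2 × the total per-observation noise sd,
    √(noise_sd² + bio_sd²)) from the first post-baseline
    time point onward. Replicate trajectories are i.i.d.; values are
    truncated at zero. Deterministic given ``truth.seed``.
    """
    genes = list(truth.gene_ids)
    n = len(genes)
    idx = {g: i for i, g in enumerate(genes)}
    # signed effect matrix W[target, regulator]
    W = np.zeros((n, n))
    for row in truth.network.edges.itertuples(index=False):
        W[idx[row.target], idx[row.regulator]] = row.sign * truth.edge_effect[
            (row.regulator, row.target)
        ]
    basal = truth.basal.to_numpy()
    indegree = (W != 0).sum(axis=1)
    sqrt_k = np.sqrt(np.maximum(indegree, 1))
    total_noise_sd = math.sqrt(truth.noise_sd**2 + truth.bio_sd**2)
    stim_value = (
        2.0 * total_noise_sd if design.stimulus is None else design.stimulus
    )
    module_mask = np.array([g in truth.treatment_module for g in genes])
    amp = truth.saturation

    def step(x: np.ndarray, sigma: np.ndarray, extra: np.ndarray | float,
             bio: np.ndarray) -> np.ndarray:
        z = (x - basal) / sigma
        drive = amp * np.tanh((z @ W.T) / sqrt_k)
        return np.maximum(0.0, basal + drive + extra + bio)

    # per-gene latent operating scales, calibrated on a reference ensemble
    rng_cal = _rng(truth.seed, 6)
    m_ref = 256
    bio_ref = rng_cal.normal(0.0, truth.bio_sd, size=(m_ref, n))
    sigma = np.full(n, max(truth.bio_sd, 1e-9))
    if truth.network.n_edges:
        for _ in range(4):
            x_ref = np.maximum(0.0, basal + bio_ref)
            for _ in range(n):  # a DAG fixed point needs ≤ depth steps
                x_new = step(x_ref, sigma, 0.0, bio_ref)
                if np.max(np.abs(x_new - x_ref)) < 1e-10:
                    x_ref = x_new
                    break
                x_ref = x_new
            sigma = np.maximum(x_ref.std(axis=0), 1e-9)

    out: dict[str, ExpressionMatrix] = {}
    for ci, condition in enumerate(design.conditions):
        treated = condition != design.conditions[0]
        columns: dict[str, np.ndarray] = {}
        meta_rows = []
        for rep in range(1, design.replicates + 1):
            rng = _rng(truth.seed, 2, ci, rep)
            bio = rng.normal(0.0, truth.bio_sd, size=n)
            x = np.maximum(0.0, basal + bio)  # latent regulatory state
            for _ in range(design.burn_in):
                x = step(x, sigma, 0.0, bio)
            for ti, tp in enumerate(design.timepoints):
                if ti > 0:
                    stim = stim_value * module_mask if treated else 0.0
                    x = step(x, sigma, stim, bio)
                sid = f"{condition}_{tp}_r{rep}"
                # technical noise enters at observation only
                columns[sid] = np.maximum(
                    0.0, x + rng.normal(0.0, truth.noise_sd, size=n)
                )
                meta_rows.append(
                    {
                        "sample_id": sid,
                        "timepoint": tp,
                        "condition": condition,
                        "replicate": rep,
                    }
                )
        values = pd.DataFrame(columns, index=pd.Index(genes, name="gene_id"))
        # canonical column order: timepoint-major, replicate-minor
        ordered = [
            f"{condition}_{tp}_r{rep}"
            for tp in design.timepoints
            for rep in range(1, design.replicates + 1)
        ]
        values = values[ordered]
        meta = pd.DataFrame(meta_rows).set_index("sample_id").loc[ordered]
        out[condition] = ExpressionMatrix(values, meta)
    return out


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (via statsmodels)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def derive_differential_tables(
    expr: ExpressionMatrix,
    contrast_pairs: Sequence[tuple[tuple[str, str], tuple[str, str]]],
    alpha: float = 0.05,
) -> dict[str, DifferentialTable]:
    """Welch-t + BH differential tables for (timepoint, condition) contrasts.

    Each contrast is ``((tp_a, cond_a), (tp_b, cond_b))`` and is reported as
    *a versus b*: ``log2fc = log2((mean_a + 1) / (mean_b + 1))`` with a
    pseudocount of 1. This simple caller stands in for a count-model fit;
    the pipeline only consumes (log2fc, padj, call).
    """
    tables: dict[str, DifferentialTable] = {}
    for (tp_a, cond_a), (tp_b, cond_b) in contrast_pairs:
        ids_a = expr.samples_where(timepoint=tp_a, condition=cond_a)
        ids_b = expr.samples_where(timepoint=tp_b, condition=cond_b)
        if len(ids_a) < 2 or len(ids_b) < 2:
            raise ValueError(
                f"contrast ({tp_a},{cond_a}) vs ({tp_b},{cond_b}): "
                f"groups have {len(ids_a)} and {len(ids_b)} replicates, need ≥ 2"
            )
        a = expr.values[ids_a].to_numpy()
        b = expr.values[ids_b].to_numpy()
        log2fc = np.log2((a.mean(axis=1) + 1.0) / (b.mean(axis=1) + 1.0))
        with np.errstate(invalid="ignore", divide="ignore"):
            _, pvals = stats.ttest_ind(a, b, axis=1, equal_var=False)
        pvals = np.where(np.isnan(pvals), 1.0, pvals)
        padj = benjamini_hochberg(pvals)
        name = f"{tp_a}_{cond_a}_vs_{tp_b}_{cond_b}"
        tables[name] = DifferentialTable.from_stats(
            expr.gene_ids, log2fc, pvals, padj, alpha
        )
    return tables


def corrupt_prior(
    truth: GroundTruth,
    false_negative_rate: float,
    false_positive_rate: float,
    seed: int = 0,
) -> Network:
    """A noisy curated prior: drop true edges, add spurious signed edges.

    Each true edge is dropped independently with probability
    ``false_negative_rate``; the number of spurious edges added is
    Binomial(E, ``false_positive_rate``) so its expectation is
    ``false_positive_rate × E`` for E true edges. Retained edges keep their
    true signs; spurious edges get a random sign.
    """
    if not (0 <= false_negative_rate < 1 and 0 <= false_positive_rate < 1):
        raise ValueError("rates must lie in [0, 1)")
    rng = _rng(seed, 3)
    genes = list(truth.gene_ids)
    true_pairs = truth.network.edge_pairs()
    sign_of = truth.network.sign_map()
    records = []
    for reg, tgt in sorted(true_pairs):
        if rng.random() >= false_negative_rate:
            records.append(
                {
                    "regulator": reg,
                    "target": tgt,
                    "sign": sign_of[(reg, tgt)],
                    "provenance": frozenset({"prior"}),
                }
            )
    n_spurious = rng.binomial(len(true_pairs), false_positive_rate)
    candidates = [
        (r, t)
        for r in genes
        for t in genes
        if r != t and (r, t) not in true_pairs
    ]
    if n_spurious > 0 and candidates:
        chosen = rng.choice(len(candidates), size=min(n_spurious, len(candidates)),
                            replace=False)
        for c in chosen:
            reg, tgt = candidates[c]
            records.append(
                {
                    "regulator": reg,
                    "target": tgt,
                    "sign": 1 if rng.random() < 0.5 else -1,
                    "provenance": frozenset({"prior"}),
                }
            )
    return Network.from_records(records)


def synthetic_de_table(
    n_genes: int,
    frac_de: float = 0.9,
    effect_sd: float = 1.5,
    alpha: float = 0.05,
    seed: int = 0,
) -> DifferentialTable:
    """A directly constructed genome-wide differential table.

    A random ``frac_de`` of genes are significant (padj uniform below
    ``alpha``) with log2 fold changes ~ N(0, effect_sd²); the rest are
    non-significant with small fold changes. Significance is assigned
    independently of effect size so downstream significance filters do not
    bias fold-change correlations.
    """
    rng = _rng(seed, 4)
    genes = [f"G{i + 1:05d}" for i in range(n_genes)]
    n_de = int(round(frac_de * n_genes))
    de_mask = np.zeros(n_genes, dtype=bool)
    de_mask[rng.choice(n_genes, size=n_de, replace=False)] = True
    log2fc = np.where(
        de_mask,
        rng.normal(0.0, effect_sd, size=n_genes),
        rng.normal(0.0, 0.3, size=n_genes),
    )
    padj = np.where(
        de_mask,
        rng.uniform(0.0, alpha * 0.99, size=n_genes),
        rng.uniform(alpha, 1.0, size=n_genes),
    )
    pvalue = padj * rng.uniform(0.1, 1.0, size=n_genes)
    return DifferentialTable.from_stats(genes, log2fc, pvalue, padj, alpha)


def simulate_accessibility(
    de_table: DifferentialTable,
    rho: float,
    n_off_target: int = 100,
    seed: int = 0,
    *,
    frac_significant: float = 0.8,
    gene_spacing: int = 10_000,
    peak_halfwidth: int = 300,
    chrom: str = "chr1",
) -> tuple[AccessibilityTable, TssTable]:
    """Promoter accessibility fold changes correlated with expression.

    One promoter peak is placed at each gene's synthetic TSS. On the
    standardized scale the peak log2FC is ``rho·z_expr + √(1−rho²)·noise``,
    rescaled back to the expression fold-change scale, so the population
    Pearson correlation with expression log2FC equals ``rho``. FDR values
    are assigned independently of effect size so that ``frac_significant``
    of promoter peaks pass 0.05. ``n_off_target`` distal peaks lie farther
    than any promoter window and are assigned to no gene.
    """
    if not -1 <= rho <= 1:
        raise ValueError("rho must lie in [-1, 1]")
    rng = _rng(seed, 5)
    genes = list(de_table.gene_ids)
    n = len(genes)
    expr_lfc = de_table.table["log2fc"].to_numpy()
    sd = expr_lfc.std(ddof=0)
    if sd > 0:
        z = (expr_lfc - expr_lfc.mean()) / sd
    else:
        z = np.zeros(n)
    noise = rng.normal(0.0, 1.0, size=n)
    y = rho * z + math.sqrt(max(0.0, 1.0 - rho * rho)) * noise
    peak_lfc = y * (sd if sd > 0 else 1.0)

    tss = np.arange(1, n + 1) * gene_spacing
    strand = np.where(np.arange(n) % 2 == 0, "+", "-")
    tss_df = pd.DataFrame(
        {"chrom": chrom, "strand": strand, "tss": tss},
        index=pd.Index(genes, name="gene_id"),
    )

    n_sig = int(round(frac_significant * n))
    sig_mask = np.zeros(n, dtype=bool)
    if n_sig:
        sig_mask[rng.choice(n, size=n_sig, replace=False)] = True
    fdr = np.where(
        sig_mask,
        rng.uniform(0.0, 0.05 * 0.99, size=n),
        rng.uniform(0.05, 1.0, size=n),
    )
    jitter = rng.integers(-100, 101, size=n)
    rows = []
    for i, g in enumerate(genes):
        center = int(tss[i] + jitter[i])
        rows.append(
            {
                "chrom": chrom,
                "start": center - peak_halfwidth,
                "end": center + peak_halfwidth,
                "peak_id": f"peak_{g}",
                "log2fc": peak_lfc[i],
                "fdr": fdr[i],
            }
        )
    # distal peaks midway between promoters: ≥ gene_spacing/2 − halfwidth bp
    # from every TSS, beyond any sane promoter window
    for j in range(n_off_target):
        k = int(rng.integers(0, n))
        center = int(tss[k] + gene_spacing // 2)
        rows.append(
            {
                "chrom": chrom,
                "start": center - peak_halfwidth,
                "end": center + peak_halfwidth,
                "peak_id": f"distal_{j + 1:04d}",
                "log2fc": float(rng.normal(0.0, max(sd, 0.5))),
                "fdr": float(rng.uniform(0.0, 1.0)),
            }
        )
    # deduplicate identical distal intervals drawn twice
    df = pd.DataFrame(rows).drop_duplicates(subset="peak_id")
    return AccessibilityTable(df), TssTable(tss_df)
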