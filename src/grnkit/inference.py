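"""Tree-ensemble regulatory-link inference and bootstrap consensus.

For each target gene, an ensemble of randomized regression trees predicts
the target's (standardized) expression from the expression of candidate
regulators; the importance of regulator *i* is the total impurity (variance)
reduction attributed to splits on *i*, summed over trees and normalized to
sum to one over candidates. Running the inference over all regulators as
targets yields a directed TF–TF network ranked by importance.

Stability is assessed by bootstrapping: the inference is repeated B times on
sample resamples drawn with replacement (stratified by (timepoint,
condition) group so every run sees every design cell), and an edge is
retained only if its importance is greater than zero in strictly more than
a fraction ``tau`` (default 0.5) of runs.

`GRNInference` and `GRNBootstrapConsensus` are sklearn-style estimators
(``fit`` → fitted ``network_`` attribute, ``get_params``/``set_params``);
:func:`infer_grn`, :func:`bootstrap_consensus` and
:func:`target_importances` are thin functional wrappers.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.tree import DecisionTreeRegressor

from .io import ExpressionMatrix, Network

__all__ = [
    "InferenceParams",
    "GRNInference",
    "GRNBootstrapConsensus",
    "target_importances",
    "infer_grn",
    "bootstrap_consensus",
    "consensus_from_runs",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class InferenceParams:
    """Tree-ensemble hyperparameters.

    ``candidates_per_split`` is "sqrt", "all", or an integer number of
    regulators examined per split. ``n_trees`` accepts any value ≥ 1 so that
    single-tree diagnostics (depth-1 stumps) can reuse the same code path;
    production runs should use the default 200.
    """

    n_trees: int = 200
    candidates_per_split: str | int = "sqrt"
    min_samples_leaf: int = 1
    seed: int = 0
    max_depth: int | None = None
    bagging: bool = True

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be ≥ 1")
        if self.min_samples_leaf < 1:
            raise ValueError("min_samples_leaf must be ≥ 1")
        if isinstance(self.candidates_per_split, str):
            if self.candidates_per_split not in ("sqrt", "all"):
                raise ValueError("candidates_per_split must be 'sqrt', 'all' or int")
        elif self.candidates_per_split < 1:
            raise ValueError("candidates_per_split must be ≥ 1")

    def max_features(self, n_candidates: int):
        if self.candidates_per_split == "sqrt":
            return "sqrt"
        if self.candidates_per_split == "all":
            return None
        return min(int(self.candidates_per_split), n_candidates)


def _derived_seed(seed: int, *key: int) -> int:
    """A deterministic 31-bit child seed for (seed, key)."""
    state = np.random.SeedSequence(entropy=seed, spawn_key=key).generate_state(1)[0]
    return int(state >> 1)  # < 2**31, accepted by sklearn


def _target_key(target_gene: str) -> int:
    return zlib.crc32(target_gene.encode("utf-8"))


def _forest_importances(
    X: np.ndarray, y: np.ndarray, params: InferenceParams, seed: int
) -> np.ndarray:
    """Total unnormalized impurity reduction per feature over a bagged
    ensemble of randomized regression trees.

    Equivalent to a random-forest regressor (bootstrap resampling plus
    per-split candidate subsampling) but fitted tree-by-tree with input
    checks hoisted out of the loop, which matters at these sample sizes.
    """
    n_samples, n_features = X.shape
    X = np.asfortranarray(X, dtype=np.float32)  # sklearn trees operate in float32
    y = np.ascontiguousarray(y, dtype=np.float64)
    rng = np.random.default_rng(seed)
    max_features = params.max_features(n_features)
    totals = np.zeros(n_features)
    for _ in range(params.n_trees):
        if params.bagging:
            idx = rng.integers(0, n_samples, size=n_samples)
            Xb = np.asfortranarray(X[idx])
            yb = y[idx]
        else:
            Xb, yb = X, y
        tree = DecisionTreeRegressor(
            max_features=max_features,
            min_samples_leaf=params.min_samples_leaf,
            max_depth=params.max_depth,
            random_state=int(rng.integers(2**31)),
        )
        tree.fit(Xb, yb, check_input=False)
        totals += tree.tree_.compute_feature_importances(normalize=False)
    return totals


def target_importances(
    expr: ExpressionMatrix,
    target_gene: str,
    candidate_regulators: Sequence[str],
    params: InferenceParams,
) -> pd.Series:
    """Importance weights of candidate regulators for one target gene.

    The target's expression is standardized to unit variance before the fit
    so importances are comparable across targets; weights are normalized to
    sum to 1 (all-zero for a constant target, with a logged warning).
    Samples are sorted into a canonical order before fitting, so the result
    is invariant to the input column order given the same seed.
    """
    candidates = list(candidate_regulators)
    if target_gene in candidates:
        raise ValueError(f"target {target_gene!r} must not be its own candidate")
    if expr.n_samples < 4:
        raise ValueError(f"need ≥ 4 samples, got {expr.n_samples}")
    missing = [g for g in [target_gene, *candidates] if g not in expr.values.index]
    if missing:
        raise KeyError(f"genes absent from expression matrix: {missing}")

    order = sorted(expr.sample_ids)
    y = expr.values.loc[target_gene, order].to_numpy(dtype=float)
    X = expr.values.loc[candidates, order].to_numpy(dtype=float).T
    sd = y.std(ddof=0)
    if sd == 0:
        logger.warning("target %s is constant; returning zero weights", target_gene)
        return pd.Series(0.0, index=candidates, name=target_gene)
    y = (y - y.mean()) / sd

    totals = _forest_importances(
        X, y, params, _derived_seed(params.seed, _target_key(target_gene))
    )
    total = totals.sum()
    if total > 0:
        totals = totals / total
    return pd.Series(totals, index=candidates, name=target_gene)


class GRNInference(BaseEstimator):
    """Tree-ensemble gene-regulatory-network inference (GENIE3-style).

    Fits one randomized-tree ensemble per target gene and assembles the
    per-target importance vectors into a directed weighted network. By
    default inference is TF-only: the regulator list doubles as the target
    list, yielding a TF–TF network; pass ``targets`` to ``fit`` for
    all-gene targets.

    Parameters
    ----------
    n_trees : int
        Trees per target ensemble.
    candidates_per_split : "sqrt" | "all" | int
        Regulators examined per split.
    min_samples_leaf : int
        Minimum samples per leaf.
    max_depth : int or None
        Tree depth cap (None = unbounded).
    bagging : bool
        Bootstrap samples within each forest.
    random_state : int
        Seed; per-target seeds are derived deterministically from it.

    Attributes
    ----------
    network_ : Network
        Inferred edges (weight > 0), sign 0, provenance {"inferred"}.
    importances_ : pd.DataFrame
        Targets × regulators importance matrix (rows sum to 1 or 0).
    """

    def __init__(
        self,
        n_trees: int = 200,
        candidates_per_split: str | int = "sqrt",
        min_samples_leaf: int = 1,
        max_depth: int | None = None,
        bagging: bool = True,
        random_state: int = 0,
    ):
        self.n_trees = n_trees
        self.candidates_per_split = candidates_per_split
        self.min_samples_leaf = min_samples_leaf
        self.max_depth = max_depth
        self.bagging = bagging
        self.random_state = random_state

    def _params(self) -> InferenceParams:
        return InferenceParams(
            n_trees=self.n_trees,
            candidates_per_split=self.candidates_per_split,
            min_samples_leaf=self.min_samples_leaf,
            seed=self.random_state,
            max_depth=self.max_depth,
            bagging=self.bagging,
        )

    def fit(
        self,
        expr: ExpressionMatrix,
        regulators: Sequence[str] | None = None,
        targets: Sequence[str] | None = None,
    ) -> "GRNInference":
        regulators = list(regulators) if regulators is not None else list(expr.gene_ids)
        if len(regulators) < 3:
            raise ValueError(f"need ≥ 3 regulators, got {len(regulators)}")
        absent = [g for g in regulators if g not in expr.values.index]
        if absent:
            raise KeyError(f"regulators absent from expression matrix: {absent}")
        targets = list(targets) if targets is not None else list(regulators)
        params = self._params()
        rows = {}
        records = []
        for target in targets:
            candidates = [g for g in regulators if g != target]
            weights = target_importances(expr, target, candidates, params)
            rows[target] = weights
            for reg, w in weights.items():
                if w > 0:
                    records.append(
                        {
                            "regulator": reg,
                            "target": target,
                            "weight": float(w),
                            "sign": 0,
                            "provenance": frozenset({"inferred"}),
                        }
                    )
        self.importances_ = pd.DataFrame(rows).T.reindex(
            index=targets, columns=regulators
        ).fillna(0.0)
        self.network_ = Network.from_records(records)
        self.regulators_ = tuple(regulators)
        self.targets_ = tuple(targets)
        return self


def consensus_from_runs(
    runs: Sequence[Network], tau: float = 0.5
) -> tuple[Network, pd.DataFrame]:
    """Aggregate per-run inferred networks into a bootstrap consensus.

    For each (regulator, target) pair, ``support`` is the fraction of runs
    in which the edge appeared with importance > 0 and ``mean_weight`` the
    mean importance over those runs. An edge is retained iff its support
    strictly exceeds ``tau`` — at tau = 0.5, an edge present in exactly
    half the runs is dropped.
    """
    if len(runs) < 2:
        raise ValueError("need ≥ 2 runs for a consensus")
    if not 0 < tau < 1:
        raise ValueError("tau must lie in (0, 1)")
    B = len(runs)
    counts: dict[tuple[str, str], int] = {}
    weight_sums: dict[tuple[str, str], float] = {}
    for run in runs:
        for row in run.edges.itertuples(index=False):
            if row.weight <= 0:
                continue
            key = (row.regulator, row.target)
            counts[key] = counts.get(key, 0) + 1
            weight_sums[key] = weight_sums.get(key, 0.0) + row.weight
    rows = [
        {
            "regulator": reg,
            "target": tgt,
            "support": cnt / B,
            "mean_weight": weight_sums[(reg, tgt)] / cnt,
        }
        for (reg, tgt), cnt in sorted(counts.items())
    ]
    consensus = pd.DataFrame(
        rows, columns=["regulator", "target", "support", "mean_weight"]
    )
    kept = consensus[consensus["support"] > tau]
    network = Network.from_records(
        {
            "regulator": r.regulator,
            "target": r.target,
            "weight": r.mean_weight,
            "sign": 0,
            "support": r.support,
            "provenance": frozenset({"inferred"}),
        }
        for r in kept.itertuples(index=False)
    )
    return network, consensus


class GRNBootstrapConsensus(BaseEstimator):
    """Bootstrap-consensus network over repeated tree-ensemble inference.

    Runs :class:`GRNInference` B times, each on a with-replacement resample
    of samples stratified by (timepoint, condition) group, and retains an
    edge iff its importance exceeded zero in strictly more than ``tau``
    (default 0.5) of runs. Retained edges carry ``support`` (the fraction
    of runs) and ``weight`` = mean importance over the runs in which the
    edge appeared.

    Attributes
    ----------
    network_ : Network
        Consensus network after the support filter.
    consensus_ : pd.DataFrame
        support and mean_weight for every edge seen in ≥ 1 run.
    """

    def __init__(
        self,
        n_trees: int = 200,
        candidates_per_split: str | int = "sqrt",
        min_samples_leaf: int = 1,
        max_depth: int | None = None,
        bagging: bool = True,
        random_state: int = 0,
        B: int = 50,
        tau: float = 0.5,
    ):
        self.n_trees = n_trees
        self.candidates_per_split = candidates_per_split
        self.min_samples_leaf = min_samples_leaf
        self.max_depth = max_depth
        self.bagging = bagging
        self.random_state = random_state
        self.B = B
        self.tau = tau

    def fit(
        self, expr: ExpressionMatrix, regulators: Sequence[str] | None = None
    ) -> "GRNBootstrapConsensus":
        if self.B < 2:
            raise ValueError("B must be ≥ 2")
        if not 0 < self.tau < 1:
            raise ValueError("tau must lie in (0, 1)")
        regulators = list(regulators) if regulators is not None else list(expr.gene_ids)

        meta = expr.sample_meta
        groups = [
            list(idx)
            for _, idx in meta.groupby(["timepoint", "condition"], sort=True).groups.items()
        ]
        runs: list[Network] = []
        for b in range(self.B):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=self.random_state, spawn_key=(7, b))
            )
            chosen: list[str] = []
            for group in groups:
                draws = rng.integers(0, len(group), size=len(group))
                chosen.extend(group[i] for i in draws)
            values = expr.values[chosen].copy()
            new_ids = [f"{sid}__b{i}" for i, sid in enumerate(chosen)]
            values.columns = new_ids
            meta_rs = meta.loc[chosen].copy()
            meta_rs.index = new_ids
            resampled = ExpressionMatrix(values, meta_rs)
            run = GRNInference(
                n_trees=self.n_trees,
                candidates_per_split=self.candidates_per_split,
                min_samples_leaf=self.min_samples_leaf,
                max_depth=self.max_depth,
                bagging=self.bagging,
                random_state=_derived_seed(self.random_state, 8, b),
            ).fit(resampled, regulators=regulators)
            runs.append(run.network_)
        self.network_, self.consensus_ = consensus_from_runs(runs, self.tau)
        self.regulators_ = tuple(regulators)
        return self


def infer_grn(
    expr: ExpressionMatrix,
    regulator_list: Sequence[str],
    params: InferenceParams | None = None,
) -> Network:
    """One-shot TF–TF network inference (see :class:`GRNInference`)."""
    params = params or InferenceParams()
    est = GRNInference(
        n_trees=params.n_trees,
        candidates_per_split=params.candidates_per_split,
        min_samples_leaf=params.min_samples_leaf,
        max_depth=params.max_depth,
        bagging=params.bagging,
        random_state=params.seed,
    )
    return est.fit(expr, regulators=regulator_list).network_


def bootstrap_consensus(
    expr: ExpressionMatrix,
    regulator_list: Sequence[str],
    params: InferenceParams | None = None,
    B: int = 50,
    tau: float = 0.5,
) -> tuple[Network, pd.DataFrame]:
    """Consensus network + per-edge support table (see
    :class:`GRNBootstrapConsensus`)."""
    params = params or InferenceParams()
    est = GRNBootstrapConsensus(
        n_trees=params.n_trees,
        candidates_per_split=params.candidates_per_split,
        min_samples_leaf=params.min_samples_leaf,
        max_depth=params.max_depth,
        bagging=params.bagging,
        random_state=params.seed,
        B=B,
        tau=tau,
    )
    est.fit(expr, regulators=regulator_list)
    return est.network_, est.consensus_
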