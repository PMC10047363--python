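"""Tree-ensemble edge importance and the bootstrap consensus rule."""

import numpy as np
import pandas as pd
import pytest

from grnkit import (
    GRNInference,
    InferenceParams,
    Network,
    bootstrap_consensus,
    consensus_from_runs,
    infer_grn,
    target_importances,
)
from conftest import make_expr, net_from_edges


def best_split_variance_reduction(x: np.ndarray, y: np.ndarray) -> float:
    """Exhaustive single-split oracle: maximum impurity decrease obtainable
    by thresholding one candidate, in sklearn's (N_t/N)-weighted convention."""
    order = np.argsort(x, kind="mergesort")
    xs, ys = x[order], y[order]
    n = len(y)
    parent = ys.var()
    best = 0.0
    for i in range(1, n):
        if xs[i] == xs[i - 1]:
            continue
        left, right = ys[:i], ys[i:]
        decrease = parent - (i / n) * left.var() - ((n - i) / n) * right.var()
        best = max(best, decrease)
    return best


class TestTargetImportances:
    def test_exact_copy_regulator_dominates(self):
        rng = np.random.default_rng(0)
        n = 50
        reg = rng.normal(size=n)
        X = rng.normal(size=(11, n))
        X[0] = reg
        X = np.vstack([X, reg])  # target = exact copy of regulator R0
        genes = [f"R{i}" for i in range(11)] + ["T"]
        expr = make_expr(X, genes, [("0h", "control")] * n)
        w = target_importances(
            expr, "T", [f"R{i}" for i in range(11)],
            InferenceParams(n_trees=100, candidates_per_split="all", seed=1),
        )
        assert w.idxmax() == "R0"
        assert w["R0"] > 0.5
        np.testing.assert_allclose(w.sum(), 1.0)

    def test_constant_target_gives_zero_vector(self, caplog):
        X = np.vstack([np.random.default_rng(1).normal(size=(3, 8)), np.ones(8)])
        expr = make_expr(X, ["a", "b", "c", "t"], [("0h", "control")] * 8)
        w = target_importances(
            expr, "t", ["a", "b", "c"], InferenceParams(n_trees=20, seed=0)
        )
        assert (w == 0).all()

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(6, 20))
        genes = list("abcdef")
        expr = make_expr(X, genes, [("0h", "control")] * 20)
        perm = rng.permutation(20)
        shuffled = expr.subset_samples([expr.sample_ids[i] for i in perm])
        params = InferenceParams(n_trees=50, seed=7)
        w1 = target_importances(expr, "a", list("bcdef"), params)
        w2 = target_importances(shuffled, "a", list("bcdef"), params)
        pd.testing.assert_series_equal(w1, w2)

    def test_target_in_candidates_rejected(self, tiny_expr):
        with pytest.raises(ValueError, match="candidate"):
            target_importances(
                tiny_expr, "gA", ["gA", "gB"], InferenceParams(seed=0)
            )

    def test_stump_selects_brute_force_best_regulator(self):
        """A single depth-1 tree over all candidates must split on the
        regulator with the maximal exhaustive variance reduction, on 50
        random 8-gene problems."""
        params = InferenceParams(
            n_trees=1, candidates_per_split="all", max_depth=1,
            bagging=False, seed=0,
        )
        genes = [f"g{i}" for i in range(8)]
        agree = 0
        for trial in range(50):
            rng = np.random.default_rng(100 + trial)
            X = rng.normal(size=(8, 24))
            # plant a signal so the argmax is non-trivial in most trials
            X[7] = 0.8 * X[rng.integers(0, 7)] + 0.6 * rng.normal(size=24)
            expr = make_expr(X, genes, [("0h", "control")] * 24)
            w = target_importances(expr, "g7", genes[:7], params)
            y = X[7]
            y = (y - y.mean()) / y.std()
            oracle = np.array(
                [best_split_variance_reduction(X[i], y) for i in range(7)]
            )
            if w.idxmax() == f"g{oracle.argmax()}":
                agree += 1
        assert agree == 50


class TestInferGrn:
    def test_minimal_truth_edge_ranks_first(self):
        """With one planted edge A→B and everything else noise, A→B gets
        the highest importance among all ordered pairs."""
        rng = np.random.default_rng(5)
        n = 60
        a = rng.normal(size=n)
        b = a + 0.2 * rng.normal(size=n)
        noise = rng.normal(size=(3, n))
        expr = make_expr(
            np.vstack([a, b, noise]), ["A", "B", "c1", "c2", "c3"],
            [("0h", "control")] * n,
        )
        net = infer_grn(
            expr, ["A", "B", "c1", "c2", "c3"], InferenceParams(n_trees=100, seed=2)
        )
        top = net.edges.sort_values("weight", ascending=False).iloc[0]
        assert {top.regulator, top.target} == {"A", "B"}

    def test_no_self_edges_and_per_target_normalization(self):
        rng = np.random.default_rng(8)
        expr = make_expr(
            rng.normal(size=(6, 15)), list("abcdef"), [("0h", "control")] * 15
        )
        est = GRNInference(n_trees=30, random_state=0).fit(expr)
        net = est.network_
        assert all(r != t for r, t in net.edge_pairs())
        assert net.n_edges <= 6 * 5
        sums = est.importances_.sum(axis=1)
        for s in sums:
            assert abs(s - 1.0) < 1e-9 or s == 0.0

    def test_fewer_than_three_regulators_rejected(self, tiny_expr):
        with pytest.raises(ValueError, match="3 regulators"):
            infer_grn(tiny_expr, ["gA", "gB"], InferenceParams(seed=0))

    def test_sklearn_params_protocol(self):
        est = GRNInference(n_trees=42)
        assert est.get_params()["n_trees"] == 42
        est.set_params(n_trees=7)
        assert est.get_params()["n_trees"] == 7


class TestBootstrapConsensus:
    def _runs(self, weights_per_run):
        runs = []
        for weights in weights_per_run:
            runs.append(
                Network.from_records(
                    {
                        "regulator": "A",
                        "target": "B",
                        "weight": w,
                        "provenance": frozenset({"inferred"}),
                    }
                    for w in [weights]
                    if w > 0
                )
            )
        return runs

    def test_edge_in_three_of_four_runs_kept_with_support_075(self):
        net, consensus = consensus_from_runs(
            self._runs([0.4, 0.2, 0.0, 0.4]), tau=0.5
        )
        assert consensus.iloc[0]["support"] == 0.75
        assert net.edge_pairs() == {("A", "B")}
        row = net.edges.iloc[0]
        np.testing.assert_allclose(row.weight, (0.4 + 0.2 + 0.4) / 3)
        np.testing.assert_allclose(row.support, 0.75)

    def test_edge_in_exactly_half_the_runs_dropped(self):
        """Support 0.50 fails the strictly-more-than-half rule."""
        net, consensus = consensus_from_runs(
            self._runs([0.4, 0.2, 0.0, 0.0]), tau=0.5
        )
        assert consensus.iloc[0]["support"] == 0.5
        assert net.n_edges == 0

    def test_high_tau_keeps_only_unanimous_edges(self):
        net, _ = consensus_from_runs(self._runs([0.1, 0.1, 0.1, 0.0]), tau=0.99)
        assert net.n_edges == 0
        net, _ = consensus_from_runs(self._runs([0.1, 0.1, 0.1, 0.1]), tau=0.99)
        assert net.edge_pairs() == {("A", "B")}

    def test_raising_tau_never_adds_edges(self):
        rng = np.random.default_rng(12)
        expr = make_expr(
            rng.normal(size=(5, 12)), list("abcde"),
            [("0h", "control")] * 6 + [("24h", "control")] * 6,
        )
        params = InferenceParams(n_trees=20, seed=3)
        nets = {}
        for tau in (0.3, 0.5, 0.8):
            net, _ = bootstrap_consensus(expr, list("abcde"), params, B=6, tau=tau)
            nets[tau] = net.edge_pairs()
        assert nets[0.8] <= nets[0.5] <= nets[0.3]

    def test_consensus_deterministic(self):
        rng = np.random.default_rng(13)
        expr = make_expr(
            rng.normal(size=(4, 10)), list("abcd"), [("0h", "control")] * 10
        )
        params = InferenceParams(n_trees=15, seed=4)
        n1, c1 = bootstrap_consensus(expr, list("abcd"), params, B=4)
        n2, c2 = bootstrap_consensus(expr, list("abcd"), params, B=4)
        pd.testing.assert_frame_equal(c1, c2)
        pd.testing.assert_frame_equal(n1.sorted_edges(), n2.sorted_edges())

    def test_validation(self, tiny_expr):
        with pytest.raises(ValueError):
            consensus_from_runs([], tau=0.5)
        with pytest.raises(ValueError):
            consensus_from_runs(self._runs([1, 1]), tau=1.5)
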