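"""Statistical and structural properties of the synthetic-data generators."""

import numpy as np
import networkx as nx
import pandas as pd
import pytest

from grnkit import (
    SimulationDesign,
    concat_expression,
    corrupt_prior,
    derive_differential_tables,
    sample_truth_network,
    simulate_accessibility,
    simulate_timecourse,
    synthetic_de_table,
)
from grnkit.simulate import benjamini_hochberg


def brute_force_bh(pvalues):
    """Independent step-up implementation of the BH procedure."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adjusted = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, p[i] * m / rank_from_top)
        adjusted[i] = running_min
    return adjusted


class TestTruthNetwork:
    def test_deterministic_and_roughly_sized(self):
        a = sample_truth_network(30, 2.0, seed=1)
        b = sample_truth_network(30, 2.0, seed=1)
        assert a.network.edge_pairs() == b.network.edge_pairs()
        assert a.network.sign_map() == b.network.sign_map()
        assert (a.basal == b.basal).all()
        assert 45 <= a.network.n_edges <= 62  # ~60 requested, DAG packing caps it

    def test_is_acyclic_hierarchy(self):
        truth = sample_truth_network(40, 2.0, seed=7)
        g = nx.DiGraph()
        g.add_edges_from(truth.network.edge_pairs())
        assert nx.is_directed_acyclic_graph(g)

    def test_all_activating_when_fraction_one(self):
        truth = sample_truth_network(20, 2.0, activation_fraction=1.0, seed=2)
        assert set(truth.network.edges["sign"]) == {1}

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            sample_truth_network(4, 2.0)
        with pytest.raises(ValueError):
            sample_truth_network(10, 2.0, activation_fraction=0.0)
        with pytest.raises(ValueError):
            sample_truth_network(10, -1.0)

    def test_out_degrees_are_heavy_tailed(self):
        """A minority of regulators should dominate: the maximum out-degree
        exceeds 3× the mean out-degree in at least 80% of 100 draws."""
        hits = 0
        for seed in range(100):
            truth = sample_truth_network(30, 2.0, seed=seed)
            out_degrees = truth.network.edges.groupby("regulator").size()
            if out_degrees.max() > 3 * 2.0:
                hits += 1
        assert hits >= 80


class TestTimecourse:
    def test_same_seed_identical_matrices(self):
        truth = sample_truth_network(12, 2.0, seed=5)
        design = SimulationDesign()
        a = simulate_timecourse(truth, design)
        b = simulate_timecourse(truth, design)
        for cond in design.conditions:
            pd.testing.assert_frame_equal(a[cond].values, b[cond].values)

    def test_empty_network_no_noise_is_constant_at_basal(self):
        truth = sample_truth_network(
            6, 0.0, seed=3, noise_sd=1e-9, bio_sd=0.0, module_fraction=0.0
        )
        design = SimulationDesign(stimulus=0.0)
        mats = simulate_timecourse(truth, design)
        for cond in design.conditions:
            vals = mats[cond].values
            for col in vals.columns:
                np.testing.assert_allclose(
                    vals[col], truth.basal.to_numpy(), atol=1e-6
                )

    def test_stimulus_propagates_through_activating_edge(self):
        """Single edge A→B (+): stimulating A raises B's mean at the later
        time points relative to its control mean, matching a direct
        evaluation of the update rule."""
        from grnkit.io import Network
        import pandas as pd

        genes = ["A", "B", "C", "D", "E"]
        net = Network.from_records(
            [{"regulator": "A", "target": "B", "sign": 1, "weight": 1.0}],
            extra_nodes=genes,
        )
        from grnkit.simulate import GroundTruth

        truth = GroundTruth(
            network=net,
            basal=pd.Series(5.0, index=pd.Index(genes, name="gene_id")),
            edge_effect={("A", "B"): 1.0},
            noise_sd=0.05,
            bio_sd=0.2,
            treatment_module=frozenset({"A"}),
            seed=11,
        )
        design = SimulationDesign(replicates=6, stimulus=2.0)
        mats = simulate_timecourse(truth, design)
        late = ["72h"]
        for cond, mat in mats.items():
            mats[cond] = mat
        b_treated = (
            mats["treated"].values.loc["B", mats["treated"].samples_where(timepoint="72h")]
        )
        b_control = (
            mats["control"].values.loc["B", mats["control"].samples_where(timepoint="72h")]
        )
        assert b_treated.mean() > b_control.mean() + 0.5
        # C has no path from A: unaffected
        c_treated = (
            mats["treated"].values.loc["C", mats["treated"].samples_where(timepoint="72h")]
        )
        c_control = (
            mats["control"].values.loc["C", mats["control"].samples_where(timepoint="72h")]
        )
        assert abs(c_treated.mean() - c_control.mean()) < 0.5

    def test_expression_nonnegative(self):
        truth = sample_truth_network(15, 2.0, seed=9, bio_sd=3.0)
        mats = simulate_timecourse(truth, SimulationDesign())
        for mat in mats.values():
            assert (mat.values.to_numpy() >= 0).all()


class TestDifferentialTables:
    def test_identical_groups_give_zero_log2fc_and_no_calls(self):
        truth = sample_truth_network(50, 0.0, seed=13, module_fraction=0.0)
        design = SimulationDesign(stimulus=0.0)
        mats = simulate_timecourse(truth, design)
        expr = mats["control"]
        # same group against itself: log2FC exactly 0, p = 1
        tables = derive_differential_tables(
            expr, [(("24h", "control"), ("24h", "control"))]
        )
        table = next(iter(tables.values()))
        np.testing.assert_allclose(table.table["log2fc"], 0.0)
        assert set(table.table["call"]) == {"unchanged"}

    def test_too_few_replicates_is_an_error(self, tiny_expr):
        with pytest.raises(ValueError, match="replicates"):
            derive_differential_tables(
                tiny_expr, [(("0h", "control"), ("24h", "control"))]
            )

    def test_null_simulation_type_one_error_calibrated(self):
        """Pure-noise two-group comparison: the raw Welch p < 0.05 rate over
        2000 genes stays within 0.05 ± 0.02."""
        truth = sample_truth_network(2000, 0.0, seed=17, module_fraction=0.0)
        design = SimulationDesign(stimulus=0.0, replicates=5)
        mats = simulate_timecourse(truth, design)
        expr = concat_expression([mats[c] for c in design.conditions])
        tables = derive_differential_tables(
            expr, [(("24h", "treated"), ("24h", "control"))]
        )
        rate = (next(iter(tables.values())).table["pvalue"] < 0.05).mean()
        assert 0.03 <= rate <= 0.07

    def test_bh_matches_brute_force_step_up(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 40))
            np.testing.assert_allclose(
                benjamini_hochberg(p), brute_force_bh(p), atol=1e-12
            )


class TestCorruptPrior:
    def test_zero_rates_reproduce_truth(self):
        truth = sample_truth_network(20, 2.0, seed=31)
        prior = corrupt_prior(truth, 0.0, 0.0, seed=1)
        assert prior.edge_pairs() == truth.network.edge_pairs()
        assert prior.sign_map() == truth.network.sign_map()

    def test_high_false_negative_rate_empties_prior(self):
        truth = sample_truth_network(20, 2.0, seed=31)
        prior = corrupt_prior(truth, 0.999, 0.0, seed=1)
        assert prior.n_edges <= 2

    def test_expected_edge_retention(self):
        """At a 20% false-negative rate the retained-edge fraction averages
        0.8 ± 0.03 over 200 draws (binomial expectation)."""
        truth = sample_truth_network(30, 2.0, seed=31)
        true_pairs = truth.network.edge_pairs()
        fracs = [
            len(corrupt_prior(truth, 0.2, 0.2, seed=s).edge_pairs() & true_pairs)
            / len(true_pairs)
            for s in range(200)
        ]
        assert abs(np.mean(fracs) - 0.8) <= 0.03

    def test_retained_signs_preserved(self):
        truth = sample_truth_network(20, 2.0, seed=37)
        prior = corrupt_prior(truth, 0.3, 0.3, seed=2)
        truth_signs = truth.network.sign_map()
        for pair, sign in prior.sign_map().items():
            if pair in truth_signs:
                assert sign == truth_signs[pair]


class TestAccessibility:
    def test_rho_one_noise_free_is_rank_perfect(self):
        de = synthetic_de_table(200, seed=41)
        acc, _ = simulate_accessibility(de, rho=1.0, n_off_target=0, seed=41)
        promoter = acc.peaks[acc.peaks["peak_id"].str.startswith("peak_")]
        expr = de.table.loc[
            promoter["peak_id"].str.replace("peak_", "", regex=False), "log2fc"
        ]
        rho = pd.Series(promoter["log2fc"].to_numpy()).corr(
            pd.Series(expr.to_numpy()), method="spearman"
        )
        assert rho > 0.9999

    def test_rho_zero_sample_correlation_near_zero(self):
        de = synthetic_de_table(2000, seed=43)
        acc, _ = simulate_accessibility(de, rho=0.0, n_off_target=0, seed=43)
        promoter = acc.peaks[acc.peaks["peak_id"].str.startswith("peak_")]
        expr = de.table.loc[
            promoter["peak_id"].str.replace("peak_", "", regex=False), "log2fc"
        ]
        r = np.corrcoef(promoter["log2fc"], expr)[0, 1]
        assert abs(r) < 0.05

    def test_off_target_peaks_are_distal(self):
        de = synthetic_de_table(50, seed=47)
        acc, tss = simulate_accessibility(de, rho=0.5, n_off_target=30, seed=47)
        distal = acc.peaks[acc.peaks["peak_id"].str.startswith("distal_")]
        positions = tss.table["tss"].to_numpy()
        for row in distal.itertuples(index=False):
            midpoint = (row.start + row.end) // 2
            assert np.abs(positions - midpoint).min() > 2000

    def test_significant_fraction_configurable(self):
        de = synthetic_de_table(1000, seed=53)
        acc, _ = simulate_accessibility(
            de, rho=0.5, n_off_target=0, seed=53, frac_significant=0.6
        )
        frac = (acc.peaks["fdr"] < 0.05).mean()
        assert abs(frac - 0.6) < 0.02
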