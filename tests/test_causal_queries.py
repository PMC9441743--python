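"""Do-calculus: graph mutilation, adjustment-formula equivalence, edge signs."""

import numpy as np
import pandas as pd
import pytest

from causalbag.bayesian_network import (
    BayesianNetworkModel,
    CPDTable,
    fit_cpds,
    query_conditional,
)
from causalbag.causal_queries import (
    classify_edge_sign,
    intervene,
    interventional_distribution,
    observe_vs_intervene_table,
    plot_observe_vs_intervene,
    to_dot,
)
from causalbag.structure_learning import DAGStructure
from oracles import backdoor_adjustment, conditional_by_enumeration, random_ternary_model


def confounded_triangle(rng) -> BayesianNetworkModel:
    """Z -> X, Z -> Y, X -> Y with random Dirichlet CPTs."""
    dag = DAGStructure(
        nodes=("z", "x", "y"),
        edges={("z", "x"): 1.0, ("z", "y"): 1.0, ("x", "y"): 1.0},
    )
    cpds = {
        "z": CPDTable("z", (), (), rng.dirichlet(np.ones(3), 1)),
        "x": CPDTable("x", ("z",), (3,), rng.dirichlet(np.ones(3), 3)),
        "y": CPDTable("y", ("x", "z"), (3, 3), rng.dirichlet(np.ones(3), 9)),
    }
    return BayesianNetworkModel(dag=dag, cpds=cpds)


class TestIntervene:
    def test_root_intervention_changes_only_its_marginal(self, rng):
        model = confounded_triangle(rng)
        mut = intervene(model, "z", 2)
        assert mut.dag.edges == model.dag.edges  # z had no incoming edges
        np.testing.assert_allclose(mut.cpds["z"].table, [[0, 0, 1]])
        np.testing.assert_allclose(mut.cpds["y"].table, model.cpds["y"].table)

    def test_incoming_edges_severed_and_cpd_clamped(self, rng):
        model = confounded_triangle(rng)
        mut = intervene(model, "x", 1)
        assert ("z", "x") not in mut.dag.edges
        assert ("z", "y") in mut.dag.edges and ("x", "y") in mut.dag.edges
        assert mut.cpds["x"].parents == ()
        np.testing.assert_allclose(mut.cpds["x"].table, [[0, 1, 0]])

    def test_double_intervention_last_assignment_wins(self, rng):
        model = confounded_triangle(rng)
        mut = intervene(intervene(model, "x", 0), "x", 2)
        np.testing.assert_allclose(mut.cpds["x"].table, [[0, 0, 1]])
        again = intervene(mut, "x", 2)
        np.testing.assert_allclose(again.cpds["x"].table, mut.cpds["x"].table)

    def test_mutilated_model_satisfies_all_invariants(self, rng):
        model = random_ternary_model(rng)
        non_root = next(v for v in model.nodes if model.dag.parents(v))
        mut = intervene(model, non_root, 0)
        assert mut.dag.is_acyclic()
        for cpd in mut.cpds.values():
            np.testing.assert_allclose(cpd.table.sum(axis=1), 1.0, atol=1e-12)
        # joint still sums to 1
        from oracles import enumerate_joint
        assert sum(enumerate_joint(mut).values()) == pytest.approx(1.0, abs=1e-9)

    def test_unknown_node_or_state_rejected(self, rng):
        model = confounded_triangle(rng)
        with pytest.raises(ValueError):
            intervene(model, "ghost", 0)
        with pytest.raises(ValueError):
            intervene(model, "x", 7)


class TestInterventionalDistribution:
    def test_matches_backdoor_adjustment_on_confounded_triangles(self):
        rng = np.random.default_rng(31)
        for _ in range(15):
            model = confounded_triangle(rng)
            x_state = int(rng.integers(3))
            got = interventional_distribution(model, "y", "x", x_state)
            expected = backdoor_adjustment(model, "y", "x", x_state, adjust=("z",))
            np.testing.assert_allclose(got.probabilities, expected, atol=1e-9)
            assert got.mode == "interventional"

    def test_matches_truncated_factorization_on_random_models(self):
        rng = np.random.default_rng(32)
        for _ in range(10):
            model = random_ternary_model(rng)
            target = model.nodes[int(rng.integers(8))]
            do_node = next(v for v in model.nodes if v != target)
            do_state = int(rng.integers(3))
            got = interventional_distribution(model, target, do_node, do_state)
            expected = conditional_by_enumeration(
                model, target, {}, do={do_node: do_state}
            )
            np.testing.assert_allclose(got.probabilities, expected, atol=1e-9)

    def test_root_node_observation_equals_intervention(self, rng):
        model = confounded_triangle(rng)
        for s in range(3):
            obs = query_conditional(model, "y", {"z": s})
            do = interventional_distribution(model, "y", "z", s)
            np.testing.assert_allclose(obs.probabilities, do.probabilities, atol=1e-12)

    def test_intervention_on_non_ancestor_leaves_marginal_unchanged(self, rng):
        model = confounded_triangle(rng)
        marginal = query_conditional(model, "x", {})
        do = interventional_distribution(model, "x", "y", 1)  # y is downstream of x
        np.testing.assert_allclose(do.probabilities, marginal.probabilities, atol=1e-12)


class TestObserveVsInterveneTable:
    def test_rows_sum_to_one_and_cover_all_states_and_modes(self, rng):
        model = confounded_triangle(rng)
        table = observe_vs_intervene_table(model, "x", "y")
        prob_cols = [c for c in table.columns if c.startswith("p_")]
        np.testing.assert_allclose(table[prob_cols].sum(axis=1), 1.0, atol=1e-9)
        assert len(table) == 6  # 3 states x 2 modes
        assert set(table["mode"]) == {"observational", "interventional"}

    def test_root_risk_factor_columns_identical(self, rng):
        model = confounded_triangle(rng)
        table = observe_vs_intervene_table(model, "z", "y")
        prob_cols = [c for c in table.columns if c.startswith("p_")]
        for s in range(3):
            grp = table[table["state_code"] == s]
            obs = grp[grp["mode"] == "observational"][prob_cols].to_numpy()
            do = grp[grp["mode"] == "interventional"][prob_cols].to_numpy()
            np.testing.assert_allclose(obs, do, atol=1e-12)

    def test_confounding_separates_observation_from_intervention(self, strong_cohort):
        """BMI has parent WHR which also points at BAG, so conditioning and
        intervening on BMI must differ on the fitted study network."""
        from causalbag.discretize import discretize_cohort
        from causalbag.synthetic_data import study_true_edges

        dag = DAGStructure(nodes=tuple(
            ["age", "sex", "whr", "bmi", "bp", "smoking", "drinking", "bag"]
        ), edges={e: 1.0 for e in study_true_edges()})
        disc = discretize_cohort(strong_cohort).drop(columns=["subject_id"])
        model = fit_cpds(dag, disc, pseudo_count=1.0)
        table = observe_vs_intervene_table(model, "bmi", "bag")
        prob_cols = [c for c in table.columns if c.startswith("p_")]
        high = table[table["state_code"] == 2]
        obs = high[high["mode"] == "observational"][prob_cols].to_numpy()[0]
        do = high[high["mode"] == "interventional"][prob_cols].to_numpy()[0]
        assert np.abs(obs - do).sum() > 0.01

    def test_law_of_total_probability_on_observational_column(self, rng):
        model = confounded_triangle(rng)
        table = observe_vs_intervene_table(model, "x", "y")
        prob_cols = [c for c in table.columns if c.startswith("p_")]
        px = query_conditional(model, "x", {}).probabilities
        marginal = query_conditional(model, "y", {}).probabilities
        obs = table[table["mode"] == "observational"].sort_values("state_code")
        mixture = (obs[prob_cols].to_numpy() * px[:, None]).sum(axis=0)
        np.testing.assert_allclose(mixture, marginal, atol=1e-9)


def two_node_model(child_rows: np.ndarray) -> BayesianNetworkModel:
    dag = DAGStructure(nodes=("p", "c"), edges={("p", "c"): 1.0})
    cpds = {
        "p": CPDTable("p", (), (), np.full((1, 3), 1 / 3)),
        "c": CPDTable("c", ("p",), (3,), child_rows),
    }
    return BayesianNetworkModel(dag=dag, cpds=cpds)


class TestEdgeSigns:
    def test_monotone_increasing_cpd_is_positive(self):
        rows = np.array([[0.8, 0.15, 0.05], [0.3, 0.4, 0.3], [0.05, 0.15, 0.8]])
        sign = classify_edge_sign(two_node_model(rows), ("p", "c"))
        assert sign.label == "positive"

    def test_reversed_cpd_is_negative(self):
        rows = np.array([[0.05, 0.15, 0.8], [0.3, 0.4, 0.3], [0.8, 0.15, 0.05]])
        sign = classify_edge_sign(two_node_model(rows), ("p", "c"))
        assert sign.label == "negative"

    def test_v_shaped_cpd_is_nonlinear(self):
        rows = np.array([[0.1, 0.1, 0.8], [0.8, 0.1, 0.1], [0.1, 0.1, 0.8]])
        sign = classify_edge_sign(two_node_model(rows), ("p", "c"))
        assert sign.label == "nonlinear"
        assert not sign.zero_effect

    def test_constant_cpd_is_nonlinear_with_zero_effect_flag(self):
        rows = np.tile([0.2, 0.3, 0.5], (3, 1))
        sign = classify_edge_sign(two_node_model(rows), ("p", "c"))
        assert sign.label == "nonlinear"
        assert sign.zero_effect

    def test_absent_edge_rejected(self, rng):
        model = confounded_triangle(rng)
        with pytest.raises(ValueError):
            classify_edge_sign(model, ("y", "x"))


class TestExports:
    def test_dot_export_styles_edges_by_sign(self):
        rows = np.array([[0.8, 0.15, 0.05], [0.3, 0.4, 0.3], [0.05, 0.15, 0.8]])
        dot = to_dot(two_node_model(rows))
        assert '"p" -> "c" [color=red, style=solid];' in dot

    def test_plot_writes_figure(self, rng, tmp_path):
        model = confounded_triangle(rng)
        table = observe_vs_intervene_table(model, "x", "y")
        path = tmp_path / "fig.png"
        plot_observe_vs_intervene(table, "x", "y", path=path)
        assert path.stat().st_size > 0
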