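"""Discrete BN: Dirichlet CPD fitting, exact inference, CV AUC validation."""

import numpy as np
import pandas as pd
import pytest

from causalbag.bayesian_network import (
    BayesianNetworkModel,
    CPDTable,
    ImpossibleEvidenceError,
    UndefinedCPDError,
    crossvalidated_auc,
    fit_cpds,
    full_evidence_probabilities,
    predict_node,
    query_conditional,
)
from causalbag.structure_learning import DAGStructure
from oracles import conditional_by_enumeration, enumerate_joint, random_ternary_model


def single_node_dag():
    return DAGStructure(nodes=("x",), edges={})


def chain_dag():
    return DAGStructure(nodes=("a", "b"), edges={("a", "b"): 1.0})


class TestFitCpds:
    def test_maximum_likelihood_counts(self):
        data = pd.DataFrame({"x": [0] * 7 + [1] * 3})
        model = fit_cpds(single_node_dag(), data, pseudo_count=0.0)
        np.testing.assert_allclose(model.cpds["x"].table, [[0.7, 0.3]])

    def test_dirichlet_posterior_mean_with_unit_prior(self):
        data = pd.DataFrame({"x": [0] * 7 + [1] * 3})
        model = fit_cpds(single_node_dag(), data, pseudo_count=1.0)
        np.testing.assert_allclose(model.cpds["x"].table, [[8 / 12, 4 / 12]])

    def test_unseen_parent_configuration_gets_uniform_prior_row(self):
        data = pd.DataFrame({"a": [0, 0, 0], "b": [0, 1, 1]})
        model = fit_cpds(chain_dag(), data, pseudo_count=1.0,
                         cardinalities={"a": 3, "b": 2})
        np.testing.assert_allclose(model.cpds["b"].table[1], [0.5, 0.5])
        np.testing.assert_allclose(model.cpds["b"].table[2], [0.5, 0.5])

    def test_rows_normalized_on_random_fits(self, rng):
        model = random_ternary_model(rng)
        data = pd.DataFrame({v: rng.integers(0, 3, 200) for v in model.nodes})
        fitted = fit_cpds(model.dag, data, pseudo_count=1.0)
        for cpd in fitted.cpds.values():
            np.testing.assert_allclose(cpd.table.sum(axis=1), 1.0, atol=1e-9)

    def test_empty_data_with_zero_pseudo_count_is_undefined(self):
        with pytest.raises(UndefinedCPDError):
            fit_cpds(single_node_dag(), pd.DataFrame({"x": []}), pseudo_count=0.0,
                     cardinalities={"x": 2})

    def test_parameter_recovery_at_large_n(self, study_scm, study_cohort):
        """Fitted CPDs converge to the generating CPT (smoking | sex)."""
        from causalbag import synthetic_data as sd

        cohort = sd.generate_scm_cohort(study_scm, 50_000, seed=77)
        dag = DAGStructure(nodes=("sex", "smoking"), edges={("sex", "smoking"): 1.0})
        model = fit_cpds(dag, cohort[["sex", "smoking"]], pseudo_count=1.0)
        truth = study_scm.mechanisms["smoking"].table()
        assert np.abs(model.cpds["smoking"].table - truth).max() < 0.02


class TestInference:
    def test_root_marginal_with_empty_evidence(self, rng):
        model = random_ternary_model(rng)
        root = next(v for v in model.nodes if not model.dag.parents(v))
        dist = query_conditional(model, root, {})
        np.testing.assert_allclose(dist.probabilities, model.cpds[root].table[0],
                                   atol=1e-12)

    def test_fully_specified_parents_of_leaf_return_cpd_row(self, rng):
        model = random_ternary_model(rng, d=5)
        leaf = next(v for v in model.nodes
                    if not model.dag.children(v) and model.dag.parents(v))
        cpd = model.cpds[leaf]
        ev = {p: 1 for p in cpd.parents}
        dist = query_conditional(model, leaf, ev)
        np.testing.assert_allclose(dist.probabilities,
                                   cpd.table[cpd.row_index(ev)], atol=1e-12)

    def test_variable_elimination_matches_enumeration_on_random_networks(self):
        rng = np.random.default_rng(2024)
        for _ in range(15):
            model = random_ternary_model(rng)
            target = model.nodes[rng.integers(8)]
            ev = {v: int(rng.integers(3)) for v in model.nodes
                  if v != target and rng.random() < 0.3}
            try:
                expected = conditional_by_enumeration(model, target, ev)
            except ZeroDivisionError:
                continue
            got = query_conditional(model, target, ev)
            np.testing.assert_allclose(got.probabilities, expected, atol=1e-9)

    def test_enumerated_joint_of_fitted_model_sums_to_one(self, rng):
        model = random_ternary_model(rng)
        total = sum(enumerate_joint(model).values())
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_impossible_evidence_raises(self):
        dag = chain_dag()
        cpds = {
            "a": CPDTable("a", (), (), np.array([[1.0, 0.0]])),
            "b": CPDTable("b", ("a",), (2,), np.array([[0.5, 0.5], [0.5, 0.5]])),
        }
        model = BayesianNetworkModel(dag=dag, cpds=cpds)
        with pytest.raises(ImpossibleEvidenceError):
            query_conditional(model, "b", {"a": 1})

    def test_invalid_queries_rejected(self, rng):
        model = random_ternary_model(rng)
        with pytest.raises(ValueError):
            query_conditional(model, "nope", {})
        with pytest.raises(ValueError):
            query_conditional(model, model.nodes[0], {model.nodes[0]: 1})
        with pytest.raises(ValueError):
            query_conditional(model, model.nodes[0], {model.nodes[1]: 9})


class TestPredictNode:
    def test_deterministic_cpds_predict_generating_value(self):
        dag = chain_dag()
        cpds = {
            "a": CPDTable("a", (), (), np.array([[0.5, 0.5]])),
            "b": CPDTable("b", ("a",), (2,), np.array([[1.0, 0.0], [0.0, 1.0]])),
        }
        model = BayesianNetworkModel(dag=dag, cpds=cpds)
        for a in (0, 1):
            state, _ = predict_node(model, "b", {"a": a})
            assert state == a

    def test_target_independent_of_evidence_predicts_marginal_mode(self):
        dag = DAGStructure(nodes=("a", "b"), edges={})
        cpds = {
            "a": CPDTable("a", (), (), np.array([[0.5, 0.5]])),
            "b": CPDTable("b", (), (), np.array([[0.2, 0.8]])),
        }
        model = BayesianNetworkModel(dag=dag, cpds=cpds)
        state, probs = predict_node(model, "b", {"a": 0})
        assert state == 1
        np.testing.assert_allclose(probs, [0.2, 0.8], atol=1e-12)

    def test_tie_breaks_toward_lower_state_code(self):
        dag = single_node_dag()
        model = BayesianNetworkModel(
            dag=dag, cpds={"x": CPDTable("x", (), (), np.array([[0.5, 0.5]]))}
        )
        state, _ = predict_node(model, "x", {})
        assert state == 0

    def test_vectorized_full_evidence_scores_match_query_conditional(self, rng):
        model = random_ternary_model(rng)
        data = pd.DataFrame({v: rng.integers(0, 3, 20) for v in model.nodes})
        target = model.nodes[3]
        probs = full_evidence_probabilities(model, target, data)
        for i in range(len(data)):
            ev = {v: int(data[v].iloc[i]) for v in model.nodes if v != target}
            dist = query_conditional(model, target, ev)
            np.testing.assert_allclose(probs[i], dist.probabilities, atol=1e-9)


class TestCrossValidatedAuc:
    def test_independent_node_scores_chance_and_copy_node_high(self, rng):
        n = 5000
        parent = rng.integers(0, 2, n)
        noise = rng.integers(0, 2, n)
        copy = np.where(rng.random(n) < 0.9, parent, 1 - parent)
        data = pd.DataFrame({"parent": parent, "noise": noise, "copy": copy})
        dag = DAGStructure(
            nodes=("parent", "noise", "copy"), edges={("parent", "copy"): 1.0}
        )
        report = crossvalidated_auc(dag, data, k=10, repeats=10, seed=0)
        assert abs(report.node_means["noise"] - 0.5) < 0.05
        assert report.node_means["copy"] > 0.85

    def test_report_covers_all_nodes_plus_overall_average(self, strong_cohort):
        from causalbag.discretize import discretize_cohort
        from causalbag.structure_learning import (
            default_constraints, learn_weighted_adjacency, prepare_structure_data,
            prune_edges,
        )

        W = learn_weighted_adjacency(
            prepare_structure_data(strong_cohort), default_constraints(), 0.1
        )
        dag = prune_edges(W, 0.25)
        disc = discretize_cohort(strong_cohort).drop(columns=["subject_id"])
        report = crossvalidated_auc(dag, disc, k=5, repeats=2, seed=1)
        assert set(report.node_means) == set(dag.nodes)
        frame = report.to_frame()
        assert len(frame) == len(dag.nodes) + 1
        assert frame.iloc[-1]["node"] == "average"
        assert report.overall_mean == pytest.approx(
            np.mean(list(report.node_means.values()))
        )
        assert all(s >= 0 for s in report.node_sds.values())


class TestSerialization:
    def test_json_round_trip_preserves_inference(self, rng, tmp_path):
        model = random_ternary_model(rng)
        path = tmp_path / "model.json"
        model.to_json(path)
        back = BayesianNetworkModel.from_json(path)
        assert back.nodes == model.nodes
        assert back.dag.edges == model.dag.edges
        target = model.nodes[2]
        ev = {model.nodes[5]: 1}
        np.testing.assert_allclose(
            query_conditional(back, target, ev).probabilities,
            query_conditional(model, target, ev).probabilities,
            atol=1e-12,
        )
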