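"""End-to-end study pipeline on a synthetic cohort.

simulate -> brain-age regression + bias correction -> clinical
discretization -> constrained NOTEARS -> threshold selection by CV AUC ->
Bayesian network fit -> observational vs interventional reports.  A run
is fully determined by one :class:`PipelineConfig` plus one integer seed
and writes plain-text artifacts (CSV/JSON) byte-reproducibly.

The morphometric features are driven by the subject's biological brain
age (chronological age + the SCM's BAG), so the estimated, bias-corrected
BAG recovers the simulated one and the downstream causal analysis has
real signal to find.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import brain_age as ba
from . import bayesian_network as bn
from . import causal_queries as cq
from . import discretize as dz
from . import structure_learning as sl
from . import synthetic_data as sd


@dataclass(frozen=True)
class PipelineConfig:
    """Everything that defines one pipeline run apart from the seed."""

    n: int = 2025
    strong_scm: bool = False
    #: drive features by age + BAG (biological brain age) rather than age
    #: alone; True gives the estimated BAG real signal, False makes the
    #: features a pure function of chronological age
    bag_in_features: bool = True
    feature_noise_sd: float = 0.0
    cv_folds: int = 10
    hidden_layers: tuple[int, ...] = (256, 128)
    max_epochs: int = 500
    patience: int = 20
    l1_penalty: float = 0.1
    threshold_grid: tuple[float, ...] = (0.05, 0.1, 0.15, 0.2, 0.3)
    threshold_cv_repeats: int = 3
    auc_repeats: int = 10
    pseudo_count: float = 1.0

    def to_dict(self) -> dict:
        return {
            "n": self.n, "strong_scm": self.strong_scm,
            "bag_in_features": self.bag_in_features,
            "feature_noise_sd": self.feature_noise_sd,
            "cv_folds": self.cv_folds, "hidden_layers": list(self.hidden_layers),
            "max_epochs": self.max_epochs, "patience": self.patience,
            "l1_penalty": self.l1_penalty,
            "threshold_grid": list(self.threshold_grid),
            "threshold_cv_repeats": self.threshold_cv_repeats,
            "auc_repeats": self.auc_repeats, "pseudo_count": self.pseudo_count,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kw = dict(d)
        if "hidden_layers" in kw:
            kw["hidden_layers"] = tuple(kw["hidden_layers"])
        if "threshold_grid" in kw:
            kw["threshold_grid"] = tuple(kw["threshold_grid"])
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


STATE_NAMES = {
    "age": ("low", "normal", "high"),
    "sex": ("male", "female"),
    "whr": ("low", "normal", "high"),
    "bmi": ("low", "normal", "high"),
    "bp": ("low", "normal", "high"),
    "smoking": ("non", "past", "current"),
    "drinking": ("non", "occasional", "regular"),
    "bag": ("low", "normal", "high"),
}


def run_pipeline(config: PipelineConfig, seed: int, outdir) -> dict:
    """Run every stage and write artifacts under ``outdir``.

    Returns a summary dict (also written as ``summary.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    sub = lambda: int(rng.integers(2**31))
    seeds = {k: sub() for k in ("cohort", "features", "folds", "mlp", "threshold", "auc")}

    # 1. simulate
    spec = sd.default_study_scm(strong=config.strong_scm)
    cohort = sd.generate_scm_cohort(spec, config.n, seed=seeds["cohort"])
    cohort["brain_age_true"] = cohort["age"] + (
        cohort["bag"] if config.bag_in_features else 0.0
    )
    slopes, intercepts, _ = sd.default_morphometric_params(seed=seeds["features"])
    noise = np.full(sd.N_FEATURES, config.feature_noise_sd)
    features = sd.generate_morphometrics(
        cohort, slopes, noise, seed=seeds["features"],
        intercepts=intercepts, age_column="brain_age_true",
    )
    cohort.drop(columns=["brain_age_true"]).to_csv(outdir / "cohort.csv", index=False)

    # 2. brain age + bias correction + BAG
    ages = cohort["age"].to_numpy()
    folds = ba.make_stratified_folds(ages, k=config.cv_folds, seed=seeds["folds"])
    reg_cfg = ba.RegressorConfig(
        hidden_layers=config.hidden_layers, max_epochs=config.max_epochs,
        patience=config.patience, seed=seeds["mlp"],
    )
    result = ba.run_brain_age(features, ages, reg_cfg, folds)
    pred = result.to_frame(ages, subject_id=cohort["subject_id"])
    pred.to_csv(outdir / "predictions.csv", index=False, float_format="%.6f")
    with open(outdir / "brain_age_report.json", "w") as fh:
        json.dump(result.report(), fh, indent=1, sort_keys=True)

    # 3. discretize (estimated BAG replaces the simulated one downstream)
    analysed = cohort.drop(columns=["bag"]).assign(bag=result.bag)
    disc = dz.discretize_cohort(analysed)
    disc.to_csv(outdir / "discrete.csv", index=False)

    # 4. structure learning + threshold selection
    cont = sl.prepare_structure_data(analysed)
    W = sl.learn_weighted_adjacency(
        cont, constraints=sl.default_constraints(), l1_penalty=config.l1_penalty
    )
    disc_nodes = disc.drop(columns=["subject_id"], errors="ignore")
    threshold, thr_report = sl.select_threshold(
        W, config.threshold_grid, disc_nodes,
        k=config.cv_folds, repeats=config.threshold_cv_repeats,
        seed=seeds["threshold"], pseudo_count=config.pseudo_count,
    )
    dag = sl.prune_edges(W, threshold)
    dag.to_frame().to_csv(outdir / "dag.csv", index=False, float_format="%.6f")
    thr_report.to_csv(outdir / "threshold_report.csv", index=False, float_format="%.6f")

    # 5. fit + validate the Bayesian network
    model = bn.fit_cpds(
        dag, disc_nodes, pseudo_count=config.pseudo_count,
        cardinalities=dict(sd.STUDY_CARDINALITIES), state_names=STATE_NAMES,
    )
    model.to_json(outdir / "model.json")
    auc = bn.crossvalidated_auc(
        dag, disc_nodes, k=config.cv_folds, repeats=config.auc_repeats,
        seed=seeds["auc"], pseudo_count=config.pseudo_count,
        cardinalities=dict(sd.STUDY_CARDINALITIES),
    )
    auc.to_frame().to_csv(outdir / "auc_report.csv", index=False, float_format="%.6f")

    # 6. observational vs interventional reports + edge signs
    bag_parents = sorted(model.dag.parents("bag"))
    for rf in bag_parents:
        table = cq.observe_vs_intervene_table(model, rf, "bag")
        table.to_csv(outdir / f"observe_vs_intervene_{rf}.csv",
                     index=False, float_format="%.6f")
    signs = cq.classify_all_edges(model)
    pd.DataFrame(
        [{"parent": s.edge[0], "child": s.edge[1], "label": s.label,
          "zero_effect": s.zero_effect} for s in signs]
    ).to_csv(outdir / "edge_signs.csv", index=False)
    with open(outdir / "graph.dot", "w") as fh:
        fh.write(cq.to_dot(model, signs))

    summary = {
        "seed": int(seed),
        "n": config.n,
        "pooled_mae_raw": result.pooled_mae_raw,
        "pooled_mae_corrected": result.pooled_mae_corrected,
        "chosen_threshold": float(threshold),
        "n_edges": len(dag.edges),
        "mean_node_auc": auc.overall_mean,
        "bag_node_auc": (
            None if np.isnan(auc.node_means["bag"]) else auc.node_means["bag"]
        ),
        "bag_parents": bag_parents,
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return summary
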