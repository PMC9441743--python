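"""Interventional (do-calculus) queries and edge-sign classification.

A point intervention do(X = x) is implemented by graph mutilation: all
edges into X are severed and X's CPD is replaced by a point mass on x,
leaving every other CPD untouched.  Exact inference on the mutilated
model then yields P(target | do(X = x)), which for a fully specified
discrete model coincides with the truncated-factorization / backdoor-
adjustment formulas.  For parentless nodes there is nothing to sever, so
observation and intervention agree exactly.

Edge signs summarize each CPD direction qualitatively: the expected
child state code m(s) = E[child | parent = s] (other parents
marginalized) is computed for each parent state in ascending order;
strictly monotone profiles are labelled positive/negative and anything
else (including flat profiles) non-linear.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bayesian_network import (
    BayesianNetworkModel,
    CPDTable,
    DistributionResult,
    query_conditional,
)
from .structure_learning import DAGStructure


@dataclass(frozen=True)
class InterventionQuery:
    """do(node = state) applied before querying ``target``."""

    target: str
    do_node: str
    do_state: int

    def __post_init__(self) -> None:
        if self.target == self.do_node:
            raise ValueError("cannot intervene on the query target itself")


@dataclass
class EdgeSign:
    """Qualitative association label for one DAG edge."""

    edge: tuple[str, str]
    label: str  # "positive" | "negative" | "nonlinear"
    zero_effect: bool = False
    expected_child_state: tuple[float, ...] = ()


def intervene(model: BayesianNetworkModel, do_node: str, do_state: int) -> BayesianNetworkModel:
    """Graph mutilation: sever edges into ``do_node`` and clamp its CPD."""
    if do_node not in model.nodes:
        raise ValueError(f"unknown node {do_node!r}")
    card = model.card(do_node)
    if not 0 <= int(do_state) < card:
        raise ValueError(f"invalid state {do_state} for node {do_node!r}")
    edges = {(p, c): w for (p, c), w in model.dag.edges.items() if c != do_node}
    dag = DAGStructure(nodes=model.dag.nodes, edges=edges, threshold=model.dag.threshold)
    point = np.zeros((1, card))
    point[0, int(do_state)] = 1.0
    cpds = {v: copy.deepcopy(t) for v, t in model.cpds.items()}
    cpds[do_node] = CPDTable(node=do_node, parents=(), parent_cards=(), table=point)
    return BayesianNetworkModel(dag=dag, cpds=cpds, state_names=dict(model.state_names))


def interventional_distribution(
    model: BayesianNetworkModel, target: str, do_node: str, do_state: int
) -> DistributionResult:
    """P(target | do(do_node = do_state)) via mutilation + exact inference."""
    InterventionQuery(target=target, do_node=do_node, do_state=int(do_state))
    mutilated = intervene(model, do_node, do_state)
    dist = query_conditional(mutilated, target, {})
    return DistributionResult(
        target=target,
        states=dist.states,
        probabilities=dist.probabilities,
        mode="interventional",
        given={do_node: int(do_state)},
    )


def observe_vs_intervene_table(
    model: BayesianNetworkModel, risk_factor: str, target: str = "bag"
) -> pd.DataFrame:
    """Paired observational and interventional target distributions.

    One row per (risk-factor state, mode): P(target | rf = s) and
    P(target | do(rf = s)), with one probability column per target state.
    """
    if risk_factor == target:
        raise ValueError("risk factor and target must differ")
    labels = model.state_names.get(
        target, tuple(str(s) for s in range(model.card(target)))
    )
    rows = []
    for s in range(model.card(risk_factor)):
        obs = query_conditional(model, target, {risk_factor: s})
        do = interventional_distribution(model, target, risk_factor, s)
        state_label = model.state_names.get(risk_factor, tuple(map(str, range(model.card(risk_factor)))))[s]
        for mode, dist in (("observational", obs), ("interventional", do)):
            row = {"state": state_label, "state_code": s, "mode": mode}
            for lab, p in zip(labels, dist.probabilities):
                row[f"p_{lab}"] = float(p)
            rows.append(row)
    return pd.DataFrame(rows)


def classify_edge_sign(model: BayesianNetworkModel, edge: tuple[str, str]) -> EdgeSign:
    """Label an edge by monotonicity of the expected child state.

    m(s) = sum_c c * P(child = c | parent = s), other parents
    marginalized; strictly increasing -> positive, strictly decreasing ->
    negative, anything else -> nonlinear (flat profiles additionally
    flagged zero-effect).
    """
    parent, child = edge
    if tuple(edge) not in model.dag.edges:
        raise ValueError(f"edge {edge} is not in the DAG")
    codes = np.arange(model.card(child))
    m = []
    for s in range(model.card(parent)):
        dist = query_conditional(model, child, {parent: s})
        m.append(float(np.dot(codes, dist.probabilities)))
    diffs = np.diff(m)
    if np.allclose(diffs, 0.0, atol=1e-12):
        return EdgeSign(edge=tuple(edge), label="nonlinear", zero_effect=True,
                        expected_child_state=tuple(m))
    if (diffs > 0).all():
        label = "positive"
    elif (diffs < 0).all():
        label = "negative"
    else:
        label = "nonlinear"
    return EdgeSign(edge=tuple(edge), label=label, expected_child_state=tuple(m))


def classify_all_edges(model: BayesianNetworkModel) -> list[EdgeSign]:
    return [classify_edge_sign(model, e) for e in sorted(model.dag.edges)]


_EDGE_STYLE = {
    "positive": ("red", "solid"),
    "negative": ("blue", "solid"),
    "nonlinear": ("black", "dashed"),
}


def to_dot(model: BayesianNetworkModel, signs: list[EdgeSign] | None = None) -> str:
    """DOT export with red/blue solid edges for monotone associations and
    dashed edges for non-linear ones."""
    signs = signs if signs is not None else classify_all_edges(model)
    by_edge = {s.edge: s for s in signs}
    lines = ["digraph G {"]
    for v in model.nodes:
        lines.append(f'  "{v}";')
    for (p, c) in sorted(model.dag.edges):
        sign = by_edge.get((p, c))
        color, style = _EDGE_STYLE[sign.label] if sign else ("black", "solid")
        lines.append(f'  "{p}" -> "{c}" [color={color}, style={style}];')
    lines.append("}")
    return "\n".join(lines)


def plot_observe_vs_intervene(table: pd.DataFrame, risk_factor: str, target: str, path=None):
    """Line plot of paired observational (solid) and interventional
    (dashed) target distributions, one line per risk-factor state."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    prob_cols = [c for c in table.columns if c.startswith("p_")]
    xticks = [c[2:] for c in prob_cols]
    fig, ax = plt.subplots(figsize=(5, 4))
    colors = plt.rcParams["axes.prop_cycle"].by_key()["color"]
    for i, (state, grp) in enumerate(table.groupby("state_code")):
        color = colors[i % len(colors)]
        for mode, ls in (("observational", "-"), ("interventional", "--")):
            row = grp[grp["mode"] == mode].iloc[0]
            ax.plot(xticks, [row[c] for c in prob_cols], ls, color=color,
                    label=f"{row['state']} ({mode})")
    ax.set_xlabel(target)
    ax.set_ylabel("probability")
    ax.set_title(f"P({target} | {risk_factor}) vs P({target} | do({risk_factor}))")
    ax.legend(fontsize=7)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
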