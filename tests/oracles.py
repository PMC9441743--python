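"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (full-joint enumeration, power
series, closed forms) and shares no code with the package's inference or
optimization paths.
"""

from __future__ import annotations

import itertools

import numpy as np

from causalbag.bayesian_network import BayesianNetworkModel, CPDTable
from causalbag.structure_learning import DAGStructure


def expm_series(A: np.ndarray, terms: int = 60) -> np.ndarray:
    """Matrix exponential by truncated power series."""
    out = np.eye(A.shape[0])
    term = np.eye(A.shape[0])
    for k in range(1, terms):
        term = term @ A / k
        out = out + term
    return out


def random_ternary_model(rng: np.random.Generator, d: int = 8, edge_p: float = 0.4) -> BayesianNetworkModel:
    """Random DAG over d ternary nodes with Dirichlet(1) CPD rows."""
    nodes = tuple(f"x{i}" for i in range(d))
    perm = rng.permutation(d)
    edges = {}
    for a in range(d):
        for b in range(a + 1, d):
            if rng.random() < edge_p:
                edges[(nodes[perm[a]], nodes[perm[b]])] = 1.0
    dag = DAGStructure(nodes=nodes, edges=edges)
    cpds = {}
    for v in nodes:
        pa = tuple(sorted(dag.parents(v)))
        tab = rng.dirichlet(np.ones(3), size=3 ** len(pa))
        cpds[v] = CPDTable(node=v, parents=pa, parent_cards=(3,) * len(pa), table=tab)
    return BayesianNetworkModel(dag=dag, cpds=cpds)


def enumerate_joint(model: BayesianNetworkModel, do: dict[str, int] | None = None) -> dict:
    """Full joint by enumeration; ``do`` clamps nodes (truncated factorization)."""
    nodes = model.nodes
    cards = [model.card(v) for v in nodes]
    joint = {}
    for assign in itertools.product(*(range(c) for c in cards)):
        st = dict(zip(nodes, assign))
        p = 1.0
        for v in nodes:
            if do is not None and v in do:
                p *= 1.0 if st[v] == do[v] else 0.0
            else:
                cpd = model.cpds[v]
                p *= cpd.table[cpd.row_index(st), st[v]]
        joint[assign] = p
    return joint


def conditional_by_enumeration(
    model: BayesianNetworkModel, target: str, evidence: dict[str, int],
    do: dict[str, int] | None = None,
) -> np.ndarray:
    """P(target | evidence) (under an optional intervention) from the joint."""
    nodes = model.nodes
    num = np.zeros(model.card(target))
    for assign, p in enumerate_joint(model, do=do).items():
        st = dict(zip(nodes, assign))
        if all(st[v] == s for v, s in evidence.items()):
            num[st[target]] += p
    total = num.sum()
    if total == 0:
        raise ZeroDivisionError("evidence has probability zero")
    return num / total


def backdoor_adjustment(model: BayesianNetworkModel, target: str, x: str, x_state: int,
                        adjust: tuple[str, ...]) -> np.ndarray:
    """Sum_z P(target | x, z) P(z), all terms taken from the enumerated joint."""
    out = np.zeros(model.card(target))
    joint = enumerate_joint(model)
    nodes = model.nodes
    # marginal of the adjustment set
    for z_assign in itertools.product(*(range(model.card(z)) for z in adjust)):
        z_ev = dict(zip(adjust, z_assign))
        pz = sum(p for a, p in joint.items()
                 if all(dict(zip(nodes, a))[v] == s for v, s in z_ev.items()))
        if pz == 0:
            continue
        cond = conditional_by_enumeration(model, target, {x: x_state, **z_ev})
        out += cond * pz
    return out / out.sum()
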