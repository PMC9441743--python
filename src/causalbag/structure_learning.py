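"""Constrained DAG discovery with the NOTEARS continuous optimization.

DAG learning over the eight study variables is cast as an L1-penalized
least-squares problem with the smooth acyclicity function

    h(W) = trace(exp(W o W)) - d        (o = Hadamard product)

driven to zero by an augmented-Lagrangian outer loop.  Domain knowledge
enters as hard forbidden edges held at exactly zero throughout the
optimization (via box constraints on the split positive/negative weight
parametrization): nothing may point into age or sex, nothing may leave
the BAG, and the anthropometric variables (BMI, WHR, BP) may not point
into smoking or drinking.

Weak edges are pruned at a magnitude threshold; the threshold is chosen
by refitting the discrete Bayesian network per candidate and maximizing
the mean of (average node AUC, BAG-node AUC) under cross-validation,
with ties resolved toward the sparser (larger-threshold) graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize
import yaml


class StructureLearningError(RuntimeError):
    """Optimization failed to reach the acyclicity tolerance."""

    def __init__(self, message: str, h: float):
        super().__init__(message)
        self.h = h


class CyclicGraphError(ValueError):
    """Pruned edge set contains a directed cycle."""


@dataclass(frozen=True)
class ConstraintSet:
    """Forbidden-edge bookkeeping for structure learning.

    ``no_incoming`` lists variables nothing may affect, ``no_outgoing``
    variables that may affect nothing, and ``forbidden_pairs`` explicit
    (parent, child) exclusions.
    """

    no_incoming: tuple[str, ...] = ()
    no_outgoing: tuple[str, ...] = ()
    forbidden_pairs: tuple[tuple[str, str], ...] = ()

    def forbidden_mask(self, nodes) -> np.ndarray:
        """Boolean d x d matrix, True where an edge parent->child is forbidden.

        The diagonal is always forbidden (no self-loops).
        """
        nodes = list(nodes)
        idx = {v: i for i, v in enumerate(nodes)}
        for v in self.no_incoming + self.no_outgoing:
            if v not in idx:
                raise ValueError(f"constraint references unknown variable {v!r}")
        d = len(nodes)
        mask = np.eye(d, dtype=bool)
        for v in self.no_incoming:
            mask[:, idx[v]] = True
        for v in self.no_outgoing:
            mask[idx[v], :] = True
        for p, c in self.forbidden_pairs:
            if p not in idx or c not in idx:
                raise ValueError(f"constraint references unknown pair ({p!r}, {c!r})")
            mask[idx[p], idx[c]] = True
        return mask

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "no_incoming": list(self.no_incoming),
                    "no_outgoing": list(self.no_outgoing),
                    "forbidden_pairs": [list(p) for p in self.forbidden_pairs],
                },
                fh, sort_keys=True,
            )

    @classmethod
    def from_yaml(cls, path) -> "ConstraintSet":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(
            no_incoming=tuple(d.get("no_incoming", ())),
            no_outgoing=tuple(d.get("no_outgoing", ())),
            forbidden_pairs=tuple((p, c) for p, c in d.get("forbidden_pairs", ())),
        )


def default_constraints() -> ConstraintSet:
    """The study's three forbidden-edge rules."""
    return ConstraintSet(
        no_incoming=("age", "sex"),
        no_outgoing=("bag",),
        forbidden_pairs=(
            ("bmi", "smoking"), ("bmi", "drinking"),
            ("whr", "smoking"), ("whr", "drinking"),
            ("bp", "smoking"), ("bp", "drinking"),
        ),
    )


@dataclass
class WeightedAdjacency:
    """Continuous edge-weight matrix W plus optimization metadata."""

    W: np.ndarray
    nodes: tuple[str, ...]
    h: float = 0.0
    n_dual_iterations: int = 0

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        if self.W.ndim != 2 or self.W.shape[0] != self.W.shape[1]:
            raise ValueError("W must be square")


@dataclass
class DAGStructure:
    """Named nodes plus retained directed edges with their weights."""

    nodes: tuple[str, ...]
    edges: dict[tuple[str, str], float]
    threshold: float | None = None

    def parents(self, node: str) -> tuple[str, ...]:
        return tuple(p for (p, c) in self.edges if c == node)

    def children(self, node: str) -> tuple[str, ...]:
        return tuple(c for (p, c) in self.edges if p == node)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for (p, c), w in self.edges.items():
            g.add_edge(p, c, weight=w)
        return g

    def is_acyclic(self) -> bool:
        return nx.is_directed_acyclic_graph(self.to_networkx())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"parent": p, "child": c, "weight": w}
            for (p, c), w in sorted(self.edges.items())
        ]
        return pd.DataFrame(rows, columns=["parent", "child", "weight"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame, nodes) -> "DAGStructure":
        edges = {
            (r.parent, r.child): float(r.weight) for r in df.itertuples(index=False)
        }
        return cls(nodes=tuple(nodes), edges=edges)


def acyclicity_h(W) -> float:
    """h(W) = trace(exp(W o W)) - d; zero iff the support of W is acyclic."""
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("W must be a square matrix")
    d = W.shape[0]
    return float(np.trace(scipy.linalg.expm(W * W)) - d)


@dataclass(frozen=True)
class NotearsOptions:
    """Augmented-Lagrangian schedule for the NOTEARS solver."""

    h_tol: float = 1e-8
    rho_init: float = 1.0
    rho_scale: float = 10.0
    rho_max: float = 1e16
    max_dual_iterations: int = 100
    progress_ratio: float = 0.25  # h must shrink 4x per dual step to keep rho


def learn_weighted_adjacency(
    data,
    constraints: ConstraintSet | None = None,
    l1_penalty: float = 0.1,
    opts: NotearsOptions = NotearsOptions(),
) -> WeightedAdjacency:
    """Constrained NOTEARS on a numeric table.

    ``data`` is a DataFrame (columns = variables) or an (n, d) array;
    continuous columns should already be z-scored and categorical ones
    ordinal-coded.  Forbidden entries of W are pinned to exactly 0 by the
    optimizer's box constraints.  The run is deterministic for fixed data
    and options (zero initialization, L-BFGS-B inner solver).
    """
    if isinstance(data, pd.DataFrame):
        cols = [c for c in data.columns if c != "subject_id"]
        nodes = tuple(cols)
        X = data[cols].to_numpy(dtype=float)
    else:
        X = np.asarray(data, dtype=float)
        nodes = tuple(f"x{i}" for i in range(X.shape[1]))
    n, d = X.shape
    if d < 2:
        raise ValueError("need at least 2 variables")
    if l1_penalty < 0:
        raise ValueError("l1_penalty must be >= 0")
    constraints = constraints if constraints is not None else ConstraintSet()
    forbidden = constraints.forbidden_mask(nodes)

    def _unpack(w):
        return (w[: d * d] - w[d * d:]).reshape(d, d)

    def _func(w, rho, alpha):
        W = _unpack(w)
        R = X - X @ W
        loss = 0.5 / n * float((R * R).sum())
        G_loss = -1.0 / n * (X.T @ R)
        with np.errstate(over="ignore", invalid="ignore"):
            E = scipy.linalg.expm(W * W)
        h = float(np.trace(E) - d)
        G_h = E.T * W * 2.0
        obj = loss + 0.5 * rho * h * h + alpha * h + l1_penalty * w.sum()
        G = G_loss + (rho * h + alpha) * G_h
        grad = np.concatenate([G.ravel(), -G.ravel()]) + l1_penalty
        return obj, grad

    bounds = []
    flat_forbidden = forbidden.ravel()
    for _ in range(2):  # positive then negative part
        bounds.extend((0.0, 0.0) if f else (0.0, None) for f in flat_forbidden)
    w = np.zeros(2 * d * d)
    rho, alpha, h = opts.rho_init, 0.0, np.inf
    iterations = 0
    for iterations in range(1, opts.max_dual_iterations + 1):
        h_new = None
        while rho < opts.rho_max:
            sol = scipy.optimize.minimize(
                _func, w, args=(rho, alpha), method="L-BFGS-B",
                jac=True, bounds=bounds,
            )
            w_new = sol.x
            h_new = acyclicity_h(_unpack(w_new))
            if h_new > opts.progress_ratio * h:
                rho *= opts.rho_scale
            else:
                break
        w, h = w_new, h_new
        alpha += rho * h
        if h <= opts.h_tol or rho >= opts.rho_max:
            break
    W = _unpack(w)
    W[forbidden] = 0.0  # exact zeros (bounds already enforce this)
    h_final = acyclicity_h(W)
    if h_final > opts.h_tol:
        raise StructureLearningError(
            f"NOTEARS did not reach h <= {opts.h_tol:g} "
            f"within {opts.max_dual_iterations} dual iterations (final h = {h_final:g})",
            h=h_final,
        )
    return WeightedAdjacency(W=W, nodes=nodes, h=h_final, n_dual_iterations=iterations)


def prune_edges(W: WeightedAdjacency, threshold: float) -> DAGStructure:
    """Keep edges with |w| > threshold and verify the result is acyclic."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    edges = {}
    d = len(W.nodes)
    for i in range(d):
        for j in range(d):
            if i != j and abs(W.W[i, j]) > threshold:
                edges[(W.nodes[i], W.nodes[j])] = float(W.W[i, j])
    dag = DAGStructure(nodes=W.nodes, edges=edges, threshold=float(threshold))
    if not dag.is_acyclic():
        raise CyclicGraphError(
            f"edge set at threshold {threshold:g} contains a cycle; increase the threshold"
        )
    return dag


def select_threshold(
    W: WeightedAdjacency,
    candidate_thresholds,
    disc_data: pd.DataFrame,
    bag_node: str = "bag",
    k: int = 10,
    repeats: int = 3,
    seed: int = 0,
    pseudo_count: float = 1.0,
):
    """Choose the pruning threshold by the cross-validated AUC criterion.

    For each candidate, the pruned DAG's Bayesian network is validated by
    repeated k-fold CV; the score is the unweighted mean of the average
    node AUC and the BAG-node AUC.  Ties break toward the larger
    (sparser) threshold.  Returns (best threshold, per-candidate report).
    """
    from .bayesian_network import crossvalidated_auc

    candidates = sorted(float(t) for t in candidate_thresholds)
    if not candidates:
        raise ValueError("need at least one candidate threshold")
    rows = []
    best_t, best_score = None, -np.inf
    for t in candidates:
        try:
            dag = prune_edges(W, t)
        except CyclicGraphError:
            rows.append({"threshold": t, "n_edges": np.nan, "avg_auc": np.nan,
                         "bag_auc": np.nan, "score": np.nan, "valid": False})
            continue
        report = crossvalidated_auc(
            dag, disc_data, k=k, repeats=repeats, seed=seed, pseudo_count=pseudo_count
        )
        avg_auc = report.overall_mean
        bag_auc = report.node_means[bag_node]
        # a degenerate (single-class) BAG has no AUC; fall back to the
        # average-node component alone
        with np.errstate(invalid="ignore"):
            score = float(np.nanmean([avg_auc, bag_auc]))
        rows.append({"threshold": t, "n_edges": len(dag.edges), "avg_auc": avg_auc,
                     "bag_auc": bag_auc, "score": score,
                     "valid": not np.isnan(score)})
        if not np.isnan(score) and score >= best_score:
            # >= so equal scores prefer the larger (sparser) threshold
            best_t, best_score = t, score
    if best_t is None:
        raise CyclicGraphError("no candidate threshold yields an acyclic graph")
    return best_t, pd.DataFrame(rows)


def prepare_structure_data(cohort: pd.DataFrame, nodes=None) -> pd.DataFrame:
    """Encode a cohort for NOTEARS: z-score continuous columns, center codes.

    Age, WHR, BMI, BP and BAG are standardized to zero mean and unit
    variance.  Sex keeps its {0,1} coding and smoking/drinking their
    ordinal {0,1,2} spacing, but all three are mean-centered: the NOTEARS
    least-squares model has no intercept, so uncentered regressors would
    distort every weight.
    """
    from .synthetic_data import STUDY_NODES

    nodes = tuple(nodes) if nodes is not None else STUDY_NODES
    categorical = {"sex", "smoking", "drinking"}
    out = {}
    for v in nodes:
        col = cohort[v].to_numpy(dtype=float)
        if v in categorical:
            out[v] = col - col.mean()
        else:
            sd = col.std()
            out[v] = (col - col.mean()) / (sd if sd > 0 else 1.0)
    return pd.DataFrame(out, index=cohort.index)


def structural_hamming_distance(edges_a, edges_b) -> int:
    """Edge insertions/deletions/reversals separating two directed graphs.

    A reversed edge counts once; an edge present in only one graph (with
    no reverse in the other) counts once.
    """
    a, b = set(map(tuple, edges_a)), set(map(tuple, edges_b))
    shd = 0
    counted = set()
    for e in a ^ b:
        if e in counted:
            continue
        rev = (e[1], e[0])
        if (e in a and rev in b and e not in b and rev not in a) or (
            e in b and rev in a and e not in a and rev not in b
        ):
            shd += 1
            counted.add(rev)
        else:
            shd += 1
        counted.add(e)
    return shd
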