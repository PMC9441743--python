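"""Synthetic cohorts from a known structural causal model (SCM).

The study population this package targets (a general adult cohort with
morphometric brain features and cardiovascular risk factors) is restricted
access, so every downstream stage is exercised on cohorts drawn from a
user-specified SCM with a known directed acyclic graph.  Ancestral sampling
in topological order produces, per subject: chronological age, sex
(0 = male, 1 = female), BMI [kg/m^2], systolic blood pressure [mmHg],
waist-to-hip ratio, smoking {0: non-, 1: past, 2: current smoker},
drinking {0: non-, 1: <=1 glass/week, 2: >1 glass/week} and a brain age
gap (BAG, years) causally driven by chosen risk factors.

Morphometric feature tables (223 unit-free analogues of regional volumes,
surface areas and thicknesses) are noisy affine functions of age — or of
any designated "biological brain age" column, which is how an age + BAG
signal is planted for end-to-end runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .discretize import DiscretizationScheme, default_scheme, discretize_value

N_FEATURES = 223

#: canonical node order of the study graph
STUDY_NODES = ("age", "sex", "whr", "bmi", "bp", "smoking", "drinking", "bag")

#: number of states per study variable once discretized
STUDY_CARDINALITIES = {
    "age": 3, "sex": 2, "whr": 3, "bmi": 3, "bp": 3,
    "smoking": 3, "drinking": 3, "bag": 3,
}


class SCMValidationError(ValueError):
    """Invalid mechanism parameters (bad CPT row, negative noise SD...)."""


class SCMStructureError(ValueError):
    """Mechanism parent sets inconsistent with an acyclic order."""


@dataclass(frozen=True)
class UniformRoot:
    """Exogenous root drawn uniformly on [low, high]."""

    low: float
    high: float

    def validate(self, name: str) -> None:
        if not self.low < self.high:
            raise SCMValidationError(f"{name}: uniform bounds must satisfy low < high")


@dataclass(frozen=True)
class LinearGaussian:
    """value = intercept + coefficients . parents + Normal(0, noise_sd)."""

    parents: tuple[str, ...]
    coefficients: tuple[float, ...]
    intercept: float
    noise_sd: float

    def validate(self, name: str) -> None:
        if len(self.parents) != len(self.coefficients):
            raise SCMValidationError(f"{name}: one coefficient per parent required")
        if self.noise_sd < 0:
            raise SCMValidationError(f"{name}: noise_sd must be >= 0")


@dataclass(frozen=True)
class Categorical:
    """CPT-based mechanism over discrete states.

    ``cpt`` has one row per parent-state combination (row index is the
    mixed-radix encoding of parent states, first parent most significant)
    and one column per own state.  Continuous parents are discretized with
    the clinical scheme before indexing, so mixed parent sets are allowed.
    """

    parents: tuple[str, ...]
    parent_cards: tuple[int, ...]
    cpt: tuple[tuple[float, ...], ...]
    n_states: int

    def table(self) -> np.ndarray:
        return np.asarray(self.cpt, dtype=float)

    def validate(self, name: str) -> None:
        tab = self.table()
        n_rows = int(np.prod(self.parent_cards)) if self.parents else 1
        if len(self.parents) != len(self.parent_cards):
            raise SCMValidationError(f"{name}: one cardinality per parent required")
        if tab.shape != (n_rows, self.n_states):
            raise SCMValidationError(
                f"{name}: CPT shape {tab.shape} != ({n_rows}, {self.n_states})"
            )
        if (tab < 0).any():
            raise SCMValidationError(f"{name}: negative CPT entry")
        if np.abs(tab.sum(axis=1) - 1.0).max() > 1e-12:
            raise SCMValidationError(f"{name}: CPT rows must sum to 1 (tol 1e-12)")


Mechanism = UniformRoot | LinearGaussian | Categorical


@dataclass(frozen=True)
class SCMSpec:
    """Node order plus one mechanism per node.

    The node order must be topological: every mechanism may only reference
    parents that appear earlier in ``nodes``.
    """

    nodes: tuple[str, ...]
    mechanisms: dict[str, Mechanism] = field(default_factory=dict)

    def validate(self) -> None:
        seen: set[str] = set()
        for name in self.nodes:
            if name not in self.mechanisms:
                raise SCMValidationError(f"no mechanism for node {name!r}")
            mech = self.mechanisms[name]
            mech.validate(name)
            for p in getattr(mech, "parents", ()):
                if p not in seen:
                    raise SCMStructureError(
                        f"{name}: parent {p!r} does not precede it in node order "
                        "(cyclic or ill-ordered mechanism graph)"
                    )
            seen.add(name)

    def parent_map(self) -> dict[str, tuple[str, ...]]:
        return {n: tuple(getattr(self.mechanisms[n], "parents", ())) for n in self.nodes}

    def edges(self) -> set[tuple[str, str]]:
        return {(p, n) for n, ps in self.parent_map().items() for p in ps}

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        out: dict = {"nodes": list(self.nodes), "mechanisms": {}}
        for name, m in self.mechanisms.items():
            if isinstance(m, UniformRoot):
                out["mechanisms"][name] = {"kind": "uniform", "low": m.low, "high": m.high}
            elif isinstance(m, LinearGaussian):
                out["mechanisms"][name] = {
                    "kind": "linear_gaussian", "parents": list(m.parents),
                    "coefficients": list(m.coefficients),
                    "intercept": m.intercept, "noise_sd": m.noise_sd,
                }
            else:
                out["mechanisms"][name] = {
                    "kind": "categorical", "parents": list(m.parents),
                    "parent_cards": list(m.parent_cards),
                    "cpt": [list(r) for r in m.cpt], "n_states": m.n_states,
                }
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "SCMSpec":
        mechs: dict[str, Mechanism] = {}
        for name, md in d["mechanisms"].items():
            kind = md["kind"]
            if kind == "uniform":
                mechs[name] = UniformRoot(float(md["low"]), float(md["high"]))
            elif kind == "linear_gaussian":
                mechs[name] = LinearGaussian(
                    tuple(md["parents"]), tuple(float(c) for c in md["coefficients"]),
                    float(md["intercept"]), float(md["noise_sd"]),
                )
            elif kind == "categorical":
                mechs[name] = Categorical(
                    tuple(md["parents"]), tuple(int(c) for c in md["parent_cards"]),
                    tuple(tuple(float(x) for x in r) for r in md["cpt"]), int(md["n_states"]),
                )
            else:
                raise SCMValidationError(f"unknown mechanism kind {kind!r}")
        return cls(nodes=tuple(d["nodes"]), mechanisms=mechs)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SCMSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SCMSpec":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _parent_codes(name: str, values: dict[str, np.ndarray], scheme: DiscretizationScheme) -> np.ndarray:
    """Discrete codes of a parent column, discretizing continuous parents."""
    v = values[name]
    if np.issubdtype(v.dtype, np.integer):
        return v
    sex = values.get("sex")
    return np.asarray(
        discretize_value(v, name, sex=sex, scheme=scheme), dtype=np.int64
    )


def generate_scm_cohort(spec: SCMSpec, n: int, seed: int) -> pd.DataFrame:
    """Ancestral sampling of ``n`` subjects; reproducible for a fixed seed."""
    if n < 0:
        raise ValueError("n must be >= 0")
    spec.validate()
    rng = np.random.default_rng(seed)
    scheme = default_scheme()
    values: dict[str, np.ndarray] = {}
    for name in spec.nodes:
        mech = spec.mechanisms[name]
        if isinstance(mech, UniformRoot):
            values[name] = rng.uniform(mech.low, mech.high, size=n)
        elif isinstance(mech, LinearGaussian):
            out = np.full(n, mech.intercept, dtype=float)
            for p, c in zip(mech.parents, mech.coefficients):
                out += c * values[p].astype(float)
            if mech.noise_sd > 0:
                out += rng.normal(0.0, mech.noise_sd, size=n)
            values[name] = out
        else:  # Categorical
            tab = mech.table()
            if mech.parents:
                rows = np.zeros(n, dtype=np.int64)
                for p, card in zip(mech.parents, mech.parent_cards):
                    rows = rows * card + _parent_codes(p, values, scheme)
            else:
                rows = np.zeros(n, dtype=np.int64)
            u = rng.random(n)
            cum = np.cumsum(tab, axis=1)
            values[name] = (u[:, None] > cum[rows]).sum(axis=1).astype(np.int64)
    out = pd.DataFrame({"subject_id": np.arange(n, dtype=np.int64)})
    for name in spec.nodes:
        out[name] = values[name]
    return out


def generate_morphometrics(
    cohort: pd.DataFrame,
    slopes,
    noise_sd,
    seed: int,
    intercepts=None,
    age_column: str = "age",
) -> pd.DataFrame:
    """223 features, each ``intercept_j + slope_j * age + N(0, noise_sd_j)``.

    ``age_column`` selects the driving signal; passing an "age + BAG"
    column plants a recoverable brain-age signal in the features.
    """
    if len(cohort) == 0:
        raise ValueError("cohort must be nonempty")
    slopes = np.asarray(slopes, dtype=float)
    noise_sd = np.asarray(noise_sd, dtype=float)
    if noise_sd.ndim == 0:
        noise_sd = np.full(N_FEATURES, float(noise_sd))
    intercepts = (
        np.zeros(N_FEATURES) if intercepts is None else np.asarray(intercepts, dtype=float)
    )
    for name, arr in (("slopes", slopes), ("noise_sd", noise_sd), ("intercepts", intercepts)):
        if arr.shape != (N_FEATURES,):
            raise ValueError(f"{name} must have exactly {N_FEATURES} entries")
    if (noise_sd < 0).any():
        raise ValueError("noise_sd entries must be >= 0")
    rng = np.random.default_rng(seed)
    age = cohort[age_column].to_numpy(dtype=float)
    feats = intercepts[None, :] + age[:, None] * slopes[None, :]
    feats = feats + rng.normal(0.0, 1.0, size=feats.shape) * noise_sd[None, :]
    cols = {"subject_id": cohort["subject_id"].to_numpy()}
    cols.update({f"feat{j:03d}": feats[:, j] for j in range(N_FEATURES)})
    return pd.DataFrame(cols)


def default_morphometric_params(seed: int = 0, noise_sd: float = 2.0):
    """Random per-feature slopes/intercepts plus a shared noise SD.

    Slopes are uniform on +/-[0.2, 1.0] so every feature carries age signal
    of the same order as its noise.
    """
    rng = np.random.default_rng(seed)
    slopes = rng.uniform(0.2, 1.0, N_FEATURES) * rng.choice([-1.0, 1.0], N_FEATURES)
    intercepts = rng.uniform(-20.0, 20.0, N_FEATURES)
    return slopes, intercepts, np.full(N_FEATURES, float(noise_sd))


#: cohort size and seed of the reference synthetic study
DEFAULT_COHORT_SIZE = 2025
DEFAULT_SEED = 20220822


def study_true_edges() -> set[tuple[str, str]]:
    """Ground-truth directed edges of the default study SCM."""
    return {
        ("sex", "bmi"), ("sex", "bp"), ("sex", "smoking"), ("sex", "drinking"),
        ("whr", "bmi"), ("whr", "bp"),
        ("bmi", "bag"), ("whr", "bag"), ("smoking", "bag"), ("drinking", "bag"),
    }


def default_study_scm(strong: bool = False) -> SCMSpec:
    """Fully parameterized SCM over the eight study variables.

    Roots are age (uniform 21-82 y), sex (Bernoulli, slight female excess)
    and WHR; sex drives BMI, BP, smoking and drinking; WHR drives BMI and
    BP; BMI, WHR, smoking and drinking drive the BAG.  Nothing points into
    age or sex and nothing leaves the BAG.  Marginal means/SDs are loosely
    matched to a general adult population (BMI ~27 +/- 4, systolic BP
    ~127 +/- 16, WHR 0.88 +/- 0.08, BAG ~0 +/- 3.5).

    ``strong=True`` sets every edge to a standardized effect of about
    0.4-0.55 SD of the child for structure-recovery experiments; the
    marginal locations stay realistic.  Moderate (rather than near-
    deterministic) effects are deliberate: on standardized data the
    penalized least-squares score can prefer reversing a low-noise root
    into a leaf, whereas around 0.5 SD the true collider structure is
    score-optimal.
    """
    p_female = 1050.0 / 2025.0
    if strong:
        smoking_cpt = ((0.65, 0.25, 0.10), (0.10, 0.25, 0.65))
        drinking_cpt = ((0.60, 0.30, 0.10), (0.08, 0.32, 0.60))
        bmi = LinearGaussian(("sex", "whr"), (-4.0, 25.0), 7.0, 2.83)
        bp = LinearGaussian(("sex", "whr"), (-13.0, 80.0), 63.0, 9.2)
        bag_coeffs = {"bmi": 0.45, "whr": 22.5, "smoking": 2.1, "drinking": 2.05}
        bag_noise = 2.0
    else:
        smoking_cpt = ((0.314, 0.428, 0.258), (0.473, 0.297, 0.230))
        drinking_cpt = ((0.061, 0.134, 0.805), (0.086, 0.396, 0.518))
        bmi = LinearGaussian(("sex", "whr"), (-1.1, 25.0), 6.0, 3.2)
        bp = LinearGaussian(("sex", "whr"), (-13.0, 38.0), 100.0, 13.0)
        bag_coeffs = {"bmi": 0.25, "whr": 12.0, "smoking": 1.2, "drinking": 0.8}
        bag_noise = 3.0

    mechs: dict[str, Mechanism] = {
        "age": UniformRoot(21.0, 82.0),
        "sex": Categorical((), (), ((1.0 - p_female, p_female),), 2),
        "whr": LinearGaussian((), (), 0.88, 0.08),
        "bmi": bmi,
        "bp": bp,
        "smoking": Categorical(("sex",), (2,), smoking_cpt, 3),
        "drinking": Categorical(("sex",), (2,), drinking_cpt, 3),
    }
    # center the BAG at ~0 given the means implied by the mechanisms above
    spec_wo_bag = SCMSpec(nodes=STUDY_NODES[:-1], mechanisms=mechs)
    probe = generate_scm_cohort(spec_wo_bag, 20000, seed=12345)
    parents = tuple(bag_coeffs)
    mean_drive = sum(c * probe[p].mean() for p, c in bag_coeffs.items())
    mechs["bag"] = LinearGaussian(
        parents, tuple(bag_coeffs[p] for p in parents),
        -round(float(mean_drive), 3), bag_noise,
    )
    spec = SCMSpec(nodes=STUDY_NODES, mechanisms=mechs)
    spec.validate()
    return spec
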