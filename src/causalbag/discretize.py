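"""Three-level clinical discretization of risk factors and the brain age gap.

Continuous variables are mapped to ordered categories {0: low, 1: normal,
2: high} at fixed clinical cut-offs (BMI 25/30 kg/m^2, systolic BP 120/140
mmHg, age 35/65 y, BAG -3/+3 y).  The waist-to-hip ratio uses sex-specific
cut-offs (males 0.95/1.0, females 0.80/0.85), so discretizing WHR requires
the subject's sex.  Sex, smoking and drinking are already categorical and
pass through unchanged.

Boundary convention: the outer bins are open ("<25", ">30"), so a value
exactly on an edge belongs to the closed middle ("normal") interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

LOW, NORMAL, HIGH = 0, 1, 2
CATEGORY_LABELS = ("low", "normal", "high")

#: code -> label for the sex variable (0 = male, 1 = female)
SEX_CODES = (0, 1)


class DiscretizationError(ValueError):
    """Raised for unknown variables or missing required context (e.g. sex)."""


def _check_edges(name: str, edges: tuple[float, float]) -> tuple[float, float]:
    e1, e2 = float(edges[0]), float(edges[1])
    if not e1 < e2:
        raise DiscretizationError(f"{name}: bin edges must be strictly increasing, got {edges}")
    return (e1, e2)


@dataclass(frozen=True)
class DiscretizationScheme:
    """Bin edges per variable, with sex-keyed edges for WHR.

    ``edges`` maps a variable name to its two inner cut points; variables in
    ``sex_specific`` instead map sex code -> cut points.  ``passthrough``
    variables are copied as integer codes without binning.
    """

    edges: dict[str, tuple[float, float]] = field(default_factory=dict)
    sex_specific: dict[str, dict[int, tuple[float, float]]] = field(default_factory=dict)
    passthrough: tuple[str, ...] = ("sex", "smoking", "drinking")

    def __post_init__(self) -> None:
        for name, e in self.edges.items():
            object.__setattr__(self, "edges", {**self.edges, name: _check_edges(name, e)})
        for name, by_sex in self.sex_specific.items():
            for sex, e in by_sex.items():
                _check_edges(f"{name}[sex={sex}]", e)

    @property
    def variables(self) -> tuple[str, ...]:
        return tuple(self.edges) + tuple(self.sex_specific) + self.passthrough

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "edges": {k: list(v) for k, v in self.edges.items()},
            "sex_specific": {
                k: {int(s): list(e) for s, e in by_sex.items()}
                for k, by_sex in self.sex_specific.items()
            },
            "passthrough": list(self.passthrough),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DiscretizationScheme":
        return cls(
            edges={k: tuple(v) for k, v in d.get("edges", {}).items()},
            sex_specific={
                k: {int(s): tuple(e) for s, e in by_sex.items()}
                for k, by_sex in d.get("sex_specific", {}).items()
            },
            passthrough=tuple(d.get("passthrough", ("sex", "smoking", "drinking"))),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "DiscretizationScheme":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_scheme() -> DiscretizationScheme:
    """The study's clinical cut-offs for all binned variables."""
    return DiscretizationScheme(
        edges={
            "bmi": (25.0, 30.0),
            "bp": (120.0, 140.0),
            "age": (35.0, 65.0),
            "bag": (-3.0, 3.0),
        },
        sex_specific={"whr": {0: (0.95, 1.0), 1: (0.80, 0.85)}},
    )


def _bin(values: np.ndarray, edges: tuple[float, float]) -> np.ndarray:
    e1, e2 = edges
    return np.where(values < e1, LOW, np.where(values <= e2, NORMAL, HIGH)).astype(np.int64)


def discretize_value(value, variable: str, sex=None, scheme: DiscretizationScheme | None = None):
    """Map one value (or array) of ``variable`` to its category code.

    ``sex`` is required (scalar or aligned array of codes) when the variable
    has sex-specific edges.
    """
    scheme = scheme if scheme is not None else default_scheme()
    arr = np.asarray(value, dtype=float)
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr)
    if variable in scheme.passthrough:
        out = arr.astype(np.int64)
    elif variable in scheme.edges:
        out = _bin(arr, scheme.edges[variable])
    elif variable in scheme.sex_specific:
        if sex is None:
            raise DiscretizationError(f"{variable!r} has sex-specific edges; sex is required")
        by_sex = scheme.sex_specific[variable]
        sex_arr = np.broadcast_to(np.atleast_1d(np.asarray(sex, dtype=np.int64)), arr.shape)
        out = np.empty(arr.shape, dtype=np.int64)
        for code, edges in by_sex.items():
            mask = sex_arr == code
            out[mask] = _bin(arr[mask], edges)
        unknown = ~np.isin(sex_arr, list(by_sex))
        if unknown.any():
            raise DiscretizationError(f"unknown sex code(s) {sorted(set(sex_arr[unknown]))}")
    else:
        raise DiscretizationError(f"unknown variable {variable!r}")
    return int(out[0]) if scalar else out


def discretize_cohort(cohort: pd.DataFrame, scheme: DiscretizationScheme | None = None) -> pd.DataFrame:
    """Discretize every scheme variable present as a column of ``cohort``.

    All scheme variables are required columns; rows are preserved one-to-one.
    Returns an integer-coded table (plus ``subject_id`` when present).
    """
    scheme = scheme if scheme is not None else default_scheme()
    missing = [v for v in scheme.variables if v not in cohort.columns]
    if missing:
        raise DiscretizationError(f"missing required column(s): {missing}")
    out = {}
    if "subject_id" in cohort.columns:
        out["subject_id"] = cohort["subject_id"].to_numpy()
    for var in scheme.variables:
        sex = cohort["sex"].to_numpy() if var in scheme.sex_specific else None
        out[var] = discretize_value(cohort[var].to_numpy(), var, sex=sex, scheme=scheme)
    return pd.DataFrame(out, index=cohort.index)


def category_frequencies(disc: pd.DataFrame) -> pd.DataFrame:
    """Per-variable category proportions of a discretized table."""
    cols = [c for c in disc.columns if c != "subject_id"]
    rows = {}
    for c in cols:
        counts = disc[c].value_counts(normalize=True).sort_index()
        rows[c] = {int(k): float(v) for k, v in counts.items()}
    return pd.DataFrame(rows).T.fillna(0.0)
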