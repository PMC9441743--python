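"""Brain-age regression, age-bias correction and the brain age gap (BAG).

A feed-forward regressor (MLP) maps 223 morphometric features to
chronological age under 10-fold age-stratified cross-validation.  Within
each iteration, 15% of the training portion is held out as a validation
set used both for early stopping and for fitting the linear age-bias
correction: regress predicted on chronological age (PredictedAge =
alpha * ChronologicalAge + beta) on the validation subjects, then correct
the test fold with

    CorrectedPredictedAge = PredictedAge
                            + [ChronologicalAge - (ChronologicalAge * alpha + beta)]

which removes the regression-toward-the-mean bias (young subjects
over-predicted, old subjects under-predicted).  The BAG is corrected
predicted age minus chronological age; positive values mean accelerated
brain aging.

All seeded operations order subjects by chronological age internally, so
results are invariant to the row order of the input tables.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.neural_network import MLPRegressor

#: hidden-layer candidates for architecture search (1 to 4 hidden layers)
CANDIDATE_ARCHITECTURES = ((256,), (256, 128), (256, 128, 64), (256, 128, 64, 32))


class DegenerateFitError(ValueError):
    """Bias correction requested on constant chronological ages."""


@dataclass(frozen=True)
class RegressorConfig:
    """Training settings for the brain-age MLP."""

    hidden_layers: tuple[int, ...] = (256, 128)
    max_epochs: int = 500
    patience: int = 20
    learning_rate: float = 1e-3
    batch_size: int = 128
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.hidden_layers or any(int(w) <= 0 for w in self.hidden_layers):
            raise ValueError("hidden_layers must be a nonempty tuple of positive widths")

    def n_parameters(self, n_features: int) -> int:
        widths = (n_features, *self.hidden_layers, 1)
        return sum(a * b + b for a, b in zip(widths[:-1], widths[1:]))


@dataclass(frozen=True)
class BiasCorrectionModel:
    """OLS fit of predicted age on chronological age."""

    alpha: float
    beta: float


@dataclass
class FoldAssignment:
    """Age-stratified k-fold partition with per-iteration validation sets.

    ``folds[i]`` is subject i's test-fold index.  ``validation[j]`` holds
    the indices (drawn age-stratified from the nine training folds of
    iteration j) reserved for early stopping and bias-correction fitting.
    """

    folds: np.ndarray
    k: int
    validation: tuple[np.ndarray, ...]

    def test_indices(self, i: int) -> np.ndarray:
        return np.flatnonzero(self.folds == i)

    def validation_indices(self, i: int) -> np.ndarray:
        return self.validation[i]

    def train_indices(self, i: int) -> np.ndarray:
        mask = self.folds != i
        mask[self.validation[i]] = False
        return np.flatnonzero(mask)

    def roles(self, i: int) -> np.ndarray:
        """Per-subject role label {'train','validation','test'} in iteration i."""
        out = np.full(len(self.folds), "train", dtype=object)
        out[self.folds == i] = "test"
        out[self.validation[i]] = "validation"
        return out


def make_stratified_folds(
    ages, k: int, validation_fraction: float = 0.15, seed: int = 0
) -> FoldAssignment:
    """Partition subjects into k folds, stratified by age.

    Subjects are sorted by age and fold labels are assigned by shuffled
    round-robin over consecutive age blocks of size k, so every fold spans
    the full age range.  Validation subjects are then drawn age-stratified
    (one per contiguous age chunk) from each iteration's training portion.
    """
    ages = np.asarray(ages, dtype=float)
    n = len(ages)
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError(f"need at least k={k} subjects, got {n}")
    if not 0.0 < validation_fraction < 1.0:
        raise ValueError("validation_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    order = np.argsort(ages, kind="stable")
    folds = np.empty(n, dtype=np.int64)
    for start in range(0, n, k):
        block = order[start:start + k]
        labels = rng.permutation(k)[: len(block)]
        folds[block] = labels
    validation = []
    for i in range(k):
        train = np.flatnonzero(folds != i)
        train = train[np.argsort(ages[train], kind="stable")]
        m = max(1, int(round(validation_fraction * len(train))))
        chosen = [rng.integers(len(chunk)) for chunk in np.array_split(train, m)]
        validation.append(
            np.sort(np.array([chunk[c] for chunk, c in zip(np.array_split(train, m), chosen)]))
        )
    return FoldAssignment(folds=folds, k=k, validation=tuple(validation))


# ---------------------------------------------------------------------------
# bias correction
# ---------------------------------------------------------------------------

def fit_bias_correction(predicted, chronological) -> BiasCorrectionModel:
    """Least squares of predicted age on chronological age."""
    predicted = np.asarray(predicted, dtype=float)
    chronological = np.asarray(chronological, dtype=float)
    if len(np.unique(chronological)) < 2:
        raise DegenerateFitError("chronological ages are all identical; slope undefined")
    alpha, beta = np.polyfit(chronological, predicted, 1)
    return BiasCorrectionModel(alpha=float(alpha), beta=float(beta))


def apply_bias_correction(predicted, chronological, model: BiasCorrectionModel):
    """corrected = predicted + [chron - (chron * alpha + beta)], element-wise."""
    predicted = np.asarray(predicted, dtype=float)
    chronological = np.asarray(chronological, dtype=float)
    return predicted + (chronological - (chronological * model.alpha + model.beta))


def compute_bag(corrected, chronological) -> np.ndarray:
    """BAG = corrected predicted age - chronological age (positive = accelerated)."""
    return np.asarray(corrected, dtype=float) - np.asarray(chronological, dtype=float)


# ---------------------------------------------------------------------------
# MLP training
# ---------------------------------------------------------------------------

def _as_matrix(features) -> np.ndarray:
    if isinstance(features, pd.DataFrame):
        cols = [c for c in features.columns if c != "subject_id"]
        X = features[cols].to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("features contain non-finite values")
    return X


def _zscore_fit(X: np.ndarray):
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return mu, sd


class _CenteredMLP:
    """MLP trained on mean-centered ages (the output scale of an untrained
    net sits near zero, so centering removes ~50 years of bias the
    optimizer would otherwise have to climb)."""

    def __init__(self, model: MLPRegressor, y_mean: float):
        self.model = model
        self.y_mean = y_mean

    def predict(self, X) -> np.ndarray:
        return self.model.predict(X) + self.y_mean


def _fit_mlp(Xtr, ytr, Xval, yval, config: RegressorConfig, seed: int) -> _CenteredMLP:
    """Minibatch training with patience-based early stopping on validation MAE."""
    model = MLPRegressor(
        hidden_layer_sizes=config.hidden_layers,
        solver="adam",
        learning_rate_init=config.learning_rate,
        random_state=int(seed % (2**31)),
    )
    y_mean = float(np.mean(ytr))
    ytr = ytr - y_mean
    yval = yval - y_mean
    rng = np.random.default_rng(seed)
    bs = min(config.batch_size, len(ytr))
    best_mae = np.inf
    best_state = None
    stale = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(config.max_epochs):
            perm = rng.permutation(len(ytr))
            for start in range(0, len(ytr), bs):
                idx = perm[start:start + bs]
                model.partial_fit(Xtr[idx], ytr[idx])
            val_mae = float(np.mean(np.abs(model.predict(Xval) - yval)))
            if val_mae < best_mae - 1e-6:
                best_mae = val_mae
                best_state = (copy.deepcopy(model.coefs_), copy.deepcopy(model.intercepts_))
                stale = 0
            else:
                stale += 1
                if stale > config.patience:
                    break
    if best_state is not None:
        model.coefs_, model.intercepts_ = best_state
    return _CenteredMLP(model, y_mean)


@dataclass
class CVPredictions:
    """Out-of-fold predictions plus the per-fold bias corrections."""

    raw: np.ndarray
    corrected: np.ndarray
    alphas: np.ndarray
    betas: np.ndarray


def train_regressor(
    features, ages, config: RegressorConfig, folds: FoldAssignment
) -> CVPredictions:
    """Cross-validated brain-age prediction.

    Each subject's prediction comes from the single model that held its
    fold out of training; the validation subset is used only for early
    stopping and for fitting that iteration's bias correction.
    """
    X = _as_matrix(features)
    ages = np.asarray(ages, dtype=float)
    if len(X) != len(ages):
        raise ValueError("features and ages are misaligned")
    n = len(ages)
    raw = np.full(n, np.nan)
    corrected = np.full(n, np.nan)
    alphas = np.empty(folds.k)
    betas = np.empty(folds.k)
    for i in range(folds.k):
        tr = folds.train_indices(i)
        va = folds.validation_indices(i)
        te = folds.test_indices(i)
        # canonical age order makes training invariant to input row order
        tr = tr[np.argsort(ages[tr], kind="stable")]
        mu, sd = _zscore_fit(X[tr])
        scale = lambda A: (A - mu) / sd
        model = _fit_mlp(
            scale(X[tr]), ages[tr], scale(X[va]), ages[va], config,
            seed=(config.seed * 1000 + i) % (2**31),
        )
        raw[te] = model.predict(scale(X[te]))
        val_pred = model.predict(scale(X[va]))
        bc = fit_bias_correction(val_pred, ages[va])
        alphas[i], betas[i] = bc.alpha, bc.beta
        corrected[te] = apply_bias_correction(raw[te], ages[te], bc)
    return CVPredictions(raw=raw, corrected=corrected, alphas=alphas, betas=betas)


@dataclass
class BrainAgeResult:
    """Per-subject predictions and per-fold / pooled error summaries."""

    raw: np.ndarray
    corrected: np.ndarray
    bag: np.ndarray
    fold_mae_raw: list[float]
    fold_mae_corrected: list[float]
    pooled_mae_raw: float
    pooled_mae_corrected: float
    alphas: np.ndarray
    betas: np.ndarray
    config: RegressorConfig

    def to_frame(self, ages, subject_id=None) -> pd.DataFrame:
        out = pd.DataFrame({
            "subject_id": np.arange(len(self.raw)) if subject_id is None else subject_id,
            "age": np.asarray(ages, dtype=float),
            "predicted_age": self.raw,
            "corrected_age": self.corrected,
            "bag": self.bag,
        })
        return out

    def report(self) -> dict:
        return {
            "architecture": list(self.config.hidden_layers),
            "fold_mae_raw": self.fold_mae_raw,
            "fold_mae_corrected": self.fold_mae_corrected,
            "pooled_mae_raw": self.pooled_mae_raw,
            "pooled_mae_corrected": self.pooled_mae_corrected,
            "alpha_per_fold": self.alphas.tolist(),
            "beta_per_fold": self.betas.tolist(),
        }


def run_brain_age(features, ages, config: RegressorConfig, folds: FoldAssignment) -> BrainAgeResult:
    """Full stage: CV prediction, bias correction and BAG computation."""
    ages = np.asarray(ages, dtype=float)
    cv = train_regressor(features, ages, config, folds)
    fold_raw, fold_cor = [], []
    for i in range(folds.k):
        te = folds.test_indices(i)
        fold_raw.append(float(np.mean(np.abs(cv.raw[te] - ages[te]))))
        fold_cor.append(float(np.mean(np.abs(cv.corrected[te] - ages[te]))))
    return BrainAgeResult(
        raw=cv.raw,
        corrected=cv.corrected,
        bag=compute_bag(cv.corrected, ages),
        fold_mae_raw=fold_raw,
        fold_mae_corrected=fold_cor,
        pooled_mae_raw=float(np.mean(np.abs(cv.raw - ages))),
        pooled_mae_corrected=float(np.mean(np.abs(cv.corrected - ages))),
        alphas=cv.alphas,
        betas=cv.betas,
        config=config,
    )


def select_architecture(
    features,
    ages,
    candidates=CANDIDATE_ARCHITECTURES,
    folds: FoldAssignment | None = None,
    base_config: RegressorConfig | None = None,
    evaluator=None,
) -> RegressorConfig:
    """Pick the candidate architecture with the lowest cross-validated MAE.

    All candidates are evaluated on the same fold splits; exact MAE ties
    break toward the architecture with fewer parameters.  ``evaluator``
    (candidate tuple -> pooled MAE) may be injected for testing.
    """
    candidates = [tuple(c) for c in candidates]
    if not candidates:
        raise ValueError("need at least one candidate architecture")
    base = base_config if base_config is not None else RegressorConfig()
    ages = np.asarray(ages, dtype=float)
    if folds is None:
        folds = make_stratified_folds(ages, k=10, seed=base.seed)
    n_features = _as_matrix(features).shape[1] if evaluator is None else 0

    def default_eval(arch):
        cfg = replace(base, hidden_layers=arch)
        cv = train_regressor(features, ages, cfg, folds)
        return float(np.mean(np.abs(cv.raw - ages)))

    score = evaluator if evaluator is not None else default_eval
    results = [(score(arch), replace(base, hidden_layers=arch).n_parameters(n_features), arch)
               for arch in candidates]
    best = min(results, key=lambda t: (t[0], t[1]))
    return replace(base, hidden_layers=best[2])
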