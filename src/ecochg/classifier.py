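"""Cost-sensitive drop classification with patient-grouped cross-validation.

Falling-edge time points are hugely imbalanced — drops are rare — so training
is biased toward detecting drops by weighting 'drop' samples with a
misclassification cost.  A natural starting value is the 'no drop' : 'drop'
class ratio; the operating cost is then found by an iterative grid search
that maximises the worse of cross-validated sensitivity and specificity
(computed after post-processing and early-detection credit).

The reference model is an AdaBoost ensemble of shallow decision trees, but
any binary classifier honouring the fit/predict contract can be plugged in
through a model descriptor (a nearest-neighbour variant ships as the second
implementation).

Cross-validation folds are partitions of *patients*, never of time points,
and every fold must contain at least one patient with a drop so each test
set exercises the positive class.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import AdaBoostClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.tree import DecisionTreeClassifier

from .evaluation import ConfusionCounts, Metrics, compute_metrics, evaluate_series
from .features import LabelledSeries, NormalizationParams, apply_minmax, fit_minmax
from .postprocess import S_C_DEFAULT, apply_rules

__all__ = [
    "CostConfig",
    "TrainingSet",
    "TrainedModel",
    "ModelBundle",
    "DEFAULT_MODEL_SPEC",
    "DEFAULT_COST_GRID",
    "train",
    "predict",
    "crossval_split",
    "assemble_training_set",
    "run_cross_validation",
    "cost_search",
    "feature_importance",
]

#: Reference ensemble: 100 rounds of AdaBoost over depth-1 trees with
#: shrinkage 0.3.  The shrunk learning rate keeps the weighted training loss
#: from collapsing to zero, so the drop-misclassification cost retains its
#: intended pull on the decision boundary.
DEFAULT_MODEL_SPEC: dict = {
    "kind": "adaboost",
    "n_estimators": 100,
    "max_depth": 1,
    "learning_rate": 0.3,
}

#: Default misclassification-cost grid for the iterative search.
DEFAULT_COST_GRID: tuple[int, ...] = tuple(range(1, 61, 2))


@dataclass(frozen=True)
class CostConfig:
    """Penalty multiplier for misclassifying a 'drop' instance."""

    drop_miss_cost: float = 22.0

    def __post_init__(self) -> None:
        if self.drop_miss_cost < 1:
            raise ValueError("drop_miss_cost must be >= 1")

    @classmethod
    def from_class_ratio(cls, labels: np.ndarray) -> "CostConfig":
        """Initial cost = (#'no drop') / (#'drop')."""
        labels = np.asarray(labels, dtype=bool)
        n_drop = int(labels.sum())
        if n_drop == 0 or n_drop == labels.size:
            raise ValueError("both classes must be present")
        return cls(max(1.0, (labels.size - n_drop) / n_drop))


@dataclass(frozen=True)
class TrainingSet:
    """Normalised falling-edge feature vectors with labels and patient ids."""

    X: np.ndarray
    y: np.ndarray  # bool, True = 'drop'
    patient_ids: np.ndarray

    def __post_init__(self) -> None:
        if self.X.shape[0] != self.y.size or self.y.size != self.patient_ids.size:
            raise ValueError("X, y and patient_ids must have equal length")


@dataclass
class TrainedModel:
    """A fitted classifier plus the descriptor it was built from."""

    estimator: object
    spec: dict
    cost: CostConfig

    @property
    def feature_importances(self) -> np.ndarray | None:
        return getattr(self.estimator, "feature_importances_", None)


def _make_estimator(spec: Mapping, seed: int) -> object:
    kind = spec.get("kind", "adaboost")
    if kind == "adaboost":
        return AdaBoostClassifier(
            estimator=DecisionTreeClassifier(
                max_depth=int(spec.get("max_depth", 1)), random_state=seed
            ),
            n_estimators=int(spec.get("n_estimators", 100)),
            learning_rate=float(spec.get("learning_rate", 0.3)),
            random_state=seed,
        )
    if kind == "knn":
        return KNeighborsClassifier(n_neighbors=int(spec.get("n_neighbors", 10)))
    raise ValueError(f"unknown model kind {kind!r}")


def train(
    ts: TrainingSet,
    cost: CostConfig | float = 22.0,
    spec: Mapping | None = None,
    seed: int = 0,
) -> TrainedModel:
    """Fit a cost-weighted classifier on a training set.

    The cost enters as a per-sample weight on 'drop' instances (class-weighted
    loss).  Estimators that ignore sample weights (e.g. nearest neighbour)
    are trained unweighted.
    """
    if not isinstance(cost, CostConfig):
        cost = CostConfig(float(cost))
    spec = dict(spec or DEFAULT_MODEL_SPEC)
    y = np.asarray(ts.y, dtype=bool)
    if y.all() or not y.any():
        raise ValueError("training data must contain both classes")
    est = _make_estimator(spec, seed)
    weights = np.where(y, cost.drop_miss_cost, 1.0)
    try:
        est.fit(ts.X, y, sample_weight=weights)
    except TypeError:
        est.fit(ts.X, y)
    return TrainedModel(est, spec, cost)


def predict(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """Boolean drop predictions, one per feature vector."""
    X = np.asarray(X, dtype=float)
    n_expected = getattr(model.estimator, "n_features_in_", X.shape[1])
    if X.shape[1] != n_expected:
        raise ValueError(f"expected {n_expected} features, got {X.shape[1]}")
    return np.asarray(model.estimator.predict(X), dtype=bool)


def crossval_split(
    patient_ids: Sequence[str],
    drop_patients: Sequence[str],
    k: int = 5,
    seed: int = 0,
) -> list[list[str]]:
    """Random partition of patients into k folds, each with >= 1 drop patient.

    Drop patients are dealt round-robin across shuffled folds first, then the
    remaining patients are distributed to keep fold sizes balanced.
    Deterministic for a fixed seed.
    """
    patient_ids = list(dict.fromkeys(patient_ids))
    drop_set = set(drop_patients)
    droppers = [p for p in patient_ids if p in drop_set]
    others = [p for p in patient_ids if p not in drop_set]
    if len(droppers) < k:
        raise ValueError(
            f"need at least {k} patients with drops for {k} folds, have {len(droppers)}"
        )
    rng = np.random.default_rng(seed)
    rng.shuffle(droppers)
    rng.shuffle(others)
    folds: list[list[str]] = [[] for _ in range(k)]
    for i, p in enumerate(droppers):
        folds[i % k].append(p)
    # fill smallest folds first so sizes stay balanced; ties broken by index
    for p in others:
        folds[min(range(k), key=lambda i: (len(folds[i]), i))].append(p)
    return folds


def assemble_training_set(
    series: Sequence[LabelledSeries], patients: Sequence[str] | None = None
) -> TrainingSet:
    """Stack eligible (valid falling-edge) points from selected patients."""
    keep = set(patients) if patients is not None else None
    Xs, ys, pids = [], [], []
    for s in series:
        if keep is not None and s.patient_id not in keep:
            continue
        el = s.eligible
        Xs.append(s.features[el])
        ys.append(s.expert[el])
        pids.append(np.full(int(el.sum()), s.patient_id, dtype=object))
    if not Xs:
        raise ValueError("no series selected")
    return TrainingSet(np.vstack(Xs), np.concatenate(ys), np.concatenate(pids))


@dataclass(frozen=True)
class FoldResult:
    test_patients: tuple[str, ...]
    counts: ConfusionCounts
    metrics: Metrics
    model: TrainedModel
    norm: NormalizationParams


@dataclass(frozen=True)
class CVResult:
    folds: tuple[FoldResult, ...]

    @property
    def mean_metrics(self) -> Metrics:
        """Unweighted mean of per-fold metrics (the headline aggregate)."""
        return Metrics(
            sensitivity=float(np.mean([f.metrics.sensitivity for f in self.folds])),
            specificity=float(np.mean([f.metrics.specificity for f in self.folds])),
            accuracy=float(np.mean([f.metrics.accuracy for f in self.folds])),
        )

    @property
    def pooled_counts(self) -> ConfusionCounts:
        total = ConfusionCounts()
        for f in self.folds:
            total = total + f.counts
        return total

    @property
    def pooled_metrics(self) -> Metrics:
        return compute_metrics(self.pooled_counts)

    @property
    def models(self) -> list[TrainedModel]:
        return [f.model for f in self.folds]


def _predict_series(
    s: LabelledSeries,
    model: TrainedModel,
    norm: NormalizationParams,
    s_c: float,
    postprocessing: bool,
) -> np.ndarray:
    """Full-length boolean label array for one insertion (False off-edge)."""
    labels = np.zeros(s.cm_amp.size, dtype=bool)
    el = s.eligible
    if el.any():
        labels[el] = predict(model, apply_minmax(s.features[el], norm))
    if postprocessing:
        labels = apply_rules(s.cm_amp, s.falling, labels, s_c=s_c)
        labels &= el  # post-processing never labels unclassified points
    return labels


def run_cross_validation(
    series: Sequence[LabelledSeries],
    folds: Sequence[Sequence[str]],
    cost: CostConfig | float,
    spec: Mapping | None = None,
    s_c: float = S_C_DEFAULT,
    postprocessing: bool = True,
    early_credit: bool = True,
    seed: int = 0,
) -> CVResult:
    """Train on k-1 folds, test on the held-out fold, for every fold.

    Min-max normalisation is fitted on each fold's training rows only.
    Test-set metrics include post-processing and early-detection credit
    unless disabled.
    """
    by_id = {s.patient_id: s for s in series}
    results = []
    for i, test_patients in enumerate(folds):
        train_patients = [p for j, f in enumerate(folds) if j != i for p in f]
        ts = assemble_training_set(series, train_patients)
        norm = fit_minmax(ts.X)
        model = train(
            TrainingSet(apply_minmax(ts.X, norm), ts.y, ts.patient_ids),
            cost,
            spec,
            seed=seed,
        )
        counts = ConfusionCounts()
        for pid in test_patients:
            s = by_id[pid]
            labels = _predict_series(s, model, norm, s_c, postprocessing)
            if early_credit:
                counts = counts + evaluate_series(
                    labels, s.annotation, s.cm_amp, s.falling, s.eligible
                )
            else:
                el = s.eligible
                counts = counts + ConfusionCounts(
                    true_drops=int((labels & s.expert & el).sum()),
                    false_no_drops=int((~labels & s.expert & el).sum()),
                    true_no_drops=int((~labels & ~s.expert & el).sum()),
                    false_drops=int((labels & ~s.expert & el).sum()),
                )
        results.append(
            FoldResult(tuple(test_patients), counts, compute_metrics(counts), model, norm)
        )
    return CVResult(tuple(results))


@dataclass(frozen=True)
class CostSearchResult:
    best_cost: float
    curves: pd.DataFrame  # columns: cost, sensitivity, specificity, accuracy
    results: dict[float, CVResult]

    @property
    def best_result(self) -> CVResult:
        return self.results[self.best_cost]


def cost_search(
    series: Sequence[LabelledSeries],
    folds: Sequence[Sequence[str]],
    grid: Sequence[float] = DEFAULT_COST_GRID,
    spec: Mapping | None = None,
    s_c: float = S_C_DEFAULT,
    seed: int = 0,
) -> CostSearchResult:
    """Grid search over the drop-misclassification cost.

    Each grid point is scored by cross-validated mean sensitivity and
    specificity (post-processing and early credit applied).  The best cost
    maximises min(sensitivity, specificity); ties break toward higher
    accuracy, then lower cost.
    """
    if len(grid) == 0:
        raise ValueError("cost grid must be non-empty")
    rows = []
    results: dict[float, CVResult] = {}
    for cost in grid:
        cv = run_cross_validation(series, folds, cost, spec, s_c=s_c, seed=seed)
        m = cv.mean_metrics
        results[float(cost)] = cv
        rows.append(
            {
                "cost": float(cost),
                "sensitivity": m.sensitivity,
                "specificity": m.specificity,
                "accuracy": m.accuracy,
            }
        )
    curves = pd.DataFrame(rows)
    key = curves.apply(
        lambda r: (
            min(r["sensitivity"], r["specificity"]),
            r["accuracy"],
            -r["cost"],
        ),
        axis=1,
    )
    best_cost = float(curves.loc[key.idxmax(), "cost"])
    return CostSearchResult(best_cost, curves, results)


def feature_importance(models: Sequence[TrainedModel]) -> np.ndarray:
    """Mean per-feature weight fractions across fold models (sum to 1).

    Each model contributes its normalised total impurity-decrease weights;
    the fold average is renormalised.
    """
    ws = []
    for m in models:
        w = m.feature_importances
        if w is None:
            raise ValueError("model exposes no feature importances")
        ws.append(np.asarray(w, dtype=float))
    mean = np.mean(ws, axis=0)
    total = mean.sum()
    return mean / total if total > 0 else mean


@dataclass
class ModelBundle:
    """Everything needed to classify a new insertion, persistable to one file."""

    model: TrainedModel
    norm: NormalizationParams
    feature_mode: str = "primary"
    s_a: float = 0.5
    s_b: float = 0.1
    s_c: float = S_C_DEFAULT

    def save(self, path: str | Path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path: str | Path) -> "ModelBundle":
        with open(path, "rb") as fh:
            bundle = pickle.load(fh)
        if not isinstance(bundle, ModelBundle):
            raise ValueError(f"{path} does not contain a model bundle")
        return bundle
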