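"""The integrated HRR-deficiency (iHRD) classifier.

A binary Gaussian-RBF-kernel support-vector machine over six whole-exome
genomic features: CSig3 weight, CSig8 weight, LOH score, total somatic
mutation count, tumor ploidy, and the number of copy-number segments.  The
positive training class is tumors with biallelic loss of a core HRR gene;
the negative class is tumors without any HRR-gene aberration.

Feature handling: the two heavy-tailed count features (mutation count,
segment count) are log1p-transformed, then all features are z-scored.  Both
steps are fitted inside every cross-validation fold (no leakage).  (C, gamma)
are selected by stratified k-fold cross-validation minimising
misclassification; the final model is refit on all training data.  The
decision threshold is the SVM sign (0 on the decision function).

The fitted model reduces to plain arrays (scaling parameters, support
vectors, dual coefficients, kernel parameters) and the decision function is
evaluated explicitly as ``sum_i alpha_i K(sv_i, z) + b``, which makes JSON
serialisation exact: a round-tripped model reproduces decision values
bit-for-bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import FunctionTransformer, StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .cn_features import FEATURE_NAMES, GenomicFeatureVector

__all__ = [
    "IHRDClassifier",
    "TrainingSpec",
    "TrainedClassifier",
    "train_ihrd",
    "predict_ihrd",
    "cv_misclassification",
    "features_to_matrix",
    "DEFAULT_SEED",
]

DEFAULT_SEED = 20211208
_DEFAULT_C_GRID = (0.1, 1.0, 10.0, 100.0)
# "auto" = 1/n_features (1/6 for the canonical feature set)
_DEFAULT_GAMMA_GRID = (0.01, 0.1, "auto", 1.0, 10.0)
# indices of n_somatic_mutations and n_segments in FEATURE_NAMES
_DEFAULT_LOG1P_INDICES = (3, 5)


def features_to_matrix(
    features: Sequence[GenomicFeatureVector],
) -> tuple[np.ndarray, list[str]]:
    """Stack feature vectors into an (n, 6) matrix plus the sample-id order."""
    if not features:
        raise ValueError("no feature vectors supplied")
    return np.vstack([f.as_array() for f in features]), [f.sample_id for f in features]


def _log1p_selected(X, indices):
    X = np.array(X, dtype=float, copy=True)
    idx = [i for i in indices if i < X.shape[1]]
    X[:, idx] = np.log1p(X[:, idx])
    return X


class IHRDClassifier(ClassifierMixin, BaseEstimator):
    """RBF-SVM classifier over genomic HRRd features, scikit-learn style.

    Parameters
    ----------
    C_grid, gamma_grid : sequences
        Hyperparameter grid searched by stratified CV.  ``gamma`` entries may
        be floats or the string "auto" (1 / n_features).
    cv : int
        Number of stratified folds (default 5).
    class_weight : None or "balanced"
        Passed to the SVM; "balanced" compensates the positive/negative
        imbalance of the training design (default).
    log1p_indices : tuple of int
        Feature columns log1p-transformed before standardisation; defaults
        to the mutation-count and segment-count columns.  Empty tuple
        disables the transform.
    kernel : str
        "rbf" (default) or "linear" (ablation).
    random_state : int
        Seeds fold shuffling; identical data + seed give an identical model.

    Attributes (after fit)
    ----------------------
    C_, gamma_ : selected hyperparameters (gamma_ numeric)
    cv_misclassification_ : CV error of the selected grid point
    center_, scale_ : standardisation parameters fitted on all training data
    support_vectors_, dual_coef_, intercept_ : kernel expansion of the model
    """

    def __init__(
        self,
        C_grid: Sequence[float] = _DEFAULT_C_GRID,
        gamma_grid: Sequence = _DEFAULT_GAMMA_GRID,
        cv: int = 5,
        class_weight: str | None = "balanced",
        log1p_indices: tuple[int, ...] = _DEFAULT_LOG1P_INDICES,
        kernel: str = "rbf",
        random_state: int = DEFAULT_SEED,
    ):
        self.C_grid = C_grid
        self.gamma_grid = gamma_grid
        self.cv = cv
        self.class_weight = class_weight
        self.log1p_indices = log1p_indices
        self.kernel = kernel
        self.random_state = random_state

    # ------------------------------------------------------------------ fit

    def _make_pipeline(self) -> Pipeline:
        return Pipeline([
            ("log1p", FunctionTransformer(
                _log1p_selected, kw_args={"indices": tuple(self.log1p_indices)},
                validate=False)),
            ("scale", StandardScaler()),
            ("svc", SVC(kernel=self.kernel, class_weight=self.class_weight)),
        ])

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        if self.cv < 2:
            raise ValueError("cv must be >= 2")
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) != 2:
            raise ValueError(f"need exactly 2 classes, got {list(classes)}")
        if counts.min() < self.cv:
            small = classes[counts.argmin()]
            raise ValueError(
                f"class {small!r} has {counts.min()} members, fewer than "
                f"cv={self.cv} folds"
            )
        Xt = _log1p_selected(X, self.log1p_indices)
        variances = Xt.var(axis=0)
        if np.any(variances == 0):
            names = (
                [FEATURE_NAMES[i] for i in np.nonzero(variances == 0)[0]]
                if X.shape[1] == len(FEATURE_NAMES)
                else list(np.nonzero(variances == 0)[0])
            )
            raise ValueError(f"zero-variance feature(s): {names}")

        folds = StratifiedKFold(
            n_splits=self.cv, shuffle=True, random_state=self.random_state
        )
        search = GridSearchCV(
            self._make_pipeline(),
            param_grid={"svc__C": list(self.C_grid),
                        "svc__gamma": list(self.gamma_grid)},
            scoring="accuracy",
            cv=folds,
            refit=True,
        )
        search.fit(X, y)

        self.classes_ = classes
        self.n_features_in_ = X.shape[1]
        self.best_params_ = dict(search.best_params_)
        self.cv_misclassification_ = float(1.0 - search.best_score_)
        pipe: Pipeline = search.best_estimator_
        scaler: StandardScaler = pipe.named_steps["scale"]
        svc: SVC = pipe.named_steps["svc"]
        self.C_ = float(svc.C)
        gamma = svc.gamma
        if gamma == "auto":
            gamma = 1.0 / X.shape[1]
        elif gamma == "scale":
            Z_all = (Xt - scaler.mean_) / scaler.scale_
            gamma = 1.0 / (X.shape[1] * Z_all.var())
        self.gamma_ = float(gamma)
        self.center_ = scaler.mean_.copy()
        self.scale_ = scaler.scale_.copy()
        self.support_vectors_ = svc.support_vectors_.copy()
        self.dual_coef_ = svc.dual_coef_[0].copy()
        self.intercept_ = float(svc.intercept_[0])
        # sklearn's decision sign convention relative to classes_ ordering
        self._svc_classes_ = svc.classes_.copy()
        self.decision_threshold_ = 0.0
        return self

    # ------------------------------------------------------------- predict

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        Xt = _log1p_selected(X, self.log1p_indices)
        return (Xt - self.center_) / self.scale_

    def decision_function(self, X) -> np.ndarray:
        """Explicit kernel expansion: sum_i alpha_i K(sv_i, z) + b."""
        check_is_fitted(self, "support_vectors_")
        X = check_array(X, dtype=float, ensure_all_finite=False)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}"
            )
        if not np.all(np.isfinite(X)):
            bad = np.nonzero(~np.isfinite(X).all(axis=1))[0]
            raise ValueError(f"non-finite feature values in rows {bad.tolist()}")
        Z = self._standardize(X)
        if self.kernel == "rbf":
            d2 = (
                (Z**2).sum(axis=1)[:, None]
                + (self.support_vectors_**2).sum(axis=1)[None, :]
                - 2.0 * Z @ self.support_vectors_.T
            )
            K = np.exp(-self.gamma_ * np.maximum(d2, 0.0))
        elif self.kernel == "linear":
            K = Z @ self.support_vectors_.T
        else:  # pragma: no cover - guarded in fit
            raise ValueError(f"unsupported kernel {self.kernel!r}")
        return K @ self.dual_coef_ + self.intercept_

    def predict(self, X) -> np.ndarray:
        df = self.decision_function(X)
        pos, neg = self._svc_classes_[1], self._svc_classes_[0]
        return np.where(df > self.decision_threshold_, pos, neg)

    # ------------------------------------------------------- serialisation

    def to_json(self) -> str:
        check_is_fitted(self, "support_vectors_")
        doc = {
            "model": "ihrd-rbf-svm",
            "version": 1,
            "kernel": self.kernel,
            "params": self.get_params(),
            "C": self.C_,
            "gamma": self.gamma_,
            "cv_misclassification": self.cv_misclassification_,
            "center": self.center_.tolist(),
            "scale": self.scale_.tolist(),
            "support_vectors": self.support_vectors_.tolist(),
            "dual_coef": self.dual_coef_.tolist(),
            "intercept": self.intercept_,
            "decision_threshold": self.decision_threshold_,
            "classes": np.asarray(self.classes_).tolist(),
            "svc_classes": np.asarray(self._svc_classes_).tolist(),
            "n_features_in": self.n_features_in_,
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "IHRDClassifier":
        doc = json.loads(text)
        if doc.get("model") != "ihrd-rbf-svm":
            raise ValueError("not an iHRD model document")
        params = doc["params"]
        params["gamma_grid"] = [
            g if isinstance(g, (int, float)) else str(g) for g in params["gamma_grid"]
        ]
        params["log1p_indices"] = tuple(params["log1p_indices"])
        est = cls(**params)
        est.kernel = doc["kernel"]
        est.C_ = float(doc["C"])
        est.gamma_ = float(doc["gamma"])
        est.cv_misclassification_ = float(doc["cv_misclassification"])
        est.center_ = np.asarray(doc["center"], dtype=float)
        est.scale_ = np.asarray(doc["scale"], dtype=float)
        est.support_vectors_ = np.asarray(doc["support_vectors"], dtype=float)
        est.dual_coef_ = np.asarray(doc["dual_coef"], dtype=float)
        est.intercept_ = float(doc["intercept"])
        est.decision_threshold_ = float(doc["decision_threshold"])
        est.classes_ = np.asarray(doc["classes"])
        est._svc_classes_ = np.asarray(doc["svc_classes"])
        est.n_features_in_ = int(doc["n_features_in"])
        est.best_params_ = {"svc__C": est.C_, "svc__gamma": est.gamma_}
        return est


# ------------------------------------------------------------ thin wrappers


@dataclass(frozen=True)
class TrainingSpec:
    """Training design: positive HRG-BAL tumors vs HRR-proficient tumors."""

    positive_ids: tuple[str, ...]
    negative_ids: tuple[str, ...]
    C_grid: tuple[float, ...] = _DEFAULT_C_GRID
    gamma_grid: tuple = _DEFAULT_GAMMA_GRID
    cv_folds: int = 5
    seed: int = DEFAULT_SEED
    class_weight: str | None = "balanced"

    def __post_init__(self):
        pos, neg = set(self.positive_ids), set(self.negative_ids)
        if not pos or not neg:
            raise ValueError("positive and negative id sets must be non-empty")
        if pos & neg:
            raise ValueError(f"overlapping training ids: {sorted(pos & neg)}")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


@dataclass
class TrainedClassifier:
    """A fitted iHRD model plus training metadata."""

    estimator: IHRDClassifier
    training_ids: list[str] = field(default_factory=list)
    spec: TrainingSpec | None = None

    @property
    def cv_misclassification(self) -> float:
        return self.estimator.cv_misclassification_

    def to_json(self) -> str:
        return self.estimator.to_json()


def _design_matrix(features, spec):
    by_id = {f.sample_id: f for f in features}
    missing = [s for s in (*spec.positive_ids, *spec.negative_ids) if s not in by_id]
    if missing:
        raise ValueError(f"no feature vector for training ids: {missing}")
    ids = list(spec.positive_ids) + list(spec.negative_ids)
    X = np.vstack([by_id[s].as_array() for s in ids])
    y = np.array([1] * len(spec.positive_ids) + [0] * len(spec.negative_ids))
    return X, y, ids


def train_ihrd(
    features: Sequence[GenomicFeatureVector], spec: TrainingSpec
) -> TrainedClassifier:
    """Train the iHRD classifier per a training spec; reproducible from seed."""
    X, y, ids = _design_matrix(features, spec)
    est = IHRDClassifier(
        C_grid=tuple(spec.C_grid),
        gamma_grid=tuple(spec.gamma_grid),
        cv=spec.cv_folds,
        class_weight=spec.class_weight,
        random_state=spec.seed,
    ).fit(X, y)
    return TrainedClassifier(estimator=est, training_ids=ids, spec=spec)


def predict_ihrd(
    model: TrainedClassifier | IHRDClassifier,
    features: Sequence[GenomicFeatureVector],
) -> "pd.DataFrame":
    """Per-sample boolean iHRD call plus the raw decision value."""
    import pandas as pd

    est = model.estimator if isinstance(model, TrainedClassifier) else model
    X, ids = features_to_matrix(features)
    decision = est.decision_function(X)
    return pd.DataFrame({
        "sample_id": ids,
        "ihrd_decision_value": decision,
        "ihrd_positive": decision > est.decision_threshold_,
    })


def cv_misclassification(
    features: Sequence[GenomicFeatureVector],
    labels: Sequence[int] | None = None,
    spec: TrainingSpec | None = None,
    cv: int | None = None,
    seed: int | None = None,
) -> float:
    """Nested stratified-CV misclassification of the full pipeline.

    Standardisation and hyperparameter selection run inside every outer
    training fold, so the reported rate is leakage-free.  Either a
    ``TrainingSpec`` (labels from the positive/negative id sets) or an
    explicit label vector may be given.
    """
    if spec is not None:
        X, y, _ = _design_matrix(features, spec)
        cv = cv or spec.cv_folds
        seed = spec.seed if seed is None else seed
        base = IHRDClassifier(
            C_grid=tuple(spec.C_grid), gamma_grid=tuple(spec.gamma_grid),
            cv=cv, class_weight=spec.class_weight, random_state=seed,
        )
    else:
        if labels is None:
            raise ValueError("either spec or labels must be supplied")
        X, _ = features_to_matrix(features)
        y = np.asarray(labels)
        cv = cv or 5
        seed = DEFAULT_SEED if seed is None else seed
        base = IHRDClassifier(cv=cv, random_state=seed)
    outer = StratifiedKFold(n_splits=cv, shuffle=True, random_state=seed)
    errors = 0
    for train_idx, test_idx in outer.split(X, y):
        fold = IHRDClassifier(**base.get_params()).fit(X[train_idx], y[train_idx])
        errors += int((fold.predict(X[test_idx]) != y[test_idx]).sum())
    return errors / len(y)
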