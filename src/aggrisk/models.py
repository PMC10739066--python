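"""Classifier families behind one train/score contract.

Three families are supported: ridge-regularized logistic regression (LR),
RBF-kernel support vector machines (SVM), and small feed-forward neural
networks (NN).  All share the same preprocessing — feature-wise median
imputation and standardization fitted on the training data only — and the
same scoring convention: higher score means higher predicted risk.  LR and
NN emit probabilities; the SVM emits its margin distance, which is
rank-valid for AUROC.

Multi-label targets get one fitted scorer per behavior class sharing the
training standardization.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.model_selection import GridSearchCV, GroupKFold, StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

FAMILIES = ("lr", "svm", "nn")

LR_C_GRID = tuple(np.logspace(-4, 2, 7))
SVM_GRID = {"C": [1.0, 10.0]}
SVM_MAX_TRAIN = 20_000
NN_HIDDEN = (32, 32)


class SingleClassError(ValueError):
    """Training labels contain a single class; skip this fold/class."""


@dataclass(frozen=True)
class ModelSpec:
    """Classifier family, hyperparameter overrides and seed.

    ``params`` overrides the family defaults (e.g. ``{"C": 1.0}`` pins the
    LR ridge strength and skips the inner CV search).
    """

    family: str = "lr"
    seed: int = 0
    params: dict = field(default_factory=dict, hash=False)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; use one of {FAMILIES}")


def _inner_cv(y: np.ndarray, groups: np.ndarray | None, seed: int):
    """Inner folds for hyperparameter selection.

    With session groups, folds are grouped so temporally adjacent
    (autocorrelated) instances never straddle an inner train/validation
    boundary — random inner folds systematically favor undersmoothed
    models on sliding-window data.  Returns None when no valid folds
    can be formed (caller falls back to fixed defaults).
    """
    if groups is not None:
        uniq = np.unique(groups)
        n_splits = min(3, uniq.size)
        if n_splits >= 2:
            folds = [
                (tr, va)
                for tr, va in GroupKFold(n_splits).split(np.zeros(y.size), y, groups)
                if np.unique(y[tr]).size == 2 and np.unique(y[va]).size == 2
            ]
            if folds:
                return folds
        return None
    n_splits = min(3, int(np.bincount(y).min()))
    if n_splits < 2:
        return None
    return StratifiedKFold(n_splits, shuffle=True, random_state=seed)


def _make_estimator(
    spec: ModelSpec, y: np.ndarray, groups: np.ndarray | None = None
):
    if spec.family == "lr":
        base = LogisticRegression(class_weight="balanced", max_iter=2000)
        if "C" in spec.params:
            return base.set_params(C=float(spec.params["C"]))
        cv = _inner_cv(y, groups, spec.seed)
        if cv is None:
            return base.set_params(C=0.01)
        return GridSearchCV(
            base,
            {"C": list(spec.params.get("C_grid", LR_C_GRID))},
            scoring="roc_auc",
            cv=cv,
            error_score=0.0,
        )
    if spec.family == "svm":
        base = SVC(kernel="rbf", gamma="scale", class_weight="balanced")
        if "C" in spec.params:
            return base.set_params(C=float(spec.params["C"]))
        cv = _inner_cv(y, groups, spec.seed)
        if cv is None:
            return base
        return GridSearchCV(
            base,
            spec.params.get("grid", SVM_GRID),
            scoring="roc_auc",
            cv=cv,
            error_score=0.0,
        )
    # nn: capacity controlled by the L2 penalty; a held-out early-stopping
    # split is unstratified and unreliable with rare positives
    return MLPClassifier(
        hidden_layer_sizes=spec.params.get("hidden", NN_HIDDEN),
        alpha=spec.params.get("alpha", 1e-2),
        early_stopping=spec.params.get("early_stopping", False),
        n_iter_no_change=10,
        max_iter=spec.params.get("max_epochs", 300),
        random_state=spec.seed,
    )


@dataclass
class FittedModel:
    """A trained scorer bundle: spec + preprocessing + per-class estimators."""

    spec: ModelSpec
    feature_names: list[str]
    medians: pd.Series
    scaler: StandardScaler
    estimators: dict[str, object]
    subsampled: bool = False

    def _matrix(self, X: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.feature_names if c not in X.columns]
        if missing:
            raise ValueError(f"feature mismatch: missing columns {missing}")
        M = X[self.feature_names].astype(float).fillna(self.medians)
        return self.scaler.transform(M.to_numpy())

    def score(self, X: pd.DataFrame) -> pd.DataFrame:
        """Risk scores, one column per target class (higher = riskier)."""
        Z = self._matrix(X)
        out = {}
        for target, est in self.estimators.items():
            if hasattr(est, "predict_proba"):
                out[target] = est.predict_proba(Z)[:, 1]
            else:
                out[target] = est.decision_function(Z)
        return pd.DataFrame(out, index=X.index)

    def score_one(self, X: pd.DataFrame, target: str | None = None) -> np.ndarray:
        s = self.score(X)
        return s[target or next(iter(self.estimators))].to_numpy()

    @property
    def chosen_params(self) -> dict[str, dict]:
        """Selected hyperparameters per target (after any inner search)."""
        out = {}
        for target, est in self.estimators.items():
            if isinstance(est, LogisticRegressionCV):
                out[target] = {"C": float(est.C_[0])}
            elif isinstance(est, GridSearchCV):
                out[target] = dict(est.best_params_)
            elif isinstance(est, (LogisticRegression, SVC)):
                out[target] = {"C": float(est.C)}
            else:
                out[target] = {}
        return out

    def coefficients(self, target: str | None = None) -> np.ndarray:
        est = self.estimators[target or next(iter(self.estimators))]
        if isinstance(est, GridSearchCV):
            est = est.best_estimator_
        return est.coef_.ravel()

    def save(self, path: str | Path) -> None:
        with open(path, "wb") as fh:
            pickle.dump({"format": 1, "model": self}, fh)

    @classmethod
    def load(cls, path: str | Path) -> "FittedModel":
        with open(path, "rb") as fh:
            payload = pickle.load(fh)
        if payload.get("format") != 1:
            raise ValueError("unrecognized model archive format")
        return payload["model"]


def train(
    spec: ModelSpec,
    X: pd.DataFrame,
    y: pd.DataFrame | pd.Series | np.ndarray,
    feature_names: list[str] | None = None,
    sample_weight: np.ndarray | None = None,
    groups: np.ndarray | None = None,
) -> FittedModel:
    """Fit one scorer per target column on the training instances.

    Standardization statistics and imputation medians come from the
    training data only.  A target with a single observed class raises
    :class:`SingleClassError` so the caller can skip and record the cell.
    SVM training subsamples to at most 20 000 instances (seeded).
    """
    if isinstance(y, (pd.Series, np.ndarray)):
        y = pd.DataFrame({"label": np.asarray(y)})
    feature_names = feature_names or list(X.columns)
    Xf = X[feature_names].astype(float)
    medians = Xf.median()
    medians = medians.fillna(0.0)
    M = Xf.fillna(medians).to_numpy()

    rng = np.random.default_rng(spec.seed)
    subsampled = False
    if spec.family == "svm" and M.shape[0] > SVM_MAX_TRAIN:
        idx = rng.choice(M.shape[0], SVM_MAX_TRAIN, replace=False)
        M = M[idx]
        y = y.iloc[idx]
        sample_weight = sample_weight[idx] if sample_weight is not None else None
        groups = groups[idx] if groups is not None else None
        subsampled = True

    scaler = StandardScaler().fit(M, sample_weight=sample_weight)
    Z = scaler.transform(M)
    estimators: dict[str, object] = {}
    for target in y.columns:
        yv = np.asarray(y[target]).astype(int)
        if len(np.unique(yv)) < 2:
            raise SingleClassError(
                f"target {target!r} has a single class in training data; "
                "skip this fold/class and record it"
            )
        est = _make_estimator(spec, yv, groups)
        if sample_weight is not None and spec.family != "nn":
            est.fit(Z, yv, sample_weight=sample_weight)
        else:
            est.fit(Z, yv)
        estimators[target] = est
    return FittedModel(
        spec=spec,
        feature_names=feature_names,
        medians=medians,
        scaler=scaler,
        estimators=estimators,
        subsampled=subsampled,
    )
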