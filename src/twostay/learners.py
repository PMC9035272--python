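"""Uniform contract over the three pluggable base-learner families.

The families are the standard trio for tabular clinical prediction:

* ``penalized_linear`` — L1-penalized linear/logistic regression (LASSO),
* ``tree_ensemble``    — random forest,
* ``feedforward_net``  — multilayer perceptron.

Each is wrapped in a preprocessing pipeline (median imputation with missing
indicators, one-hot encoding with an explicit reference level, and
standardized numerics for the scale-sensitive families) and tuned by internal
k-fold cross-validation over a small default grid.  The grids are exposed on
:class:`LearnerSpec` so a configuration file can override them.

Fitted learners record the feature schema and the training-target range; the
range matters because tree-ensemble predictions are averages of training
targets and therefore can never leave it — the mechanism that makes a
truncated-outcome forest blind to prolonged stays.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.compose import ColumnTransformer
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.impute import SimpleImputer
from sklearn.linear_model import Lasso, LogisticRegression
from sklearn.model_selection import GridSearchCV, KFold, StratifiedKFold
from sklearn.neural_network import MLPClassifier, MLPRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import OneHotEncoder, StandardScaler

from .exceptions import DegenerateTargetError, SchemaMismatchError
from .transforms import OutcomeTransform

__all__ = ["LearnerSpec", "FittedLearner", "OneStageModel", "fit_learner", "fit_one_stage"]

FAMILIES = ("penalized_linear", "tree_ensemble", "feedforward_net")
TASKS = ("regression", "classification")

# Default hyperparameter search grids, keyed by (family, task).  Kept small:
# one axis per family's dominant regularizer.
_DEFAULT_GRIDS: dict[tuple[str, str], dict[str, list]] = {
    ("penalized_linear", "regression"): {"model__alpha": [0.001, 0.01, 0.1, 1.0]},
    ("penalized_linear", "classification"): {"model__C": [0.01, 0.1, 1.0, 10.0]},
    ("tree_ensemble", "regression"): {"model__max_depth": [None, 12]},
    ("tree_ensemble", "classification"): {"model__max_depth": [None, 12]},
    ("feedforward_net", "regression"): {"model__alpha": [1e-4, 1e-2]},
    ("feedforward_net", "classification"): {"model__alpha": [1e-4, 1e-2]},
}


@dataclass
class LearnerSpec:
    """Family, task, hyperparameter overrides, search grid and CV settings."""

    family: str
    task: str = "regression"
    hyperparameters: Mapping[str, Any] = field(default_factory=dict)
    grid: Mapping[str, list] | None = None
    cv_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}, got {self.family!r}")
        if self.task not in TASKS:
            raise ValueError(f"task must be one of {TASKS}, got {self.task!r}")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")

    def with_task(self, task: str) -> "LearnerSpec":
        if task == self.task:
            return self
        # note: an explicit grid/hyperparameter override must be valid for the
        # new task too when one spec is reused across stages
        return LearnerSpec(
            family=self.family,
            task=task,
            hyperparameters=dict(self.hyperparameters),
            grid=None if self.grid is None else dict(self.grid),
            cv_folds=self.cv_folds,
            seed=self.seed,
        )

    def resolved_grid(self) -> dict[str, list]:
        if self.grid is not None:
            return dict(self.grid)
        return dict(_DEFAULT_GRIDS[(self.family, self.task)])


def _base_estimator(spec: LearnerSpec):
    fam, task = spec.family, spec.task
    if fam == "penalized_linear":
        if task == "regression":
            est = Lasso(max_iter=10000, random_state=spec.seed)
        else:
            est = LogisticRegression(
                l1_ratio=1.0, solver="liblinear", max_iter=2000, random_state=spec.seed
            )
    elif fam == "tree_ensemble":
        cls = RandomForestRegressor if task == "regression" else RandomForestClassifier
        est = cls(n_estimators=200, n_jobs=1, random_state=spec.seed)
    else:
        cls = MLPRegressor if task == "regression" else MLPClassifier
        est = cls(hidden_layer_sizes=(32,), max_iter=500, random_state=spec.seed)
    if spec.hyperparameters:
        est.set_params(**dict(spec.hyperparameters))
    return est


def _preprocessor(X: pd.DataFrame, scale_numeric: bool) -> ColumnTransformer:
    cat_cols = [
        c
        for c in X.columns
        if X[c].dtype == object
        or isinstance(X[c].dtype, pd.CategoricalDtype)
        or X[c].dtype == bool
    ]
    num_cols = [c for c in X.columns if c not in cat_cols]
    num_steps = [("impute", SimpleImputer(strategy="median", add_indicator=True))]
    if scale_numeric:
        num_steps.append(("scale", StandardScaler()))
    cat_pipe = Pipeline(
        [
            ("impute", SimpleImputer(strategy="most_frequent")),
            ("onehot", OneHotEncoder(drop="first", handle_unknown="ignore")),
        ]
    )
    return ColumnTransformer(
        [("num", Pipeline(num_steps), num_cols), ("cat", cat_pipe, cat_cols)],
        remainder="drop",
    )


@dataclass
class FittedLearner:
    """A fitted pipeline plus the schema and target range it was trained on."""

    spec: LearnerSpec
    pipeline: Pipeline
    feature_columns: list[str]
    y_min: float
    y_max: float
    best_params: dict

    def _check_schema(self, X: pd.DataFrame) -> pd.DataFrame:
        missing = [c for c in self.feature_columns if c not in X.columns]
        extra = [c for c in X.columns if c not in self.feature_columns]
        if missing or extra:
            raise SchemaMismatchError(missing=missing, extra=extra)
        return X[self.feature_columns]

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return np.asarray(self.pipeline.predict(self._check_schema(X)), dtype=float)

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        """Probability of the positive (prolonged) class."""
        if self.spec.task != "classification":
            raise ValueError("predict_proba requires a classification learner")
        proba = self.pipeline.predict_proba(self._check_schema(X))
        classes = list(self.pipeline.classes_)
        return np.asarray(proba[:, classes.index(1)], dtype=float)


def fit_learner(X: pd.DataFrame, y: np.ndarray, spec: LearnerSpec) -> FittedLearner:
    """Fit one base learner with internal k-fold CV over its search grid.

    Regression grids are scored by negative MAE (the study's selection
    metric), classification grids by ROC AUC.  A grid with a single candidate
    skips the search.  Reproducible from ``spec.seed``.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y).ravel()
    if len(y) != len(X):
        raise ValueError(f"y has length {len(y)} but X has {len(X)} rows")
    if spec.task == "classification" and np.unique(y).size < 2:
        raise DegenerateTargetError(
            "classification target contains a single class; cannot fit a classifier"
        )
    scale = spec.family in ("penalized_linear", "feedforward_net")
    pipe = Pipeline([("prep", _preprocessor(X, scale)), ("model", _base_estimator(spec))])
    grid = spec.resolved_grid()
    n_candidates = int(np.prod([len(v) for v in grid.values()])) if grid else 1
    if n_candidates <= 1:
        if grid:
            pipe.set_params(**{k: v[0] for k, v in grid.items()})
        fitted = pipe.fit(X, y)
        best_params = {k: v[0] for k, v in grid.items()}
    else:
        if spec.task == "classification":
            cv = StratifiedKFold(spec.cv_folds, shuffle=True, random_state=spec.seed)
            scoring = "roc_auc"
        else:
            cv = KFold(spec.cv_folds, shuffle=True, random_state=spec.seed)
            scoring = "neg_mean_absolute_error"
        search = GridSearchCV(pipe, grid, cv=cv, scoring=scoring, n_jobs=1, refit=True)
        search.fit(X, y)
        fitted = search.best_estimator_
        best_params = dict(search.best_params_)
    return FittedLearner(
        spec=spec,
        pipeline=fitted,
        feature_columns=list(X.columns),
        y_min=float(np.min(y)),
        y_max=float(np.max(y)),
        best_params=best_params,
    )


@dataclass
class OneStageModel:
    """A base learner trained on transformed outcomes, predicting in days.

    Log-model predictions are exponentiated back; truncated-model predictions
    are reported as-is (truncation is not invertible).
    """

    learner: FittedLearner
    transform: OutcomeTransform

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        z = self.learner.predict(X)
        if self.transform.kind == "log":
            return self.transform.invert(z)
        return z


def fit_one_stage(
    X: pd.DataFrame, y: np.ndarray, spec: LearnerSpec, t: OutcomeTransform | None = None
) -> OneStageModel:
    """Fit a one-stage regressor on transformed training outcomes."""
    t = t or OutcomeTransform.identity()
    if spec.task != "regression":
        raise ValueError("fit_one_stage requires a regression spec")
    z = t.apply(np.asarray(y, dtype=float).ravel())
    return OneStageModel(learner=fit_learner(X, z, spec), transform=t)
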