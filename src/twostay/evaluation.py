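"""Study-design harness: splitting, CV comparison, calibration, PR/ROC, bootstrap.

The harness mirrors a standard development workflow for a clinical prediction
model: a random 2/3 : 1/3 train/test split, fivefold cross-validation on the
training set to compare modelling choices (algorithm x transform x approach)
under several losses, and final test-set evaluation with percentile-bootstrap
confidence intervals.

Calibration here is the least-squares slope of *observed on predicted*
outcome: 1 means the spread of predictions matches the spread of outcomes, a
slope below 1 means large stays are systematically under-predicted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import (
    average_precision_score,
    precision_recall_curve,
    roc_auc_score,
    roc_curve,
)
from sklearn.model_selection import KFold

from .exceptions import UndefinedMetricError
from .learners import LearnerSpec, fit_one_stage
from .losses import BinSpec, PredictionPair, stratified_loss
from .transforms import OutcomeTransform

__all__ = [
    "SplitSpec",
    "ComparisonGrid",
    "EvalReport",
    "split_data",
    "crossval_compare",
    "calibration_slope",
    "sensitivity_short",
    "sensitivity_prolonged",
    "pr_and_roc",
    "bootstrap_ci",
    "BootstrapCI",
]


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 2.0 / 3.0
    cv_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.train_fraction < 1):
            raise ValueError("train_fraction must be in (0, 1)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


def split_data(table: pd.DataFrame, spec: SplitSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random disjoint, exhaustive train/test split, reproducible from seed."""
    n = len(table)
    if n < 3:
        raise ValueError(f"need at least 3 rows to split, got {n}")
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(n)
    n_train = int(round(spec.train_fraction * n))
    n_train = min(max(n_train, 1), n - 1)
    return table.iloc[np.sort(perm[:n_train])], table.iloc[np.sort(perm[n_train:])]


def calibration_slope(pair: PredictionPair) -> float:
    """OLS slope of observed on predicted outcome; 1.0 is perfect calibration."""
    if np.var(pair.y_pred) == 0:
        raise UndefinedMetricError("calibration slope undefined: predictions are constant")
    slope, _ = np.polyfit(pair.y_pred, pair.y_true, 1)
    return float(slope)


def _short_mask_predicted(pred, tau_c: float) -> np.ndarray:
    # gated output: not flagged prolonged; numeric output: prediction < tau_c
    if hasattr(pred, "is_prolonged"):
        return ~np.asarray(pred.is_prolonged, dtype=bool)
    return np.asarray(pred, dtype=float).ravel() < tau_c


def sensitivity_short(y_true: np.ndarray, pred, tau_c: float = 7.0) -> float:
    """Among truly short stays (y < tau_c), the fraction predicted short.

    ``pred`` is either a numeric prediction vector (predicted short iff
    prediction < tau_c) or a gated-prediction object (predicted short iff not
    flagged prolonged).
    """
    y = np.asarray(y_true, dtype=float).ravel()
    true_short = y < tau_c
    if not true_short.any():
        raise UndefinedMetricError("no truly short samples; short sensitivity undefined")
    return float(np.mean(_short_mask_predicted(pred, tau_c)[true_short]))


def sensitivity_prolonged(y_true: np.ndarray, pred, tau_c: float = 7.0) -> float:
    """Among truly prolonged stays (y >= tau_c), the fraction predicted prolonged."""
    y = np.asarray(y_true, dtype=float).ravel()
    prolonged = y >= tau_c
    if not prolonged.any():
        raise UndefinedMetricError("no truly prolonged samples; sensitivity undefined")
    return float(np.mean(~_short_mask_predicted(pred, tau_c)[prolonged]))


@dataclass(frozen=True)
class PRRocResult:
    average_precision: float
    auc: float
    pr_points: pd.DataFrame
    roc_points: pd.DataFrame


def pr_and_roc(scores: np.ndarray, labels: np.ndarray) -> PRRocResult:
    """Precision-recall (with step-wise average precision) and ROC for stage 1.

    AP is the step-function area sum((R_k - R_{k-1}) * P_k); AUC is the
    rank-based area with ties counted half.  Both classes must be present.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel().astype(int)
    if np.unique(labels).size < 2:
        raise UndefinedMetricError("PR/ROC undefined with a single class")
    ap = float(average_precision_score(labels, scores))
    auc = float(roc_auc_score(labels, scores))
    precision, recall, _ = precision_recall_curve(labels, scores)
    fpr, tpr, thresholds = roc_curve(labels, scores)
    return PRRocResult(
        average_precision=ap,
        auc=auc,
        pr_points=pd.DataFrame({"recall": recall, "precision": precision}),
        roc_points=pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds}),
    )


@dataclass(frozen=True)
class BootstrapCI:
    lower: float
    upper: float
    point: float
    n_redrawn: int = 0


def bootstrap_ci(
    metric_fn: Callable[[PredictionPair], float],
    pair: PredictionPair,
    B: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> BootstrapCI:
    """Two-sided percentile bootstrap over row resamples of a fixed test set.

    Models are not refit; only the evaluation rows are resampled.  A resample
    on which the metric is undefined is redrawn and counted in ``n_redrawn``.
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    if not (0 < level < 1):
        raise ValueError("level must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n = pair.n
    values = np.empty(B)
    redrawn = 0
    for b in range(B):
        for _attempt in range(100):
            idx = rng.integers(0, n, size=n)
            try:
                values[b] = metric_fn(pair.subset(np.sort(idx)))
                break
            except Exception:
                redrawn += 1
        else:
            raise UndefinedMetricError(
                "metric undefined on 100 consecutive bootstrap resamples"
            )
    alpha = (1 - level) / 2
    lower, upper = np.quantile(values, [alpha, 1 - alpha])
    return BootstrapCI(float(lower), float(upper), float(metric_fn(pair)), redrawn)


@dataclass
class ComparisonGrid:
    """The model-comparison matrix: approaches x algorithms x transforms x losses."""

    algorithms: Sequence[LearnerSpec]
    transforms: Sequence[OutcomeTransform] = field(
        default_factory=lambda: [OutcomeTransform.identity()]
    )
    losses: Sequence[str] = ("mse", "mae", "mre", "customized")
    approaches: Sequence[str] = ("one_stage",)

    def __post_init__(self) -> None:
        if not self.algorithms or not self.transforms or not self.losses or not self.approaches:
            raise ValueError("every grid axis must be non-empty")
        for a in self.approaches:
            if a not in ("one_stage", "two_stage"):
                raise ValueError(f"unknown approach {a!r}")


@dataclass
class EvalReport:
    """Long-format metric table plus any per-cell failures."""

    table: pd.DataFrame
    errors: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _cell_label(approach: str, spec: LearnerSpec, t: OutcomeTransform) -> tuple[str, str, str]:
    tname = t.kind if t.kind != "truncate" else f"truncate@{t.truncation_level:g}"
    return approach, spec.family, tname


def crossval_compare(
    train: pd.DataFrame,
    outcome_col: str,
    grid: ComparisonGrid,
    spec: SplitSpec,
    tau_c: float = 7.0,
    tau_r: float = 35.0,
    bins: BinSpec | None = None,
) -> EvalReport:
    """Pooled out-of-fold losses for every grid cell on the training table.

    Each cell's model is refit within each of ``spec.cv_folds`` folds; its
    out-of-fold day-scale predictions are pooled and every requested loss is
    computed on the pooled pair, overall and stratified by outcome bin.
    Two-stage cells gate as at prediction time, with gated samples imputed at
    ``tau_c`` for the losses.  Fold assignment is keyed to the sorted row
    labels, so results are invariant to row order.  A failing cell is recorded
    in ``errors`` and the run continues.
    """
    from .two_stage import TwoStageConfig, fit_two_stage  # avoid circular import

    bins = bins or BinSpec()
    table = train.sort_index()
    y_all = table[outcome_col].to_numpy(dtype=float)
    X_all = table.drop(columns=[outcome_col])
    cv = KFold(spec.cv_folds, shuffle=True, random_state=spec.seed)

    rows, errors = [], {}
    for approach, algo, t in product(grid.approaches, grid.algorithms, grid.transforms):
        label = _cell_label(approach, algo, t)
        try:
            oof = np.full(len(table), np.nan)
            for tr_idx, te_idx in cv.split(X_all):
                X_tr, y_tr = X_all.iloc[tr_idx], y_all[tr_idx]
                X_te = X_all.iloc[te_idx]
                if approach == "one_stage":
                    model = fit_one_stage(X_tr, y_tr, algo.with_task("regression"), t)
                    oof[te_idx] = model.predict(X_te)
                else:
                    cfg = TwoStageConfig(
                        classifier_spec=algo,
                        regressor_spec=algo,
                        tau_c=tau_c,
                        tau_r=tau_r,
                        stage2_transform=t,
                    )
                    gated = fit_two_stage(X_tr, y_tr, cfg).predict(X_te)
                    oof[te_idx] = gated.imputed(tau_c)
            pair = PredictionPair(y_all, oof)
            for loss_name in grid.losses:
                report = stratified_loss(pair, loss_name, bins, tau_c=tau_c)
                frame = report.to_frame()
                frame.insert(0, "transform", label[2])
                frame.insert(0, "algorithm", label[1])
                frame.insert(0, "approach", label[0])
                rows.append(frame)
        except Exception as exc:  # record and continue with the rest of the grid
            errors[label] = f"{type(exc).__name__}: {exc}"
    table_out = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(
            columns=["approach", "algorithm", "transform", "metric", "bin", "n", "value"]
        )
    )
    return EvalReport(table=table_out, errors=errors)
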