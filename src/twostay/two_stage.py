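"""The two-stage (hurdle-style) length-of-stay model.

Stage 1 is a binary classifier separating prolonged stays (``y >= tau_c``,
default 7 days) from short ones, trained on every training row.  Its decision
cutoff on the prolonged-class probability is tuned on out-of-fold
cross-validated scores so that short-class sensitivity meets a target
(default 0.99) — the operating point at which almost every truly short stay
still receives a numeric prediction.

Stage 2 is a regressor trained only on rows with ``y <= tau_r`` (default 35
days).  Setting the regressor threshold above the classifier threshold
exposes the regressor to stays between 7 and 35 days so it can predict beyond
7, while the extreme tail — which no pre-admission feature set can resolve —
is excluded entirely.

At prediction time each sample is gated: probability at or above the cutoff
yields a "prolonged" flag with no numeric estimate; everything else receives
the back-transformed stage-2 regression estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.model_selection import StratifiedKFold

from .exceptions import (
    DegenerateTargetError,
    InfeasibleCutoffError,
    UnfittableStageError,
)
from .learners import FittedLearner, LearnerSpec, OneStageModel, fit_learner, fit_one_stage
from .transforms import OutcomeTransform

__all__ = [
    "TwoStageConfig",
    "TwoStageModel",
    "GatedPredictions",
    "CutoffResult",
    "tune_cutoff",
    "fit_two_stage",
    "predict_two_stage",
    "sweep_regressor_threshold",
]

MODES = ("short_sensitivity", "prolonged_sensitivity")


@dataclass
class TwoStageConfig:
    """Thresholds, sensitivity target and stage specs for the two-stage model."""

    classifier_spec: LearnerSpec
    regressor_spec: LearnerSpec
    tau_c: float = 7.0
    tau_r: float = 35.0
    target_short_sensitivity: float = 0.99
    stage2_transform: OutcomeTransform = field(default_factory=OutcomeTransform.log)
    mode: str = "short_sensitivity"
    oof_folds: int = 5

    def __post_init__(self) -> None:
        if self.tau_c <= 0:
            raise ValueError("tau_c must be positive")
        if self.tau_r < self.tau_c:
            raise ValueError(
                f"tau_r ({self.tau_r}) must be >= tau_c ({self.tau_c}): the regressor "
                "threshold sits at or above the classifier threshold"
            )
        if not (0 < self.target_short_sensitivity <= 1):
            raise ValueError("target_short_sensitivity must be in (0, 1]")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")


@dataclass(frozen=True)
class CutoffResult:
    """A tuned probability cutoff with its achieved class sensitivities."""

    cutoff: float
    short_sensitivity: float
    prolonged_sensitivity: float
    target: float
    mode: str = "short_sensitivity"

    def __float__(self) -> float:
        return self.cutoff


def _class_sensitivities(
    scores: np.ndarray, prolonged: np.ndarray, cutoff: float
) -> tuple[float, float]:
    pred_prolonged = scores >= cutoff
    short_sens = float(np.mean(~pred_prolonged[~prolonged]))
    prolonged_sens = float(np.mean(pred_prolonged[prolonged]))
    return short_sens, prolonged_sens


def tune_cutoff(
    oof_scores: np.ndarray,
    labels: np.ndarray,
    target: float = 0.99,
    mode: str = "short_sensitivity",
) -> CutoffResult:
    """Choose the probability cutoff meeting a sensitivity target.

    ``labels`` is the prolonged indicator (truthy = prolonged); a sample is
    classified prolonged iff its score is at or above the cutoff.  In the
    default mode the cutoff maximizes prolonged-class sensitivity subject to
    short-class sensitivity >= ``target`` (equivalently: the smallest
    admissible cutoff; ties break toward the smaller cutoff).  The alternative
    ``"prolonged_sensitivity"`` mode constrains prolonged-class sensitivity
    instead and maximizes short-class sensitivity (the largest admissible
    cutoff).

    Scores must come from out-of-fold predictions; tuning on in-fold scores
    leaks and overstates the achievable operating point.
    """
    scores = np.asarray(oof_scores, dtype=float).ravel()
    prolonged = np.asarray(labels).ravel().astype(bool)
    if scores.size != prolonged.size or scores.size == 0:
        raise ValueError("scores and labels must be equal-length and non-empty")
    if prolonged.all() or (~prolonged).all():
        raise DegenerateTargetError("both classes must be present to tune a cutoff")
    if not (0 <= target <= 1):
        raise ValueError("target must be in [0, 1]")
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")

    candidates = np.unique(scores)
    above_max = np.nextafter(candidates[-1], np.inf)
    if above_max <= 1.0:  # "classify nothing prolonged" stays a valid probability
        candidates = np.append(candidates, above_max)

    best: CutoffResult | None = None
    best_attainable = -np.inf
    for c in candidates:
        short_sens, prolonged_sens = _class_sensitivities(scores, prolonged, float(c))
        constrained = short_sens if mode == "short_sensitivity" else prolonged_sens
        best_attainable = max(best_attainable, constrained)
        if constrained < target:
            continue
        objective = prolonged_sens if mode == "short_sensitivity" else short_sens
        if best is None or objective > (
            best.prolonged_sensitivity if mode == "short_sensitivity" else best.short_sensitivity
        ):
            best = CutoffResult(float(c), short_sens, prolonged_sens, target, mode)
    if best is None:
        raise InfeasibleCutoffError(target, best_attainable)
    return best


def _derived_fold_seed(seed: int) -> int:
    # distinct stream from the hyperparameter-CV seed, still reproducible from it
    return int(np.random.SeedSequence([int(seed), 0x5EED]).generate_state(1)[0] % 2**31)


def _oof_scores(
    fitted: FittedLearner, X: pd.DataFrame, labels: np.ndarray, folds: int
) -> np.ndarray:
    """Out-of-fold prolonged-class probabilities with frozen hyperparameters."""
    cv = StratifiedKFold(folds, shuffle=True, random_state=_derived_fold_seed(fitted.spec.seed))
    scores = np.empty(len(X), dtype=float)
    for train_idx, test_idx in cv.split(X, labels):
        pipe = clone(fitted.pipeline)
        pipe.fit(X.iloc[train_idx], labels[train_idx])
        proba = pipe.predict_proba(X.iloc[test_idx])
        scores[test_idx] = proba[:, list(pipe.classes_).index(1)]
    return scores


@dataclass
class GatedPredictions:
    """Per-sample gated output: a prolonged flag xor a numeric day estimate."""

    is_prolonged: np.ndarray
    los_estimate: np.ndarray
    scores: np.ndarray | None = None

    def __post_init__(self) -> None:
        flag = np.asarray(self.is_prolonged).ravel().astype(bool)
        est = np.asarray(self.los_estimate, dtype=float).ravel()
        if flag.size != est.size:
            raise ValueError("flag and estimate vectors must align")
        if not np.array_equal(np.isnan(est), flag):
            raise ValueError(
                "each sample must carry exactly one of {numeric estimate, prolonged flag}"
            )
        if np.any(est[~flag] < 0):
            raise ValueError("numeric estimates must be non-negative days")
        self.is_prolonged = flag
        self.los_estimate = est

    @property
    def n(self) -> int:
        return int(self.is_prolonged.size)

    @property
    def n_prolonged(self) -> int:
        return int(self.is_prolonged.sum())

    def imputed(self, tau_c: float) -> np.ndarray:
        """Numeric vector for loss evaluation: gated samples enter at ``tau_c``.

        Under the customized loss this scores a correct gate as 0 and a wrong
        gate as the distance from the threshold to the true short stay.
        """
        return np.where(self.is_prolonged, float(tau_c), self.los_estimate)

    def to_frame(self, row_id: Sequence | None = None) -> pd.DataFrame:
        rid = np.arange(self.n) if row_id is None else np.asarray(row_id)
        return pd.DataFrame(
            {"row_id": rid, "is_prolonged": self.is_prolonged, "los_estimate": self.los_estimate}
        )

    def to_csv(self, path, row_id: Sequence | None = None) -> None:
        # prolonged rows carry an empty estimate field, never a sentinel number
        self.to_frame(row_id).to_csv(path, index=False)


@dataclass
class TwoStageModel:
    classifier: FittedLearner
    cutoff: CutoffResult
    regressor: OneStageModel
    config: TwoStageConfig
    oof_short_sensitivity: float = float("nan")
    n_stage2_train: int = 0

    def stage1_scores(self, X: pd.DataFrame) -> np.ndarray:
        return self.classifier.predict_proba(X)

    def predict(self, X: pd.DataFrame) -> GatedPredictions:
        scores = self.stage1_scores(X)
        prolonged = scores >= self.cutoff.cutoff
        est = np.full(len(X), np.nan)
        if (~prolonged).any():
            raw = self.regressor.predict(X.loc[~prolonged])
            est[~prolonged] = np.clip(raw, 0.0, None)
        return GatedPredictions(prolonged, est, scores=scores)


def fit_two_stage(X: pd.DataFrame, y: np.ndarray, cfg: TwoStageConfig) -> TwoStageModel:
    """Fit classifier (all rows), tune its cutoff out-of-fold, fit the gated regressor.

    Stage 1 labels every row as prolonged iff ``y >= tau_c`` and trains on all
    of them.  Stage 2 trains only on rows with ``y <= tau_r`` (the extreme
    tail is excluded entirely), with the target transformed per
    ``cfg.stage2_transform``.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float).ravel()
    if len(y) != len(X):
        raise ValueError("X and y must align")
    if np.any(y < 0):
        raise ValueError("outcomes must be non-negative days")
    labels = (y >= cfg.tau_c).astype(int)
    if np.unique(labels).size < 2:
        raise DegenerateTargetError(
            f"training outcomes fall entirely on one side of tau_c={cfg.tau_c}; "
            "the stage-1 classifier is degenerate"
        )

    clf_spec = cfg.classifier_spec.with_task("classification")
    classifier = fit_learner(X, labels, clf_spec)
    oof = _oof_scores(classifier, X, labels, cfg.oof_folds)
    cutoff = tune_cutoff(oof, labels, cfg.target_short_sensitivity, mode=cfg.mode)

    stage2_mask = y <= cfg.tau_r
    if not stage2_mask.any():
        raise UnfittableStageError(
            f"no training rows with y <= tau_r={cfg.tau_r}; stage 2 cannot be fit"
        )
    reg_spec = cfg.regressor_spec.with_task("regression")
    regressor = fit_one_stage(
        X.loc[stage2_mask], y[stage2_mask], reg_spec, cfg.stage2_transform
    )
    return TwoStageModel(
        classifier=classifier,
        cutoff=cutoff,
        regressor=regressor,
        config=cfg,
        oof_short_sensitivity=cutoff.short_sensitivity,
        n_stage2_train=int(stage2_mask.sum()),
    )


def predict_two_stage(model: TwoStageModel, X_new: pd.DataFrame) -> GatedPredictions:
    return model.predict(X_new)


def sweep_regressor_threshold(
    X_train: pd.DataFrame,
    y_train: np.ndarray,
    X_test: pd.DataFrame,
    y_test: np.ndarray,
    cfg: TwoStageConfig,
    taus: Sequence[float],
) -> pd.DataFrame:
    """Refit stage 2 at each regressor threshold and score on the held-out set.

    Stage 1 (classifier and tuned cutoff) is shared across thresholds — only
    the regressor's training subpopulation changes — so each row of the result
    is exactly what ``fit_two_stage`` at that ``tau_r`` would produce.
    Reported per threshold: customized loss, MAE (both with gated samples
    imputed at ``tau_c``), calibration slope over numeric predictions,
    short-class sensitivity, and the largest numeric prediction.
    """
    from .evaluation import calibration_slope, sensitivity_short
    from .losses import PredictionPair, customized_loss, mae

    taus = [float(t) for t in taus]
    for t in taus:
        if t < cfg.tau_c:
            raise ValueError(f"every sweep threshold must be >= tau_c; got {t} < {cfg.tau_c}")
    y_test = np.asarray(y_test, dtype=float).ravel()

    base = fit_two_stage(X_train, y_train, replace(cfg, tau_r=max(taus)))
    rows = []
    for t in taus:
        if t == base.config.tau_r:
            model = base
        else:
            mask = np.asarray(y_train, dtype=float).ravel() <= t
            if not mask.any():
                raise UnfittableStageError(f"no training rows with y <= {t}")
            regressor = fit_one_stage(
                pd.DataFrame(X_train).loc[mask],
                np.asarray(y_train, dtype=float).ravel()[mask],
                cfg.regressor_spec.with_task("regression"),
                cfg.stage2_transform,
            )
            model = TwoStageModel(
                classifier=base.classifier,
                cutoff=base.cutoff,
                regressor=regressor,
                config=replace(cfg, tau_r=t),
                oof_short_sensitivity=base.oof_short_sensitivity,
                n_stage2_train=int(mask.sum()),
            )
        gated = model.predict(X_test)
        pair = PredictionPair(y_test, gated.imputed(cfg.tau_c))
        numeric = ~gated.is_prolonged
        slope = np.nan
        if numeric.sum() >= 2 and np.var(gated.los_estimate[numeric]) > 0:
            slope = calibration_slope(
                PredictionPair(y_test[numeric], gated.los_estimate[numeric])
            )
        rows.append(
            {
                "tau_r": t,
                "customized": customized_loss(pair, cfg.tau_c),
                "mae": mae(pair),
                "calibration_slope": slope,
                "short_sensitivity": sensitivity_short(y_test, gated, cfg.tau_c),
                "max_numeric_prediction": float(np.nanmax(gated.los_estimate))
                if numeric.any()
                else np.nan,
                "n_stage2_train": model.n_stage2_train,
            }
        )
    return pd.DataFrame(rows)
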