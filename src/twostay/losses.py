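"""Scalar and stratified evaluation losses for length-of-stay predictions.

The three classical losses (MSE, MAE, MRE) are evaluated on the day scale,
never on a transformed scale.  The *customized* loss is a truncated,
hinge-style variant of the MAE built around the classifier threshold
``tau_c`` (default 7 days): stays that are truly prolonged and predicted
prolonged incur no loss; truly prolonged stays predicted short are charged
only the distance from the prediction to the threshold; everything else is
charged the plain absolute error.  This is the loss under which a gated
two-stage model is comparable with a one-stage regressor.

All losses are plain means of per-sample terms, so the overall loss always
equals the count-weighted mean of per-bin losses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .exceptions import InvalidPairError, LossDomainError

__all__ = [
    "PredictionPair",
    "BinSpec",
    "LossReport",
    "mse",
    "mae",
    "mre",
    "customized_loss",
    "stratified_loss",
    "LOSS_NAMES",
]

DEFAULT_TAU_C = 7.0


@dataclass(frozen=True)
class PredictionPair:
    """Aligned vectors of true and predicted outcomes, in days.

    Invariants enforced at construction: equal lengths, at least one sample,
    all true outcomes non-negative and finite.
    """

    y_true: np.ndarray
    y_pred: np.ndarray

    def __post_init__(self) -> None:
        yt = np.asarray(self.y_true, dtype=float).ravel()
        yp = np.asarray(self.y_pred, dtype=float).ravel()
        if yt.size == 0 or yp.size == 0:
            raise InvalidPairError("prediction pair must contain at least one sample")
        if yt.size != yp.size:
            raise InvalidPairError(
                f"y_true has length {yt.size} but y_pred has length {yp.size}"
            )
        if not np.all(np.isfinite(yt)) or not np.all(np.isfinite(yp)):
            raise InvalidPairError("prediction pair contains non-finite values")
        if np.any(yt < 0):
            raise InvalidPairError("true outcomes must be non-negative (days)")
        object.__setattr__(self, "y_true", yt)
        object.__setattr__(self, "y_pred", yp)

    @property
    def n(self) -> int:
        return int(self.y_true.size)

    def subset(self, mask: np.ndarray) -> "PredictionPair":
        return PredictionPair(self.y_true[mask], self.y_pred[mask])


@dataclass(frozen=True)
class BinSpec:
    """Ordered outcome-bin boundaries in days, covering [0, +inf).

    Bins are half-open ``[a, b)``; the final bin is ``[a, +inf)`` and labelled
    ``">=a"`` so every outcome falls in exactly one bin.
    """

    edges: tuple = (0.0, 2.0, 4.0, 7.0, np.inf)

    def __post_init__(self) -> None:
        edges = tuple(float(e) for e in self.edges)
        if len(edges) < 2:
            raise ValueError("BinSpec needs at least two edges")
        if any(b <= a for a, b in zip(edges, edges[1:])):
            raise ValueError("bin edges must be strictly increasing")
        if edges[0] != 0.0 or not np.isinf(edges[-1]):
            raise ValueError("bins must cover [0, +inf): first edge 0, last edge inf")
        object.__setattr__(self, "edges", edges)

    @property
    def labels(self) -> list[str]:
        out = []
        for a, b in zip(self.edges, self.edges[1:]):
            out.append(f">={a:g}" if np.isinf(b) else f"[{a:g},{b:g})")
        return out

    def assign(self, y: np.ndarray) -> np.ndarray:
        """Bin index of each outcome (right-open binning)."""
        idx = np.searchsorted(np.asarray(self.edges[1:-1]), y, side="right")
        return idx


@dataclass
class LossReport:
    """Overall plus per-bin values of one loss; empty bins carry ``None``."""

    metric: str
    overall: float
    per_bin: Mapping[str, float | None]
    n_per_bin: Mapping[str, int]
    n: int = field(default=0)

    def __post_init__(self) -> None:
        if self.n == 0:
            self.n = int(sum(self.n_per_bin.values()))

    def to_frame(self) -> pd.DataFrame:
        rows = [{"metric": self.metric, "bin": "overall", "n": self.n, "value": self.overall}]
        for label in self.per_bin:
            rows.append(
                {
                    "metric": self.metric,
                    "bin": label,
                    "n": self.n_per_bin[label],
                    "value": self.per_bin[label],
                }
            )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "overall": self.overall,
            "n": self.n,
            "per_bin": dict(self.per_bin),
            "n_per_bin": dict(self.n_per_bin),
        }


def mse(pair: PredictionPair) -> float:
    """Mean squared error, days squared."""
    d = pair.y_pred - pair.y_true
    return float(np.mean(d * d))


def mae(pair: PredictionPair) -> float:
    """Mean absolute error: the average deviation from the true stay, in days."""
    return float(np.mean(np.abs(pair.y_pred - pair.y_true)))


def mre(pair: PredictionPair) -> float:
    """Mean relative error, |error| / truth; weights short stays most heavily.

    Undefined when any true outcome is zero; the error names the first
    offending index.
    """
    zero = np.flatnonzero(pair.y_true == 0)
    if zero.size:
        raise LossDomainError(
            f"MRE undefined: y_true is 0 at index {int(zero[0])} "
            f"({zero.size} zero outcome(s) in total)"
        )
    return float(np.mean(np.abs(pair.y_pred - pair.y_true) / pair.y_true))


def _customized_terms(y: np.ndarray, yhat: np.ndarray, tau_c: float) -> np.ndarray:
    both_long = (y >= tau_c) & (yhat >= tau_c)
    long_missed = (y >= tau_c) & (yhat < tau_c)
    return np.where(
        both_long, 0.0, np.where(long_missed, np.abs(yhat - tau_c), np.abs(yhat - y))
    )


def customized_loss(pair: PredictionPair, tau_c: float = DEFAULT_TAU_C) -> float:
    """Truncated hinge-style MAE around the classifier threshold, in days.

    Per sample: 0 if both truth and prediction are at or beyond ``tau_c``;
    ``|yhat - tau_c|`` if the truth is prolonged but the prediction short;
    ``|yhat - y|`` otherwise.  Samples a two-stage model gates to "prolonged"
    enter with the imputed prediction ``yhat = tau_c`` (see
    ``GatedPredictions.imputed``), under which a correct gate costs 0 and a
    wrong gate costs ``tau_c - y``.
    """
    if tau_c <= 0:
        raise ValueError("tau_c must be positive")
    return float(np.mean(_customized_terms(pair.y_true, pair.y_pred, tau_c)))


LOSS_NAMES = ("mse", "mae", "mre", "customized")


def _resolve_loss(
    loss_name: str, tau_c: float
) -> Callable[[PredictionPair], float]:
    name = loss_name.strip().lower()
    if name == "mse":
        return mse
    if name == "mae":
        return mae
    if name == "mre":
        return mre
    if name == "customized":
        return lambda p: customized_loss(p, tau_c)
    raise ValueError(f"unknown loss {loss_name!r}; expected one of {LOSS_NAMES}")


def stratified_loss(
    pair: PredictionPair,
    loss_name: str,
    bins: BinSpec | None = None,
    tau_c: float = DEFAULT_TAU_C,
) -> LossReport:
    """One loss overall and restricted to each true-outcome bin.

    Binning is by ``y_true``.  A bin with no samples reports ``None`` rather
    than 0 — an absent loss is not a zero loss.
    """
    bins = bins or BinSpec()
    fn = _resolve_loss(loss_name, tau_c)
    overall = fn(pair)
    idx = bins.assign(pair.y_true)
    per_bin: dict[str, float | None] = {}
    n_per_bin: dict[str, int] = {}
    for k, label in enumerate(bins.labels):
        mask = idx == k
        n_per_bin[label] = int(mask.sum())
        per_bin[label] = fn(pair.subset(mask)) if mask.any() else None
    return LossReport(
        metric=loss_name.strip().lower(),
        overall=overall,
        per_bin=per_bin,
        n_per_bin=n_per_bin,
        n=pair.n,
    )
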