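"""Outcome transformations applied to *training* outcomes only.

Two manipulations tame a right-skewed stay distribution before fitting:

* ``log`` — natural log (optionally after adding a positive offset for data
  containing zeros); predictions are exponentiated back to days.
* ``truncate`` — outcomes above a level (default 7 days) are reduced to that
  level; this removes the tail's leverage but is not invertible, so truncated
  models report predictions as-is on the day scale.

Test-set outcomes are never transformed: every loss compares predictions with
untouched observed days.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import UnsupportedTransformError

__all__ = ["OutcomeTransform", "apply_transform", "invert_transform"]

KINDS = ("identity", "log", "truncate")


@dataclass(frozen=True)
class OutcomeTransform:
    kind: str = "identity"
    truncation_level: float = 7.0
    log_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")
        if self.kind == "truncate" and self.truncation_level <= 0:
            raise ValueError("truncation_level must be positive")
        if self.kind == "log" and self.log_offset < 0:
            raise ValueError("log_offset must be non-negative")

    @classmethod
    def identity(cls) -> "OutcomeTransform":
        return cls("identity")

    @classmethod
    def log(cls, offset: float = 0.0) -> "OutcomeTransform":
        return cls("log", log_offset=offset)

    @classmethod
    def truncate(cls, level: float = 7.0) -> "OutcomeTransform":
        return cls("truncate", truncation_level=level)

    @property
    def invertible(self) -> bool:
        return self.kind in ("identity", "log")

    def apply(self, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        if self.kind == "identity":
            return y.copy()
        if self.kind == "truncate":
            return np.minimum(y, self.truncation_level)
        shifted = y + self.log_offset
        if np.any(shifted <= 0):
            bad = int(np.flatnonzero(shifted <= 0)[0])
            raise ValueError(
                f"log transform undefined: y + offset <= 0 at index {bad} "
                f"(value {y.ravel()[bad] if y.ndim else y})"
            )
        return np.log(shifted)

    def invert(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        if self.kind == "identity":
            return z.copy()
        if self.kind == "log":
            return np.exp(z) - self.log_offset
        raise UnsupportedTransformError(
            "truncation is not invertible; truncated-model predictions are "
            "reported on the day scale as-is"
        )


def apply_transform(y: np.ndarray, t: OutcomeTransform) -> np.ndarray:
    return t.apply(y)


def invert_transform(z: np.ndarray, t: OutcomeTransform) -> np.ndarray:
    return t.invert(z)
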