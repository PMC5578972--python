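"""The universal input container: paired predictor values and binary labels.

A :class:`BinaryOutcomeSample` holds one continuous predictor per record and
a 0/1 outcome label (1 = event, e.g. hospital death).  Everything downstream
— ROC construction, AUROC, transforms, inference — consumes this type.

Orientation is always explicit.  The same data support two readings: higher
values predict the event, or lower values do (clinically both occur — e.g.
acidosis means *low* pH predicts death).  :class:`Direction` carries that
choice; it is never auto-detected.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateSampleError, InputError

__all__ = ["BinaryOutcomeSample", "Direction"]


class Direction(enum.Enum):
    """Which end of the predictor scale is taken to predict the event."""

    HIGHER_PREDICTS_EVENT = "higher_predicts_event"
    LOWER_PREDICTS_EVENT = "lower_predicts_event"

    def orient(self, values: np.ndarray) -> np.ndarray:
        """Return values on the "higher score = more event-like" scale."""
        v = np.asarray(values, dtype=float)
        return v if self is Direction.HIGHER_PREDICTS_EVENT else -v

    @classmethod
    def from_string(cls, s: str) -> "Direction":
        try:
            return cls(s.strip().lower())
        except ValueError:
            valid = ", ".join(d.value for d in cls)
            raise InputError(f"unknown direction {s!r}; expected one of: {valid}")


@dataclass(frozen=True)
class BinaryOutcomeSample:
    """Paired predictor values and 0/1 outcome labels.

    Invariants enforced at construction: equal non-zero lengths, labels in
    {0, 1}, all values finite.  Class balance is *not* required here — a
    single-class sample is loadable, but ROC operations reject it via
    :meth:`require_both_classes`.
    """

    values: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        labels = np.asarray(self.labels)
        if values.ndim != 1 or labels.ndim != 1:
            raise InputError("values and labels must be one-dimensional")
        if len(values) != len(labels):
            raise InputError(
                f"length mismatch: {len(values)} values vs {len(labels)} labels"
            )
        if len(values) == 0:
            raise InputError("empty sample")
        if not np.all(np.isfinite(values)):
            bad = int(np.flatnonzero(~np.isfinite(values))[0])
            raise InputError(f"non-finite predictor value at index {bad}")
        if not np.isin(labels, (0, 1)).all():
            bad = int(np.flatnonzero(~np.isin(labels, (0, 1)))[0])
            raise InputError(f"label not in {{0,1}} at index {bad}")
        labels = labels.astype(np.int8)
        values.setflags(write=False)
        labels.setflags(write=False)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "labels", labels)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def n_pos(self) -> int:
        """Number of event records (m in the Mann-Whitney formula)."""
        return int(self.labels.sum())

    @property
    def n_neg(self) -> int:
        """Number of non-event records (n in the Mann-Whitney formula)."""
        return len(self) - self.n_pos

    def require_both_classes(self) -> None:
        if self.n_pos == 0 or self.n_neg == 0:
            raise DegenerateSampleError(
                "degenerate sample: both outcome classes must be present "
                f"(n_pos={self.n_pos}, n_neg={self.n_neg})"
            )

    def with_values(self, values: np.ndarray) -> "BinaryOutcomeSample":
        """Same records, new predictor column (e.g. after a transform)."""
        return BinaryOutcomeSample(np.asarray(values, dtype=float), self.labels)
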