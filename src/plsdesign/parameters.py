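"""Parameter vectors in log10 space.

All estimation, profiling and reporting in this package happens on the
log10 scale: kinetic rate constants of biochemical networks span many
orders of magnitude, and log-space boxes turn multiplicative uncertainty
into additive intervals. Conversion to the linear scale happens only at
the point where the ODE right-hand side is evaluated.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping

import numpy as np

__all__ = ["Log10ParameterVector"]


class Log10ParameterVector:
    """Ordered map ``parameter label -> log10 value``.

    Immutable by convention: every transforming method returns a copy.
    """

    __slots__ = ("labels", "values")

    def __init__(self, labels: Iterable[str], values: Iterable[float]):
        self.labels: tuple[str, ...] = tuple(labels)
        self.values: np.ndarray = np.asarray(list(values), dtype=float)
        if len(self.labels) != self.values.size:
            raise ValueError("labels and values differ in length")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate parameter labels")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite log10 parameter values")

    # -- constructors ---------------------------------------------------
    @classmethod
    def from_mapping(cls, mapping: Mapping[str, float]) -> "Log10ParameterVector":
        return cls(mapping.keys(), mapping.values())

    @classmethod
    def from_linear(cls, mapping: Mapping[str, float]) -> "Log10ParameterVector":
        vals = np.asarray(list(mapping.values()), dtype=float)
        if np.any(vals <= 0):
            raise ValueError("linear-scale parameters must be positive")
        return cls(mapping.keys(), np.log10(vals))

    # -- accessors ------------------------------------------------------
    def to_linear(self) -> dict[str, float]:
        return dict(zip(self.labels, 10.0 ** self.values))

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.labels, self.values))

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown parameter {label!r}") from None

    def __getitem__(self, label: str) -> float:
        return float(self.values[self.index(label)])

    def __len__(self) -> int:
        return len(self.labels)

    def __iter__(self):
        return iter(self.labels)

    # -- transforms -----------------------------------------------------
    def with_value(self, label: str, log10_value: float) -> "Log10ParameterVector":
        vals = self.values.copy()
        vals[self.index(label)] = log10_value
        return Log10ParameterVector(self.labels, vals)

    def with_array(self, values: np.ndarray) -> "Log10ParameterVector":
        return Log10ParameterVector(self.labels, np.asarray(values, dtype=float))

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Log10ParameterVector)
            and self.labels == other.labels
            and np.array_equal(self.values, other.values)
        )

    def __repr__(self) -> str:
        body = ", ".join(f"{k}={v:.4g}" for k, v in zip(self.labels, self.values))
        return f"Log10ParameterVector({body})"
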