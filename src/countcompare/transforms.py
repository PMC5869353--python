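"""Variance-stabilising transformations applied to counts before OLS.

Two families are supported: ``sqrt(y + c)`` (textbook presets c = 0, 0.5,
3/8 for zero-heavy counts) and ``log_b(y + c)`` (default ``ln(y + 1)``,
the standard workaround for log of zero).  The offset travels with the
spec so the matching inverse always uses the same constant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

__all__ = ["TransformSpec", "SQRT", "LOG1P", "apply_transform", "invert_transform"]


@dataclass(frozen=True)
class TransformSpec:
    """A named response transformation with its offset.

    ``sqrt`` maps y to sqrt(y + offset) (default offset 0);
    ``log`` maps y to log_base(y + offset) (default offset 1, base e).
    """

    name: Literal["sqrt", "log"]
    offset: float | None = None
    log_base: Literal["e", "10"] = "e"

    def __post_init__(self) -> None:
        if self.name not in ("sqrt", "log"):
            raise ValueError(f"unknown transform {self.name!r}")
        if self.offset is None:
            object.__setattr__(self, "offset", 1.0 if self.name == "log" else 0.0)
        if self.offset < 0:
            raise ValueError("offset must be non-negative")
        if self.log_base not in ("e", "10"):
            raise ValueError("log_base must be 'e' or '10'")

    @property
    def base(self) -> float:
        return np.e if self.log_base == "e" else 10.0

    @property
    def label(self) -> str:
        if self.name == "sqrt":
            return f"sqrt(y+{self.offset:g})" if self.offset else "sqrt(y)"
        base = "" if self.log_base == "e" else "10"
        return f"log{base}(y+{self.offset:g})" if self.offset else f"log{base}(y)"


SQRT = TransformSpec("sqrt")
LOG1P = TransformSpec("log")


def apply_transform(y: Sequence[float], spec: TransformSpec) -> np.ndarray:
    """Elementwise transform of a non-negative count sequence."""
    y = np.asarray(y, dtype=float)
    if np.any(y < 0):
        raise ValueError("counts must be non-negative")
    shifted = y + spec.offset
    if spec.name == "sqrt":
        return np.sqrt(shifted)
    if np.any(shifted <= 0):
        bad = int(np.flatnonzero(shifted <= 0)[0])
        raise ValueError(
            f"log transform undefined at index {bad}: y={y[bad]:g} with offset {spec.offset:g}"
        )
    return np.log(shifted) / np.log(spec.base)


def invert_transform(z: Sequence[float], spec: TransformSpec) -> np.ndarray:
    """Exact inverse on the transformed scale: square minus c, or b**z minus c."""
    z = np.asarray(z, dtype=float)
    if spec.name == "sqrt":
        return z**2 - spec.offset
    return spec.base**z - spec.offset
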