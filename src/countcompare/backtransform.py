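"""Return route coefficients to the original count scale.

Each route has its own convention:

* square-root LM — the transformed group mean (or intercept/slope) is
  squared, with the original sign reapplied afterwards so a negative
  trend stays negative.  The forward offset c is *not* subtracted after
  squaring; it is recorded in the provenance label instead (this matters
  whenever c > 0 and is deliberate: the convention squares, full stop).
* log LM — each count-scale quantity is ``base**m - 1`` (default base e),
  i.e. a geometric-mean-style estimate shifted by the forward offset's
  companion constant 1.
* GLM — the log link makes coefficients multiplicative, so a one-way
  group mean is ``exp(b0 + b_level)`` (exponentiated intercept times
  exponentiated factor coefficient); a regression slope is reported as
  the per-unit proportional change minus one, ``exp(b1) - 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .fitting import FitResult
from .transforms import TransformSpec

__all__ = [
    "OriginalScaleEstimates",
    "backtransform_sqrt",
    "backtransform_log",
    "backtransform_glm",
    "backtransform",
]


@dataclass
class OriginalScaleEstimates:
    """Route-specific coefficients on the count scale.

    One-way fits carry a mean per group level; regression fits carry an
    intercept and slope.  ``provenance`` names the formula applied so
    alternative back-transformation conventions can be compared.
    """

    route: Literal["sqrt_lm", "log_lm", "glm"]
    kind: Literal["oneway", "regression"]
    group_means: dict[str, float] | None = None
    intercept: float | None = None
    slope: float | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.kind == "oneway":
            if not self.group_means:
                raise ValueError("oneway estimates need group means")
            if self.route == "glm" and any(m <= 0 for m in self.group_means.values()):
                raise ValueError("GLM group means must be positive")
        else:
            if self.intercept is None or self.slope is None:
                raise ValueError("regression estimates need intercept and slope")

    def coefficients(self) -> dict[str, float]:
        """Flat name -> value map, one entry per reported coefficient."""
        if self.kind == "oneway":
            return {f"mean[{lev}]": m for lev, m in self.group_means.items()}
        return {"intercept": self.intercept, "slope": self.slope}


def _check(fit: FitResult, route: str, kind: str | None) -> None:
    if fit.route != route:
        raise ValueError(f"expected a {route} fit, got {fit.route}")
    if kind is not None and fit.kind != kind:
        raise ValueError(f"fit is for a {fit.kind} dataset, not {kind}")


def _transformed_group_means(fit: FitResult) -> dict[str, float]:
    """Reference level: intercept; others: intercept + factor coefficient."""
    b0 = fit.coefficients[0]
    means = {fit.levels[0]: b0}
    for level, b in zip(fit.levels[1:], fit.coefficients[1:]):
        means[level] = b0 + b
    return means


def _signed_square(v: float) -> float:
    return float(np.sign(v) * v**2)


def backtransform_sqrt(fit: FitResult, kind: str | None = None) -> OriginalScaleEstimates:
    """Square the transformed-scale quantities, retaining the original sign."""
    _check(fit, "sqrt_lm", kind)
    offset = fit.transform.offset if fit.transform is not None else 0.0
    provenance = f"signed square of sqrt(y+{offset:g})-scale estimate (offset not subtracted)"
    if fit.kind == "oneway":
        means = {lev: _signed_square(m) for lev, m in _transformed_group_means(fit).items()}
        return OriginalScaleEstimates("sqrt_lm", "oneway", group_means=means, provenance=provenance)
    return OriginalScaleEstimates(
        "sqrt_lm",
        "regression",
        intercept=_signed_square(fit.coefficients[0]),
        slope=_signed_square(fit.coefficients[1]),
        provenance=provenance,
    )


def backtransform_log(
    fit: FitResult, kind: str | None = None, spec: TransformSpec | None = None
) -> OriginalScaleEstimates:
    """Map each quantity m to base**m - 1 (default base e)."""
    _check(fit, "log_lm", kind)
    if spec is None:
        spec = fit.transform or TransformSpec("log")
    base = spec.base
    provenance = f"base^m - 1 with base {spec.log_base} (forward transform {spec.label})"
    expm1 = lambda m: float(base**m - 1.0)
    if fit.kind == "oneway":
        means = {lev: expm1(m) for lev, m in _transformed_group_means(fit).items()}
        return OriginalScaleEstimates("log_lm", "oneway", group_means=means, provenance=provenance)
    return OriginalScaleEstimates(
        "log_lm",
        "regression",
        intercept=expm1(fit.coefficients[0]),
        slope=expm1(fit.coefficients[1]),
        provenance=provenance,
    )


def backtransform_glm(fit: FitResult, kind: str | None = None) -> OriginalScaleEstimates:
    """Exponentiate log-link coefficients into count-scale means or changes."""
    _check(fit, "glm", kind)
    if fit.kind == "oneway":
        means = {lev: float(np.exp(m)) for lev, m in _transformed_group_means(fit).items()}
        return OriginalScaleEstimates(
            "glm",
            "oneway",
            group_means=means,
            provenance="exp(b0) * exp(b_level) multiplicative group means",
        )
    return OriginalScaleEstimates(
        "glm",
        "regression",
        intercept=float(np.exp(fit.coefficients[0])),
        slope=float(np.exp(fit.coefficients[1]) - 1.0),
        provenance="exp(b0) intercept; exp(b1) - 1 proportional change per unit",
    )


def backtransform(fit: FitResult) -> OriginalScaleEstimates:
    """Dispatch on the fit's route."""
    if fit.route == "sqrt_lm":
        return backtransform_sqrt(fit)
    if fit.route == "log_lm":
        return backtransform_log(fit)
    return backtransform_glm(fit)
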