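"""Per-dataset comparison of the three routes.

Three comparison surfaces for each dataset: residual-versus-fit
diagnostics with a local-regression smooth and a heteroscedasticity
("fan") index, decision agreement at a fixed type-I-error tolerance
alpha, and the percentage difference of each back-transformed LM
coefficient relative to its GLM counterpart.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .backtransform import (
    OriginalScaleEstimates,
    backtransform_glm,
    backtransform_log,
    backtransform_sqrt,
)
from .datasets import CountDataset
from .fitting import FitResult, choose_family, fit_glm_irls, fit_ols
from .transforms import TransformSpec

__all__ = [
    "DiagnosticSummary",
    "RouteResult",
    "ComparisonReport",
    "CaseSuiteSummary",
    "pct_difference",
    "residual_diagnostics",
    "compare_dataset",
    "run_case_suite",
]

ROUTES = ("sqrt_lm", "log_lm", "glm")


@dataclass
class DiagnosticSummary:
    """Residual-versus-fit summary for one route.

    ``fan_index`` is the Spearman rank correlation between |residual|
    and fitted value: near zero for a uniform band, positive when the
    spread fans out with the fitted value.  ``smooth_curve`` is a local
    weighted regression (tricube weights) through the residual cloud.
    """

    route: str
    residual_type: Literal["raw", "deviance"]
    fitted: np.ndarray
    residuals: np.ndarray
    smooth_curve: np.ndarray  # (m, 2): sorted fitted value, smoothed residual
    fan_index: float

    def __post_init__(self) -> None:
        if not (math.isnan(self.fan_index) or -1.0 <= self.fan_index <= 1.0):
            raise ValueError("fan_index must lie in [-1, 1]")


@dataclass
class RouteResult:
    route: str
    fit: FitResult
    estimates: OriginalScaleEstimates
    diagnostics: DiagnosticSummary
    decision: bool  # True = reject at alpha


@dataclass
class ComparisonReport:
    dataset_id: str
    alpha: float
    routes: dict[str, RouteResult]
    pct_diff: dict[tuple[str, str], float | None]  # (route, coefficient) -> %
    decisions_agree: bool

    def decision_table(self):
        import pandas as pd

        rows = []
        for name, rr in self.routes.items():
            for coef, value in rr.estimates.coefficients().items():
                rows.append(
                    {
                        "dataset": self.dataset_id,
                        "route": name,
                        "family": rr.fit.family,
                        "coefficient": coef,
                        "estimate": value,
                        "p_value": rr.fit.p_value,
                        "significant": rr.decision,
                        "pct_diff_vs_glm": self.pct_diff.get((name, coef)),
                        "fan_index": rr.diagnostics.fan_index,
                    }
                )
        return pd.DataFrame(rows)


def pct_difference(lm_estimate: float, glm_estimate: float) -> float:
    """Percentage difference of an LM estimate relative to the GLM's."""
    if glm_estimate == 0:
        raise ZeroDivisionError("percent difference undefined for a zero GLM estimate")
    return 100.0 * (lm_estimate - glm_estimate) / glm_estimate


def residual_diagnostics(fit: FitResult, span: float = 0.75) -> DiagnosticSummary:
    """Residual-versus-fit summary with lowess smooth and fan index.

    LM routes use raw residuals against transformed-scale fitted values;
    the GLM route uses deviance residuals against link-scale (log mean)
    fitted values, the standard GLM diagnostic plot.
    """
    if fit.route == "glm":
        fitted = np.log(fit.fitted)
        residual_type: Literal["raw", "deviance"] = "deviance"
    else:
        fitted = fit.fitted
        residual_type = "raw"
    resid = fit.residuals
    n = len(resid)
    if n >= 4 and np.ptp(fitted) > 0:
        smooth = lowess(resid, fitted, frac=span, return_sorted=True)
    else:
        smooth = np.empty((0, 2))
    if n >= 3:
        if np.ptp(fitted) == 0 or np.ptp(np.abs(resid)) == 0:
            fan = 0.0  # no spread in either margin: no fan trend by definition
        else:
            rho = stats.spearmanr(np.abs(resid), fitted).statistic
            fan = float(rho) if np.isfinite(rho) else 0.0
    else:
        fan = float("nan")
    return DiagnosticSummary(
        route=fit.route,
        residual_type=residual_type,
        fitted=fitted,
        residuals=resid,
        smooth_curve=smooth,
        fan_index=fan,
    )


def compare_dataset(
    dataset: CountDataset,
    alpha: float = 0.05,
    sqrt_spec: TransformSpec | None = None,
    log_spec: TransformSpec | None = None,
    family_threshold: float = 1.5,
    span: float = 0.75,
) -> ComparisonReport:
    """Run all three routes on one dataset and assemble the comparison.

    Fits OLS on the square-root- and log-transformed response, picks the
    GLM family by the Pearson dispersion of a Poisson fit, back-transforms
    every route to the count scale, and tabulates decisions at ``alpha``
    and percentage differences of LM coefficients relative to the GLM.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    sqrt_spec = sqrt_spec or TransformSpec("sqrt")
    log_spec = log_spec or TransformSpec("log")

    fits: dict[str, FitResult] = {}
    for route, runner in (
        ("sqrt_lm", lambda: fit_ols(dataset, sqrt_spec)),
        ("log_lm", lambda: fit_ols(dataset, log_spec)),
        ("glm", lambda: fit_glm_irls(dataset, choose_family(dataset, family_threshold))),
    ):
        try:
            fits[route] = runner()
        except Exception as exc:
            raise RuntimeError(f"route {route} failed on dataset {dataset.id!r}: {exc}") from exc

    estimates = {
        "sqrt_lm": backtransform_sqrt(fits["sqrt_lm"]),
        "log_lm": backtransform_log(fits["log_lm"], spec=log_spec),
        "glm": backtransform_glm(fits["glm"]),
    }
    glm_coefs = estimates["glm"].coefficients()
    pct: dict[tuple[str, str], float | None] = {}
    for route in ("sqrt_lm", "log_lm"):
        lm_coefs = estimates[route].coefficients()
        for name, glm_value in glm_coefs.items():
            pct[(route, name)] = (
                pct_difference(lm_coefs[name], glm_value) if glm_value != 0 else None
            )

    routes = {
        name: RouteResult(
            route=name,
            fit=fit,
            estimates=estimates[name],
            diagnostics=residual_diagnostics(fit, span=span),
            decision=fit.p_value < alpha,
        )
        for name, fit in fits.items()
    }
    decisions = [rr.decision for rr in routes.values()]
    return ComparisonReport(
        dataset_id=dataset.id,
        alpha=alpha,
        routes=routes,
        pct_diff=pct,
        decisions_agree=all(decisions) or not any(decisions),
    )


@dataclass
class CaseSuiteSummary:
    reports: list[ComparisonReport]
    n_decision_changes: int  # datasets where an LM decision differs from the GLM's
    n_sqrt_more_fanned: int  # datasets where the sqrt route is the most fan-shaped
    changed_dataset_ids: list[str] = field(default_factory=list)


def run_case_suite(
    datasets: Sequence[CountDataset],
    alpha: float = 0.05,
    fan_margin: float = 0.1,
    **kwargs,
) -> CaseSuiteSummary:
    """Compare every dataset and count cross-route disagreements.

    Counts (a) datasets where either LM route's decision differs from the
    GLM decision and (b) datasets where the sqrt route's fan index
    exceeds both other routes' by at least ``fan_margin``.
    """
    if not datasets:
        raise ValueError("need at least one dataset")
    reports = [compare_dataset(d, alpha=alpha, **kwargs) for d in datasets]
    changed = [
        r.dataset_id
        for r in reports
        if any(
            r.routes[lm].decision != r.routes["glm"].decision
            for lm in ("sqrt_lm", "log_lm")
        )
    ]
    n_fanned = sum(
        1
        for r in reports
        if all(
            r.routes["sqrt_lm"].diagnostics.fan_index
            >= r.routes[other].diagnostics.fan_index + fan_margin
            for other in ("log_lm", "glm")
        )
    )
    return CaseSuiteSummary(
        reports=reports,
        n_decision_changes=len(changed),
        n_sqrt_more_fanned=n_fanned,
        changed_dataset_ids=changed,
    )
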