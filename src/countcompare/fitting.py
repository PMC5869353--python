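"""Model fitting for the three analysis routes.

Route 1 and 2 are ordinary least squares on a transformed response
(square-root or log); route 3 is a log-link GLM with Poisson or
negative-binomial errors, fitted by iteratively reweighted least squares
(IRLS).  Every fit reports the predictor-term p-value: the overall F-test
for the OLS routes and the likelihood-ratio (analysis-of-deviance) chi2
test for the GLM route.

The negative-binomial dispersion theta (variance mu + mu^2/theta) is
estimated, when not supplied, by alternating IRLS for the coefficients
with one-dimensional maximisation of the NB log-likelihood in log(theta).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import optimize, special, stats

from .datasets import CountDataset
from .transforms import TransformSpec, apply_transform

__all__ = [
    "DesignMatrix",
    "FitResult",
    "build_design",
    "fit_ols",
    "fit_glm_irls",
    "fit_intercept_only",
    "dispersion_statistic",
    "choose_family",
]

Route = Literal["sqrt_lm", "log_lm", "glm"]

IRLS_TOL = 1e-8
IRLS_MAX_ITER = 100
THETA_LOG_BOUNDS = (-7.0, 12.0)


@dataclass
class DesignMatrix:
    """Intercept-first model matrix with treatment coding.

    For a one-way design the alphabetically first level is the reference;
    each remaining level gets a 0/1 indicator column.
    """

    X: np.ndarray
    column_names: list[str]
    levels: list[str] | None = None

    def __post_init__(self) -> None:
        if not np.all(self.X[:, 0] == 1.0):
            raise ValueError("first design column must be the intercept")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("design matrix is rank deficient")

    @property
    def n_params(self) -> int:
        return self.X.shape[1]


def build_design(dataset: CountDataset) -> DesignMatrix:
    n = dataset.n
    if dataset.kind == "oneway":
        levels = dataset.levels
        X = np.ones((n, len(levels)))
        for j, level in enumerate(levels[1:], start=1):
            X[:, j] = (dataset.x == level).astype(float)
        names = ["intercept"] + [f"x[{lev}]" for lev in levels[1:]]
        return DesignMatrix(X=X, column_names=names, levels=levels)
    X = np.column_stack([np.ones(n), dataset.x])
    return DesignMatrix(X=X, column_names=["intercept", "x"])


@dataclass
class FitResult:
    """Coefficients on the model scale plus the predictor-term test.

    ``coefficients`` live on the transformed scale for the LM routes and
    on the log-link scale for the GLM route.  ``fitted`` and
    ``residuals`` are on the fitted model's response scale (transformed
    scale for LM; count scale mu with deviance residuals for GLM).
    """

    route: Route
    family: Literal["gaussian", "poisson", "negbin"]
    kind: Literal["oneway", "regression"]
    coefficients: np.ndarray
    standard_errors: np.ndarray
    coef_names: list[str]
    fitted: np.ndarray
    residuals: np.ndarray
    p_value: float
    converged: bool
    n_iter: int
    scale_info: dict = field(default_factory=dict)
    levels: list[str] | None = None
    transform: TransformSpec | None = None
    theta: float | None = None

    def __post_init__(self) -> None:
        if len(self.fitted) != len(self.residuals):
            raise ValueError("fitted and residuals must have equal length")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")

    def coef(self, name: str) -> float:
        return float(self.coefficients[self.coef_names.index(name)])


def fit_ols(dataset: CountDataset, spec: TransformSpec) -> FitResult:
    """OLS of the transformed response on the design matrix.

    The p-value is the overall F-test of the predictor term (full model
    against intercept-only).
    """
    z = apply_transform(dataset.y, spec)
    design = build_design(dataset)
    X = design.X
    n, p = X.shape
    beta, _, rank, _ = np.linalg.lstsq(X, z, rcond=None)
    if rank < p:
        raise ValueError("design matrix is rank deficient")
    fitted = X @ beta
    resid = z - fitted
    rss = float(resid @ resid)
    df_resid = n - p
    rss0 = float(np.sum((z - z.mean()) ** 2))
    df_num = p - 1
    if df_resid <= 0 or rss <= 0:
        # saturated or perfect fit: the F-statistic is degenerate
        p_value = 0.0 if (rss0 > rss and df_resid > 0) else 1.0
        sigma2 = 0.0
    else:
        f_stat = ((rss0 - rss) / df_num) / (rss / df_resid)
        p_value = float(stats.f.sf(f_stat, df_num, df_resid))
        sigma2 = rss / df_resid
    XtX_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.maximum(np.diag(XtX_inv) * sigma2, 0.0))
    route: Route = "sqrt_lm" if spec.name == "sqrt" else "log_lm"
    return FitResult(
        route=route,
        family="gaussian",
        kind=dataset.kind,
        coefficients=beta,
        standard_errors=se,
        coef_names=design.column_names,
        fitted=fitted,
        residuals=resid,
        p_value=p_value,
        converged=True,
        n_iter=1,
        scale_info={"rss": rss, "df_resid": df_resid},
        levels=design.levels,
        transform=spec,
    )


def _poisson_loglik(y: np.ndarray, mu: np.ndarray) -> float:
    return float(np.sum(y * np.log(mu) - mu - special.gammaln(y + 1)))


def _negbin_loglik(y: np.ndarray, mu: np.ndarray, theta: float) -> float:
    return float(
        np.sum(
            special.gammaln(y + theta)
            - special.gammaln(theta)
            - special.gammaln(y + 1)
            + theta * np.log(theta / (theta + mu))
            + y * np.log(mu / (theta + mu))
        )
    )


def _deviance_residuals(
    y: np.ndarray, mu: np.ndarray, family: str, theta: float | None
) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        ylogy = np.where(y > 0, y * np.log(y / mu), 0.0)
    if family == "poisson":
        dev_i = 2.0 * (ylogy - (y - mu))
    else:
        dev_i = 2.0 * (ylogy - (y + theta) * np.log((y + theta) / (mu + theta)))
    return np.sign(y - mu) * np.sqrt(np.maximum(dev_i, 0.0))


def _irls(
    y: np.ndarray, X: np.ndarray, family: str, theta: float | None
) -> tuple[np.ndarray, np.ndarray, int]:
    """Log-link IRLS; returns (beta, mu, iterations)."""
    mu = y + 0.5  # guards log(0)
    eta = np.log(mu)
    beta = np.zeros(X.shape[1])
    for it in range(1, IRLS_MAX_ITER + 1):
        w = mu if family == "poisson" else mu / (1.0 + mu / theta)
        z = eta + (y - mu) / mu
        WX = X * w[:, None]
        beta_new = np.linalg.solve(X.T @ WX, WX.T @ z)
        delta = np.max(np.abs(beta_new - beta))
        beta = beta_new
        eta = X @ beta
        mu = np.exp(eta)
        if delta < IRLS_TOL:
            return beta, mu, it
    raise RuntimeError(
        f"IRLS did not converge in {IRLS_MAX_ITER} iterations "
        f"(last max |delta beta| = {delta:.3e})"
    )


def _estimate_theta(y: np.ndarray, X: np.ndarray) -> tuple[float, np.ndarray, np.ndarray, int]:
    """Alternate IRLS(beta | theta) with 1-d likelihood maximisation in log(theta)."""
    theta = 1.0
    beta, mu, n_it = _irls(y, X, "negbin", theta)
    loglik = _negbin_loglik(y, mu, theta)
    total_iter = n_it
    for _ in range(50):
        res = optimize.minimize_scalar(
            lambda lt: -_negbin_loglik(y, mu, np.exp(lt)),
            bounds=THETA_LOG_BOUNDS,
            method="bounded",
            options={"xatol": 1e-10},
        )
        theta = float(np.exp(res.x))
        beta, mu, n_it = _irls(y, X, "negbin", theta)
        total_iter += n_it
        new_loglik = _negbin_loglik(y, mu, theta)
        if abs(new_loglik - loglik) < 1e-8:
            break
        loglik = new_loglik
    return theta, beta, mu, total_iter


def fit_glm_irls(
    dataset: CountDataset,
    family: Literal["poisson", "negbin"] = "poisson",
    theta: float | None = None,
) -> FitResult:
    """Log-link GLM via IRLS, with LR test of the predictor term.

    For the negative binomial, ``theta`` may be fixed or (default)
    estimated by profile likelihood; the LR test holds theta at the
    full-model estimate for both the full and intercept-only fits.
    """
    if family not in ("poisson", "negbin"):
        raise ValueError(f"unknown family {family!r}")
    y = dataset.y.astype(float)
    if np.all(y == 0):
        raise ValueError("all-zero response: log-link GLM mean is unidentifiable")
    design = build_design(dataset)
    X = design.X

    if family == "poisson":
        beta, mu, n_iter = _irls(y, X, "poisson", None)
        ll_full = _poisson_loglik(y, mu)
        theta_hat = None
    elif theta is not None:
        if theta <= 0:
            raise ValueError("theta must be strictly positive")
        beta, mu, n_iter = _irls(y, X, "negbin", theta)
        ll_full = _negbin_loglik(y, mu, theta)
        theta_hat = float(theta)
    else:
        theta_hat, beta, mu, n_iter = _estimate_theta(y, X)
        ll_full = _negbin_loglik(y, mu, theta_hat)

    # intercept-only fit at the same theta for the analysis-of-deviance test
    X0 = np.ones((len(y), 1))
    _, mu0, _ = _irls(y, X0, family, theta_hat)
    ll_null = (
        _poisson_loglik(y, mu0)
        if family == "poisson"
        else _negbin_loglik(y, mu0, theta_hat)
    )
    lr = max(2.0 * (ll_full - ll_null), 0.0)
    df = X.shape[1] - 1
    p_value = float(stats.chi2.sf(lr, df))

    w = mu if family == "poisson" else mu / (1.0 + mu / theta_hat)
    cov = np.linalg.inv(X.T @ (X * w[:, None]))
    se = np.sqrt(np.diag(cov))
    resid = _deviance_residuals(y, mu, family, theta_hat)
    deviance = float(np.sum(resid**2))
    return FitResult(
        route="glm",
        family=family,
        kind=dataset.kind,
        coefficients=beta,
        standard_errors=se,
        coef_names=design.column_names,
        fitted=mu,
        residuals=resid,
        p_value=p_value,
        converged=True,
        n_iter=n_iter,
        scale_info={
            "deviance": deviance,
            "df_resid": len(y) - X.shape[1],
            "loglik": ll_full,
            "lr_statistic": lr,
        },
        levels=design.levels,
        theta=theta_hat,
    )


def fit_intercept_only(
    y, family: Literal["poisson", "negbin"] = "poisson", theta: float | None = None
) -> float:
    """MLE of the constant log-mean; for Poisson this is log of the sample mean."""
    y = np.asarray(y, dtype=float)
    if np.all(y == 0):
        raise ValueError("all-zero response: log-link GLM mean is unidentifiable")
    X0 = np.ones((len(y), 1))
    if family == "negbin" and theta is None:
        theta, beta, _, _ = _estimate_theta(y, X0)
        return float(beta[0])
    beta, _, _ = _irls(y, X0, family, theta)
    return float(beta[0])


def dispersion_statistic(fit: FitResult, dataset: CountDataset) -> float:
    """Pearson chi2 / residual df of a Poisson fit; ~1 when equidispersed."""
    if fit.route != "glm" or fit.family != "poisson":
        raise ValueError("dispersion statistic is defined for Poisson GLM fits")
    mu = fit.fitted
    if np.any(mu == 0):
        raise ValueError("fitted mean of zero: Pearson statistic undefined")
    y = dataset.y.astype(float)
    pearson = float(np.sum((y - mu) ** 2 / mu))
    df = len(y) - len(fit.coefficients)
    if df <= 0:
        raise ValueError("no residual degrees of freedom")
    return pearson / df


def choose_family(
    dataset: CountDataset, threshold: float = 1.5
) -> Literal["poisson", "negbin"]:
    """Pick negbin iff the Poisson fit's Pearson dispersion exceeds the threshold."""
    fit = fit_glm_irls(dataset, family="poisson")
    return "negbin" if dispersion_statistic(fit, dataset) > threshold else "poisson"
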