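"""Synthetic count-data generation with known ground truth.

Datasets emulate the classic textbook case studies this package is built
around: counts per unit under a one-way categorical design (group means on
the count scale) or a single-covariate log-linear regression
(``mu_i = exp(beta0 + beta1 * x_i)``), with Poisson or negative-binomial
sampling.  The generating parameters are echoed on the dataset so recovery
studies can measure bias against truth.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = ["GeneratorConfig", "CountDataset", "generate", "null_dataset"]

Design = Literal["oneway", "regression"]
Family = Literal["poisson", "negbin"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Recipe for one synthetic count dataset.

    Parameters
    ----------
    design
        ``"oneway"`` (categorical predictor) or ``"regression"``
        (continuous predictor, log-linear mean).
    n
        Observations per group (oneway) or total (regression).
    group_means
        Count-scale mean per group; one-way designs only.
    beta
        ``(beta0, beta1)`` on the log-link scale; regression designs only.
    covariate_range
        Interval over which the regression covariate is evenly spaced.
    family
        ``"poisson"`` or ``"negbin"``.
    theta
        Negative-binomial dispersion; variance is ``mu + mu**2 / theta``,
        so ``theta -> inf`` recovers Poisson.
    seed
        Seed for the dataset's private random generator.  Identical
        config + seed reproduces the dataset exactly.
    """

    design: Design
    n: int
    group_means: tuple[float, ...] | None = None
    beta: tuple[float, float] | None = None
    covariate_range: tuple[float, float] = (0.0, 10.0)
    family: Family = "poisson"
    theta: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.design not in ("oneway", "regression"):
            raise ValueError(f"unknown design {self.design!r}")
        if self.family not in ("poisson", "negbin"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.n < 2:
            raise ValueError("need at least 2 observations per group/total")
        if self.design == "oneway":
            if not self.group_means or len(self.group_means) < 2:
                raise ValueError("oneway design requires >= 2 group means")
            if any(m <= 0 for m in self.group_means):
                raise ValueError("group means must be strictly positive")
        else:
            if self.beta is None:
                raise ValueError("regression design requires beta=(beta0, beta1)")
            lo, hi = self.covariate_range
            if not lo < hi:
                raise ValueError("covariate_range must be a nonempty interval")
        if self.theta <= 0:
            raise ValueError("theta must be strictly positive")


@dataclass
class CountDataset:
    """Counts plus one explanatory variable.

    ``y`` holds non-negative integer counts; ``x`` holds either group
    labels (``kind == "oneway"``) or real covariate values
    (``kind == "regression"``).  ``truth`` echoes the generating config
    when the dataset is synthetic.
    """

    y: np.ndarray
    x: np.ndarray
    kind: Design
    id: str = ""
    truth: GeneratorConfig | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y)
        if self.y.ndim != 1 or len(self.y) < 2:
            raise ValueError("y must be a 1-d sequence of length >= 2")
        if not np.issubdtype(self.y.dtype, np.integer):
            as_int = np.asarray(self.y, dtype=float)
            if not np.all(np.isfinite(as_int)) or np.any(as_int != np.round(as_int)):
                raise ValueError("y must contain integers")
            self.y = as_int.astype(np.int64)
        if np.any(self.y < 0):
            raise ValueError("counts must be non-negative")
        self.x = np.asarray(self.x)
        if len(self.x) != len(self.y):
            raise ValueError("x and y must have equal length")
        if self.kind == "oneway":
            self.x = self.x.astype(str)
            levels, counts = np.unique(self.x, return_counts=True)
            if len(levels) < 2:
                raise ValueError("oneway dataset needs >= 2 distinct levels")
        elif self.kind == "regression":
            self.x = self.x.astype(float)
        else:
            raise ValueError(f"unknown kind {self.kind!r}")

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def levels(self) -> list[str]:
        """Sorted group labels (oneway only)."""
        if self.kind != "oneway":
            raise ValueError("levels only defined for oneway datasets")
        return sorted(np.unique(self.x).tolist())

    def group_mean(self, level: str) -> float:
        return float(self.y[self.x == level].mean())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"y": self.y, "x": self.x})

    def write(self, path: str | Path, sep: str = ",") -> None:
        """Write as a delimited table with columns y, x and a header row."""
        self.to_frame().to_csv(path, sep=sep, index=False)


def _group_labels(k: int) -> list[str]:
    letters = string.ascii_lowercase
    if k <= len(letters):
        return list(letters[:k])
    return [f"g{i:03d}" for i in range(k)]


def _draw(rng: np.random.Generator, mu: np.ndarray, config: GeneratorConfig) -> np.ndarray:
    if config.family == "poisson":
        return rng.poisson(mu)
    # NB(mu, theta): gamma-Poisson mixture, variance mu + mu^2/theta
    p = config.theta / (config.theta + mu)
    return rng.negative_binomial(config.theta, p)


def generate(config: GeneratorConfig) -> CountDataset:
    """Draw one dataset from the configured generative model.

    One-way designs draw ``n`` counts per group at that group's mean.
    Regression designs place the covariate evenly over
    ``covariate_range`` (deterministic, so truth recovery is not
    confounded by design randomness) and draw counts at
    ``mu_i = exp(beta0 + beta1 * x_i)``.
    """
    rng = np.random.default_rng(config.seed)
    if config.design == "oneway":
        means = np.asarray(config.group_means, dtype=float)
        labels = _group_labels(len(means))
        mu = np.repeat(means, config.n)
        x = np.repeat(labels, config.n)
        dataset_id = f"oneway-{config.family}-seed{config.seed}"
    else:
        beta0, beta1 = config.beta
        x = np.linspace(*config.covariate_range, config.n)
        mu = np.exp(beta0 + beta1 * x)
        dataset_id = f"regression-{config.family}-seed{config.seed}"
    y = _draw(rng, mu, config)
    return CountDataset(y=y, x=x, kind=config.design, id=dataset_id, truth=config)


def null_dataset(config: GeneratorConfig) -> CountDataset:
    """Draw a dataset under the null of no predictor effect.

    The one-way null replaces all group means with their common mean
    (the mean of the configured means); the regression null forces the
    slope to zero.  The echoed truth records the null configuration.
    """
    if config.design == "oneway":
        common = float(np.mean(config.group_means))
        null_config = replace(config, group_means=(common,) * len(config.group_means))
    else:
        null_config = replace(config, beta=(config.beta[0], 0.0))
    dataset = generate(null_config)
    dataset.id = "null-" + dataset.id
    return dataset
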