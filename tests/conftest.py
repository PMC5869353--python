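import numpy as np
import pytest

from countcompare.datasets import CountDataset, GeneratorConfig, generate


@pytest.fixture
def rng():
    return np.random.default_rng(20180216)


@pytest.fixture
def oneway_dataset():
    """Moderate one-way Poisson dataset with a real group difference."""
    return generate(GeneratorConfig("oneway", n=30, group_means=(3.0, 7.0), seed=11))


@pytest.fixture
def regression_dataset():
    """Log-linear Poisson regression dataset over a unit-spaced covariate."""
    return generate(
        GeneratorConfig(
            "regression", n=25, beta=(1.2, 0.15), covariate_range=(0.0, 8.0), seed=7
        )
    )


def random_oneway(rng, n_groups=2, n_per_group=20, mean_range=(1.0, 20.0)):
    """Random all-positive one-way dataset for property checks."""
    means = rng.uniform(*mean_range, size=n_groups)
    y = np.concatenate([rng.poisson(m, n_per_group) for m in means])
    x = np.repeat([f"g{i}" for i in range(n_groups)], n_per_group)
    # re-draw any all-zero group so every group mean is positive
    while True:
        groups = y.reshape(n_groups, n_per_group)
        zero = groups.sum(axis=1) == 0
        if not zero.any():
            break
        for i in np.flatnonzero(zero):
            groups[i] = rng.poisson(max(means[i], 1.0), n_per_group)
        y = groups.ravel()
    return CountDataset(y=y, x=x, kind="oneway", id="random-oneway")
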