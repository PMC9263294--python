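import numpy as np
import pandas as pd
import pytest

from slesurv.cssnn import LossConfig, NetConfig
from slesurv.synthetic_cohort import CohortSpec, FeatureSpec, generate_cohort


def small_feature_set(n_informative=3, n_noise=7, weight=0.6):
    feats = [
        FeatureSpec(
            f"risk{i}",
            "binary",
            prevalence_survival=0.30,
            prevalence_death=0.55,
            hazard_weight=weight,
        )
        for i in range(n_informative)
    ]
    feats += [
        FeatureSpec(f"noise{i}", "binary", prevalence_survival=0.30, prevalence_death=0.30)
        for i in range(n_noise)
    ]
    return tuple(feats)


@pytest.fixture(scope="session")
def small_cohort():
    """A fast, informative cohort: 600 patients, 1/3 censored."""
    spec = CohortSpec(
        n_total=600,
        n_censored=200,
        death_fraction_labeled=0.3,
        death_fraction_censored=0.45,
        features=small_feature_set(),
        seed=42,
    )
    return generate_cohort(spec)


@pytest.fixture
def fast_net_cfg():
    return NetConfig(input_dim=10, hidden=(16, 16), epochs=60, seed=0)


@pytest.fixture
def fast_loss_cfg():
    return LossConfig(alpha_f=3.0, t1=10, t2=40)


@pytest.fixture
def separable_xy():
    """Linearly separable two-class data: trivially learnable."""
    rng = np.random.default_rng(0)
    n = 120
    y = np.repeat([0, 1], n // 2)
    x = rng.normal(size=(n, 4)) * 0.3
    x[:, 0] += y * 3.0
    return x, y
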