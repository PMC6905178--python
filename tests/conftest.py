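import numpy as np
import pandas as pd
import pytest

from eegssb.spectral import SpectralFeatureSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_feature_set(
    n_pem=60,
    n_ctrl=60,
    p=50,
    shifted=(),
    shift=-1.0,
    age_slope=0.0,
    seed=0,
    band="low_alpha",
):
    """Gaussian feature table with optional group shifts, for classifier tests."""
    rng = np.random.default_rng(seed)
    n = n_pem + n_ctrl
    X = rng.standard_normal((n, p))
    groups = np.array(["PEM"] * n_pem + ["Control"] * n_ctrl)
    ages = rng.uniform(5, 11, n)
    for j in shifted:
        X[groups == "PEM", j] += shift + age_slope * (ages[groups == "PEM"] - 8.0)
    ids = [f"s{i:03d}" for i in range(n)]
    cols = pd.MultiIndex.from_tuples([(f"R{j:02d}", band) for j in range(p)])
    return SpectralFeatureSet(
        values=pd.DataFrame(X, index=ids, columns=cols),
        ages=pd.Series(ages, index=ids, name="age"),
        groups=pd.Series(groups, index=ids, name="group"),
    )


@pytest.fixture
def small_effect_features():
    """120 subjects, 50 features, features 3 and 17 shifted by 1 SD."""
    return make_feature_set(shifted=(3, 17), shift=-1.0, seed=7)


@pytest.fixture
def null_features():
    return make_feature_set(shifted=(), seed=11)
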