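import numpy as np
import pandas as pd
import pytest

from csmsb.randomizers import CoinSpec, Covariate, RandomizerConfig
from csmsb.synthetic import make_trial_fixture


@pytest.fixture(scope="session")
def mixed_covariates():
    return (
        Covariate("age", "numeric"),
        Covariate("nihss", "numeric", weight=2.0),
        Covariate("occ", "nominal", categories=("ica", "m1", "m2")),
        Covariate("af", "binary", categories=("no", "yes")),
        Covariate("sev", "ordinal", categories=("low", "mid", "high")),
    )


def make_mixed_stream(n, rng, missing=False):
    df = pd.DataFrame({
        "age": rng.normal(70, 10, n),
        "nihss": np.round(rng.normal(15, 5, n)),
        "occ": rng.choice(["ica", "m1", "m2"], n, p=[0.3, 0.5, 0.2]),
        "af": rng.choice(["no", "yes"], n, p=[0.7, 0.3]),
        "sev": rng.choice(["low", "mid", "high"], n, p=[0.3, 0.4, 0.3]),
    })
    if missing:
        df.loc[rng.random(n) < 0.1, "age"] = np.nan
        df.loc[rng.random(n) < 0.1, "occ"] = np.nan
    return df


@pytest.fixture(scope="session")
def tnk1_fixture():
    """A TNK-I-like synthetic population with counterfactual outcomes."""
    return make_trial_fixture("tnk1_like", n=200, seed=7)


@pytest.fixture(scope="session")
def pooled_config(tnk1_fixture):
    return RandomizerConfig("csmsb", "pooled", CoinSpec("static", 0.9), 0.05,
                            tnk1_fixture.covariates)


@pytest.fixture(scope="session")
def msb_config(tnk1_fixture):
    return RandomizerConfig("msb", "majority", CoinSpec("static", 0.9), 0.05,
                            tnk1_fixture.covariates)
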