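import numpy as np
import pandas as pd
import pytest

from stratarx.cohort import Cohort
from stratarx.rewards import RewardMatrix


def build_cohort(treatment, event, follow_up=None, ids=None, **covariates):
    """Assemble a Cohort from parallel value lists.

    Covariate kinds are inferred: numeric -> continuous, else categorical.
    """
    n = len(treatment)
    data = {"id": ids if ids is not None else [f"p{i}" for i in range(n)]}
    kinds = {}
    for name, values in covariates.items():
        data[name] = values
        kinds[name] = ("continuous"
                       if np.issubdtype(np.asarray(values).dtype, np.number)
                       else "categorical")
    data["treatment"] = treatment
    data["event"] = event
    if follow_up is not None:
        data["follow_up"] = follow_up
    return Cohort(pd.DataFrame(data), kinds)


def build_rewards(risk0, risk1, **covariates):
    """RewardMatrix over explicit risk columns and covariates."""
    risk0 = np.asarray(risk0, dtype=float)
    n = len(risk0)
    X = pd.DataFrame(covariates if covariates else {"x": np.zeros(n)})
    categorical = [c for c in X.columns
                   if not np.issubdtype(X[c].dtype, np.number)]
    return RewardMatrix(ids=np.array([f"p{i}" for i in range(n)]),
                        risk0=risk0, risk1=np.asarray(risk1, dtype=float),
                        covariates=X, categorical=categorical)


class ConstantRiskModel:
    """Stub standing in for a FittedClassifier."""

    def __init__(self, value):
        self.value = value

    def predict_risk(self, X):
        return np.full(len(X), self.value, dtype=float)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def fast_model_config():
    """Small random forest for quick fits in unit tests."""
    return {"model": "random_forest", "n_estimators": 50, "min_samples_leaf": 10}
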