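"""Pluggable probabilistic classifiers behind a single fit/predict contract.

Two families are provided:

* ``random_forest`` (default) — well suited to the tabular, interaction-heavy
  prognostic problems this package targets.
* ``logistic`` — unpenalized logistic regression, whose training objective is
  the *exact* weighted empirical cross-entropy.  This makes it the reference
  learner for checking that an integer sample weight is equivalent to
  duplicating records.

Categorical covariates are one-hot expanded with an order-stable encoding
recorded at fit time; an unseen level at prediction time raises rather than
being silently mapped to all-zeros.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression

from .exceptions import FittingError

DEFAULT_MODEL_CONFIG = {
    "model": "random_forest",
    "n_estimators": 200,
    "min_samples_leaf": 10,
    "max_features": "sqrt",
}


def _build_estimator(config: dict, seed: int):
    cfg = dict(DEFAULT_MODEL_CONFIG, **(config or {}))
    kind = cfg.pop("model")
    if kind == "random_forest":
        return RandomForestClassifier(
            n_estimators=cfg.get("n_estimators", 200),
            min_samples_leaf=cfg.get("min_samples_leaf", 10),
            max_features=cfg.get("max_features", "sqrt"),
            random_state=seed,
            n_jobs=1,
        )
    if kind == "logistic":
        return LogisticRegression(
            C=np.inf, solver="lbfgs", max_iter=5000, tol=1e-10,
        )
    raise ValueError(f"unknown model kind {kind!r}")


@dataclass
class FittedClassifier:
    """A fitted probability model over a fixed covariate list."""

    estimator: object
    covariates: list
    categorical: list
    levels: dict = field(default_factory=dict)   # categorical -> seen levels
    feature_columns: list = field(default_factory=list)
    seed: int = 0

    def _encode(self, X: pd.DataFrame, training: bool) -> pd.DataFrame:
        X = X[self.covariates].copy()
        for name in self.categorical:
            col = X[name].astype(str)
            if training:
                self.levels[name] = sorted(col.unique())
            else:
                unseen = set(col.unique()) - set(self.levels[name])
                if unseen:
                    raise ValueError(
                        f"unseen level(s) {sorted(unseen)} for categorical "
                        f"covariate {name!r}"
                    )
            X[name] = col
        enc = pd.get_dummies(X, columns=self.categorical, dtype=float)
        if training:
            self.feature_columns = list(enc.columns)
        return enc.reindex(columns=self.feature_columns, fill_value=0.0)

    def fit(self, X: pd.DataFrame, y: np.ndarray,
            sample_weight: np.ndarray | None = None) -> "FittedClassifier":
        y = np.asarray(y, dtype=int)
        if len(np.unique(y)) < 2:
            raise FittingError(
                "training outcome has a single class; cannot fit a risk model"
            )
        enc = self._encode(X, training=True)
        self.estimator.fit(enc.to_numpy(), y, sample_weight=sample_weight)
        return self

    def predict_risk(self, X: pd.DataFrame) -> np.ndarray:
        """P(event = 1 | x) for each row, in [0, 1]."""
        enc = self._encode(X, training=False)
        proba = self.estimator.predict_proba(enc.to_numpy())
        idx = int(np.flatnonzero(self.estimator.classes_ == 1)[0])
        return proba[:, idx]


def fit_classifier(X: pd.DataFrame, y, covariates, categorical, config=None,
                   seed: int = 0, sample_weight=None) -> FittedClassifier:
    clf = FittedClassifier(
        estimator=_build_estimator(config, seed),
        covariates=list(covariates),
        categorical=[c for c in categorical if c in covariates],
        seed=seed,
    )
    return clf.fit(X, y, sample_weight=sample_weight)
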