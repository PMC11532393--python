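"""Paired counterfactual outcome models and the confounding-gap correction.

Two classifiers are trained on the matched cohort: ``h0`` on the untreated
arm with the plain empirical cross-entropy, and ``h1`` on the treated arm
where every treated, event-free record carries multiplicative loss weight
rho >= 1 (cost-sensitive learning).  Raising rho pulls the treated model's
predicted risk down; the smallest rho for which the mean predicted treated
risk no longer exceeds the mean predicted untreated risk cancels the minimum
residual unobserved confounding.

A ``direction="untreated"`` mode instead up-weights untreated, event-free
records, for the mirrored bias where unobserved factors *favor* the treated
arm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import Cohort
from .exceptions import FittingError, GridExhaustedError
from .models import FittedClassifier, fit_classifier


def _as_cohort(obj) -> Cohort:
    if isinstance(obj, Cohort):
        return obj
    cohort = getattr(obj, "cohort", None)
    if isinstance(cohort, Cohort):
        return cohort
    raise TypeError(f"expected a Cohort or cohort-bearing object, got {type(obj)!r}")


@dataclass
class RewardModelPair:
    """h0 (untreated) and h1 (treated, rho-weighted) risk models."""

    h0: FittedClassifier
    h1: FittedClassifier
    rho: float
    seed: int
    direction: str = "treated"


@dataclass
class RewardMatrix:
    """Per-patient predicted risk under each treatment, plus the covariates
    they were predicted from (needed to fit and route a policy tree)."""

    ids: np.ndarray
    risk0: np.ndarray         # predicted risk under no treatment
    risk1: np.ndarray         # predicted risk under treatment
    covariates: pd.DataFrame
    categorical: list

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def w_hat_t0(self) -> float:
        return float(np.mean(self.risk0))

    @property
    def w_hat_t1(self) -> float:
        return float(np.mean(self.risk1))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"id": self.ids, "risk0": self.risk0,
                             "risk1": self.risk1})


def _arm_fit(cohort: Cohort, arm: int, weight_no_event: float,
             covariates, config, seed) -> FittedClassifier:
    mask = (cohort.treatment == arm) & cohort.training_mask
    if not mask.any():
        raise FittingError(f"matched arm t={arm} is empty")
    X = cohort.X.loc[mask]
    y = cohort.event[mask]
    sw = None
    if weight_no_event != 1.0:
        sw = np.where(y == 0, weight_no_event, 1.0)
    return fit_classifier(X, y, covariates, cohort.categorical_names(),
                          config=config, seed=seed, sample_weight=sw)


def fit_reward_models(mc, rho: float = 1.0, config=None, seed: int = 0,
                      covariates=None, direction: str = "treated") -> RewardModelPair:
    """Fit the counterfactual pair (h0, h1) on the matched cohort.

    ``rho`` multiplies the loss of the no-event subset of the arm named by
    ``direction``; the other arm's model is the plain unweighted fit.  At
    rho = 1 both fits are unweighted.
    """
    if rho < 1.0:
        raise ValueError(f"rho must be >= 1, got {rho}")
    if direction not in ("treated", "untreated"):
        raise ValueError(f"direction must be 'treated' or 'untreated', got {direction!r}")
    cohort = _as_cohort(mc)
    covariates = list(covariates) if covariates is not None else list(cohort.covariates)
    w0 = rho if direction == "untreated" else 1.0
    w1 = rho if direction == "treated" else 1.0
    h0 = _arm_fit(cohort, 0, w0, covariates, config, seed)
    h1 = _arm_fit(cohort, 1, w1, covariates, config, seed)
    return RewardModelPair(h0=h0, h1=h1, rho=rho, seed=seed, direction=direction)


def predict_rewards(pair: RewardModelPair, cohort_like) -> RewardMatrix:
    """Predict both counterfactual risk columns for every patient."""
    cohort = _as_cohort(cohort_like)
    risk0 = np.clip(pair.h0.predict_risk(cohort.X), 0.0, 1.0)
    risk1 = np.clip(pair.h1.predict_risk(cohort.X), 0.0, 1.0)
    return RewardMatrix(ids=cohort.ids.to_numpy(), risk0=risk0, risk1=risk1,
                        covariates=cohort.X.copy(),
                        categorical=cohort.categorical_names())


def confounding_gap(rm: RewardMatrix) -> float:
    """Signed gap mean(risk1) - mean(risk0).

    A positive gap is the minimum amount of residual unobserved confounding:
    an effective (or even neutral) treatment cannot make the treated arm's
    predicted risk exceed the untreated arm's.
    """
    return rm.w_hat_t1 - rm.w_hat_t0


@dataclass
class WeightSearchResult:
    """Outcome of the minimum-weight grid scan."""

    rho_min: float
    trace: pd.DataFrame       # rho, w_hat_t1, w_hat_t0, gap
    pair: RewardModelPair
    rewards: RewardMatrix


def find_minimum_weight(mc, grid=None, config=None, seed: int = 0,
                        covariates=None, direction: str = "treated") -> WeightSearchResult:
    """Scan an ascending weight grid for the smallest rho closing the gap.

    ``h0`` is fitted once (it does not depend on rho); ``h1`` is refitted
    with the same seed at each grid point.  The first grid rho with gap <= 0
    wins — if that is the first point, no correction was needed.  If no grid
    point closes the gap, :class:`GridExhaustedError` carries the full trace.
    """
    if grid is None:
        grid = default_weight_grid()
    grid = [float(r) for r in grid]
    if not grid:
        raise ValueError("weight grid is empty")
    if any(r < 1.0 for r in grid) or list(grid) != sorted(grid):
        raise ValueError("weight grid must be ascending and all >= 1")

    cohort = _as_cohort(mc)
    covariates = list(covariates) if covariates is not None else list(cohort.covariates)
    w0 = 1.0  # direction='untreated' would invert which model is rescanned
    if direction == "untreated":
        raise NotImplementedError(
            "minimum-weight search currently supports direction='treated'; "
            "fit_reward_models accepts both directions"
        )
    h0 = _arm_fit(cohort, 0, w0, covariates, config, seed)
    risk0 = np.clip(h0.predict_risk(cohort.X), 0.0, 1.0)
    what0 = float(risk0.mean())

    rows = []
    for rho in grid:
        h1 = _arm_fit(cohort, 1, rho, covariates, config, seed)
        risk1 = np.clip(h1.predict_risk(cohort.X), 0.0, 1.0)
        what1 = float(risk1.mean())
        gap = what1 - what0
        rows.append({"rho": rho, "w_hat_t1": what1, "w_hat_t0": what0, "gap": gap})
        if gap <= 0:
            pair = RewardModelPair(h0=h0, h1=h1, rho=rho, seed=seed)
            rm = RewardMatrix(ids=cohort.ids.to_numpy(), risk0=risk0,
                              risk1=risk1, covariates=cohort.X.copy(),
                              categorical=cohort.categorical_names())
            return WeightSearchResult(rho_min=rho, trace=pd.DataFrame(rows),
                                      pair=pair, rewards=rm)
    raise GridExhaustedError(
        f"no weight in {grid[0]}..{grid[-1]} closed the confounding gap "
        f"(final gap {rows[-1]['gap']:+.4f})",
        trace=pd.DataFrame(rows),
    )


def default_weight_grid(start: float = 1.0, stop: float = 3.5,
                        step: float = 0.05) -> list:
    n = int(round((stop - start) / step)) + 1
    return [round(start + i * step, 10) for i in range(n)]
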