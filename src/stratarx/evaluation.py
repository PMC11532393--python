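"""Recommendation-level validation of a fitted policy.

Metrics are computed on an external cohort of *untreated* patients whose
outcomes were observed without the treatment in question, so their baseline
risks are unmodified:

* sensitivity — of the patients who had the event, the fraction the policy
  would have treated;
* specificity — of the event-free patients, the fraction the policy spares
  from treatment;
* NPV — of the patients the policy leaves untreated, the fraction that stays
  event-free (prevalence-dependent, reported with the cohort's prevalence).

95% intervals use the Wilson score method.  The same metrics drive weight
tuning (scanning rho and judging each resulting tree on the validation
cohort) and robustness scans across tree hyperparameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .cohort import Cohort
from .rewards import RewardMatrix, _arm_fit, predict_rewards
from .tree import PolicyTree, fit_policy_tree


@dataclass
class EvaluationReport:
    """Confusion counts and derived metrics over untreated validation patients."""

    tp: int   # recurred, treatment recommended
    fn: int   # recurred, no treatment recommended
    tn: int   # event-free, no treatment recommended
    fp: int   # event-free, treatment recommended

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    @property
    def prevalence(self) -> float:
        return (self.tp + self.fn) / self.n

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)

    @property
    def npv(self) -> float:
        denom = self.tn + self.fn
        # an all-treat policy leaves nobody untreated: NPV undefined
        return self.tn / denom if denom else float("nan")

    def intervals(self, alpha: float = 0.05) -> dict:
        """Wilson 95% intervals for sensitivity, specificity and NPV."""
        out = {}
        for name, count, nobs in (
            ("sensitivity", self.tp, self.tp + self.fn),
            ("specificity", self.tn, self.tn + self.fp),
            ("npv", self.tn, self.tn + self.fn),
        ):
            if nobs == 0:
                out[name] = (float("nan"), float("nan"))
                continue
            lo, hi = proportion_confint(count, nobs, alpha=alpha, method="wilson")
            out[name] = (float(lo), float(hi))
        return out

    def to_dict(self) -> dict:
        ci = self.intervals()
        return {
            "counts": {"tp": self.tp, "fn": self.fn, "tn": self.tn, "fp": self.fp},
            "n": self.n,
            "prevalence": self.prevalence,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "npv": self.npv,
            "ci95": {k: list(v) for k, v in ci.items()},
        }


def evaluate_policy(tree: PolicyTree, validation: Cohort) -> EvaluationReport:
    """Score the tree's recommendations against observed untreated outcomes.

    Raises ``ValueError`` if any validation patient was treated (their
    baseline risk is modified, breaking the construction) or if no patient
    had the event (sensitivity undefined).
    """
    if (validation.treatment != 0).any():
        raise ValueError(
            "validation cohort must be untreated; "
            f"{int(validation.treatment.sum())} treated patients present"
        )
    y = validation.event
    if y.sum() == 0:
        raise ValueError("no events in validation cohort; sensitivity undefined")
    rec = tree.assign(validation.X)
    return EvaluationReport(
        tp=int(((y == 1) & (rec == 1)).sum()),
        fn=int(((y == 1) & (rec == 0)).sum()),
        tn=int(((y == 0) & (rec == 0)).sum()),
        fp=int(((y == 0) & (rec == 1)).sum()),
    )


def npv_from_rates(sensitivity: float, specificity: float, n_events: int,
                   n_total: int) -> float:
    """NPV implied by summary rates via the 2x2-table construction.

    TN = specificity x (event-free count), FN = (1 - sensitivity) x event
    count; NPV = TN / (TN + FN).  Algebraically identical to the Bayes form
    spec(1-prev) / [(1-sens)prev + spec(1-prev)].
    """
    n_free = n_total - n_events
    tn = specificity * n_free
    fn = (1.0 - sensitivity) * n_events
    return tn / (tn + fn)


@dataclass
class WeightTuningTable:
    """(rho, training gap, validation sensitivity/specificity) rows plus the
    rho selected by the stated rule.  The full table is always kept: the
    final pick trades marginal sensitivity gains against specificity losses
    and deserves human judgment."""

    table: pd.DataFrame
    selected_rho: float
    rule: str


def _select_rho(table: pd.DataFrame, rule: str, sens_floor: float) -> float:
    if rule == "max_youden":
        youden = table["sensitivity"] + table["specificity"]
        return float(table.loc[youden.idxmax(), "rho"])
    if rule == "sens_floor":
        ok = table.loc[table["sensitivity"] >= sens_floor]
        if ok.empty:  # floor unreachable: fall back to the most sensitive rho
            return float(table.loc[table["sensitivity"].idxmax(), "rho"])
        return float(ok.loc[ok["specificity"].idxmax(), "rho"])
    raise ValueError(f"unknown selection rule {rule!r}")


def tune_weight(train_mc, validation: Cohort, grid, rule: str = "max_youden",
                sens_floor: float = 0.85, config=None, seed: int = 0,
                covariates=None, minbucket: int = 15,
                max_depth: int = 4) -> WeightTuningTable:
    """For each grid rho: fit reward models, fit a tree, score it on the
    validation cohort; then apply the selection rule.

    The untreated-arm model does not depend on rho and is fitted once.
    """
    grid = [float(r) for r in grid]
    if not grid:
        raise ValueError("weight grid is empty")
    from .rewards import _as_cohort

    cohort = _as_cohort(train_mc)
    covs = list(covariates) if covariates is not None else list(cohort.covariates)
    h0 = _arm_fit(cohort, 0, 1.0, covs, config, seed)
    risk0 = np.clip(h0.predict_risk(cohort.X), 0.0, 1.0)

    rows = []
    for rho in grid:
        h1 = _arm_fit(cohort, 1, rho, covs, config, seed)
        risk1 = np.clip(h1.predict_risk(cohort.X), 0.0, 1.0)
        rm = RewardMatrix(ids=cohort.ids.to_numpy(), risk0=risk0, risk1=risk1,
                          covariates=cohort.X.copy(),
                          categorical=cohort.categorical_names())
        tree = fit_policy_tree(rm, covariates=covs, minbucket=minbucket,
                               max_depth=max_depth, seed=seed)
        report = evaluate_policy(tree, validation)
        rows.append({"rho": rho,
                     "w_hat_t1": float(risk1.mean()),
                     "w_hat_t0": float(risk0.mean()),
                     "gap": float(risk1.mean() - risk0.mean()),
                     "sensitivity": report.sensitivity,
                     "specificity": report.specificity})
    table = pd.DataFrame(rows)
    return WeightTuningTable(table=table,
                             selected_rho=_select_rho(table, rule, sens_floor),
                             rule=rule)


@dataclass
class RobustnessReport:
    table: pd.DataFrame       # minbucket, max_depth, sensitivity, specificity
    trees: list

    @property
    def sensitivity_range(self) -> tuple:
        return (float(self.table["sensitivity"].min()),
                float(self.table["sensitivity"].max()))

    @property
    def specificity_range(self) -> tuple:
        return (float(self.table["specificity"].min()),
                float(self.table["specificity"].max()))


def robustness_scan(train_mc, validation: Cohort, hyper_grid, rho: float = 1.0,
                    config=None, seed: int = 0, covariates=None) -> RobustnessReport:
    """Fit one tree per (minbucket, max_depth) pair at fixed rho and report
    the spread of validation metrics; converging metrics across structurally
    different trees indicate a robust recommendation."""
    from .rewards import fit_reward_models

    pair = fit_reward_models(train_mc, rho=rho, config=config, seed=seed,
                             covariates=covariates)
    rm = predict_rewards(pair, train_mc)
    rows, trees = [], []
    for minbucket, max_depth in hyper_grid:
        tree = fit_policy_tree(rm, covariates=covariates, minbucket=minbucket,
                               max_depth=max_depth, seed=seed)
        report = evaluate_policy(tree, validation)
        rows.append({"minbucket": minbucket, "max_depth": max_depth,
                     "sensitivity": report.sensitivity,
                     "specificity": report.specificity})
        trees.append(tree)
    return RobustnessReport(table=pd.DataFrame(rows), trees=trees)
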