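"""Synthetic confounded cohorts with exported ground truth.

The generator plants every structure the pipeline is supposed to recover:

* baseline outcome risk driven by observed covariates (tumor size, mitotic
  count, site, optionally a binary mutation marker);
* a single latent standard-normal confounder U entering both the outcome
  logit (coefficient ``gamma_y``) and, in observational mode, the
  treatment-assignment logit (``gamma_t``) — the simplest mechanism that
  makes the treated arm look *worse* than the untreated arm despite a
  beneficial treatment;
* a subgroup rule (a pandas query expression over the covariates) inside
  which treatment multiplies the outcome odds by exp(-delta);
* an RCT mode with fair coin assignment but participation bias: high-risk
  patients enter the control arm with reduced probability, recreating sparse
  high-risk strata.

The returned cohort never contains U; ground truth (U, true risks, the
oracle policy) travels in a separate object/file so pipeline code physically
cannot peek.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from .cohort import Cohort, write_cohort


@dataclass(frozen=True)
class SyntheticConfig:
    n: int = 2000
    mode: str = "observational"          # observational | rct
    # covariate generators
    size_logmean: float = math.log(4.5)
    size_logsd: float = 0.55
    mitoses_logmean: float = math.log(3.0)
    mitoses_logsd: float = 0.9
    p_gastric: float = 0.65
    mutation_prob: float = 0.0           # adds a binary 'mutation' covariate
    # baseline outcome logit
    risk_intercept: float = -5.0
    beta_size: float = 1.2
    beta_mitoses: float = 1.0
    beta_nongastric: float = 0.7
    # unobserved confounder
    gamma_y: float = 1.2
    gamma_t: float = 2.2
    # observational treatment-assignment logit (on the observed risk score)
    treat_intercept: float = 0.65
    treat_risk_slope: float = 1.4
    # planted treatment effect
    delta: float = 1.8
    subgroup_rule: str = "(mitoses >= 6) | ((size >= 5) & (site == 'nongastric'))"
    # RCT participation bias (untreated arm, above the risk quantile)
    rct_bias_quantile: float = 0.9
    rct_bias_strength: float = 0.0
    # follow-up construction
    horizon: float = 84.0
    censor_prob: float = 0.0

    def __post_init__(self):
        if self.mode not in ("observational", "rct"):
            raise ValueError(f"unknown mode {self.mode!r}")
        for name in ("p_gastric", "mutation_prob", "rct_bias_quantile",
                     "rct_bias_strength", "censor_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if self.n < 1:
            raise ValueError("n must be positive")

    @property
    def covariates(self) -> dict:
        covs = {"size": "continuous", "mitoses": "continuous",
                "site": "categorical"}
        if self.mutation_prob > 0:
            covs["mutation"] = "categorical"
        return covs

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)


@dataclass
class GroundTruth:
    """Per-patient generating quantities, kept apart from the cohort."""

    frame: pd.DataFrame   # id, u, p_baseline, p_treated, in_subgroup, oracle

    @property
    def oracle(self) -> np.ndarray:
        return self.frame["oracle"].to_numpy()

    def write(self, path) -> None:
        self.frame.to_csv(path, index=False)


def _observed_risk_score(cfg: SyntheticConfig, X: pd.DataFrame) -> np.ndarray:
    score = (cfg.risk_intercept
             + cfg.beta_size * np.log(X["size"].to_numpy())
             + cfg.beta_mitoses * np.log1p(X["mitoses"].to_numpy())
             + cfg.beta_nongastric * (X["site"].to_numpy() == "nongastric"))
    return score


def _draw_covariates(cfg: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n
    size = np.round(rng.lognormal(cfg.size_logmean, cfg.size_logsd, n), 2)
    size = np.maximum(size, 0.1)
    mitoses = np.floor(rng.lognormal(cfg.mitoses_logmean, cfg.mitoses_logsd, n))
    X = pd.DataFrame({
        "size": size,
        "mitoses": mitoses,
        "site": np.where(rng.random(n) < cfg.p_gastric, "gastric", "nongastric"),
    })
    if cfg.mutation_prob > 0:
        X["mutation"] = (rng.random(n) < cfg.mutation_prob).astype(int).astype(str)
    return X


def subgroup_mask(cfg: SyntheticConfig, X: pd.DataFrame) -> np.ndarray:
    return X.eval(cfg.subgroup_rule).to_numpy().astype(bool)


def simulate_observational_cohort(cfg: SyntheticConfig,
                                  seed: int = 0) -> tuple[Cohort, GroundTruth]:
    """Confounded observational draw: treatment assignment follows both the
    observed risk score and the unobserved confounder."""
    if cfg.mode != "observational":
        raise ValueError("config mode is not 'observational'")
    rng = np.random.default_rng(seed)
    X = _draw_covariates(cfg, rng)
    score = _observed_risk_score(cfg, X)
    u_t = rng.standard_normal(cfg.n)
    p_t = expit(cfg.treat_intercept + cfg.treat_risk_slope * score
                + cfg.gamma_t * u_t)
    t = (rng.random(cfg.n) < p_t).astype(int)
    # the same latent draw must confound treatment and outcome: reuse u_t as
    # the outcome confounder by seeding _assemble's rng stream with it
    return _assemble_with_u(cfg, rng, X, t, u_t)


def _assemble_with_u(cfg, rng, X, t, u) -> tuple[Cohort, GroundTruth]:
    n = len(X)
    sub = subgroup_mask(cfg, X)
    score = _observed_risk_score(cfg, X)
    logit0 = score + cfg.gamma_y * u
    p0 = expit(logit0)
    p1 = expit(logit0 - cfg.delta * sub)
    p_y = np.where(t == 1, p1, p0)
    y = (rng.random(n) < p_y).astype(int)
    fu = np.where(y == 1, rng.uniform(1.0, cfg.horizon, n),
                  rng.uniform(cfg.horizon, 2 * cfg.horizon, n))
    if cfg.censor_prob > 0:
        censored = (y == 0) & (rng.random(n) < cfg.censor_prob)
        fu = np.where(censored, rng.uniform(1.0, cfg.horizon, n), fu)
    ids = np.array([f"p{i:05d}" for i in range(n)])
    data = X.copy()
    data.insert(0, "id", ids)
    data["treatment"] = t
    data["event"] = y
    data["follow_up"] = np.round(fu, 1)
    truth = pd.DataFrame({
        "id": ids, "u": u, "p_baseline": p0, "p_treated": p1,
        "in_subgroup": sub.astype(int), "oracle": (p1 < p0).astype(int),
    })
    return Cohort(data, cfg.covariates), GroundTruth(frame=truth)


def simulate_rct_cohort(cfg: SyntheticConfig,
                        seed: int = 0) -> tuple[Cohort, GroundTruth]:
    """Fair-coin assignment, but high-risk patients drop out of the control
    arm with probability ``rct_bias_strength`` — so the realized cohort is
    smaller than n when the bias is active."""
    if cfg.mode != "rct":
        raise ValueError("config mode is not 'rct'")
    rng = np.random.default_rng(seed)
    X = _draw_covariates(cfg, rng)
    t = (rng.random(cfg.n) < 0.5).astype(int)
    u = rng.standard_normal(cfg.n)
    cohort, truth = _assemble_with_u(cfg, rng, X, t, u)
    if cfg.rct_bias_strength > 0:
        # participation bias acts on the *observable* risk score: clinicians
        # steering high-risk patients away from the control arm see x, not U
        p_obs = expit(_observed_risk_score(cfg, X))
        thr = np.quantile(p_obs, cfg.rct_bias_quantile)
        drop = ((t == 0) & (p_obs > thr)
                & (rng.random(cfg.n) < cfg.rct_bias_strength))
        keep = ~drop
        cohort = cohort.subset(keep)
        truth = GroundTruth(frame=truth.frame.loc[keep].reset_index(drop=True))
    return cohort, truth


def simulate(cfg: SyntheticConfig, seed: int = 0) -> tuple[Cohort, GroundTruth]:
    if cfg.mode == "rct":
        return simulate_rct_cohort(cfg, seed)
    return simulate_observational_cohort(cfg, seed)


def oracle_policy(gt: GroundTruth) -> np.ndarray:
    """Treat exactly when the true risk under treatment is below the true
    baseline risk — the recovery benchmark for the fitted policy."""
    f = gt.frame
    return (f["p_treated"].to_numpy() < f["p_baseline"].to_numpy()).astype(int)


def write_bundle(cfg: SyntheticConfig, cohort: Cohort, gt: GroundTruth,
                 out_dir) -> None:
    """Write cohort CSV + ground-truth CSV + config echo (YAML)."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_cohort(cohort, out / "cohort.csv")
    gt.write(out / "ground_truth.csv")
    (out / "config.yaml").write_text(cfg.to_yaml())


# ---------------------------------------------------------------------------
# presets


def gist_observational(**overrides) -> SyntheticConfig:
    """Confounded observational cohort with a strong planted subgroup effect."""
    return SyntheticConfig(**overrides)


def genetic_observational(**overrides) -> SyntheticConfig:
    """Small observational cohort with a binary mutation marker that zeroes
    the treatment benefit for its carriers."""
    defaults = dict(
        n=300,
        mutation_prob=0.12,
        subgroup_rule=("(mutation == '0') & ((mitoses >= 6) | "
                       "(site == 'nongastric'))"),
        gamma_y=0.6, gamma_t=0.6,
    )
    defaults.update(overrides)
    return SyntheticConfig(**defaults)


def sarcoma_rct(**overrides) -> SyntheticConfig:
    """RCT cohort with participation bias confined to the top risk decile;
    at the default strength roughly 10% of patients sit in the biased bands."""
    defaults = dict(
        mode="rct",
        delta=1.2,
        gamma_t=0.0,
        rct_bias_strength=0.7,
        rct_bias_quantile=0.9,
    )
    defaults.update(overrides)
    return SyntheticConfig(**defaults)


def rct_null(**overrides) -> SyntheticConfig:
    """Unconfounded, effect-free RCT: any measured confounding gap is noise."""
    defaults = dict(mode="rct", delta=0.0, gamma_t=0.0, rct_bias_strength=0.0)
    defaults.update(overrides)
    return SyntheticConfig(**defaults)


PRESETS = {
    "gist": gist_observational,
    "genetic": genetic_observational,
    "sarcoma_rct": sarcoma_rct,
    "rct_null": rct_null,
}
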