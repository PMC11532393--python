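"""Baseline (no-treatment) risk model, risk-bucket stratification and
per-bucket arm-balance diagnostics.

The baseline model is fitted *only* on untreated, training-eligible patients
and then used to predict counterfactual baseline risk for every patient,
treated ones included.  Patients are stratified into contiguous risk buckets
covering [0, 1]; sparse buckets are merged top-down (highest risk first)
until each retains a workable number of patients per arm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort
from .exceptions import FittingError
from .models import FittedClassifier, fit_classifier


@dataclass
class BaselineRiskModel:
    """Classifier g over covariates estimating P(event | x, no treatment)."""

    classifier: FittedClassifier
    covariates: list
    seed: int


def fit_baseline_model(cohort: Cohort, covariates=None, config=None,
                       seed: int = 0) -> BaselineRiskModel:
    """Fit the baseline outcome model on untreated, training-eligible patients.

    Raises :class:`FittingError` when there are no untreated patients or the
    untreated outcome is single-class.
    """
    covariates = list(covariates) if covariates is not None else list(cohort.covariates)
    mask = (cohort.treatment == 0) & cohort.training_mask
    if not mask.any():
        raise FittingError("no untreated training-eligible patients to fit on")
    X = cohort.X.loc[mask]
    y = cohort.event[mask]
    clf = fit_classifier(X, y, covariates, cohort.categorical_names(),
                         config=config, seed=seed)
    return BaselineRiskModel(classifier=clf, covariates=covariates, seed=seed)


def predict_baseline_risk(model: BaselineRiskModel, cohort: Cohort) -> np.ndarray:
    """Counterfactual baseline risk w for every patient (treated included)."""
    w = model.classifier.predict_risk(cohort.X)
    return np.clip(w, 0.0, 1.0)


@dataclass(frozen=True)
class BucketSpec:
    """Ordered, contiguous risk intervals jointly covering [0, 1].

    Interval k is ``(lo_k, hi_k]`` except the first, which includes 0.
    """

    edges: tuple  # m + 1 increasing values, edges[0] == 0.0, edges[-1] == 1.0

    def __post_init__(self):
        e = np.asarray(self.edges, dtype=float)
        if len(e) < 2 or e[0] != 0.0 or e[-1] != 1.0 or np.any(np.diff(e) <= 0):
            raise ValueError(f"invalid bucket edges {self.edges}")

    @property
    def m(self) -> int:
        return len(self.edges) - 1

    @property
    def intervals(self) -> list:
        return [(self.edges[k], self.edges[k + 1]) for k in range(self.m)]

    def assign(self, w: np.ndarray) -> np.ndarray:
        """Bucket index for each risk value."""
        w = np.asarray(w, dtype=float)
        inner = np.asarray(self.edges[1:-1])
        return np.searchsorted(inner, w, side="left")


@dataclass
class StratifiedCohort:
    """Cohort annotated with baseline risk and bucket membership."""

    cohort: Cohort
    w: np.ndarray
    bucket: np.ndarray
    spec: BucketSpec
    merge_log: list = field(default_factory=list)

    @property
    def m(self) -> int:
        return self.spec.m

    def to_frame(self) -> pd.DataFrame:
        """Stratification table: id, w, bucket, treatment, event."""
        return pd.DataFrame({
            "id": self.cohort.ids,
            "w": self.w,
            "bucket": self.bucket,
            "treatment": self.cohort.treatment,
            "event": self.cohort.event,
        })

    def arm_counts(self) -> pd.DataFrame:
        """Per-bucket (n_untreated, n_treated)."""
        t = self.cohort.treatment
        rows = []
        for k in range(self.m):
            in_k = self.bucket == k
            rows.append({"bucket": k,
                         "n0": int((in_k & (t == 0)).sum()),
                         "n1": int((in_k & (t == 1)).sum())})
        return pd.DataFrame(rows)


def _initial_edges(w: np.ndarray, strategy: str, m: int) -> np.ndarray:
    if strategy == "fixed_width":
        wmax = float(np.max(w))
        if wmax <= 0:
            raise ValueError("all risks are zero; cannot build fixed-width buckets")
        edges = np.linspace(0.0, wmax, m + 1)
        edges[-1] = 1.0
        return edges
    if strategy == "quantile":
        qs = np.quantile(w, np.linspace(0, 1, m + 1))
        qs[0], qs[-1] = 0.0, 1.0
        if len(np.unique(qs)) != m + 1:
            raise ValueError(
                f"m={m} exceeds the number of distinct risk values; "
                "quantile edges collapse"
            )
        return qs
    raise ValueError(f"unknown stratification strategy {strategy!r}")


def stratify(cohort: Cohort, w, strategy: str = "quantile", m: int = 6,
             min_per_arm: int = 0) -> StratifiedCohort:
    """Split patients into m risk buckets and merge sparse ones top-down.

    While any bucket holds fewer than ``min_per_arm`` patients in either arm,
    the highest-indexed offending bucket is merged with its lower neighbour
    (sparsity concentrates in high-risk strata).  The realized spec — which
    may have fewer than m buckets — is recorded, along with a merge log.
    """
    w = np.asarray(w, dtype=float)
    if len(w) != cohort.n:
        raise ValueError("risk vector length does not match cohort size")
    if m < 1:
        raise ValueError("m must be >= 1")
    if np.any((w < 0) | (w > 1)):
        raise ValueError("risks must lie in [0, 1]")

    edges = list(_initial_edges(w, strategy, m))
    t = cohort.treatment
    merge_log = []
    while len(edges) > 2 and min_per_arm > 0:
        spec = BucketSpec(edges=tuple(edges))
        b = spec.assign(w)
        offending = None
        for k in reversed(range(spec.m)):
            n0 = int(((b == k) & (t == 0)).sum())
            n1 = int(((b == k) & (t == 1)).sum())
            if min(n0, n1) < min_per_arm:
                offending = k
                break
        if offending is None:
            break
        drop = offending if offending > 0 else 1  # merge with lower neighbour
        merge_log.append(
            f"merged bucket {offending} (sparse arm) by removing edge "
            f"{edges[drop]:.6g}"
        )
        del edges[drop]

    spec = BucketSpec(edges=tuple(edges))
    return StratifiedCohort(cohort=cohort, w=w, bucket=spec.assign(w),
                            spec=spec, merge_log=merge_log)


@dataclass
class BalanceDiagnostics:
    """Per-bucket arm counts, empirical treatment probabilities and flags."""

    counts: pd.DataFrame      # bucket, n0, n1, p_treated, p_untreated, flagged
    ratio_threshold: float

    @property
    def flagged_buckets(self) -> list:
        return self.counts.loc[self.counts["flagged"], "bucket"].tolist()

    @property
    def any_flagged(self) -> bool:
        return bool(self.counts["flagged"].any())


def diagnose_balance(sc: StratifiedCohort,
                     ratio_threshold: float = 2.0) -> BalanceDiagnostics:
    """Flag bucket k iff max(n1, n0) > threshold * min(n1, n0) or an arm is empty.

    Empty buckets are reported (probabilities NaN), never raised.
    """
    rows = []
    for rec in sc.arm_counts().itertuples(index=False):
        n0, n1 = rec.n0, rec.n1
        total = n0 + n1
        p1 = n1 / total if total else float("nan")
        p0 = n0 / total if total else float("nan")
        flagged = (min(n0, n1) == 0 and total > 0) or (
            min(n0, n1) > 0 and max(n0, n1) > ratio_threshold * min(n0, n1)
        )
        rows.append({"bucket": rec.bucket, "n0": n0, "n1": n1,
                     "p_untreated": p0, "p_treated": p1, "flagged": flagged})
    return BalanceDiagnostics(counts=pd.DataFrame(rows),
                              ratio_threshold=ratio_threshold)


def default_bucket_count(n: int, mode: str = "observational") -> int:
    """Preset bucket counts: 6 observational, 5 RCT, 3 for small cohorts."""
    if n < 300:
        return 3
    return 5 if mode == "rct" else 6
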