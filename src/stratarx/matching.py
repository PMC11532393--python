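"""Within-bucket 1:1 treated/untreated matching and the RCT oversampling remedy.

The per-bucket matching problem — match every minority-arm patient to a
distinct majority-arm patient so that the total squared Euclidean distance
over standardized covariates is minimal — is a rectangular assignment
problem with a totally unimodular constraint matrix, so
:func:`scipy.optimize.linear_sum_assignment` returns the exact optimum of the
binary program.  A microscopic index-ordered perturbation makes the solution
among equal-cost optima deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .baseline import StratifiedCohort
from .cohort import Cohort
from .exceptions import MatchingError, PipelineError

log = logging.getLogger(__name__)


def normalize_covariates(cohort: Cohort, names) -> tuple[pd.DataFrame, dict]:
    """Standardize continuous covariates to mean 0, population SD 1.

    Statistics are computed on the full cohort (global normalization); the
    (mean, sd) pairs are returned so the transform is reproducible.  A
    zero-variance covariate is a hard error naming the column.
    """
    names = list(names)
    for name in names:
        if cohort.covariates.get(name) != "continuous":
            raise ValueError(f"distance covariate {name!r} is not continuous")
    X = cohort.X[names].astype(float)
    params = {}
    out = {}
    for name in names:
        mu = float(X[name].mean())
        sd = float(X[name].std(ddof=0))
        if sd == 0.0:
            raise ValueError(f"zero-variance covariate {name!r} cannot be normalized")
        params[name] = (mu, sd)
        out[name] = (X[name] - mu) / sd
    return pd.DataFrame(out, index=X.index), params


@dataclass
class MatchProblem:
    """One bucket's matching instance over standardized coordinates."""

    bucket: int
    treated_index: np.ndarray     # positional rows of treated patients
    untreated_index: np.ndarray   # positional rows of untreated patients
    coords: np.ndarray            # (n_cohort, d) standardized coordinates
    ids: np.ndarray               # cohort ids aligned with coords rows


@dataclass
class MatchResult:
    """Optimal pairs for one bucket."""

    bucket: int
    pairs: pd.DataFrame           # treated_id, untreated_id, dist2
    treated_rows: np.ndarray
    untreated_rows: np.ndarray
    total_cost: float

    @property
    def n_s(self) -> int:
        return 2 * len(self.pairs)


def match_within_bucket(problem: MatchProblem) -> MatchResult:
    """Exactly solve the bucket's minimum-total-squared-distance matching.

    Every minority-arm patient is matched exactly once; majority-arm patients
    at most once (arm roles swap automatically when treated outnumber
    untreated).  Ties between equal-cost optima break toward the
    lexicographically smallest pair-index vector.
    """
    ti, ui = problem.treated_index, problem.untreated_index
    if len(ti) == 0 or len(ui) == 0:
        raise MatchingError(f"bucket {problem.bucket} has an empty arm")
    cost = cdist(problem.coords[ti], problem.coords[ui], metric="sqeuclidean")
    # deterministic tie-break: prefer low (treated, untreated) indices
    nr, nc = cost.shape
    scale = max(cost.max(), 1.0)
    rank = np.arange(nr)[:, None] * nc + np.arange(nc)[None, :]
    eps = 1e-12 * scale / (nr * nc + 1)
    rows, cols = linear_sum_assignment(cost + eps * rank)
    order = np.argsort(rows)
    rows, cols = rows[order], cols[order]
    treated_rows = ti[rows]
    untreated_rows = ui[cols]
    d2 = cost[rows, cols]
    pairs = pd.DataFrame({
        "treated_id": problem.ids[treated_rows],
        "untreated_id": problem.ids[untreated_rows],
        "dist2": d2,
    })
    return MatchResult(bucket=problem.bucket, pairs=pairs,
                       treated_rows=treated_rows, untreated_rows=untreated_rows,
                       total_cost=float(d2.sum()))


@dataclass
class MatchedCohort:
    """Union of all per-bucket matched pairs; arms are equal per bucket."""

    cohort: Cohort                # retained patients only, original row order
    w: np.ndarray                 # baseline risk of retained patients
    bucket: np.ndarray            # bucket of retained patients
    pairs: pd.DataFrame           # bucket, treated_id, untreated_id, dist2
    dropped_buckets: list = field(default_factory=list)

    @property
    def n_s(self) -> int:
        return self.cohort.n

    def arm_counts(self) -> pd.DataFrame:
        t = self.cohort.treatment
        rows = []
        for k in sorted(np.unique(self.bucket)):
            in_k = self.bucket == k
            rows.append({"bucket": int(k),
                         "n0": int((in_k & (t == 0)).sum()),
                         "n1": int((in_k & (t == 1)).sum())})
        return pd.DataFrame(rows)


def match_cohort(sc: StratifiedCohort, distance_covariates=None) -> MatchedCohort:
    """Match 1:1 separately within every risk bucket.

    Buckets with an empty arm are dropped with a warning (matching is
    impossible there); if all buckets are degenerate the pipeline fails.
    After matching, the empirical treatment probability is exactly 0.5 in
    each retained bucket.
    """
    cohort = sc.cohort
    if distance_covariates is None:
        distance_covariates = cohort.continuous_names()
    coords, _ = normalize_covariates(cohort, distance_covariates)
    coords = coords.to_numpy()
    ids = cohort.ids.to_numpy()
    t = cohort.treatment

    results, dropped = [], []
    for k in range(sc.m):
        in_k = sc.bucket == k
        ti = np.flatnonzero(in_k & (t == 1))
        ui = np.flatnonzero(in_k & (t == 0))
        if len(ti) == 0 or len(ui) == 0:
            if in_k.any():
                log.warning("bucket %d dropped: empty arm (n1=%d, n0=%d)",
                            k, len(ti), len(ui))
                dropped.append(k)
            continue
        problem = MatchProblem(bucket=k, treated_index=ti, untreated_index=ui,
                               coords=coords, ids=ids)
        results.append(match_within_bucket(problem))

    if not results:
        raise PipelineError("matching", "all buckets degenerate; nothing to match")

    keep = np.zeros(cohort.n, dtype=bool)
    for r in results:
        keep[r.treated_rows] = True
        keep[r.untreated_rows] = True
    pairs = pd.concat(
        [r.pairs.assign(bucket=r.bucket) for r in results], ignore_index=True
    )[["bucket", "treated_id", "untreated_id", "dist2"]]

    return MatchedCohort(
        cohort=cohort.subset(keep),
        w=sc.w[keep],
        bucket=sc.bucket[keep],
        pairs=pairs,
        dropped_buckets=dropped,
    )


def oversample_strata(sc: StratifiedCohort, target=None, seed: int = 0,
                      ratio_threshold: float = 2.0) -> StratifiedCohort:
    """RCT remedy: resample minority arms of imbalanced buckets with replacement.

    ``target`` is the per-arm size each flagged bucket is raised to; by
    default the median per-arm count over unflagged buckets.  Duplicated rows
    get fresh ids and carry a ``source_id`` provenance column.  Records are
    never removed.
    """
    from .baseline import diagnose_balance

    diag = diagnose_balance(sc, ratio_threshold=ratio_threshold)
    flagged = diag.flagged_buckets
    if not flagged:
        return sc

    counts = diag.counts
    if target is None:
        ok = counts.loc[~counts["flagged"]]
        if ok.empty:
            raise MatchingError("all buckets flagged; no reference size for target")
        target = int(np.median(np.concatenate([ok["n0"].to_numpy(),
                                               ok["n1"].to_numpy()])))
    rng = np.random.default_rng(seed)
    data = sc.cohort.data.copy()
    if "source_id" not in data.columns:
        data["source_id"] = data["id"]
    w = list(sc.w)
    bucket = list(sc.bucket)
    new_rows = []
    t = sc.cohort.treatment
    for k in flagged:
        for arm in (0, 1):
            rows = np.flatnonzero((sc.bucket == k) & (t == arm))
            if len(rows) == 0:
                raise MatchingError(
                    f"bucket {k} arm {arm} is empty; cannot oversample"
                )
            deficit = target - len(rows)
            if deficit <= 0:
                continue
            draws = rng.choice(rows, size=deficit, replace=True)
            for j, src in enumerate(draws):
                rec = data.iloc[src].copy()
                rec["source_id"] = rec["id"]
                rec["id"] = f"{rec['id']}#dup{k}_{arm}_{j}"
                new_rows.append(rec)
                w.append(sc.w[src])
                bucket.append(sc.bucket[src])
    if new_rows:
        data = pd.concat([data, pd.DataFrame(new_rows)], ignore_index=True)
    new_cohort = Cohort(data, sc.cohort.covariates)
    return StratifiedCohort(cohort=new_cohort, w=np.asarray(w),
                            bucket=np.asarray(bucket), spec=sc.spec,
                            merge_log=list(sc.merge_log))
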