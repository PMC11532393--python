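import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stratarx.baseline import stratify
from stratarx.exceptions import MatchingError
from stratarx.matching import (
    MatchProblem,
    match_cohort,
    match_within_bucket,
    normalize_covariates,
    oversample_strata,
)
from stratarx.synthetic import SyntheticConfig, simulate

from conftest import build_cohort


def brute_force_cost(minority, majority):
    """Minimum total squared distance over all injections (oracle)."""
    a, b = len(minority), len(majority)
    assert a <= b
    best = np.inf
    for perm in itertools.permutations(range(b), a):
        cost = sum(np.sum((minority[i] - majority[j]) ** 2)
                   for i, j in enumerate(perm))
        best = min(best, cost)
    return best


def make_problem(treated_pts, untreated_pts):
    coords = np.vstack([treated_pts, untreated_pts]).astype(float)
    n1 = len(treated_pts)
    return MatchProblem(
        bucket=0,
        treated_index=np.arange(n1),
        untreated_index=np.arange(n1, len(coords)),
        coords=coords,
        ids=np.array([f"p{i}" for i in range(len(coords))]),
    )


class TestNormalize:
    def test_hand_arithmetic(self):
        c = build_cohort([0, 1, 0], [0, 1, 0], x=[2.0, 4.0, 6.0])
        out, params = normalize_covariates(c, ["x"])
        np.testing.assert_allclose(out["x"], [-1.2247, 0.0, 1.2247], atol=1e-4)
        mu, sd = params["x"]
        assert mu == 4.0

    def test_idempotent_on_standardized_input(self, rng):
        x = rng.normal(size=50)
        x = (x - x.mean()) / x.std(ddof=0)
        c = build_cohort([0] * 50, [0] * 50, x=x.tolist())
        out, _ = normalize_covariates(c, ["x"])
        np.testing.assert_allclose(out["x"], x, atol=1e-12)

    def test_zero_variance_names_covariate(self):
        c = build_cohort([0, 1], [0, 1], flat=[3.0, 3.0])
        with pytest.raises(ValueError, match="flat"):
            normalize_covariates(c, ["flat"])

    def test_categorical_rejected(self):
        c = build_cohort([0, 1], [0, 1], site=["a", "b"])
        with pytest.raises(ValueError, match="continuous"):
            normalize_covariates(c, ["site"])


class TestMatchWithinBucket:
    def test_identity_pair(self):
        r = match_within_bucket(make_problem([[0.0]], [[0.0]]))
        assert len(r.pairs) == 1
        assert r.total_cost == 0.0
        assert r.n_s == 2

    def test_frozen_1d_example(self):
        # exhaustive enumeration of all 6 injections gives costs
        # {2, 101, 162, 181, 401, 481}; the optimum pairs (0,1) and (10,9)
        r = match_within_bucket(make_problem([[0.0], [10.0]],
                                             [[1.0], [9.0], [20.0]]))
        assert r.total_cost == 2.0
        got = {(tr, un) for tr, un in
               zip(r.pairs.treated_id, r.pairs.untreated_id)}
        assert got == {("p0", "p2"), ("p1", "p3")}

    def test_role_swap_when_treated_majority(self):
        r = match_within_bucket(make_problem([[0.0], [5.0], [9.0]],
                                             [[1.0], [8.0]]))
        assert len(r.pairs) == 2
        assert r.pairs.untreated_id.is_unique
        assert r.pairs.treated_id.is_unique

    def test_empty_arm_errors(self):
        p = make_problem([[0.0]], [[1.0]])
        p.untreated_index = np.array([], dtype=int)
        with pytest.raises(MatchingError):
            match_within_bucket(p)

    @given(st.data())
    @settings(max_examples=60, deadline=None)
    def test_optimality_vs_enumeration(self, data):
        n1 = data.draw(st.integers(1, 5))
        n0 = data.draw(st.integers(1, 5))
        d = data.draw(st.integers(1, 2))
        vals = st.floats(-10, 10, allow_nan=False, width=32)
        treated = np.array(
            [data.draw(st.lists(vals, min_size=d, max_size=d)) for _ in range(n1)])
        untreated = np.array(
            [data.draw(st.lists(vals, min_size=d, max_size=d)) for _ in range(n0)])
        r = match_within_bucket(make_problem(treated, untreated))
        if n1 <= n0:
            oracle = brute_force_cost(treated, untreated)
        else:
            oracle = brute_force_cost(untreated, treated)
        assert r.total_cost == pytest.approx(oracle, rel=1e-9, abs=1e-9)

    def test_invariant_under_constant_shift(self):
        treated = np.array([[0.0, 1.0], [3.0, 2.0]])
        untreated = np.array([[1.0, 0.0], [2.5, 2.0], [9.0, 9.0]])
        r1 = match_within_bucket(make_problem(treated, untreated))
        r2 = match_within_bucket(make_problem(treated + [100.0, 0.0],
                                              untreated + [100.0, 0.0]))
        assert r1.total_cost == pytest.approx(r2.total_cost)
        assert r1.pairs.treated_id.tolist() == r2.pairs.treated_id.tolist()
        assert r1.pairs.untreated_id.tolist() == r2.pairs.untreated_id.tolist()


def _stratified(n=800, seed=4, m=6):
    c, gt = simulate(SyntheticConfig(n=n), seed=seed)
    from stratarx.baseline import fit_baseline_model, predict_baseline_risk

    model = fit_baseline_model(c, seed=0,
                               config={"n_estimators": 80})
    w = predict_baseline_risk(model, c)
    return stratify(c, w, strategy="quantile", m=m, min_per_arm=5), gt


class TestMatchCohort:
    def test_equal_arms_and_smd_shrinks(self):
        sc, gt = _stratified()
        mc = match_cohort(sc)
        t = mc.cohort.treatment
        counts = mc.arm_counts()
        assert (counts.n0 == counts.n1).all()
        # empirical treatment probability is 1/2 in every bucket
        for k in counts.bucket:
            in_k = mc.bucket == k
            assert t[in_k].mean() == 0.5

        def smd(w, t):
            a, b = w[t == 1], w[t == 0]
            pooled = np.sqrt((a.var() + b.var()) / 2)
            return abs(a.mean() - b.mean()) / pooled

        truth = gt.frame.set_index("id")["p_baseline"]
        before = smd(truth.loc[sc.cohort.ids].to_numpy(), sc.cohort.treatment)
        after = smd(truth.loc[mc.cohort.ids].to_numpy(), t)
        assert after < before

    def test_already_balanced_identical_bucket_retains_all(self):
        c = build_cohort([1, 0, 1, 0], [0, 0, 1, 1], x=[1.0, 1.0, 1.0, 2.0])
        sc = stratify(c, [0.5] * 4, strategy="fixed_width", m=1)
        mc = match_cohort(sc, distance_covariates=["x"])
        assert mc.n_s == 4

    def test_matching_never_fabricates_records(self):
        sc, _ = _stratified(n=500, seed=9)
        mc = match_cohort(sc)
        assert mc.n_s <= sc.cohort.n
        assert set(mc.cohort.ids) <= set(sc.cohort.ids)

    def test_empty_arm_bucket_dropped_with_warning(self, caplog):
        # bucket 1 has no treated patients
        w = [0.1, 0.15, 0.9, 0.95]
        c = build_cohort([1, 0, 0, 0], [0, 0, 1, 1], x=[1.0, 1.1, 5.0, 5.1])
        sc = stratify(c, w, strategy="fixed_width", m=2, min_per_arm=0)
        import logging

        with caplog.at_level(logging.WARNING, logger="stratarx.matching"):
            mc = match_cohort(sc, distance_covariates=["x"])
        assert mc.dropped_buckets == [1]
        assert mc.n_s == 2


class TestOversample:
    def _sc_with_counts(self, counts):
        t, w, x = [], [], []
        m = len(counts)
        edges = np.linspace(0, 1, m + 1)
        for k, (n0, n1) in enumerate(counts):
            mid = (edges[k] + edges[k + 1]) / 2
            t += [0] * n0 + [1] * n1
            w += [mid] * (n0 + n1)
        x = list(range(len(t)))
        c = build_cohort(t, [0, 1] * (len(t) // 2) + [0] * (len(t) % 2), x=x)
        return stratify(c, w, strategy="fixed_width", m=m, min_per_arm=0)

    def test_forty_ten_reaches_target(self):
        sc = self._sc_with_counts([(40, 40), (40, 40), (40, 10)])
        out = oversample_strata(sc, seed=1)
        counts = {k: (int(((out.bucket == k) & (out.cohort.treatment == 0)).sum()),
                      int(((out.bucket == k) & (out.cohort.treatment == 1)).sum()))
                  for k in range(3)}
        assert counts[2] == (40, 40)          # 30 seeded draws with replacement
        assert out.cohort.n == sc.cohort.n + 30

    def test_no_flagged_buckets_returns_input_unchanged(self):
        sc = self._sc_with_counts([(20, 20), (20, 20)])
        out = oversample_strata(sc, seed=1)
        assert out is sc

    def test_duplicates_carry_provenance(self):
        sc = self._sc_with_counts([(30, 30), (30, 5)])
        out = oversample_strata(sc, seed=2)
        dup = out.cohort.data[out.cohort.data["id"].str.contains("#dup")]
        assert len(dup) == 25
        assert set(dup["source_id"]) <= set(sc.cohort.ids)

    def test_never_removes_records(self):
        sc = self._sc_with_counts([(30, 30), (30, 5)])
        out = oversample_strata(sc, seed=2)
        assert set(sc.cohort.ids) <= set(out.cohort.ids)

    def test_empty_arm_errors(self):
        sc = self._sc_with_counts([(30, 30), (20, 0)])
        with pytest.raises(MatchingError):
            oversample_strata(sc, seed=0)

    def test_deterministic(self):
        sc = self._sc_with_counts([(30, 30), (30, 5)])
        a = oversample_strata(sc, seed=7).cohort.data
        b = oversample_strata(sc, seed=7).cohort.data
        assert a.equals(b)
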