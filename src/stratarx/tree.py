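"""Axis-aligned policy trees minimizing total predicted risk.

The tree chooses, for each leaf, the treatment whose summed predicted risk
over the leaf's patients is smaller (ties withhold treatment), and is grown
greedily: every covariate and every candidate cutoff — midpoints of
consecutive sorted unique values for continuous features, category subsets
for categoricals with at most 8 levels — is scored by the reduction in the
summed chosen-column risk, and recursion stops at ``max_depth``, a
``minbucket`` violation, or when no split improves the objective.

Routing convention: ``value < threshold`` goes left, ``value >= threshold``
(and a category inside the recorded set) goes... see :meth:`PolicyTree.assign`
— the boundary value routes to the right ("equal or greater") branch.

An exhaustive oracle (:func:`brute_force_policy_tree`) enumerates every tree
up to depth 2 over the same candidate set and is used to bound the greedy
search in tests; it replaces a globally-optimized commercial solver.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InstanceTooLargeError
from .rewards import RewardMatrix

_GAIN_TOL = 1e-12
_MAX_CAT_LEVELS = 8


@dataclass
class TreeNode:
    n: int
    sum_r0: float
    sum_r1: float
    depth: int = 0
    # internal-node fields
    feature: str | None = None
    threshold: float | None = None
    categories: frozenset | None = None      # left branch = value in set
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    # leaf field
    treatment: int | None = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    @property
    def mean_r0(self) -> float:
        return self.sum_r0 / self.n

    @property
    def mean_r1(self) -> float:
        return self.sum_r1 / self.n

    def rule(self) -> str:
        if self.is_leaf:
            return f"treat={self.treatment}"
        if self.threshold is not None:
            return f"{self.feature} < {self.threshold:g}"
        cats = ", ".join(sorted(self.categories))
        return f"{self.feature} in {{{cats}}}"


@dataclass
class PolicyTree:
    root: TreeNode
    minbucket: int
    max_depth: int
    covariates: list
    categorical: list = field(default_factory=list)

    # -- routing -----------------------------------------------------------
    def assign(self, X: pd.DataFrame) -> np.ndarray:
        """Route each row to a leaf and return its assigned treatment."""
        out = np.empty(len(X), dtype=int)
        pos = np.arange(len(X))

        def rec(node: TreeNode, rows: np.ndarray):
            if node.is_leaf:
                out[rows] = node.treatment
                return
            if node.feature not in X.columns:
                raise ValueError(f"missing split covariate {node.feature!r}")
            vals = X[node.feature].to_numpy()[rows]
            left = _left_mask(node, vals)
            rec(node.left, rows[left])
            rec(node.right, rows[~left])

        rec(self.root, pos)
        return out

    def assign_one(self, patient) -> int:
        """Assign a treatment to a single patient (mapping or Series)."""
        row = pd.DataFrame([dict(patient)])
        return int(self.assign(row)[0])

    def nodes(self):
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            if not node.is_leaf:
                stack.extend([node.right, node.left])

    def leaves(self):
        return [nd for nd in self.nodes() if nd.is_leaf]

    def depth(self) -> int:
        return max(nd.depth for nd in self.nodes())

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "minbucket": self.minbucket,
            "max_depth": self.max_depth,
            "covariates": list(self.covariates),
            "categorical": list(self.categorical),
            "root": _node_to_dict(self.root),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "PolicyTree":
        try:
            return cls(
                root=_node_from_dict(payload["root"], depth=0),
                minbucket=int(payload["minbucket"]),
                max_depth=int(payload["max_depth"]),
                covariates=list(payload["covariates"]),
                categorical=list(payload.get("categorical", [])),
            )
        except (KeyError, TypeError) as exc:
            raise ValueError(f"malformed policy-tree payload: {exc}") from exc

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kw)

    @classmethod
    def from_json(cls, text: str) -> "PolicyTree":
        return cls.from_dict(json.loads(text))

    def render(self) -> str:
        """ASCII rendering, splits in depth-first order."""
        lines = []

        def rec(node: TreeNode, prefix: str, tail: str):
            label = node.rule()
            stats = f"n={node.n} p0={node.mean_r0:.3f} p1={node.mean_r1:.3f}"
            if node.is_leaf:
                lines.append(f"{prefix}{tail}{label} [{stats}]")
                return
            lines.append(f"{prefix}{tail}[{label}] ({stats})")
            child_prefix = prefix + ("    " if tail in ("", "`-- ") else "|   ")
            rec(node.left, child_prefix, "|-- ")
            rec(node.right, child_prefix, "`-- ")

        rec(self.root, "", "")
        return "\n".join(lines)


def _left_mask(node: TreeNode, vals: np.ndarray) -> np.ndarray:
    if node.threshold is not None:
        return vals.astype(float) < node.threshold
    return np.isin(vals.astype(str), list(node.categories))


def _node_to_dict(node: TreeNode) -> dict:
    base = {"n": node.n, "sum_r0": node.sum_r0, "sum_r1": node.sum_r1}
    if node.is_leaf:
        base["treatment"] = node.treatment
        return base
    base["feature"] = node.feature
    if node.threshold is not None:
        base["threshold"] = node.threshold
    else:
        base["categories"] = sorted(node.categories)
    base["left"] = _node_to_dict(node.left)
    base["right"] = _node_to_dict(node.right)
    return base


def _node_from_dict(payload: dict, depth: int) -> TreeNode:
    node = TreeNode(n=int(payload["n"]), sum_r0=float(payload["sum_r0"]),
                    sum_r1=float(payload["sum_r1"]), depth=depth)
    if "feature" in payload:
        node.feature = payload["feature"]
        if "threshold" in payload:
            node.threshold = float(payload["threshold"])
        else:
            node.categories = frozenset(payload["categories"])
        node.left = _node_from_dict(payload["left"], depth + 1)
        node.right = _node_from_dict(payload["right"], depth + 1)
    else:
        node.treatment = int(payload["treatment"])
    return node


# ---------------------------------------------------------------------------
# fitting


def _leaf_cost(sum_r0: float, sum_r1: float) -> tuple[float, int]:
    """(cost, treatment) of the best constant policy; ties withhold treatment."""
    if sum_r1 < sum_r0:
        return sum_r1, 1
    return sum_r0, 0


def _candidate_splits(X: pd.DataFrame, rows: np.ndarray, covariates,
                      categorical):
    """Yield (feature, threshold, categories, left_rows_mask) candidates.

    Deterministic order: covariate declaration order, then ascending
    threshold / subset enumeration order.
    """
    for feature in covariates:
        vals = X[feature].to_numpy()[rows]
        if feature in categorical:
            levels = sorted(pd.unique(vals.astype(str)))
            if len(levels) < 2 or len(levels) > _MAX_CAT_LEVELS:
                continue
            anchor, rest = levels[0], levels[1:]
            # every proper subset containing the anchor level: each
            # left/right partition enumerated exactly once
            for r in range(len(rest)):
                for combo in itertools.combinations(rest, r):
                    subset = frozenset((anchor,) + combo)
                    mask = np.isin(vals.astype(str), list(subset))
                    yield feature, None, subset, mask
        else:
            fvals = vals.astype(float)
            uniq = np.unique(fvals)
            if len(uniq) < 2:
                continue
            for lo, hi in zip(uniq[:-1], uniq[1:]):
                thr = (lo + hi) / 2.0
                yield feature, float(thr), None, fvals < thr


def _grow(X, r0, r1, rows, depth, minbucket, max_depth, covariates,
          categorical) -> TreeNode:
    s0 = float(r0[rows].sum())
    s1 = float(r1[rows].sum())
    cost, treatment = _leaf_cost(s0, s1)
    node = TreeNode(n=len(rows), sum_r0=s0, sum_r1=s1, depth=depth,
                    treatment=treatment)
    if depth >= max_depth or len(rows) < 2 * minbucket:
        return node

    best = None  # (gain, feature, threshold, categories, left_mask)
    for feature, thr, cats, left in _candidate_splits(X, rows, covariates,
                                                      categorical):
        nl = int(left.sum())
        if nl < minbucket or len(rows) - nl < minbucket:
            continue
        cl, _ = _leaf_cost(float(r0[rows[left]].sum()), float(r1[rows[left]].sum()))
        cr, _ = _leaf_cost(float(r0[rows[~left]].sum()), float(r1[rows[~left]].sum()))
        gain = cost - (cl + cr)
        if gain > _GAIN_TOL and (best is None or gain > best[0] + _GAIN_TOL):
            best = (gain, feature, thr, cats, left)

    if best is None:
        return node
    _, feature, thr, cats, left = best
    node.treatment = None
    node.feature = feature
    node.threshold = thr
    node.categories = cats
    node.left = _grow(X, r0, r1, rows[left], depth + 1, minbucket, max_depth,
                      covariates, categorical)
    node.right = _grow(X, r0, r1, rows[~left], depth + 1, minbucket, max_depth,
                       covariates, categorical)
    return node


def fit_policy_tree(rm: RewardMatrix, covariates=None, minbucket: int = 1,
                    max_depth: int = 3, seed: int = 0) -> PolicyTree:
    """Greedy top-down fit of the minimum-total-risk policy tree.

    ``seed`` is accepted for interface symmetry; the fit itself is fully
    deterministic.
    """
    if minbucket < 1:
        raise ValueError("minbucket must be >= 1")
    if minbucket > rm.n:
        raise ValueError(f"minbucket={minbucket} exceeds cohort size {rm.n}")
    if max_depth < 0:
        raise ValueError("max_depth must be >= 0")
    covariates = list(covariates) if covariates is not None else list(rm.covariates.columns)
    categorical = [c for c in rm.categorical if c in covariates]
    rows = np.arange(rm.n)
    root = _grow(rm.covariates, rm.risk0, rm.risk1, rows, 0, minbucket,
                 max_depth, covariates, categorical)
    return PolicyTree(root=root, minbucket=minbucket, max_depth=max_depth,
                      covariates=covariates, categorical=categorical)


def policy_objective(tree: PolicyTree, rm: RewardMatrix) -> float:
    """Total predicted risk of following the tree's assignments."""
    a = tree.assign(rm.covariates)
    return float(np.where(a == 1, rm.risk1, rm.risk0).sum())


def assign_treatment(tree: PolicyTree, patient) -> int:
    """Deterministic leaf routing for one patient (boundary values go right)."""
    return tree.assign_one(patient)


def node_effects(tree: PolicyTree, rm: RewardMatrix) -> pd.DataFrame:
    """Per-node baseline risk p0, treated risk p1, ARR = p0 - p1 and
    RRR = ARR / p0 (NaN when p0 = 0), computed over the patients routed
    through each node."""
    records = []
    pos = np.arange(rm.n)

    def rec(node: TreeNode, rows: np.ndarray, node_id: str):
        if len(rows) == 0:
            p0 = p1 = float("nan")
        else:
            p0 = float(rm.risk0[rows].mean())
            p1 = float(rm.risk1[rows].mean())
        arr = p0 - p1
        rrr = arr / p0 if p0 > 0 else float("nan")
        records.append({
            "node": node_id, "depth": node.depth, "n": len(rows),
            "rule": node.rule(), "is_leaf": node.is_leaf,
            "treatment": node.treatment, "p0": p0, "p1": p1,
            "arr": arr, "rrr": rrr,
        })
        if not node.is_leaf:
            vals = rm.covariates[node.feature].to_numpy()[rows]
            left = _left_mask(node, vals)
            rec(node.left, rows[left], node_id + "L")
            rec(node.right, rows[~left], node_id + "R")

    rec(tree.root, pos, "root")
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# exhaustive oracle


def brute_force_policy_tree(rm: RewardMatrix, covariates=None, depth: int = 2,
                            minbucket: int = 1) -> PolicyTree:
    """Global optimum over all trees of the given depth (<= 2) and candidate
    cutoffs; test oracle for the greedy fitter on small instances."""
    if depth > 2:
        raise InstanceTooLargeError("exhaustive search supports depth <= 2")
    covariates = list(covariates) if covariates is not None else list(rm.covariates.columns)
    if rm.n > 200 or len(covariates) > 5:
        raise InstanceTooLargeError(
            f"instance too large for enumeration (n={rm.n}, "
            f"p={len(covariates)})"
        )
    categorical = [c for c in rm.categorical if c in covariates]
    X, r0, r1 = rm.covariates, rm.risk0, rm.risk1

    def best_subtree(rows: np.ndarray, d: int, node_depth: int):
        s0 = float(r0[rows].sum())
        s1 = float(r1[rows].sum())
        cost, treatment = _leaf_cost(s0, s1)
        leaf = TreeNode(n=len(rows), sum_r0=s0, sum_r1=s1, depth=node_depth,
                        treatment=treatment)
        best_cost, best_node = cost, leaf
        if d == 0 or len(rows) < 2 * minbucket:
            return best_cost, best_node
        for feature, thr, cats, left in _candidate_splits(X, rows, covariates,
                                                          categorical):
            nl = int(left.sum())
            if nl < minbucket or len(rows) - nl < minbucket:
                continue
            cl, nodel = best_subtree(rows[left], d - 1, node_depth + 1)
            cr, noder = best_subtree(rows[~left], d - 1, node_depth + 1)
            if cl + cr < best_cost - _GAIN_TOL:
                best_cost = cl + cr
                best_node = TreeNode(n=len(rows), sum_r0=s0, sum_r1=s1,
                                     depth=node_depth, feature=feature,
                                     threshold=thr, categories=cats,
                                     left=nodel, right=noder)
        return best_cost, best_node

    _, root = best_subtree(np.arange(rm.n), depth, 0)
    return PolicyTree(root=root, minbucket=minbucket, max_depth=depth,
                      covariates=covariates, categorical=categorical)
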