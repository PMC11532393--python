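import itertools

import numpy as np
import pandas as pd
import pytest

from stratarx.exceptions import InstanceTooLargeError
from stratarx.tree import (
    PolicyTree,
    TreeNode,
    assign_treatment,
    brute_force_policy_tree,
    fit_policy_tree,
    node_effects,
    policy_objective,
)

from conftest import build_rewards


def four_patient_rewards():
    # binary feature f: f=0 rewards (0.1, 0.3); f=1 rewards (0.5, 0.2)
    return build_rewards(risk0=[0.1, 0.1, 0.5, 0.5],
                         risk1=[0.3, 0.3, 0.2, 0.2],
                         f=[0.0, 0.0, 1.0, 1.0])


def random_rewards(rng, n=50, p=3):
    X = {f"x{j}": rng.normal(size=n) for j in range(p)}
    return build_rewards(risk0=rng.random(n), risk1=rng.random(n), **X)


class TestFitPolicyTree:
    def test_uniformly_better_treatment_single_leaf(self):
        rm = build_rewards([0.5, 0.6, 0.7], [0.1, 0.2, 0.3],
                           x=[1.0, 2.0, 3.0])
        tree = fit_policy_tree(rm, max_depth=2)
        # constant treat-all is already optimal: the greedy objective equals it
        assert policy_objective(tree, rm) == pytest.approx(0.6)
        assert set(tree.assign(rm.covariates)) == {1}

    def test_four_patient_depth_one(self):
        rm = four_patient_rewards()
        tree = fit_policy_tree(rm, max_depth=1)
        assert not tree.root.is_leaf
        assert tree.root.feature == "f"
        a = tree.assign(rm.covariates)
        np.testing.assert_array_equal(a, [0, 0, 1, 1])
        # objective 2(0.1) + 2(0.2): minimum over all 8 single-split policies
        # and both constant policies (enumerated in test_matches_policy_enumeration)
        assert policy_objective(tree, rm) == pytest.approx(0.6)

    def test_matches_policy_enumeration(self):
        rm = four_patient_rewards()
        r0, r1, f = rm.risk0, rm.risk1, rm.covariates["f"].to_numpy()
        objs = [r0.sum(), r1.sum()]
        for thr in [0.5]:
            for tl, tr_ in itertools.product([0, 1], repeat=2):
                a = np.where(f < thr, tl, tr_)
                objs.append(np.where(a == 1, r1, r0).sum())
        tree = fit_policy_tree(rm, max_depth=1)
        assert policy_objective(tree, rm) == pytest.approx(min(objs))

    def test_tie_breaks_to_no_treatment(self):
        rm = build_rewards([0.3, 0.3], [0.3, 0.3], x=[0.0, 1.0])
        tree = fit_policy_tree(rm, max_depth=2)
        assert tree.root.is_leaf
        assert tree.root.treatment == 0

    def test_minbucket_larger_than_n_errors(self):
        with pytest.raises(ValueError):
            fit_policy_tree(four_patient_rewards(), minbucket=5)

    def test_minbucket_respected(self, rng):
        rm = random_rewards(rng, n=60)
        tree = fit_policy_tree(rm, minbucket=10, max_depth=3)
        a = tree.assign(rm.covariates)
        for leaf in tree.leaves():
            assert leaf.n >= 10

    def test_never_worse_than_constant_policies(self, rng):
        for _ in range(20):
            rm = random_rewards(rng)
            tree = fit_policy_tree(rm, minbucket=5, max_depth=2)
            obj = policy_objective(tree, rm)
            assert obj <= rm.risk0.sum() + 1e-9
            assert obj <= rm.risk1.sum() + 1e-9

    def test_categorical_split(self):
        rm = build_rewards([0.1, 0.1, 0.6, 0.6], [0.4, 0.4, 0.2, 0.2],
                           site=["gastric", "gastric", "nongastric", "nongastric"])
        tree = fit_policy_tree(rm, max_depth=1)
        assert tree.root.feature == "site"
        a = tree.assign(rm.covariates)
        np.testing.assert_array_equal(a, [0, 0, 1, 1])

    def test_lower_treated_risk_expands_treatment(self, rng):
        # shrinking risk1 (larger rho) weakly increases the treated fraction
        rm = random_rewards(rng, n=120)
        fracs = []
        for scale in (1.0, 0.8, 0.6, 0.4):
            rm2 = build_rewards(rm.risk0, rm.risk1 * scale,
                                **{c: rm.covariates[c] for c in rm.covariates})
            tree = fit_policy_tree(rm2, minbucket=10, max_depth=2)
            fracs.append(tree.assign(rm2.covariates).mean())
        assert all(b >= a - 1e-9 for a, b in zip(fracs, fracs[1:]))

    def test_parent_stats_aggregate_children(self, rng):
        rm = random_rewards(rng, n=80)
        tree = fit_policy_tree(rm, minbucket=5, max_depth=3)
        for node in tree.nodes():
            if node.is_leaf:
                continue
            assert node.n == node.left.n + node.right.n
            assert node.sum_r0 == pytest.approx(node.left.sum_r0 + node.right.sum_r0)
            assert node.sum_r1 == pytest.approx(node.left.sum_r1 + node.right.sum_r1)


class TestAssignTreatment:
    def test_single_leaf_treat_all(self):
        leaf = TreeNode(n=1, sum_r0=1.0, sum_r1=0.5, treatment=1)
        tree = PolicyTree(root=leaf, minbucket=1, max_depth=0, covariates=["x"])
        assert assign_treatment(tree, {"x": -99.0}) == 1

    def _gist_style_tree(self):
        # mitotic count >= 10.5 -> treat regardless of other features
        right = TreeNode(n=10, sum_r0=5.0, sum_r1=2.0, depth=1, treatment=1)
        left = TreeNode(n=30, sum_r0=3.0, sum_r1=4.0, depth=1, treatment=0)
        root = TreeNode(n=40, sum_r0=8.0, sum_r1=6.0, feature="mitoses",
                        threshold=10.5, left=left, right=right)
        return PolicyTree(root=root, minbucket=1, max_depth=1,
                          covariates=["mitoses", "size"])

    def test_high_mitotic_count_routes_to_treatment(self):
        tree = self._gist_style_tree()
        assert assign_treatment(tree, {"mitoses": 25.0, "size": 1.0}) == 1
        assert assign_treatment(tree, {"mitoses": 3.0, "size": 99.0}) == 0

    def test_boundary_value_routes_right(self):
        tree = self._gist_style_tree()
        # "equal or greater" goes to the right branch
        assert assign_treatment(tree, {"mitoses": 10.5, "size": 0.0}) == 1
        assert assign_treatment(tree, {"mitoses": 10.4999, "size": 0.0}) == 0

    def test_missing_split_covariate_errors(self):
        tree = self._gist_style_tree()
        with pytest.raises(ValueError, match="mitoses"):
            tree.assign(pd.DataFrame({"size": [1.0]}))


class TestNodeEffects:
    def test_arr_forty_at_high_baseline(self):
        # baseline 80%, relative reduction 50% -> absolute reduction 40%
        rm = build_rewards([0.8, 0.8], [0.4, 0.4], x=[0.0, 1.0])
        tree = fit_policy_tree(rm, max_depth=0)
        eff = node_effects(tree, rm)
        assert eff.iloc[0].arr == pytest.approx(0.40)
        assert eff.iloc[0].rrr == pytest.approx(0.50)

    def test_arr_twenty_at_low_baseline(self):
        rm = build_rewards([0.4, 0.4], [0.2, 0.2], x=[0.0, 1.0])
        eff = node_effects(fit_policy_tree(rm, max_depth=0), rm)
        assert eff.iloc[0].arr == pytest.approx(0.20)
        assert eff.iloc[0].rrr == pytest.approx(0.50)

    def test_no_effect(self):
        rm = build_rewards([0.3], [0.3], x=[0.0])
        eff = node_effects(fit_policy_tree(rm, max_depth=0), rm)
        assert eff.iloc[0].arr == 0.0
        assert eff.iloc[0].rrr == 0.0

    def test_rrr_undefined_at_zero_baseline(self):
        rm = build_rewards([0.0], [0.1], x=[0.0])
        eff = node_effects(fit_policy_tree(rm, max_depth=0), rm)
        assert np.isnan(eff.iloc[0].rrr)

    def test_every_node_reported(self, rng):
        rm = random_rewards(rng, n=60)
        tree = fit_policy_tree(rm, minbucket=5, max_depth=2)
        eff = node_effects(tree, rm)
        assert len(eff) == sum(1 for _ in tree.nodes())
        assert eff.iloc[0].n == rm.n


class TestBruteForce:
    def test_depth_zero_best_constant(self):
        rm = build_rewards([0.1, 0.9], [0.5, 0.5], x=[0.0, 1.0])
        tree = brute_force_policy_tree(rm, depth=0)
        assert tree.root.is_leaf
        assert policy_objective(tree, rm) == pytest.approx(1.0)  # min(1.0, 1.0) tie -> t=0

    def test_four_patient_matches_greedy(self):
        rm = four_patient_rewards()
        greedy = fit_policy_tree(rm, max_depth=1)
        oracle = brute_force_policy_tree(rm, depth=1)
        assert policy_objective(oracle, rm) == pytest.approx(0.6)
        assert policy_objective(greedy, rm) == pytest.approx(
            policy_objective(oracle, rm))

    def test_depth1_greedy_equals_oracle(self, rng):
        for _ in range(15):
            rm = random_rewards(rng, n=40, p=3)
            greedy = fit_policy_tree(rm, minbucket=3, max_depth=1)
            oracle = brute_force_policy_tree(rm, depth=1, minbucket=3)
            assert policy_objective(greedy, rm) == pytest.approx(
                policy_objective(oracle, rm), abs=1e-9)

    def test_depth2_greedy_close_to_oracle(self, rng):
        # covariate-driven rewards with a planted interaction (the regime the
        # fitter targets); pure-noise rewards are checked by the bound above
        from scipy.special import expit

        def structured(rng, n=50):
            x0, x1 = rng.normal(size=n), rng.normal(size=n)
            r0 = expit(x0)
            r1 = np.clip(r0 - 0.3 * (x1 > 0) + 0.05 * rng.normal(size=n), 0, 1)
            return build_rewards(r0, r1, x0=x0, x1=x1)

        ratios = []
        for _ in range(10):
            rm = structured(rng)
            greedy = fit_policy_tree(rm, minbucket=5, max_depth=2)
            oracle = brute_force_policy_tree(rm, depth=2, minbucket=5)
            og, oo = policy_objective(greedy, rm), policy_objective(oracle, rm)
            assert og >= oo - 1e-9
            ratios.append(og / oo)
        assert max(ratios) <= 1.1

    def test_size_guards(self, rng):
        rm = random_rewards(rng, n=250)
        with pytest.raises(InstanceTooLargeError):
            brute_force_policy_tree(rm, depth=1)
        with pytest.raises(InstanceTooLargeError):
            brute_force_policy_tree(random_rewards(rng, n=10), depth=3)


class TestSerialization:
    def test_round_trip_identity(self):
        rm = four_patient_rewards()
        tree = fit_policy_tree(rm, max_depth=1)
        back = PolicyTree.from_json(tree.to_json())
        assert back.to_dict() == tree.to_dict()
        np.testing.assert_array_equal(back.assign(rm.covariates),
                                      tree.assign(rm.covariates))

    def test_round_trip_preserves_objective(self, rng):
        rm = random_rewards(rng, n=70)
        tree = fit_policy_tree(rm, minbucket=5, max_depth=3)
        back = PolicyTree.from_json(tree.to_json())
        assert policy_objective(back, rm) == policy_objective(tree, rm)

    def test_malformed_payload_errors(self):
        with pytest.raises(ValueError, match="malformed"):
            PolicyTree.from_dict({"minbucket": 1})

    def test_ascii_render_golden(self):
        right = TreeNode(n=10, sum_r0=5.0, sum_r1=2.0, depth=1, treatment=1)
        left = TreeNode(n=30, sum_r0=3.0, sum_r1=6.0, depth=1, treatment=0)
        root = TreeNode(n=40, sum_r0=8.0, sum_r1=8.0, feature="mitoses",
                        threshold=10.5, left=left, right=right)
        tree = PolicyTree(root=root, minbucket=1, max_depth=1,
                          covariates=["mitoses"])
        expected = (
            "[mitoses < 10.5] (n=40 p0=0.200 p1=0.200)\n"
            "    |-- treat=0 [n=30 p0=0.100 p1=0.200]\n"
            "    `-- treat=1 [n=10 p0=0.500 p1=0.200]"
        )
        assert tree.render() == expected
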