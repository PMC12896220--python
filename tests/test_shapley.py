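"""Shapley attribution: the exact enumerator against the game-theoretic
axioms (efficiency, symmetry, dummy, additivity), the permutation sampler
against the exact oracle, and the summary/subgroup machinery."""

import numpy as np
import pytest

from glnet.shapley import (
    AttributionResult,
    CoalitionValue,
    attribute_dataset,
    beeswarm_export,
    exact_shapley,
    global_summary,
    parent_factor,
    sampled_shapley,
    subgroup_attribution,
    value_function,
)


def additive(rows):
    return rows.sum(axis=1)


def product2(rows):
    return rows[:, 0] * rows[:, 1]


class TestValueFunction:
    def test_full_coalition_is_model_at_instance(self):
        x = np.array([1.0, 2.0, 3.0])
        bg = np.random.default_rng(0).normal(size=(5, 3))
        v = value_function(additive, x, [0, 1, 2], bg)
        assert v == pytest.approx(6.0)

    def test_empty_coalition_is_background_mean(self):
        x = np.array([1.0, 2.0, 3.0])
        bg = np.random.default_rng(1).normal(size=(7, 3))
        assert value_function(additive, x, [], bg) \
            == pytest.approx(additive(bg).mean())

    def test_constant_model_independent_of_coalition(self):
        const = lambda rows: np.full(rows.shape[0], 0.4)
        x = np.ones(4)
        bg = np.zeros((3, 4))
        vals = [value_function(const, x, S, bg)
                for S in ([], [0], [1, 2], [0, 1, 2, 3])]
        assert np.ptp(vals) == 0.0

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError):
            CoalitionValue(additive, np.ones(3), np.zeros((0, 3)))


class TestExactShapley:
    def test_additivity_axiom(self):
        vf = CoalitionValue(additive, np.array([3.0, 5.0]), np.zeros((1, 2)))
        np.testing.assert_allclose(exact_shapley(vf), [3.0, 5.0], atol=1e-12)

    def test_product_model_hand_enumeration(self):
        # v({})=0, v({1})=0, v({2})=0, v({1,2})=1 -> phi = (0.5, 0.5)
        vf = CoalitionValue(product2, np.array([1.0, 1.0]), np.zeros((1, 2)))
        np.testing.assert_allclose(exact_shapley(vf), [0.5, 0.5], atol=1e-12)

    def test_dummy_axiom(self):
        f = lambda rows: rows[:, 0] * 2.0  # ignores feature 1
        vf = CoalitionValue(f, np.array([1.5, 9.9]),
                            np.random.default_rng(0).normal(size=(4, 2)))
        phi = exact_shapley(vf)
        assert phi[1] == pytest.approx(0.0, abs=1e-12)

    def test_symmetry_axiom(self):
        f = lambda rows: rows[:, 0] + rows[:, 1] + rows[:, 0] * rows[:, 1]
        vf = CoalitionValue(f, np.array([2.0, 2.0]), np.zeros((1, 2)))
        phi = exact_shapley(vf)
        assert phi[0] == pytest.approx(phi[1], abs=1e-9)

    def test_efficiency_axiom_on_random_models(self):
        rng = np.random.default_rng(3)
        d = 6
        W = rng.normal(size=(d, d))

        def f(rows):
            z = rows @ W
            return np.tanh(z).sum(axis=1)

        x = rng.normal(size=d)
        bg = rng.normal(size=(8, d))
        vf = CoalitionValue(f, x, bg)
        phi = exact_shapley(vf)
        assert phi.sum() + vf([]) == pytest.approx(float(f(x[None])[0]), abs=1e-6)

    def test_large_d_refused(self):
        vf = CoalitionValue(additive, np.ones(20), np.zeros((1, 20)))
        with pytest.raises(ValueError, match="sampled_shapley"):
            exact_shapley(vf)


@pytest.fixture(scope="module")
def toy_problem():
    rng = np.random.default_rng(7)
    d = 8
    W = rng.normal(size=d)
    V = rng.normal(size=(d, d)) / d

    def f(rows):
        # non-quadratic: antithetic pairs do not cancel exactly, so the
        # sampler has genuine Monte-Carlo variance
        return np.tanh(rows @ W) + np.tanh(((rows @ V) * rows).sum(axis=1))

    x = rng.normal(size=d)
    bg = rng.normal(size=(6, d))
    return CoalitionValue(f, x, bg)


class TestSampledShapley:
    def test_estimate_within_three_mc_ses_of_exact(self, toy_problem):
        exact = exact_shapley(toy_problem)
        phi, se = sampled_shapley(toy_problem, M=300, seed=0)
        assert np.all(np.abs(phi - exact) <= 3 * se + 1e-12)

    def test_additive_model_exact_at_single_permutation(self):
        vf = CoalitionValue(additive, np.array([1.0, -2.0, 0.5]),
                            np.random.default_rng(1).normal(size=(5, 3)) * 0.0)
        phi, _ = sampled_shapley(vf, M=1, seed=5)
        np.testing.assert_allclose(phi, [1.0, -2.0, 0.5], atol=1e-12)

    def test_seed_reproducibility(self, toy_problem):
        a, _ = sampled_shapley(toy_problem, M=20, seed=9)
        b, _ = sampled_shapley(toy_problem, M=20, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_estimator_unbiased_across_seeds(self, toy_problem):
        """Mean over many independent estimates approaches the exact value."""
        exact = exact_shapley(toy_problem)
        estimates = np.array([sampled_shapley(toy_problem, M=8, seed=s)[0]
                              for s in range(50)])
        mean = estimates.mean(axis=0)
        se = estimates.std(axis=0, ddof=1) / np.sqrt(50)
        assert np.all(np.abs(mean - exact) <= 3 * se + 1e-9)


class TestAttributeDataset:
    def test_exact_mode_satisfies_per_row_efficiency(self):
        rng = np.random.default_rng(0)
        W = rng.normal(size=12)
        f = lambda rows: np.tanh(rows @ W)
        rows = rng.normal(size=(10, 12))
        bg = rng.normal(size=(5, 12))
        res = attribute_dataset(f, rows, bg, [f"c{i}" for i in range(12)])
        assert res.estimator == "exact"
        totals = res.base_value + res.phi.sum(axis=1)
        np.testing.assert_allclose(totals, f(rows), atol=1e-6)

    def test_constant_column_gets_zero_phi(self):
        rng = np.random.default_rng(1)
        f = lambda rows: rows[:, 0]
        rows = rng.normal(size=(6, 5))
        rows[:, 3] = 2.0
        bg = rows.copy()
        res = attribute_dataset(f, rows, bg, list("abcde"))
        np.testing.assert_allclose(res.phi[:, 3], 0.0, atol=1e-12)

    def test_mc_error_shrinks_with_more_permutations(self):
        rng = np.random.default_rng(2)
        d = 18  # force permutation mode
        W = rng.normal(size=(d, d)) / d
        f = lambda rows: ((rows @ W) * rows).sum(axis=1)
        rows = rng.normal(size=(3, d))
        bg = rng.normal(size=(4, d))
        cols = [f"c{i}" for i in range(d)]
        r1 = attribute_dataset(f, rows, bg, cols, M=20, seed=0)
        r2 = attribute_dataset(f, rows, bg, cols, M=80, seed=0)
        assert r2.estimator == "permutation"
        assert r2.standard_errors.mean() < r1.standard_errors.mean()


class TestSummaries:
    def _result(self):
        rng = np.random.default_rng(4)
        phi = rng.normal(size=(30, 3)) * np.array([3.0, 1.0, 0.1])
        return AttributionResult(phi, 0.5, ["big", "mid", "tiny"], "exact")

    def test_ranking_orders_by_mean_abs_phi(self):
        df = global_summary(self._result())
        assert list(df["column"]) == ["big", "mid", "tiny"]
        assert list(df["rank"]) == [1, 2, 3]

    def test_ranking_invariant_to_row_order(self):
        res = self._result()
        perm = np.random.default_rng(0).permutation(res.phi.shape[0])
        shuffled = AttributionResult(res.phi[perm], res.base_value,
                                     res.columns, res.estimator)
        assert list(global_summary(res)["column"]) \
            == list(global_summary(shuffled)["column"])

    def test_all_zero_phi_warns(self):
        res = AttributionResult(np.zeros((4, 2)), 0.1, ["a", "b"], "exact")
        with pytest.warns(UserWarning, match="zero"):
            global_summary(res)

    def test_beeswarm_long_format(self):
        res = self._result()
        values = np.random.default_rng(1).normal(size=res.phi.shape)
        long = beeswarm_export(res, values)
        assert len(long) == res.phi.size
        assert set(long.columns) == {"sample", "factor", "phi", "value"}

    def test_parent_factor_mapping(self):
        assert parent_factor("city=Delhi") == "city"
        assert parent_factor("age") == "age"


class TestSubgroup:
    def _setup(self):
        rng = np.random.default_rng(9)
        n = 80
        phi = rng.normal(size=(n, 2))
        values = rng.normal(size=(n, 2))
        res = AttributionResult(phi, 0.0, ["x", "y"], "exact")
        return res, values

    def test_all_rows_filter_matches_global_summary(self):
        res, values = self._setup()
        summ = subgroup_attribution(res, values, np.ones(80, dtype=bool),
                                    "everyone")
        global_rank = global_summary(res, values)
        assert list(summ.ranking["column"]) == list(global_rank["column"])
        np.testing.assert_allclose(summ.ranking["mean_abs_phi"],
                                   global_rank["mean_abs_phi"])

    def test_empty_subgroup_rejected(self):
        res, values = self._setup()
        with pytest.raises(ValueError, match="empty"):
            subgroup_attribution(res, values, np.zeros(80, dtype=bool), "none")

    def test_small_subgroup_rejected(self):
        res, values = self._setup()
        mask = np.zeros(80, dtype=bool)
        mask[:5] = True
        with pytest.raises(ValueError, match="min_size"):
            subgroup_attribution(res, values, mask, "tiny")

    def test_partition_of_subgroups_covers_all_rows(self):
        res, values = self._setup()
        mask = np.zeros(80, dtype=bool)
        mask[:40] = True
        a = subgroup_attribution(res, values, mask, "first")
        b = subgroup_attribution(res, values, ~mask, "second")
        assert a.n + b.n == 80


def test_background_overlapping_evaluation_rows_warns():
    rng = np.random.default_rng(3)
    f = lambda rows: rows.sum(axis=1)
    rows = rng.normal(size=(2, 4))
    test_rows = rng.normal(size=(6, 4))
    bg = np.vstack([test_rows[2], rng.normal(size=4)])
    with pytest.warns(UserWarning, match="leaks"):
        attribute_dataset(f, rows, bg, list("abcd"),
                          evaluation_rows=test_rows)
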