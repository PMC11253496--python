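"""Permutation engine: plans, outcome shuffling, null-matrix assembly."""

import numpy as np
import pytest

import minpverse as mv
from minpverse import assoc
from minpverse.permutation import PermutationPlan, exhaustive_relabeling_orderings


class TestPlan:
    def test_plan_is_reproducible_from_seed(self):
        a = PermutationPlan.random(30, 10, seed=4)
        b = PermutationPlan.random(30, 10, seed=4)
        np.testing.assert_array_equal(a.orderings, b.orderings)
        c = PermutationPlan.random(30, 10, seed=5)
        assert not np.array_equal(a.orderings, c.orderings)

    def test_every_ordering_is_a_bijection(self):
        plan = PermutationPlan.random(25, 40, seed=0)
        for row in plan.orderings:
            np.testing.assert_array_equal(np.sort(row), np.arange(25))

    def test_invalid_orderings_rejected(self):
        with pytest.raises(mv.ConfigurationError, match="bijection"):
            PermutationPlan(orderings=np.array([[0, 0, 1]]))

    def test_exhaustive_relabelings_cover_all_distinct_outcomes(self):
        outcome = np.array([1, 1, 1, 0, 0, 0])
        orderings = exhaustive_relabeling_orderings(outcome)
        assert orderings.shape == (20, 6)  # C(6,3)
        relabelings = {tuple(outcome[row]) for row in orderings}
        assert len(relabelings) == 20
        assert all(sum(r) == 3 for r in relabelings)

    def test_exhaustive_relabelings_guard_against_blowup(self):
        with pytest.raises(mv.ConfigurationError, match="exceed"):
            exhaustive_relabeling_orderings(np.tile([0, 1], 20), limit=100)


class TestPermuteOutcome:
    def test_identity_ordering_changes_nothing(self):
        data = mv.generate_part1_null(40, seed=1)
        same = mv.permute_outcome(data, np.arange(40))
        np.testing.assert_array_equal(same.outcome_vector, data.outcome_vector)

    def test_outcome_multiset_is_preserved(self, rng):
        data = mv.generate_part1_null(40, seed=2)
        permuted = mv.permute_outcome(data, rng.permutation(40))
        assert sorted(permuted.outcome_vector) == sorted(data.outcome_vector)
        # exposure side untouched
        assert permuted.measurements is data.measurements or permuted.measurements.equals(
            data.measurements
        )

    def test_non_bijections_rejected(self):
        data = mv.generate_part1_null(10, seed=3)
        with pytest.raises(mv.ConfigurationError):
            mv.permute_outcome(data, np.zeros(10, int))
        with pytest.raises(mv.ConfigurationError):
            mv.permute_outcome(data, np.arange(9))


@pytest.fixture(scope="module")
def small_data():
    return mv.generate_part1_null(60, seed=13)


class TestBuildNull:
    def test_cached_equals_naive_bitwise(self, small_data, glm_grid):
        cached = mv.build_null(small_data, glm_grid, B=15, seed=5, cache=True)
        naive = mv.build_null(small_data, glm_grid, B=15, seed=5, cache=False)
        np.testing.assert_array_equal(cached.matrix, naive.matrix)

    def test_single_permutation_row_matches_manual_run(self, small_data, glm_grid):
        null = mv.build_null(small_data, glm_grid, B=1, seed=8)
        plan = PermutationPlan.random(
            small_data.n, 1, seed=mv.permutation.int_seed(8, "permutation")
        )
        manual = mv.run_grid(
            mv.permute_outcome(small_data, plan.orderings[0]), glm_grid, seed=8
        )
        np.testing.assert_array_equal(null.matrix[0], manual.p)

    def test_identity_ordering_reproduces_the_raw_profile(self, small_data, glm_grid):
        raw = mv.run_grid(small_data, glm_grid, seed=4)
        null = mv.build_null(
            small_data, glm_grid, seed=4,
            orderings=np.arange(small_data.n)[None, :],
        )
        np.testing.assert_array_equal(null.matrix[0], raw.p)

    def test_exposures_are_invariant_under_outcome_permutation(
        self, small_data, glm_grid, rng
    ):
        permuted = mv.permute_outcome(small_data, rng.permutation(small_data.n))
        ev1 = mv.GridEvaluator(small_data, glm_grid, seed=6)
        ev2 = mv.GridEvaluator(permuted, glm_grid, seed=6)
        for spec in glm_grid:
            e1, e2 = ev1.exposure_for(spec), ev2.exposure_for(spec)
            np.testing.assert_array_equal(e1.values, e2.values)
            np.testing.assert_array_equal(e1.keep, e2.keep)

    def test_one_shared_shuffle_per_row_across_strategies(
        self, small_data, glm_grid, monkeypatch
    ):
        # instrument the test stage and assert every strategy of a row saw
        # the same permuted outcome (restricted to its analysis set)
        seen = []
        original = assoc.batch_pvalues

        def spy(method, exposure, outcomes, cutoffs=(200.0, 250.0)):
            seen.append(np.asarray(outcomes).copy())
            return original(method, exposure, outcomes, cutoffs)

        monkeypatch.setattr(assoc, "batch_pvalues", spy)
        mv.build_null(small_data, glm_grid, B=7, seed=3)
        # keep the B=7 permutation batches (raw-profile calls have B=1)
        batches = [s for s in seen if s.shape[0] == 7]
        full = [s for s in batches if s.shape[1] == small_data.n]
        assert full, "expected at least one full-length outcome matrix"
        for s in full[1:]:
            np.testing.assert_array_equal(s, full[0])

    def test_row_minima_are_stochastically_below_uniform(self, small_data, glm_grid):
        # with m > 1 jointly tested strategies the minimal p-value is
        # stochastically smaller than a single uniform p-value
        null = mv.build_null(small_data, glm_grid, B=120, seed=9)
        minima = null.row_minima
        assert np.nanmean(minima) < 0.45

    def test_strategies_failing_most_permutations_abort(self, small_data, glm_grid, monkeypatch):
        original = assoc.batch_pvalues

        def flaky(method, exposure, outcomes, cutoffs=(200.0, 250.0)):
            p, fail = original(method, exposure, outcomes, cutoffs)
            if method == "binary_200_fisher" and outcomes.shape[0] > 1:
                for b in range(6):  # 6 of 10 permutations > 50%
                    p[b] = np.nan
                    fail[b] = "synthetic failure"
            return p, fail

        monkeypatch.setattr(assoc, "batch_pvalues", flaky)
        with pytest.raises(mv.MinpverseError, match="permutations"):
            mv.build_null(small_data, glm_grid, B=10, seed=2)

    def test_beta_distribution_of_minima_for_independent_uniform_columns(self, rng):
        # closed-form check: the minimum of m independent uniforms is
        # Beta(1, m); feed stub uniform columns straight into the container
        from scipy.stats import kstest

        B, m = 4000, 6
        null = mv.PermutationNull(
            matrix=rng.random((B, m)), strategy_ids=tuple(f"s{i}" for i in range(m))
        )
        stat = kstest(null.row_minima, lambda q: 1 - (1 - q) ** m)
        assert stat.pvalue > 0.01


def test_null_save_load_roundtrip(tmp_path, small_data, glm_grid):
    null = mv.build_null(small_data, glm_grid, B=5, seed=1)
    null.save(tmp_path / "null.csv", tmp_path / "null.json")
    back = mv.PermutationNull.load(tmp_path / "null.csv", tmp_path / "null.json")
    np.testing.assert_allclose(back.matrix, null.matrix, rtol=1e-12)
    assert back.strategy_ids == null.strategy_ids
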