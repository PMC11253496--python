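"""Multiplicity adjustments: counting semantics, classical formulas,
monotonicity, and the selective report."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import minpverse as mv


def _profile(p, ids=None):
    ids = ids or tuple(f"s{i}" for i in range(len(p)))
    p = np.asarray(p, float)
    failed = {ids[i]: "failed" for i in np.flatnonzero(np.isnan(p))}
    return mv.PValueProfile(p=p, strategy_ids=ids, failed=failed)


def _null(matrix, ids=None):
    matrix = np.asarray(matrix, float)
    ids = ids or tuple(f"s{i}" for i in range(matrix.shape[1]))
    return mv.PermutationNull(matrix=matrix, strategy_ids=ids)


pvec = st.lists(st.floats(0.0, 1.0), min_size=1, max_size=12).map(np.array)


class TestMinP:
    def test_direct_counting_on_a_toy_matrix(self):
        # row minima are 0.2 and 0.3: no minimum is <= 0.10, both are <= 0.35
        raw = _profile([0.10, 0.35])
        null = _null([[0.2, 0.9], [0.3, 0.8]])
        res = mv.adjust_minp(raw, null)
        np.testing.assert_array_equal(res.adjusted, [0.0, 1.0])

    def test_single_hypothesis_reduces_to_the_permutation_pvalue(self, rng):
        column = rng.random((200, 1))
        raw = _profile([0.07])
        res = mv.adjust_minp(raw, _null(column))
        assert res.adjusted[0] == (column[:, 0] <= 0.07).mean()

    def test_ties_count_toward_the_numerator(self):
        raw = _profile([0.25, 0.8])
        null = _null([[0.25, 0.9], [0.5, 0.9]])
        assert mv.adjust_minp(raw, null).adjusted[0] == 0.5  # the tie at 0.25

    def test_smoothed_variant_never_returns_zero(self):
        raw = _profile([0.001])
        null = _null(np.full((99, 1), 0.5))
        assert mv.adjust_minp(raw, null).adjusted[0] == 0.0
        assert mv.adjust_minp(raw, null, smoothed=True).adjusted[0] == pytest.approx(
            1 / 100
        )

    def test_dominates_bonferroni_for_independent_uniforms(self, rng):
        # with dependence-free columns minP still cannot exceed Bonferroni
        # beyond Monte-Carlo noise
        B, m = 4000, 6
        null = _null(rng.random((B, m)))
        raw = _profile([0.002, 0.01, 0.05, 0.1, 0.3, 0.7])
        minp = mv.adjust_minp(raw, null).adjusted
        bonf = mv.adjust_bonferroni(raw).adjusted
        assert (minp <= bonf + 3 * np.sqrt(0.25 / B)).all()

    def test_alignment_errors(self, rng):
        raw = _profile([0.1, 0.2])
        with pytest.raises(mv.AlignmentError):
            mv.adjust_minp(raw, _null(rng.random((10, 3))))
        with pytest.raises(mv.AlignmentError):
            mv.adjust_minp(raw, _null(rng.random((10, 2)), ids=("x", "y")))

    def test_failed_strategies_stay_nan_but_minima_use_the_rest(self):
        raw = _profile([0.02, np.nan, 0.5])
        matrix = np.array([[0.1, np.nan, 0.9], [0.6, np.nan, 0.7]])
        res = mv.adjust_minp(raw, _null(matrix))
        assert np.isnan(res.adjusted[1])
        np.testing.assert_array_equal(res.adjusted[[0, 2]], [0.0, 0.5])


class TestClassicalAdjustments:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ([0.01, 0.30], [0.02, 0.60]),
            ([0.60, 0.90], [1.0, 1.0]),
            ([0.04], [0.04]),  # single test: identity
        ],
    )
    def test_bonferroni_formula(self, raw, expected):
        res = mv.adjust_bonferroni(_profile(raw))
        np.testing.assert_allclose(res.adjusted, expected)

    def test_holm_step_down_example(self):
        res = mv.adjust_holm(_profile([0.01, 0.02, 0.50]))
        np.testing.assert_allclose(res.adjusted, [0.03, 0.04, 0.50])

    def test_holm_single_test_is_identity(self):
        np.testing.assert_allclose(mv.adjust_holm(_profile([0.2])).adjusted, [0.2])

    @given(pvec)
    def test_holm_matches_independent_step_down_oracle(self, p):
        res = mv.adjust_holm(_profile(p)).adjusted
        order = np.argsort(p, kind="stable")
        m = len(p)
        running, expect = 0.0, np.empty(m)
        for rank, idx in enumerate(order):
            running = max(running, min((m - rank) * p[idx], 1.0))
            expect[idx] = running
        np.testing.assert_allclose(res, expect, rtol=1e-12)

    @given(pvec)
    def test_holm_minimum_equals_bonferroni_minimum(self, p):
        prof = _profile(p)
        holm = mv.adjust_holm(prof).adjusted
        bonf = mv.adjust_bonferroni(prof).adjusted
        assert holm[prof.argmin] == pytest.approx(bonf[prof.argmin], rel=1e-12)

    def test_bonferroni_uses_the_effective_family_size(self):
        res = mv.adjust_bonferroni(_profile([0.1, np.nan, 0.3]))
        np.testing.assert_allclose(res.adjusted[[0, 2]], [0.2, 0.6])


class TestMonotonicity:
    @given(pvec)
    def test_no_method_reorders_the_raw_profile(self, p):
        prof = _profile(p)
        null = _null(np.random.default_rng(5).random((50, len(p))))
        for adjusted in (
            mv.adjust_minp(prof, null).adjusted,
            mv.adjust_bonferroni(prof).adjusted,
            mv.adjust_holm(prof).adjusted,
        ):
            order = np.argsort(p, kind="stable")
            assert (np.diff(adjusted[order]) >= -1e-12).all()


class TestSelectAndReport:
    def _results(self, p, null_matrix):
        prof = _profile(p)
        null = _null(null_matrix, ids=prof.strategy_ids)
        return prof, [
            mv.adjust_minp(prof, null),
            mv.adjust_bonferroni(prof),
            mv.adjust_holm(prof),
        ]

    def test_small_raw_minimum_can_be_unremarkable_under_the_null(self, rng, grid48):
        # a raw 0.0034 whose minP-adjusted value is 0.28 is reported as not
        # significant: a p-value that small arises ~28% of the time when
        # nothing is going on
        minima = np.concatenate([np.full(28, 0.001), np.full(72, 0.5)])
        matrix = np.tile(minima[:, None], (1, 48))
        p = np.full(48, 0.6)
        p[5] = 0.0034
        prof = mv.PValueProfile(p=p, strategy_ids=grid48.ids, failed={})
        null = mv.PermutationNull(matrix=matrix, strategy_ids=grid48.ids)
        res = [mv.adjust_minp(prof, null), mv.adjust_bonferroni(prof)]
        report = mv.select_and_report(res, grid48, alpha=0.05)
        assert report.raw_min == 0.0034
        assert report.adjusted_min["minp"] == pytest.approx(0.28)
        assert not report.significant["minp"]
        assert "not significant" in report.to_text()

    def test_degenerate_profile_of_ones(self, grid48):
        prof = mv.PValueProfile(
            p=np.ones(48), strategy_ids=grid48.ids, failed={}
        )
        null = mv.PermutationNull(
            matrix=np.full((10, 48), 1.0), strategy_ids=grid48.ids
        )
        report = mv.select_and_report(
            [mv.adjust_minp(prof, null), mv.adjust_bonferroni(prof)],
            grid48,
            alpha=0.05,
        )
        assert not any(report.significant.values())

    def test_single_strategy_needs_no_adjustment(self, rng):
        grid = mv.SpecificationGrid((mv.default_grid()[0],))
        prof = mv.PValueProfile(p=np.array([0.04]), strategy_ids=grid.ids, failed={})
        null = mv.PermutationNull(
            matrix=rng.random((500, 1)), strategy_ids=grid.ids
        )
        report = mv.select_and_report(
            [
                mv.adjust_minp(prof, null),
                mv.adjust_bonferroni(prof),
                mv.adjust_holm(prof),
            ],
            grid,
            alpha=0.05,
        )
        assert report.significant["bonferroni"] and report.significant["holm"]
        assert report.adjusted_min["minp"] == pytest.approx(0.04, abs=0.03)

    def test_all_failed_profile_is_an_explicit_error(self, grid48):
        prof = mv.PValueProfile(
            p=np.full(48, np.nan),
            strategy_ids=grid48.ids,
            failed={sid: "x" for sid in grid48.ids},
        )
        with pytest.raises(mv.DegenerateDataError):
            mv.adjust_bonferroni(prof)

    def test_mismatched_profiles_rejected(self, grid48):
        a = _profile([0.1, 0.2], ids=("x", "y"))
        b = _profile([0.3, 0.2], ids=("x", "y"))
        grid = mv.SpecificationGrid(mv.default_grid().strategies[:2])
        results = [mv.adjust_bonferroni(a), mv.adjust_bonferroni(b)]
        with pytest.raises(mv.AlignmentError):
            mv.select_and_report(results, grid, alpha=0.05)
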