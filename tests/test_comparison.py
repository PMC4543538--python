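"""Discard test, flip bookkeeping, cross-condition scoring, ranking."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tfactivity as tfa
from conftest import make_posterior


def brute_force_constant_fits(mean, sd, z=2.0, step=1e-3):
    """Search oracle for the discard test, independent of interval logic.

    Minimizes f(k) = max_t(|m_t - k| - z*sd_t) — convex and piecewise
    linear — by a coarse grid followed by bounded refinement around the
    best grid point; a constant fits iff the minimum is <= 0.
    """
    from scipy.optimize import minimize_scalar

    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)

    def f(k):
        return float(np.max(np.abs(mean - k) - z * sd))

    lo = mean.min() - 3 * sd.max()
    hi = mean.max() + 3 * sd.max()
    grid = np.arange(lo, hi + step, step)
    best = grid[np.argmin([f(k) for k in grid])]
    res = minimize_scalar(f, bounds=(best - step, best + step),
                          method="bounded",
                          options={"xatol": 1e-12})
    return min(res.fun, f(best)) <= 1e-10


class TestDiscardTest:
    def test_zero_profile_always_discarded(self):
        assert tfa.is_constant_within_errorbars(np.zeros(6),
                                                np.full(6, 0.01))

    def test_constant_profile_always_discarded(self):
        assert tfa.is_constant_within_errorbars(np.full(6, 5.0),
                                                np.full(6, 0.01))

    def test_clear_excursion_retained(self):
        # bands around 3 and -3 cannot share a constant at z=2, sd=0.5
        m = np.array([0, 3, -3, 0, 0, 0.0])
        assert not tfa.is_constant_within_errorbars(m, np.full(6, 0.5))

    def test_wide_bars_swallow_excursion(self):
        m = np.array([0, 3, -3, 0, 0, 0.0])
        assert tfa.is_constant_within_errorbars(m, np.full(6, 2.0))

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError):
            tfa.is_constant_within_errorbars([0, 1], [0.1])
        with pytest.raises(ValueError):
            tfa.is_constant_within_errorbars([0, 1], [0.1, 0.0])

    def test_agrees_with_grid_search_oracle(self):
        rng = np.random.default_rng(123)
        for _ in range(1000):
            n = rng.integers(2, 8)
            m = rng.normal(0, 1.5, n)
            s = rng.uniform(0.05, 1.0, n)
            assert tfa.is_constant_within_errorbars(m, s) == \
                brute_force_constant_fits(m, s)


class TestCompareConditions:
    def test_placeholder_for_one_sided_response(self):
        a = make_posterior([[0, 3, -3, 0, 0, 0]], [[0.5] * 6], condition="A")
        b = make_posterior([[0, 0, 0, 0, 0, 0]], [[1.0] * 6], condition="B")
        (score,) = tfa.compare_conditions(a, b)
        assert score.status == "a_only"
        assert score.score == 2
        (rev,) = tfa.compare_conditions(b, a)
        assert rev.status == "b_only" and rev.score == 2

    def test_negated_profile_scores_one(self):
        m = np.array([[0, 2, 4, 2, 0, -2.0]])
        a = make_posterior(m, np.full((1, 6), 0.1))
        b = make_posterior(-m, np.full((1, 6), 0.1))
        (score,) = tfa.compare_conditions(a, b)
        assert score.status == "both_retained"
        assert score.score == pytest.approx(1.0)

    def test_hand_computed_pearson(self):
        # direct covariance formula over the six pairs: r = 0.5 /
        # sqrt(17.5 * 2.8333) = 0.071007
        ma = np.array([0, 1, 2, 3, 4, 5.0])
        mb = np.array([0, 1, 0, -1, 0, 1.0])
        cov = np.mean((ma - ma.mean()) * (mb - mb.mean()))
        oracle = abs(cov / (ma.std() * mb.std()))
        a = make_posterior([ma], np.full((1, 6), 0.05))
        b = make_posterior([mb], np.full((1, 6), 0.05))
        (score,) = tfa.compare_conditions(a, b, include_reference_time=True)
        assert score.score == pytest.approx(oracle, abs=1e-12)
        assert score.score == pytest.approx(0.0710072, abs=1e-6)

    def test_both_discarded_has_no_score(self):
        a = make_posterior([[0, 0.1, 0, 0.1, 0, 0]], [[1.0] * 6])
        b = make_posterior([[0, 0, 0.1, 0, 0.1, 0]], [[1.0] * 6])
        (score,) = tfa.compare_conditions(a, b)
        assert score.status == "both_discarded"
        assert score.score is None

    def test_symmetry_under_condition_swap(self):
        rng = np.random.default_rng(9)
        mean_a = rng.normal(0, 2, size=(6, 6))
        mean_b = rng.normal(0, 2, size=(6, 6))
        a = make_posterior(mean_a, np.full((6, 6), 0.3), condition="A")
        b = make_posterior(mean_b, np.full((6, 6), 0.3), condition="B")
        ab = tfa.compare_conditions(a, b)
        ba = tfa.compare_conditions(b, a)
        swap = {"a_only": "b_only", "b_only": "a_only"}
        for x, y in zip(ab, ba):
            assert y.status == swap.get(x.status, x.status)
            if x.score is None:
                assert y.score is None
            else:
                assert y.score == pytest.approx(x.score)

    def test_flip_leaves_scores_unchanged(self):
        rng = np.random.default_rng(4)
        mean_a = rng.normal(0, 2, size=(4, 6))
        mean_b = rng.normal(0, 2, size=(4, 6))
        a = make_posterior(mean_a, np.full((4, 6), 0.2))
        b = make_posterior(mean_b, np.full((4, 6), 0.2))
        base = tfa.compare_conditions(a, b)
        flipped = tfa.compare_conditions(a.flip(a.tf_ids[1]), b)
        for x, y in zip(base, flipped):
            assert x.status == y.status
            if x.score is not None:
                assert y.score == pytest.approx(x.score)

    def test_mismatched_time_grids_raise(self):
        a = make_posterior([[0, 1, 2]], [[0.1] * 3], times=[0, 10, 20])
        b = make_posterior([[0, 1, 2]], [[0.1] * 3], times=[0, 10, 40])
        with pytest.raises(ValueError, match="time grids"):
            tfa.compare_conditions(a, b)

    def test_zero_variance_retained_profile_is_anomalous(self):
        # non-constant only through t=0, constant over the scored points
        a = make_posterior([[0, 5, 5, 5, 5, 5.0]], [[0.01] * 6])
        b = make_posterior([[0, 1, 2, 3, 4, 5.0]], [[0.01] * 6])
        (score,) = tfa.compare_conditions(a, b)
        assert score.status == "both_retained"
        assert score.anomalous and np.isnan(score.score)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_scores_always_in_range(self, seed):
        rng = np.random.default_rng(seed)
        mean_a = rng.normal(0, 2, size=(3, 6))
        mean_b = rng.normal(0, 2, size=(3, 6))
        a = make_posterior(mean_a, rng.uniform(0.05, 1.5, (3, 6)))
        b = make_posterior(mean_b, rng.uniform(0.05, 1.5, (3, 6)))
        for rec in tfa.compare_conditions(a, b):
            if rec.status == "both_discarded":
                assert rec.score is None
            elif rec.status in ("a_only", "b_only"):
                assert rec.score == 2
            elif not rec.anomalous:
                assert 0.0 <= rec.score <= 1.0


class TestRankTFs:
    def _score(self, tf, status, score):
        return tfa.ComparisonScore(tf_id=tf, condition_a="A",
                                   condition_b="B", status=status,
                                   score=score)

    def test_one_tf_per_partition(self):
        scores = [self._score("TFa", "both_retained", 0.95),
                  self._score("TFb", "both_retained", 0.1),
                  self._score("TFc", "a_only", 2.0)]
        parts = tfa.rank_tfs(scores)
        assert [r.tf_id for r in parts["concordant"]] == ["TFa"]
        assert [r.tf_id for r in parts["discordant"]] == ["TFb"]
        assert [r.tf_id for r in parts["condition_specific"]] == ["TFc"]
        assert not parts["unresponsive"]

    def test_all_discarded(self):
        scores = [self._score(f"TF{i}", "both_discarded", None)
                  for i in range(3)]
        parts = tfa.rank_tfs(scores)
        assert len(parts["unresponsive"]) == 3
        assert all(not parts[k] for k in parts if k != "unresponsive")

    def test_ties_break_lexicographically(self):
        scores = [self._score("TFz", "both_retained", 0.9),
                  self._score("TFa", "both_retained", 0.9)]
        parts = tfa.rank_tfs(scores)
        assert [r.tf_id for r in parts["concordant"]] == ["TFa", "TFz"]

    def test_placeholder_never_averaged(self):
        import pandas as pd
        scores = [self._score("TFa", "both_retained", 0.5),
                  self._score("TFb", "a_only", 2.0)]
        frame = tfa.comparison_frame(scores)
        retained = frame[frame["status"] == "both_retained"]
        assert retained["score"].mean() == pytest.approx(0.5)


class TestFlipProfile:
    def test_module_level_flip_delegates(self, recovery_fit):
        tf = recovery_fit.tf_ids[0]
        a = tfa.flip_profile(recovery_fit, tf)
        np.testing.assert_allclose(a.activity_mean[0],
                                   -recovery_fit.activity_mean[0])
        np.testing.assert_allclose(a.activity_sd, recovery_fit.activity_sd)
        assert tf in a.flipped

    def test_unknown_tf_raises(self, recovery_fit):
        with pytest.raises(KeyError):
            tfa.flip_profile(recovery_fit, "no-such-tf")
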