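"""Psychometric ML fitting, the zero-bias likelihood-ratio test, pooling
and group statistics."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import optimize

from hybridpsych import (
    LOG_RATIO_LEVELS,
    ObserverModel,
    ParameterBounds,
    cohens_d_from_t,
    code_response,
    fit_psychometric,
    generate_session,
    group_bias_stats,
    lr_test_bias,
    pool_categorical,
    profile_ci_mu,
    psychometric_function,
    records_to_frame,
    simulate_trials,
)
from hybridpsych.design_io import Condition
from hybridpsych.psychometrics import (
    DegenerateStatisticsError,
    negative_log_likelihood,
)
from hybridpsych.simulated_observer import simulate_binomial_counts

NO_RATES = ParameterBounds(gamma=(0.0, 0.0), lam=(0.0, 0.0))


def _nelder_mead_oracle(x, k, n):
    """Independent 2-parameter oracle: coarse exhaustive grid over (mu, sigma)
    with gamma = lambda = 0, refined by derivative-free simplex search."""
    best = None
    for mu, sigma in itertools.product(
        np.linspace(min(x) - 1, max(x) + 1, 61), np.geomspace(0.05, 10, 61)
    ):
        val = negative_log_likelihood((mu, sigma, 0.0, 0.0), x, k, n)
        if best is None or val < best[0]:
            best = (val, mu, sigma)
    res = optimize.minimize(
        lambda t: negative_log_likelihood((t[0], t[1], 0.0, 0.0), x, k, n),
        [best[1], best[2]],
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000},
    )
    return -res.fun


class TestFitPsychometric:
    def test_grid_oracle_agreement_on_toy_data(self):
        x = np.array([-1.0, 0.0, 1.0])
        k = np.array([12.0, 45.0, 88.0])
        n = np.array([100.0, 100.0, 100.0])
        fit = fit_psychometric(x, k, n, bounds=NO_RATES)
        assert fit.log_likelihood == pytest.approx(
            _nelder_mead_oracle(x, k, n), abs=1e-6
        )

    def test_antisymmetric_data_yields_zero_mu(self):
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        k = np.array([3.0, 20.0, 50.0, 80.0, 97.0])  # p(x) + p(-x) = 1
        n = np.full(5, 100.0)
        fit = fit_psychometric(x, k, n, bounds=NO_RATES)
        assert abs(fit.mu) < 1e-4
        assert fit.bias == pytest.approx(-fit.mu)

    def test_parameter_recovery_with_ci(self):
        rng = np.random.default_rng(123)
        x, k, n = simulate_binomial_counts(
            -0.5, 0.8, 0.02, 0.02, levels=LOG_RATIO_LEVELS, n_per_level=200, rng=rng
        )
        fit = fit_psychometric(x, k, n)
        lo, hi = profile_ci_mu(x, k, n)
        assert lo <= -0.5 <= hi
        assert fit.bias == pytest.approx(0.5, abs=0.15)
        assert fit.sigma == pytest.approx(0.8, abs=0.25)

    def test_degenerate_all_identical_responses(self):
        x = np.array(LOG_RATIO_LEVELS)
        n = np.full(11, 8.0)
        fit = fit_psychometric(x, np.zeros(11), n)
        assert fit.degenerate and not fit.converged
        fit = fit_psychometric(x, n.copy(), n)
        assert fit.degenerate and not fit.converged

    def test_monotone_prediction(self):
        rng = np.random.default_rng(5)
        x, k, n = simulate_binomial_counts(0.3, 1.2, 0.05, 0.01, n_per_level=50, rng=rng)
        fit = fit_psychometric(x, k, n)
        grid = np.linspace(-5, 5, 201)
        assert np.all(np.diff(fit.predict(grid)) >= 0)
        assert fit.gamma + fit.lam < 1.0

    @given(shift=st.floats(-2.0, 2.0))
    def test_reparameterization_shift(self, shift):
        rng = np.random.default_rng(99)
        x, k, n = simulate_binomial_counts(0.2, 0.9, 0.02, 0.02, n_per_level=150, rng=rng)
        base = fit_psychometric(x, k, n)
        moved = fit_psychometric(x + shift, k, n)
        assert moved.mu == pytest.approx(base.mu + shift, abs=1e-3)
        assert moved.sigma == pytest.approx(base.sigma, abs=1e-3)
        assert moved.gamma == pytest.approx(base.gamma, abs=1e-3)
        assert moved.lam == pytest.approx(base.lam, abs=1e-3)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            fit_psychometric([0.0, 0.0], [1, 1], [2, 2])  # one distinct level
        with pytest.raises(ValueError):
            fit_psychometric([0.0, 1.0], [1, 1], [2, 0])  # empty level
        with pytest.raises(ValueError):
            fit_psychometric([0.0, 1.0], [3, 1], [2, 2])  # k > n


class TestLrTestBias:
    def test_nested_identity_at_zero_mu(self):
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        k = np.array([3.0, 20.0, 50.0, 80.0, 97.0])
        n = np.full(5, 100.0)
        test = lr_test_bias(x, k, n, bounds=NO_RATES)
        assert test.deviance < 1e-4
        assert test.p_value > 0.99
        assert not test.significant

    def test_unconstrained_at_least_as_likely(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            x, k, n = simulate_binomial_counts(
                rng.uniform(-1, 1), rng.uniform(0.3, 2.0), 0.02, 0.02,
                n_per_level=8, rng=rng,
            )
            test = lr_test_bias(x, k, n)
            assert test.deviance >= 0.0
            assert (
                test.unconstrained.log_likelihood
                >= test.constrained.log_likelihood - 1e-6
            )

    def test_power_against_large_bias(self):
        rng = np.random.default_rng(31)
        rejections = 0
        n_rep = 60
        for _ in range(n_rep):
            x, k, n = simulate_binomial_counts(
                -1.0, 0.8, 0.02, 0.02, n_per_level=64, rng=rng
            )
            rejections += int(lr_test_bias(x, k, n).significant)
        assert rejections / n_rep > 0.95


def _simulated_condition_frame(mu, condition, cardinal_cat, intercardinal_cat, seed,
                               copies=30):
    cond = Condition(condition, cardinal_cat, intercardinal_cat)
    session = generate_session([cond], LOG_RATIO_LEVELS, copies=copies, seed=seed)
    observer = ObserverModel(default_params=(mu, 0.8, 0.02, 0.02))
    completed = simulate_trials(observer, session, seed=seed + 1)
    return records_to_frame(completed)


class TestPoolCategorical:
    def test_mirror_pooling_gives_zero_bias(self):
        frame_c = _simulated_condition_frame(-0.4, "CH", "house", "flower", seed=41)
        # mirrored copy: roles swapped and responses complemented, so the
        # pooled data are exactly antisymmetric about x = 0
        frame_i = frame_c.copy()
        frame_i["cardinal_category"] = frame_c["intercardinal_category"]
        frame_i["intercardinal_category"] = frame_c["cardinal_category"]
        frame_i["response_category"] = np.where(
            frame_c["response_category"] == "house", "flower", "house"
        )
        fit = pool_categorical(frame_c, frame_i, "house")
        assert abs(fit.bias) < 1e-3

    def test_category_preference_recovery(self):
        # an observer that prefers houses by +0.3 ln-units regardless of filter
        observer = ObserverModel(
            default_params=(0.0, 0.8, 0.02, 0.02),
            category_preference={"house": 0.3},
        )
        cond_c = Condition("CH", "house", "flower")
        cond_i = Condition("IH", "flower", "house")
        session_c = generate_session([cond_c], LOG_RATIO_LEVELS, copies=120, seed=51)
        session_i = generate_session([cond_i], LOG_RATIO_LEVELS, copies=120, seed=52)
        frame_c = records_to_frame(simulate_trials(observer, session_c, seed=53))
        frame_i = records_to_frame(simulate_trials(observer, session_i, seed=54))
        pooled = pool_categorical(frame_c, frame_i, "house")
        assert pooled.bias == pytest.approx(0.3, abs=0.1)
        from hybridpsych.psychometrics import fit_condition

        bias_c = fit_condition(frame_c).bias
        bias_i = fit_condition(frame_i).bias
        assert bias_c > 0 > bias_i  # opposite per-filtering biases

    def test_empty_set_rejected(self):
        frame_c = _simulated_condition_frame(0.0, "CH", "house", "flower", seed=61,
                                             copies=2)
        with pytest.raises(ValueError):
            pool_categorical(frame_c, frame_c.iloc[0:0], "house")

    def test_category_mismatch_rejected(self):
        frame_c = _simulated_condition_frame(0.0, "CH", "house", "flower", seed=62,
                                             copies=2)
        with pytest.raises(ValueError):
            pool_categorical(frame_c, frame_c, "house")


class TestGroupStats:
    def test_printed_table_identity(self):
        # a condition with t = -5.94 over 10 participants implies d = -1.88
        assert cohens_d_from_t(-5.94, 10) == pytest.approx(-1.88, abs=0.005)

    def test_symmetric_pair(self):
        stats = group_bias_stats([-1.0, 1.0])
        assert stats.mean_bias == 0.0
        assert stats.t_statistic == 0.0
        assert stats.cohens_d == 0.0

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateStatisticsError):
            group_bias_stats([0.3, 0.3, 0.3])
        with pytest.raises(DegenerateStatisticsError):
            group_bias_stats([0.3])

    @given(
        st.lists(st.floats(-3, 3), min_size=3, max_size=12).filter(
            lambda b: np.std(b, ddof=1) > 1e-6
        )
    )
    def test_d_equals_t_over_sqrt_n(self, biases):
        stats = group_bias_stats(biases)
        assert stats.cohens_d == pytest.approx(
            stats.t_statistic / math.sqrt(stats.n), rel=1e-12
        )
        assert np.sign(stats.cohens_d) == np.sign(stats.mean_bias) or stats.cohens_d == 0


def test_sign_convention_cardinal_dominance():
    """An observer favouring the cardinal component must show positive bias."""
    # mu = -0.6: at equal energy the cardinal component is chosen > 50%
    frame = _simulated_condition_frame(-0.6, "CA", "animal", "house", seed=71)
    from hybridpsych.psychometrics import fit_condition

    fit = fit_condition(frame)
    assert fit.bias > 0.3


def test_neither_policy_changes_denominator():
    frame = _simulated_condition_frame(0.0, "CH", "house", "flower", seed=81, copies=5)
    frame.loc[frame.index[:10], "response_is_cardinal"] = "neither"
    from hybridpsych.psychometrics import aggregate_binomial

    _, _, n_count = aggregate_binomial(frame, neither_policy="count")
    _, _, n_excl = aggregate_binomial(frame, neither_policy="exclude")
    assert n_count.sum() - n_excl.sum() == 10
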