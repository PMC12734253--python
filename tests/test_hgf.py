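"""Unit and property tests for the binary 3-level HGF filter."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from escalearn.hgf import (
    BeliefState,
    HGFNumericalError,
    HGFParams,
    choice_loglik,
    filter_sequence,
    predict_step,
    unit_square_sigmoid,
    update_step,
)

from _oracle import hgf_filter_oracle

DEFAULTS = HGFParams(beta=1.0)


class TestPredictStep:
    def test_indifferent_belief_gives_half_prediction(self):
        pred = predict_step(DEFAULTS.initial_state(), DEFAULTS)
        assert pred.muhat1 == 0.5
        assert pred.pihat1 == 4.0

    def test_level2_prior_precision_hand_value(self):
        # sigma2=0.1, mu3=1, omega2=-3, kappa=1 -> v2 = e^-2, pihat2 = 1/(0.1 + e^-2)
        pred = predict_step(BeliefState(0.0, 0.1, 1.0, 1.0), DEFAULTS)
        assert pred.v2 == pytest.approx(math.exp(-2.0), abs=1e-12)
        assert pred.pihat2 == pytest.approx(1.0 / (0.1 + math.exp(-2.0)), abs=1e-12)
        assert pred.pihat2 == pytest.approx(4.2493, abs=5e-5)

    def test_level3_prior_precision_hand_value(self):
        pred = predict_step(BeliefState(0.0, 0.1, 1.0, 1.0), DEFAULTS)
        assert pred.pihat3 == pytest.approx(1.0 / (1.0 + math.exp(-6.0)), abs=1e-12)
        assert pred.pihat3 == pytest.approx(0.99753, abs=5e-6)

    def test_exp_overflow_names_parameter(self):
        bad = DEFAULTS.with_(omega2=800.0)
        with pytest.raises(HGFNumericalError, match="omega2"):
            predict_step(DEFAULTS.initial_state(), bad)

    def test_saturated_belief_rejected(self):
        with pytest.raises(HGFNumericalError, match="saturated"):
            predict_step(BeliefState(900.0, 0.1, 1.0, 1.0), DEFAULTS)


class TestUpdateStep:
    def test_one_step_hand_oracle_from_defaults(self):
        """u=1 from the default initial state, against explicit arithmetic."""
        pred = predict_step(DEFAULTS.initial_state(), DEFAULTS)
        _, row = update_step(pred, 1, DEFAULTS)
        pihat2 = 1.0 / (0.1 + math.exp(-2.0))
        pi2 = pihat2 + 0.25
        mu2 = 0.5 / pi2
        sigma2 = 1.0 / pi2
        delta2 = (sigma2 + mu2**2) * pihat2 - 1.0
        w2 = math.exp(-2.0) * pihat2
        pi3 = 1.0 / (1.0 + math.exp(-6.0)) + 0.5 * w2 * (w2 + (2 * w2 - 1) * delta2)
        assert row.mu2 == pytest.approx(mu2, abs=1e-6)
        assert row.sigma2 == pytest.approx(sigma2, abs=1e-6)
        assert row.delta2 == pytest.approx(delta2, abs=1e-6)
        assert row.pi3 == pytest.approx(pi3, abs=1e-6)
        assert row.mu3 == pytest.approx(1.0 + 0.5 * (w2 / pi3) * delta2, abs=1e-6)
        assert row.psi3 == pytest.approx(pihat2 / pi3, abs=1e-6)
        # printed 5-decimal reference values
        assert row.mu2 == pytest.approx(0.11113, abs=5e-6)
        assert row.sigma2 == pytest.approx(0.22226, abs=5e-6)
        assert row.pi3 == pytest.approx(1.16275, abs=5e-6)
        assert row.mu3 == pytest.approx(0.99924, abs=5e-6)
        assert row.psi3 == pytest.approx(3.6545, abs=5e-5)

    def test_update_antisymmetric_at_indifference(self):
        """With muhat1 = 0.5, u=0 and u=1 move mu2 by equal opposite amounts."""
        pred = predict_step(DEFAULTS.initial_state(), DEFAULTS)
        _, up = update_step(pred, 1, DEFAULTS)
        _, dn = update_step(pred, 0, DEFAULTS)
        assert up.mu2 - pred.muhat2 == pytest.approx(-(dn.mu2 - pred.muhat2), abs=1e-14)

    def test_nonbinary_input_rejected(self):
        pred = predict_step(DEFAULTS.initial_state(), DEFAULTS)
        with pytest.raises(ValueError, match="binary"):
            update_step(pred, 2, DEFAULTS)

    def test_pi3_instability_is_hard_error(self):
        # high volatility-level variance + surprising input drive pi3 negative
        params = DEFAULTS.with_(kappa=1.86, omega2=2.42, omega3=4.53)
        state = BeliefState(-3.98, 4.29, -2.80, 36.6)
        pred = predict_step(state, params)
        with pytest.raises(HGFNumericalError, match="pi3"):
            update_step(pred, 1, params)


class TestFilterSequence:
    def test_constant_input_monotone_learning(self):
        traj = filter_sequence(np.ones(60, dtype=int), DEFAULTS)
        mu2 = traj.series("mu2")
        muhat1 = traj.series("muhat1")
        assert np.all(np.diff(mu2) > 0)
        assert np.all(np.diff(muhat1) > 0)
        assert muhat1[-1] > 0.9

    def test_alternating_input_hovers_near_indifference(self):
        u = np.tile([1, 0], 30)
        traj = filter_sequence(u, DEFAULTS)
        assert abs(traj.series("mu2")[-1]) < 0.35

    def test_single_input_equals_one_update_step(self):
        traj = filter_sequence([1], DEFAULTS)
        pred = predict_step(DEFAULTS.initial_state(), DEFAULTS)
        _, row = update_step(pred, 1, DEFAULTS, trial=1)
        assert len(traj) == 1
        assert traj[0] == row

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            filter_sequence([], DEFAULTS)

    def test_instability_reports_trial_index(self):
        params = DEFAULTS.with_(
            kappa=1.86, omega2=2.42, omega3=4.53,
            mu2_0=-3.98, sigma2_0=4.29, mu3_0=-2.80, sigma3_0=36.6,
        )
        with pytest.raises(HGFNumericalError, match="trial 1"):
            filter_sequence(np.ones(30, dtype=int), params)

    def test_matches_independent_oracle_on_random_instances(self):
        """Literal re-transcription agreement to 1e-10 on 1000 instances."""
        rng = np.random.default_rng(123)
        checked = 0
        for _ in range(1000):
            params = HGFParams(
                omega2=rng.uniform(-6, -1),
                omega3=rng.uniform(-8, -4),
                beta=1.0,
                mu2_0=rng.uniform(-1.5, 1.5),
                sigma2_0=rng.uniform(0.05, 1.0),
                mu3_0=rng.uniform(0.0, 2.0),
                sigma3_0=rng.uniform(0.2, 2.0),
            )
            u = rng.integers(0, 2, rng.integers(5, 40))
            traj = filter_sequence(u, params)
            oracle = hgf_filter_oracle(
                u,
                omega2=params.omega2,
                omega3=params.omega3,
                mu2_0=params.mu2_0,
                sigma2_0=params.sigma2_0,
                mu3_0=params.mu3_0,
                sigma3_0=params.sigma3_0,
            )
            for key in ("muhat1", "mu2", "sigma2", "mu3", "sigma3", "psi2", "psi3", "eps2", "eps3", "delta2", "pi3"):
                np.testing.assert_allclose(traj.series(key), oracle[key], atol=1e-10, rtol=0)
            checked += 1
        assert checked == 1000

    def test_learning_rate_and_pe_identities(self):
        """psi2 == sigma2 == 1/pi2 and eps2 == mu2 - muhat2, exactly, everywhere."""
        rng = np.random.default_rng(7)
        for _ in range(200):
            params = HGFParams(
                omega2=rng.uniform(-6, -1),
                omega3=rng.uniform(-8, -4),
                beta=1.0,
                mu2_0=rng.uniform(-1, 1),
            )
            traj = filter_sequence(rng.integers(0, 2, 30), params)
            np.testing.assert_allclose(traj.series("psi2"), traj.series("sigma2"), atol=1e-10, rtol=0)
            np.testing.assert_allclose(traj.series("psi2"), 1.0 / traj.series("pi2"), atol=1e-10, rtol=0)
            np.testing.assert_allclose(
                traj.series("eps2"), traj.series("mu2") - traj.series("muhat2"), atol=1e-10, rtol=0
            )
            np.testing.assert_allclose(traj.series("sigma3"), 1.0 / traj.series("pi3"), atol=1e-10, rtol=0)

    def test_literal_level2_rate_convention(self):
        """Sensitivity flag: psi2 = pihat1/pi2 instead of sigma2; beliefs
        themselves are unchanged."""
        u = np.array([1, 0, 1, 1, 0, 0, 1])
        default = filter_sequence(u, DEFAULTS)
        literal = filter_sequence(u, DEFAULTS.with_(level2_rate="literal"))
        np.testing.assert_allclose(
            literal.series("psi2"),
            literal.series("pihat1") / literal.series("pi2"),
            atol=1e-12, rtol=0,
        )
        np.testing.assert_array_equal(default.series("mu2"), literal.series("mu2"))
        with pytest.raises(ValueError, match="level2_rate"):
            DEFAULTS.with_(level2_rate="nope")

    def test_two_level_limit_freezes_volatility(self):
        """omega3 -> -inf with tiny sigma3_0 pins mu3 at its start value."""
        params = DEFAULTS.with_(omega3=-60.0, sigma3_0=1e-10)
        traj = filter_sequence(np.random.default_rng(0).integers(0, 2, 80), params)
        np.testing.assert_allclose(traj.series("mu3"), params.mu3_0, atol=1e-8, rtol=0)

    def test_long_run_prediction_tracks_input_rate(self):
        """Mean muhat1 approaches the Bernoulli rate of the input stream."""
        rng = np.random.default_rng(2024)
        for p in (0.2, 0.5, 0.8):
            means = []
            for _ in range(60):
                u = (rng.random(200) < p).astype(int)
                traj = filter_sequence(u, DEFAULTS)
                means.append(traj.series("muhat1")[50:].mean())
            assert np.mean(means) == pytest.approx(p, abs=0.05)


class TestResponseModel:
    @pytest.mark.parametrize(
        "muhat1, beta, expected",
        [
            (0.5, 3.7, 0.5),
            (0.123, 0.0, 0.5),
            (0.8, 2.0, 0.64 / 0.68),
        ],
    )
    def test_unit_square_sigmoid_values(self, muhat1, beta, expected):
        assert unit_square_sigmoid(muhat1, beta) == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.2, 1.3])
    def test_domain_error_outside_unit_interval(self, bad):
        with pytest.raises(ValueError):
            unit_square_sigmoid(bad, 1.0)

    @given(
        m=st.floats(1e-6, 1.0 - 1e-6),
        beta=st.floats(0.0, 20.0),
    )
    @settings(deadline=None, derandomize=True)
    def test_symmetry_property(self, m, beta):
        p = unit_square_sigmoid(m, beta)
        q = unit_square_sigmoid(1.0 - m, beta)
        assert 0.0 <= p <= 1.0
        assert p + q == pytest.approx(1.0, abs=1e-9)

    # ranges keep beta*logit(m) away from float saturation of the sigmoid
    @given(
        a=st.floats(0.01, 0.9),
        gap=st.floats(1e-3, 0.01),
        beta=st.floats(0.1, 8.0),
    )
    @settings(deadline=None, derandomize=True)
    def test_strictly_increasing_in_belief(self, a, gap, beta):
        assert unit_square_sigmoid(a + gap, beta) > unit_square_sigmoid(a, beta)

    def test_loglik_uniform_at_beta_zero(self):
        traj = filter_sequence(np.ones(25, dtype=int), DEFAULTS)
        ll = choice_loglik(traj, np.zeros(25, dtype=int), 0.0)
        assert ll == pytest.approx(25 * math.log(0.5), abs=1e-12)

    def test_loglik_single_trial_hand_value(self):
        traj = filter_sequence([1], DEFAULTS.with_(mu2_0=math.log(4.0)))  # muhat1 = 0.8
        assert traj[0].muhat1 == pytest.approx(0.8, abs=1e-12)
        ll = choice_loglik(traj, [1], 2.0)
        assert ll == pytest.approx(math.log(0.64 / 0.68), abs=1e-9)
        assert ll == pytest.approx(-0.06062, abs=5e-6)

    def test_loglik_deterministic_limit_approaches_zero(self):
        # start slightly off indifference so no trial has muhat1 exactly 0.5
        traj = filter_sequence(np.ones(40, dtype=int), DEFAULTS.with_(mu2_0=0.2))
        choices = (traj.muhat1 > 0.5).astype(int)
        ll = choice_loglik(traj, choices, 1e6)
        assert -1e-3 < ll <= 0.0

    def test_loglik_never_positive_and_length_checked(self):
        traj = filter_sequence(np.ones(10, dtype=int), DEFAULTS)
        rng = np.random.default_rng(5)
        for beta in (0.0, 0.7, 3.0, 50.0):
            assert choice_loglik(traj, rng.integers(0, 2, 10), beta) <= 0.0
        with pytest.raises(ValueError, match="mismatch"):
            choice_loglik(traj, [1, 0], 1.0)
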