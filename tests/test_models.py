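"""Learning/choice models: analytic values, invariants, trial-loop checks."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from riskbandit import MODELS, _kernels, models


class TestSoftmax:
    def test_equal_activations_give_half(self):
        p = models.softmax_probabilities([50.0, 50.0], beta=3.7)
        assert p == pytest.approx([0.5, 0.5])

    def test_zero_beta_uniform(self):
        p = models.softmax_probabilities([90.0, 10.0], beta=0.0)
        assert p == pytest.approx([0.5, 0.5])

    def test_direct_evaluation(self):
        # beta * (A1 - A2) = 2 -> p1 = 1 / (1 + e^-2)
        p = models.softmax_probabilities([60.0, 40.0], beta=0.1)
        assert p[0] == pytest.approx(1 / (1 + math.exp(-2)), abs=1e-12)
        assert p.sum() == pytest.approx(1.0)

    def test_nonfinite_activations_rejected(self):
        with pytest.raises(ValueError):
            models.softmax_probabilities([np.inf, 0.0], beta=1.0)

    @given(
        a=st.floats(-60, 60),
        b=st.floats(-60, 60),
        beta=st.floats(0, 2),
    )
    @settings(max_examples=100, deadline=None)
    def test_probabilities_in_unit_interval_and_normalised(self, a, b, beta):
        p = models.softmax_probabilities([a, b], beta)
        assert p[0] > 0 and p[1] > 0
        assert p.sum() == pytest.approx(1.0, abs=1e-12)


class TestPredictionErrors:
    def test_outcome_pe_is_reward_minus_value(self):
        assert models.outcome_prediction_error(70, 60) == 10
        assert models.outcome_prediction_error(55.5, 55.5) == 0
        assert models.outcome_prediction_error(1, 50) == -49

    def test_stimulus_pe_at_converged_values(self):
        q = np.array([60.0, 60.0, 40.0, 40.0])
        assert models.stimulus_prediction_error(q, (1, 2)) == pytest.approx(10.0)
        assert models.stimulus_prediction_error(q, (3, 4)) == pytest.approx(-10.0)
        assert models.stimulus_prediction_error(q, (1, 4)) == pytest.approx(0.0)

    def test_stimulus_pe_zero_when_values_equal(self):
        q = np.full(4, 37.2)
        assert models.stimulus_prediction_error(q, (2, 3)) == 0.0

    def test_prediction_mode_returns_pair_mean(self):
        q = np.array([60.0, 60.0, 40.0, 40.0])
        assert models.stimulus_prediction_error(q, (1, 3), "prediction") == 50.0

    def test_scaled_pe(self):
        assert models.scaled_outcome_pe(70, 60, 10) == 1.0
        assert models.scaled_outcome_pe(60, 60, 3) == 0.0
        assert models.scaled_outcome_pe(50, 60, 5) == -2.0
        with pytest.raises(ValueError):
            models.scaled_outcome_pe(50, 60, 0.0)


class TestUtility:
    @pytest.mark.parametrize(
        "family,k", [("identity", None), ("concave", 0.3), ("convex", -0.3),
                     ("s", 0.5), ("inverse-s", 1.5)]
    )
    def test_reference_point_is_fixed(self, family, k):
        assert models.utility_transform(50.0, family, k) == pytest.approx(50.0)

    def test_unit_exponent_is_identity(self):
        for r in [1, 25, 50, 75, 99]:
            assert models.utility_transform(r, "s", 1.0) == pytest.approx(r)
            assert models.utility_transform(r, "inverse-s", 1.0) == pytest.approx(r)

    def test_concave_direct_evaluation(self):
        expected = 50 + 50 * (1 - math.exp(-0.1 * 0.98)) / 0.1
        assert models.utility_transform(99, "concave", 0.1) == pytest.approx(expected)

    def test_concave_approaches_identity_for_small_k(self):
        for r in [10.0, 80.0]:
            assert models.utility_transform(r, "concave", 1e-9) == pytest.approx(
                r, abs=1e-6
            )

    def test_curvatures(self):
        # concave bends high rewards down, convex bends them up
        assert models.utility_transform(99, "concave", 0.5) < 99
        assert models.utility_transform(99, "convex", -0.5) > 99

    @pytest.mark.parametrize(
        "family,k", [("concave", -0.1), ("concave", 0.0), ("convex", 0.1),
                     ("s", 1.2), ("s", -0.1), ("inverse-s", 0.9)]
    )
    def test_out_of_range_shape_rejected(self, family, k):
        with pytest.raises(ValueError):
            models.utility_transform(60, family, k)


class TestRatesAndUpdates:
    def test_valence_rule_uses_sign_of_pe(self):
        m = MODELS["pos-neg-RATES"]
        p = {"alpha_pos": 0.4, "alpha_neg": 0.1, "beta": 1.0}
        assert models.effective_learning_rate(m, p, +3.0, 1) == 0.4
        assert models.effective_learning_rate(m, p, -3.0, 1) == 0.1

    def test_variance_rule_uses_risk_class_of_chosen(self):
        m = MODELS["variance-RATES"]
        p = {"alpha_risky": 0.2, "alpha_safe": 0.5, "beta": 1.0}
        for chosen, expected in [(1, 0.2), (3, 0.2), (2, 0.5), (4, 0.5)]:
            assert models.effective_learning_rate(m, p, 1.0, chosen) == expected

    def test_attention_rule_at_unit_surprise(self):
        m = MODELS["attention-RATES"]
        p = {"alpha": 0.3, "k_attention": 1.7, "beta": 1.0}
        assert models.effective_learning_rate(m, p, 1.0, 1) == pytest.approx(0.3)
        assert models.effective_learning_rate(m, p, -1.0, 1) == pytest.approx(0.3)
        assert models.effective_learning_rate(m, p, 0.0, 1) == 0.0

    def test_value_update_only_touches_chosen(self):
        q = np.array([50.0, 50.0, 50.0, 50.0])
        models.value_update(q, 3, 0.5, 10.0)
        assert list(q) == [50.0, 50.0, 55.0, 50.0]
        models.value_update(q, 3, 0.0, 99.0)
        assert q[2] == 55.0

    def test_full_learning_rate_jumps_to_reward(self):
        q = np.array([50.0, 50.0, 50.0, 50.0])
        models.value_update(q, 1, 1.0, 72 - q[0])
        assert q[0] == 72.0

    def test_value_converges_geometrically_on_constant_reward(self):
        # Q_n = 60 - 10 * 0.7^n for fixed reward 60, alpha 0.3, Q0 = 50
        q = np.array([50.0, 50.0, 50.0, 50.0])
        for n in range(1, 21):
            models.value_update(q, 1, 0.3, 60.0 - q[0])
            assert q[0] == pytest.approx(60 - 10 * 0.7**n, abs=1e-12)

    def test_spread_fixed_points(self):
        s = np.array([8.0, 8.0, 8.0, 8.0])
        models.spread_update(s, 2, 0.5, 8.0)  # |delta| == S: no change
        assert s[1] == 8.0
        models.spread_update(s, 2, 0.5, -1.0, scaled=True)  # |scaled pe| == 1
        assert s[1] == 8.0

    def test_spread_tracks_mean_absolute_deviation(self, rng):
        # E|N(0, sigma)| = sigma * sqrt(2/pi)
        s = np.array([10.0, 0.0, 0.0, 0.0])
        for d in rng.normal(0, 20, 20_000):
            models.spread_update(s, 1, 0.02, d)
        assert s[0] == pytest.approx(20 * math.sqrt(2 / math.pi), abs=0.5)


class TestActivations:
    def test_zero_gate_or_zero_omega_reduce_to_values(self):
        m = MODELS["PEIRS"]
        q = np.array([55.0, 45.0, 40.0, 60.0])
        s = np.array([5.0, 5.0, 5.0, 5.0])
        base = {"alpha_q": 0.3, "alpha_s": 0.1, "beta": 1.0, "s0": 5.0}
        a = models.action_activations(q, s, (1, 2), m, base | {"omega": 0.0}, 10.0)
        assert a == pytest.approx([55.0, 45.0])
        a = models.action_activations(q, s, (1, 2), m, base | {"omega": 2.0}, 0.0)
        assert a == pytest.approx([55.0, 45.0])

    def test_saturated_gate_adds_full_spread(self):
        m = MODELS["PEIRS"]
        q = np.array([55.0, 45.0, 40.0, 60.0])
        s = np.array([5.0, 2.0, 0.0, 0.0])
        p = {"alpha_q": 0.3, "alpha_s": 0.1, "beta": 1.0, "omega": 50.0, "s0": 5.0}
        a = models.action_activations(q, s, (1, 2), m, p, 10.0)
        assert a == pytest.approx([60.0, 47.0])
        a = models.action_activations(q, s, (1, 2), m, p, -10.0)
        assert a == pytest.approx([50.0, 43.0])

    def test_risky_choice_probability_monotone_in_gate(self):
        """tanh gating: with S_risky > S_safe the risky option's probability
        is non-decreasing in the stimulus prediction error."""
        m = MODELS["PEIRS"]
        q = np.array([60.0, 60.0, 40.0, 40.0])
        s = np.array([16.0, 4.0, 16.0, 4.0])
        p = {"alpha_q": 0.3, "alpha_s": 0.1, "beta": 0.2, "omega": 0.3, "s0": 5.0}
        probs = []
        for gate in np.linspace(-15, 15, 31):
            a = models.action_activations(q, s, (1, 2), m, p, gate)
            probs.append(models.softmax_probabilities(a, p["beta"])[0])
        assert all(b >= a - 1e-12 for a, b in zip(probs, probs[1:]))


class TestTrialLoop:
    def test_probabilities_sum_to_one_and_q_bounded(self, peirs_session):
        _, trace = peirs_session
        q = trace[[f"Q{i}" for i in range(1, 5)]].to_numpy()
        assert ((q >= 1.0) & (q <= 99.0)).all()  # convex hull of rewards
        assert trace["p_choice"].between(0, 1, inclusive="neither").all()
        assert trace["p_left"].between(0, 1, inclusive="neither").all()

    def test_spread_stays_nonnegative(self, peirs_session):
        _, trace = peirs_session
        s = trace[[f"S{i}" for i in range(1, 5)]].to_numpy()
        assert (s >= 0).all()

    def test_block_reset(self, peirs_session):
        _, trace = peirs_session
        starts = trace.groupby("block").first()
        for i in range(1, 5):
            assert (starts[f"Q{i}"] == 50.0).all()
            assert (starts[f"S{i}"] == 10.0).all()

    def test_same_seed_identical_sessions(self, standard_schedule):
        a, _ = models.simulate_session(
            "PEIRS", MODELS["PEIRS"].defaults, standard_schedule, seed=3
        )
        b, _ = models.simulate_session(
            "PEIRS", MODELS["PEIRS"].defaults, standard_schedule, seed=3
        )
        assert a.trials.equals(b.trials)

    def test_zero_beta_agent_chooses_uniformly(self, standard_schedule):
        session, trace = models.simulate_session(
            "RW", {"alpha": 0.3, "beta": 0.0}, standard_schedule, seed=11
        )
        assert (trace["p_choice"] == 0.5).all()
        left_rate = (session.trials["choice"] == session.trials["stim_left"]).mean()
        assert left_rate == pytest.approx(0.5, abs=0.05)

    def test_high_beta_rw_prefers_high_value_late(self, standard_schedule):
        session, _ = models.simulate_session(
            "RW", {"alpha": 0.3, "beta": 2.0}, standard_schedule, seed=11
        )
        t = session.trials
        late_diff = t[(t["condition"] == "different") & (t["trial"] > 60)]
        assert late_diff["choice"].isin([1, 2]).mean() > 0.9

    def test_peirs_risk_seeking_high_risk_averse_low(self, standard_schedule):
        """Positive gating: risky preferred when both options are high-value,
        safe preferred when both are low-value (late trials, strong gate)."""
        session, _ = models.simulate_session(
            "PEIRS",
            {"alpha_q": 0.3, "alpha_s": 0.2, "beta": 0.5, "omega": 1.0, "s0": 10.0},
            standard_schedule,
            seed=11,
        )
        t = session.trials
        late = t[t["trial"] > 60]
        bh = late[late["condition"] == "both-high"]
        bl = late[late["condition"] == "both-low"]
        assert bh["choice"].isin([1, 3]).mean() > 0.5
        assert bl["choice"].isin([1, 3]).mean() < 0.5

    def test_choice_outside_pair_rejected(self, rw_session):
        session, _ = rw_session
        bad = session.trials.copy()
        bad.loc[0, "choice"] = 1 if bad.loc[0, "stim_left"] not in (1,) else 3
        bad.loc[0, "choice"] = next(
            i for i in range(1, 5)
            if i not in (bad.loc[0, "stim_left"], bad.loc[0, "stim_right"])
        )
        broken = type(session)("p", bad)
        with pytest.raises(ValueError, match="not in shown pair"):
            models.replay_session("RW", MODELS["RW"].defaults, broken)


class TestReplayAndKernel:
    def test_replay_reproduces_simulation_latents(self, peirs_session):
        session, trace = peirs_session
        replayed = models.replay_session("PEIRS", MODELS["PEIRS"].defaults, session)
        for col in ["Q1", "Q2", "S3", "delta_stim", "p_choice", "delta_out"]:
            np.testing.assert_allclose(replayed[col], trace[col], atol=1e-12)

    @pytest.mark.parametrize("name", list(MODELS))
    def test_kernel_matches_reference_loglik(self, name, standard_schedule):
        """Compiled fitting kernel and pure-Python trial loop are identical."""
        model = MODELS[name]
        session, _ = models.simulate_session(
            model, model.defaults, standard_schedule, seed=13
        )
        ll_ref = float(
            np.log(models.replay_session(model, model.defaults, session)["p_choice"]).sum()
        )
        ll_kernel = models.session_log_likelihood(model, model.defaults, session)
        assert ll_kernel == pytest.approx(ll_ref, abs=1e-9)

    def test_single_trial_loglik_from_softmax(self, standard_schedule):
        """A one-trial session's log-likelihood equals log of the softmax
        probability of the recorded choice."""
        session, trace = models.simulate_session(
            "RW", {"alpha": 0.3, "beta": 0.1}, standard_schedule, seed=5
        )
        one = type(session)("p", session.trials.iloc[:1].copy())
        ll = models.session_log_likelihood("RW", {"alpha": 0.3, "beta": 0.1}, one)
        assert ll == pytest.approx(math.log(0.5))  # first trial: equal values

    def test_zero_beta_loglik_is_n_log_half(self, rw_session):
        session, _ = rw_session
        ll = models.session_log_likelihood("RW", {"alpha": 0.3, "beta": 0.0}, session)
        assert ll == pytest.approx(480 * math.log(0.5))

    def test_generating_parameters_beat_perturbed_on_average(
        self, standard_schedule
    ):
        """Likelihood dominance: the generating parameter set outscores a
        grossly perturbed one on average over simulated sessions."""
        true = {"alpha": 0.3, "beta": 0.3}
        wrong = {"alpha": 0.95, "beta": 0.02}
        wins = 0
        for seed in range(10):
            session, _ = models.simulate_session("RW", true, standard_schedule, seed)
            if models.session_log_likelihood(
                "RW", true, session
            ) > models.session_log_likelihood("RW", wrong, session):
                wins += 1
        assert wins >= 8


class TestModelRegistry:
    def test_twelve_models_with_expected_parameter_counts(self):
        assert len(MODELS) == 12
        expected_k = {
            "RW": 2, "concave-UTIL": 3, "convex-UTIL": 3, "s-shaped-UTIL": 3,
            "inverse-s-UTIL": 3, "pos-neg-RATES": 3, "variance-RATES": 3,
            "attention-RATES": 3, "scaled-PE": 4, "PEIRS": 5, "PIRS": 5,
            "OEIRS": 5,
        }
        assert {n: m.k for n, m in MODELS.items()} == expected_k

    def test_unknown_model_raises(self):
        with pytest.raises(KeyError, match="unknown model"):
            models.get_model("Q-lambda")
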