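"""Utility-function, softmax and likelihood tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from moralcost import models, task

GROUP_MEANS = dict(beta_P=-0.88, beta_PH=16.02, theta=5.94, omega=0.97, gamma=-2.35)
DB_TRIAL = task.Trial("Dyad", "Bribe", 96, 38)


class TestSubjectiveValue:
    def test_winning_model_accept_value_matches_hand_computation(self):
        # -0.88*58 + 0.97*4 + (16.02-5.94)*38 - 2.35*20
        sv = models.subjective_value(5, GROUP_MEANS, DB_TRIAL, "accept")
        assert sv == pytest.approx(288.88, abs=1e-9)

    def test_winning_model_reject_keeps_only_third_party_term(self):
        sv = models.subjective_value(5, GROUP_MEANS, DB_TRIAL, "reject")
        assert sv == pytest.approx(0.97 * 96, abs=1e-9)

    @pytest.mark.parametrize("model_id", [1, 2, 3, 4])
    def test_rejection_is_worth_zero_without_third_party_valuation(self, model_id):
        params = {p: 1.5 for p in models.MODELS[model_id].parameter_names}
        for trial in (DB_TRIAL, task.Trial("Solo", "Control", 64, 13)):
            assert models.subjective_value(model_id, params, trial, "reject") == 0.0

    def test_nested_model_equivalences(self):
        """M4(delta=0) = M2 ; M2(gamma=0) = M1 ; M5(omega=0) = M2."""
        rng = np.random.default_rng(3)
        offers = task.build_offer_set()
        for _ in range(20):
            o = offers[rng.integers(len(offers))]
            t = task.Trial(
                ["Solo", "Dyad"][rng.integers(2)],
                ["Control", "Bribe"][rng.integers(2)],
                o.reported_payoff,
                o.offer_amount,
            )
            base = dict(
                beta_P=rng.uniform(-3, 3),
                beta_PH=rng.uniform(-3, 18),
                theta=rng.uniform(-5, 8),
                gamma=rng.uniform(-4, 4),
            )
            for choice in ("accept", "reject"):
                sv2 = models.subjective_value(2, base, t, choice)
                assert models.subjective_value(
                    4, {**base, "delta": 0.0}, t, choice
                ) == pytest.approx(sv2)
                assert models.subjective_value(
                    5, {**base, "omega": 0.0}, t, choice
                ) == pytest.approx(sv2)
                assert models.subjective_value(
                    2, {**base, "gamma": 0.0}, t, choice
                ) == pytest.approx(models.subjective_value(1, base, t, choice))

    def test_control_sv_invariant_to_bribe_parameters(self):
        """theta/omega/delta gradients vanish on q=0 trials for models 1-5."""
        t = task.Trial("Dyad", "Control", 80, 24)
        for model_id in (1, 2, 3, 4, 5):
            spec = models.MODELS[model_id]
            base = {p: 1.0 for p in spec.parameter_names}
            for choice in ("accept", "reject"):
                ref = models.subjective_value(model_id, base, t, choice)
                for p in ("theta", "omega", "delta"):
                    if p in spec.parameter_names:
                        alt = models.subjective_value(
                            model_id, {**base, p: -7.5}, t, choice
                        )
                        assert alt == pytest.approx(ref)

    def test_fehr_schmidt_condition_specific_terms(self):
        t = task.Trial("Solo", "Bribe", 80, 24)  # p_P=56, p_PH=24 on accept
        params = {p: 0.0 for p in models.MODELS[6].parameter_names}
        params["alpha_SB"] = 0.5
        sv = models.subjective_value(6, params, t, "accept")
        assert sv == pytest.approx(24 - 0.5 * (56 - 24))
        # other-condition alphas must not leak in
        params2 = {**params, "alpha_DB": 3.0, "beta_DC": -2.0}
        assert models.subjective_value(6, params2, t, "accept") == pytest.approx(sv)

    def test_three_person_fehr_schmidt_averages_agents(self):
        t = task.Trial("Dyad", "Bribe", 96, 38)  # accept: p_P=58, p_PH=38, p_T=4
        params = {p: 0.0 for p in models.MODELS[7].parameter_names}
        params["alpha_P_DC"] = 1.0  # proposer disadvantageous inequity
        params["beta_T_DB"] = 0.4  # third-party advantageous inequity
        sv = models.subjective_value(7, params, t, "accept")
        assert sv == pytest.approx(38 - 0.5 * (58 - 38) - 0.5 * 0.4 * (38 - 4))

    def test_unknown_model_and_missing_parameter(self):
        with pytest.raises(KeyError):
            models.get_model(9)
        with pytest.raises(KeyError):
            models.subjective_value(5, {"beta_P": 0.0}, DB_TRIAL, "accept")


class TestAcceptProbability:
    def test_zero_temperature_is_random_choice(self):
        assert models.accept_probability(0.0, 500.0, -500.0) == 0.5

    def test_equal_values_are_coin_flips(self):
        assert models.accept_probability(3.0, 7.7, 7.7) == 0.5

    def test_exemplar_trial_probability(self):
        p = models.accept_probability(0.01, 288.88, 93.12)
        assert p == pytest.approx(1 / (1 + np.exp(-1.9576)), abs=1e-6)
        assert p == pytest.approx(0.8763, abs=5e-4)

    def test_numerically_stable_at_extremes(self):
        assert models.accept_probability(10.0, 1e4, -1e4) == pytest.approx(1.0)
        assert models.accept_probability(10.0, -1e4, 1e4) == pytest.approx(0.0)

    def test_rejects_out_of_range_tau(self):
        with pytest.raises(ValueError):
            models.accept_probability(-0.1, 1.0, 0.0)
        with pytest.raises(ValueError):
            models.accept_probability(10.5, 1.0, 0.0)

    @given(
        tau=st.floats(0.0, 10.0),
        a=st.floats(-500, 500),
        r=st.floats(-500, 500),
    )
    @settings(deadline=None, max_examples=200)
    def test_complement_symmetry(self, tau, a, r):
        p = models.accept_probability(tau, a, r)
        q = models.accept_probability(tau, r, a)
        assert p + q == pytest.approx(1.0, abs=1e-12)
        assert 0.0 <= p <= 1.0

    @given(
        tau=st.floats(0.01, 1.0),
        a=st.floats(-25, 25),
        gap=st.floats(0.001, 5),
    )
    @settings(deadline=None, max_examples=200)
    def test_strictly_increasing_in_value_difference(self, tau, a, gap):
        # domain kept below float saturation of the logistic (|logit| < ~30)
        assert models.accept_probability(tau, a + gap, 0.0) > models.accept_probability(
            tau, a, 0.0
        )


@pytest.fixture(scope="module")
def design():
    return task.expand_design(task.build_offer_set(), 1, seed=11)


class TestLogLikelihood:
    def test_zero_temperature_gives_log_half_everywhere(self, design):
        df = design.copy()
        df["choice"] = 1
        ll = models.log_likelihood(df, 5, {**GROUP_MEANS, "tau": 0.0})
        assert np.allclose(ll, np.log(0.5))
        assert np.isfinite(ll.sum())

    def test_single_trial_value(self):
        df = pd.DataFrame(
            [
                dict(
                    subject_id="s1",
                    scenario="Dyad",
                    conduct="Bribe",
                    reported_payoff=96,
                    offer_amount=38,
                    choice=1,
                )
            ]
        )
        ll = models.log_likelihood(df, 5, {**GROUP_MEANS, "tau": 0.01})
        assert ll[0] == pytest.approx(np.log(0.8763), abs=1e-3)

    def test_flipping_one_choice_changes_only_that_element(self, design):
        df = design.copy()
        df["choice"] = 0
        params = {**GROUP_MEANS, "tau": 0.01}
        base = models.log_likelihood(df, 5, params)
        df.loc[10, "choice"] = 1
        flipped = models.log_likelihood(df, 5, params)
        changed = np.flatnonzero(base != flipped)
        assert changed.tolist() == [10]

    def test_missing_choice_column_raises(self, design):
        with pytest.raises(ValueError, match="choice"):
            models.log_likelihood(design, 5, {**GROUP_MEANS, "tau": 0.01})


class TestSimulateChoices:
    def test_saturated_temperature_accepts_everything(self, design):
        params = [dict(beta_P=0.0, beta_PH=20.0, theta=0.0, omega=0.0, gamma=0.0, tau=10.0)]
        sim = models.simulate_choices(design, 5, params, seed=0)
        assert sim["choice"].mean() == 1.0

    def test_zero_temperature_is_binomial_half(self, design):
        params = [dict(**GROUP_MEANS, tau=0.0)]
        sim = models.simulate_choices(design, 5, params, seed=1)
        rate = sim["choice"].mean()
        assert abs(rate - 0.5) < 4 * 0.5 / np.sqrt(144)

    def test_equal_seeds_reproduce(self, design):
        params = [dict(**GROUP_MEANS, tau=0.01)]
        a = models.simulate_choices(design, 5, params, seed=5)
        b = models.simulate_choices(design, 5, params, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_subject_mismatch_raises(self, design):
        with pytest.raises(ValueError, match="parameter vectors"):
            models.simulate_choices(design, 5, [], seed=0)
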