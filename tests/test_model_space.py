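"""Utility functions, updating rules, choice rules, and the 18-model space."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pvlkit import (
    ModelSpec,
    TrialOutcome,
    choice_probabilities,
    enumerate_model_space,
    parameter_bounds,
    sensitivity_tdc,
    sensitivity_tic,
    update_delta,
    update_drl,
    update_mixed,
    utility_eu,
    utility_pu,
    utility_pu2,
)
from pvlkit.model_space import (
    DeltaParams,
    DRLParams,
    EUParams,
    MixedParams,
    PUParams,
    PU2Params,
)

unit = st.floats(0.0, 1.0, allow_nan=False)
amount = st.floats(0.0, 15.0, allow_nan=False)
expectancy = st.floats(-50.0, 50.0, allow_nan=False)


class TestUtilities:
    @pytest.mark.parametrize(
        "win,loss,W,expected",
        [(1, 3, 0.5, -1.0), (2, 0, 0.0, 2.0), (2, 0, 1.0, 0.0), (4, 4, 0.5, 0.0)],
    )
    def test_eu(self, win, loss, W, expected):
        assert utility_eu(TrialOutcome(win, loss), EUParams(W)) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "win,loss,alpha,lam,expected",
        [
            (3, 1, 0.0, 2.5, 1.0),   # step function: any net gain is worth 1
            (1, 3, 0.0, 2.5, -2.5),  # ... and any net loss -lam
            (2, 2, 0.7, 5.0, 0.0),   # equal gain and loss nets to zero
            (5, 1, 1.0, 2.0, 4.0),   # alpha=1 is linear in the net
            (1, 5, 1.0, 2.0, -8.0),
            (2, 2, 0.0, 3.0, 1.0),   # x=0 takes the nonnegative branch
        ],
    )
    def test_pu(self, win, loss, alpha, lam, expected):
        assert utility_pu(TrialOutcome(win, loss), PUParams(alpha, lam)) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "win,loss,alpha,gamma,expected",
        [
            (2, 2, 1.0, 1.5, -1.0),  # equal gain/loss is NOT neutral here
            (0, 0, 0.5, 3.0, 0.0),
            (1, 3, 1.0, 0.5, -0.5),
            (4, 0, 0.5, 2.0, 2.0),
        ],
    )
    def test_pu2(self, win, loss, alpha, gamma, expected):
        assert utility_pu2(TrialOutcome(win, loss), PU2Params(alpha, gamma)) == pytest.approx(expected)

    @given(x=amount, alpha=st.floats(0.01, 1.0, allow_nan=False), lam=st.floats(0, 10, allow_nan=False))
    def test_pu_equal_gain_loss_is_always_zero(self, x, alpha, lam):
        # (the alpha = 0 corner is excluded: the step function maps the zero
        # net onto the gain branch, giving 1 rather than 0)
        assert utility_pu(TrialOutcome(x, x), PUParams(alpha, lam)) == 0.0

    @given(win=amount, loss=amount, alpha=st.floats(0.01, 1.0), lam=st.floats(0, 10))
    def test_pu_and_pu2_coincide_on_pure_outcomes(self, win, loss, alpha, lam):
        """With a single nonzero component and lam == gamma, the net-payoff and
        separate-evaluation prospect utilities are the same function — the
        reason the two families fit identically on SGT data."""
        for outcome in (TrialOutcome(win, 0.0), TrialOutcome(0.0, loss)):
            assert utility_pu(outcome, PUParams(alpha, lam)) == pytest.approx(
                utility_pu2(outcome, PU2Params(alpha, lam)), abs=1e-12
            )

    def test_param_validation(self):
        with pytest.raises(ValueError):
            EUParams(1.5)
        with pytest.raises(ValueError):
            PUParams(0.5, -1.0)


class TestUpdatingRules:
    E0 = np.array([10.0, 0.0, 0.0, 0.0])

    @pytest.mark.parametrize("A,expected", [(0.0, 10.0), (1.0, 5.0), (0.5, 7.5)])
    def test_delta_endpoints(self, A, expected):
        out = update_delta(self.E0, "A", 5.0, DeltaParams(A))
        assert out[0] == pytest.approx(expected)
        assert list(out[1:]) == [0.0, 0.0, 0.0]

    def test_drl_is_not_bounded_by_inputs(self):
        # the canonical worked example: 0.9 * 10 + 5 = 14
        out = update_drl(self.E0, "A", 5.0, DRLParams(0.9))
        assert out[0] == 14.0

    def test_drl_decays_unchosen(self):
        out = update_drl(np.array([10.0, 8.0, 0.0, 0.0]), "A", 5.0, DRLParams(0.9))
        assert out[1] == pytest.approx(7.2)
        out0 = update_drl(self.E0, "A", 5.0, DRLParams(0.0))
        assert list(out0) == [5.0, 0.0, 0.0, 0.0]

    def test_mixed_examples(self):
        out = update_mixed(np.array([10.0, 6.0, 0.0, 0.0]), "A", 5.0, MixedParams(1.0, 0.5))
        assert list(out) == [2.5, 0.0, 0.0, 0.0]
        out = update_mixed(self.E0, "A", 5.0, MixedParams(0.1, 0.5))
        assert out[0] == pytest.approx(7.0)  # 0.9*10 + 0.5*(5 - 9)

    @given(
        E=st.lists(expectancy, min_size=4, max_size=4),
        u=expectancy,
        A=unit,
        deck=st.sampled_from("ABCD"),
    )
    def test_delta_keeps_chosen_between_old_and_utility(self, E, u, A, deck):
        E = np.array(E)
        j = "ABCD".index(deck)
        new = update_delta(E, deck, u, DeltaParams(A))[j]
        lo, hi = min(E[j], u), max(E[j], u)
        assert lo - 1e-12 <= new <= hi + 1e-12

    @given(
        E=st.lists(expectancy, min_size=4, max_size=4),
        u=expectancy,
        A=unit,
        D=unit,
        deck=st.sampled_from("ABCD"),
    )
    def test_mixed_reductions(self, E, u, A, D, deck):
        E = np.array(E)
        # D = 0 reduces exactly to the delta rule
        assert np.array_equal(
            update_mixed(E, deck, u, MixedParams(0.0, A)),
            update_delta(E, deck, u, DeltaParams(A)),
        )
        # A = 1 pins the chosen deck to u regardless of D
        j = "ABCD".index(deck)
        assert update_mixed(E, deck, u, MixedParams(D, 1.0))[j] == pytest.approx(u)
        # chosen deck stays between its decayed value and u
        new = update_mixed(E, deck, u, MixedParams(D, A))[j]
        decayed = (1 - D) * E[j]
        assert min(decayed, u) - 1e-9 <= new <= max(decayed, u) + 1e-9


class TestChoiceRules:
    @pytest.mark.parametrize("t,c,expected", [(10, 3.7, 1.0), (40, 0.5, 2.0), (5, 0.0, 1.0)])
    def test_tdc(self, t, c, expected):
        assert sensitivity_tdc(t, c) == pytest.approx(expected)

    @pytest.mark.parametrize("c,expected", [(0.0, 0.0), (1.0, 2.0), (2.0, 8.0)])
    def test_tic(self, c, expected):
        assert sensitivity_tic(c) == pytest.approx(expected)

    def test_tic_rejects_negative_c(self):
        with pytest.raises(ValueError):
            sensitivity_tic(-0.1)

    def test_zero_sensitivity_is_uniform(self):
        probs = choice_probabilities([100.0, -3.0, 0.0, 7.0], theta=0.0)
        assert np.allclose(probs, 0.25)

    def test_symmetric_expectancies_are_uniform(self):
        assert np.allclose(choice_probabilities([5.0] * 4, theta=2.3), 0.25)

    def test_argmax_limit(self):
        probs = choice_probabilities([10.0, 0.0, 0.0, 0.0], theta=100.0)
        assert probs[0] > 0.999999

    @settings(max_examples=200)
    @given(
        E=st.lists(st.floats(-1e4, 1e4), min_size=4, max_size=4),
        theta=st.floats(0.0, 1.0),
    )
    def test_softmax_is_stable_and_normalized(self, E, theta):
        # |theta * E| up to 1e4: probabilities stay finite and sum to one
        probs = choice_probabilities(E, theta)
        assert np.all(np.isfinite(probs))
        assert np.all(probs >= 0)  # gaps beyond ~745 nats underflow to exact 0
        assert abs(probs.sum() - 1.0) < 1e-12


class TestModelSpace:
    def test_enumeration_is_the_full_factorial(self):
        space = enumerate_model_space()
        assert len(space) == 18
        assert len(set(space)) == 18

    @pytest.mark.parametrize(
        "name,triple,n_params",
        [
            ("EVL", ("EU", "DELTA", "TDC"), 3),
            ("PVL", ("PU", "DRL", "TIC"), 4),
            ("PVL2", ("PU2", "DRL", "TIC"), 4),
        ],
    )
    def test_presets(self, name, triple, n_params):
        spec = ModelSpec.from_string(name)
        assert (spec.utility, spec.updating, spec.choice) == triple
        assert spec.n_parameters == n_params
        assert spec.preset_name == name

    @pytest.mark.parametrize(
        "spec,expected_n",
        [
            (ModelSpec("EU", "DRL", "TIC"), 3),
            (ModelSpec("PU2", "MIXED", "TDC"), 5),
            (ModelSpec("PU", "DELTA", "TDC"), 4),
        ],
    )
    def test_parameter_counts_match_model_structure(self, spec, expected_n):
        bounds = parameter_bounds(spec)
        assert len(bounds) == expected_n
        assert bounds[-1][0] == "c"

    def test_bounds_values(self):
        bounds = dict(
            (name, (lo, hi)) for name, lo, hi in parameter_bounds(ModelSpec("EU", "DRL", "TIC"))
        )
        assert bounds == {"W": (0.0, 1.0), "A": (0.0, 1.0), "c": (0.0, 5.0)}
        tdc_c = [b for b in parameter_bounds(ModelSpec("EU", "DRL", "TDC")) if b[0] == "c"]
        assert tdc_c == [("c", -5.0, 5.0)]

    def test_string_round_trip(self):
        for spec in enumerate_model_space():
            assert ModelSpec.from_string(str(spec)) == spec

    def test_bad_spec_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec("XX", "DRL", "TIC")
        with pytest.raises(ValueError):
            ModelSpec.from_string("PU2-DRL")
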