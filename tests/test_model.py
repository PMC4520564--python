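"""Unit and property tests for the rate equations and LT dynamics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from leadsim.model import (
    AdaptationParameters,
    ModelParameters,
    cancel_rate,
    effective_l_prime,
    following_time_constant,
    initiation_rate,
    k_factor,
    update_lt,
)


class TestKFactor:
    @pytest.mark.parametrize(
        "lt, expected",
        [
            (0.5, 1.0),  # inflection point: moderate LT leaves the model unchanged
            (0.1, 2.0 / (1.0 + math.e**4)),
            (0.9, 2.0 / (1.0 + math.e**-4)),
        ],
    )
    def test_values(self, lt, expected, params):
        assert k_factor(lt, params) == pytest.approx(expected, rel=1e-12)

    def test_out_of_domain_raises(self, params):
        for bad in (0.0, 1.0, -0.2, 1.7):
            with pytest.raises(ValueError):
                k_factor(bad, params)

    def test_symmetry_grid(self, params):
        # anti-bias: the low side pulls exactly as hard as the high side
        grid = np.linspace(0.01, 0.99, 197)
        np.testing.assert_allclose(
            k_factor(grid, params) + k_factor(1.0 - grid, params),
            params.k_max,
            atol=1e-12,
        )

    @given(st.floats(min_value=0.01, max_value=0.98))
    @settings(max_examples=50, derandomize=True)
    def test_strictly_increasing(self, lt):
        assert k_factor(lt + 0.01) > k_factor(lt)


class TestEffectiveLPrime:
    @pytest.mark.parametrize(
        "lt, kind, expected",
        [(0.8, "initiate", 0.8), (0.8, "follow", 0.2), (0.8, "cancel", 0.2), (0.5, "cancel", 0.5)],
    )
    def test_mapping(self, lt, kind, expected):
        assert effective_l_prime(lt, kind) == pytest.approx(expected)

    def test_unknown_kind(self):
        with pytest.raises(ValueError):
            effective_l_prime(0.5, "abscond")


class TestRates:
    def test_initiation_rate_values(self, params):
        assert initiation_rate(0.5, params) == pytest.approx(1.0 / 1290.0, rel=1e-12)
        assert initiation_rate(0.9, params) == pytest.approx(
            (2.0 / (1.0 + math.e**-4)) / 1290.0, rel=1e-12
        )
        assert initiation_rate(0.1, params) == pytest.approx(
            (2.0 / (1.0 + math.e**4)) / 1290.0, rel=1e-12
        )

    def test_following_time_constant_values(self, params):
        assert following_time_constant(0.5, 10, 1, params) == pytest.approx(840.9)
        assert following_time_constant(0.5, 10, 9, params) == pytest.approx(162.3 + 75.4 / 9)
        # high-LT agents are reluctant followers: same tau scaled by 1/k(0.1)
        assert following_time_constant(0.9, 10, 1, params) == pytest.approx(
            840.9 * (1.0 + math.e**4) / 2.0, rel=1e-12
        )

    def test_following_preconditions(self, params):
        with pytest.raises(ValueError):
            following_time_constant(0.5, 10, 0, params)
        with pytest.raises(ValueError):
            following_time_constant(0.5, 10, 10, params)
        with pytest.raises(ValueError):
            following_time_constant(0.5, 1, 1, params)

    def test_cancel_rate_values(self, params):
        assert cancel_rate(0.5, 2, params) == pytest.approx(0.0045, rel=1e-12)
        assert cancel_rate(0.5, 1, params) == pytest.approx(0.009 / (1.0 + 0.5**2.3), rel=1e-12)
        assert cancel_rate(0.5, 3, params) == pytest.approx(0.009 / (1.0 + 1.5**2.3), rel=1e-12)
        with pytest.raises(ValueError):
            cancel_rate(0.5, 0, params)

    def test_monotonicity(self, params):
        lts = np.linspace(0.1, 0.9, 17)
        init = np.array([initiation_rate(l, params) for l in lts])
        follow = np.array([1.0 / following_time_constant(l, 10, 3, params) for l in lts])
        cancel = np.array([cancel_rate(l, 3, params) for l in lts])
        assert np.all(np.diff(init) > 0)
        assert np.all(np.diff(follow) < 0)
        assert np.all(np.diff(cancel) < 0)
        by_r = np.array([cancel_rate(0.5, r, params) for r in range(1, 10)])
        assert np.all(np.diff(by_r) < 0)

    def test_crossover_at_two_followers_plus_initiator(self, params):
        # with k=1 and N=10 the per-follower rate overtakes cancelling at r=3
        for r in (1, 2):
            assert 1.0 / following_time_constant(0.5, 10, r, params) < cancel_rate(0.5, r, params)
        assert 1.0 / following_time_constant(0.5, 10, 3, params) > cancel_rate(0.5, 3, params)

    def test_neutrality_at_moderate_lt(self, params):
        # L=0.5 gives k=1: every rate equals the baseline model's value
        assert initiation_rate(0.5, params) * params.tau_o == pytest.approx(1.0)
        for r in range(1, 10):
            base_tau = params.alpha_f + params.beta_f * (10 - r) / r
            assert following_time_constant(0.5, 10, r, params) == pytest.approx(base_tau)
            base_c = params.alpha_c / (1.0 + (r / params.gamma_c) ** params.epsilon_c)
            assert cancel_rate(0.5, r, params) == pytest.approx(base_c)


class TestUpdateLT:
    def test_examples(self, adapt):
        assert update_lt(0.5, True, adapt) == pytest.approx(0.51)
        assert update_lt(0.9, True, adapt) == pytest.approx(0.9)  # truncated at lt_max
        assert update_lt(0.1, False, adapt) == pytest.approx(0.1)  # truncated at lt_min

    def test_fixed_points(self, adapt):
        lt = 0.5
        for _ in range(2000):
            lt = update_lt(lt, True, adapt)
        assert lt == pytest.approx(adapt.lt_max)
        lt = 0.5
        for _ in range(2000):
            lt = update_lt(lt, False, adapt)
        assert lt == pytest.approx(adapt.lt_min)

    def test_lambda_zero_is_identity(self):
        frozen = AdaptationParameters(lambda_rate=0.0)
        assert update_lt(0.37, True, frozen) == pytest.approx(0.37)
        assert update_lt(0.37, False, frozen) == pytest.approx(0.37)

    @given(st.floats(min_value=0.1, max_value=0.9), st.booleans())
    @settings(max_examples=100, derandomize=True)
    def test_stays_in_bounds(self, lt, success):
        out = update_lt(lt, success, AdaptationParameters())
        assert 0.1 <= out <= 0.9


class TestParameterValidation:
    def test_table_defaults(self):
        p = ModelParameters()
        assert (p.tau_o, p.alpha_c, p.gamma_c, p.epsilon_c, p.alpha_f, p.beta_f) == (
            1290.0,
            0.009,
            2.0,
            2.3,
            162.3,
            75.4,
        )

    @pytest.mark.parametrize("bad", [{"tau_o": 0}, {"alpha_f": -1}, {"gamma_c": 0.0}])
    def test_rejects_nonpositive(self, bad):
        with pytest.raises(ValueError):
            ModelParameters(**bad)

    @pytest.mark.parametrize(
        "bad", [{"lambda_rate": 1.5}, {"lambda_rate": -0.1}, {"lt_min": 0.6, "lt_max": 0.4}]
    )
    def test_rejects_bad_adaptation(self, bad):
        with pytest.raises(ValueError):
            AdaptationParameters(**bad)
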