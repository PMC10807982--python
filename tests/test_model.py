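"""Unit and property tests for the model core: parameter validation, the
vector field, and the per-process flow decomposition."""

import logging

import numpy as np
import pytest
from hypothesis import given, settings

from cultsim import (
    ModelParams,
    ParameterError,
    SimplexError,
    SimplexState,
    flow_decomposition,
    flows_to_rhs,
    rhs,
    validate_params,
)
from conftest import model_params, simplex_states


class TestValidateParams:
    def test_headline_values_are_valid(self):
        p = validate_params({"mu": 0.01, "m": 0.1, "c": 0.75, "se": 0.5, "si": 0.1})
        assert p == ModelParams(0.01, 0.1, 0.75, 0.5, 0.1)

    def test_all_zero_boundary_is_valid(self):
        validate_params({"mu": 0, "m": 0, "c": 0, "se": 0, "si": 0})

    @pytest.mark.parametrize(
        "field,value",
        [("c", 1.5), ("c", -0.1), ("mu", -1e-9), ("m", -0.2),
         ("se", float("nan")), ("si", float("inf"))],
    )
    def test_out_of_range_names_the_field(self, field, value):
        raw = {"mu": 0.01, "m": 0.1, "c": 0.75, "se": 0.5, "si": 0.1}
        raw[field] = value
        with pytest.raises(ParameterError, match=field):
            validate_params(raw)

    def test_missing_and_unknown_fields_rejected(self):
        with pytest.raises(ParameterError, match="missing"):
            validate_params({"mu": 0.01, "m": 0.1, "c": 0.75, "se": 0.5})
        with pytest.raises(ParameterError, match="valid names"):
            validate_params({"mu": 0.01, "m": 0.1, "c": 0.75, "se": 0.5,
                             "si": 0.1, "zeta": 1.0})

    def test_se_not_above_si_warns_but_validates(self, caplog):
        with caplog.at_level(logging.WARNING, logger="cultsim.model"):
            validate_params({"mu": 0.01, "m": 0.1, "c": 0.75,
                             "se": 0.1, "si": 0.1})
        assert any("se" in rec.message for rec in caplog.records)


class TestSimplexState:
    def test_strict_user_construction_rejects_out_of_range(self):
        with pytest.raises(SimplexError):
            SimplexState.from_fractions(-1e-15, 0.5, 0.5)
        with pytest.raises(SimplexError):
            SimplexState.from_fractions(0.4, 0.4, 0.4)

    def test_solver_slack_tolerated_but_bounded(self):
        SimplexState(-1e-13, 0.5, 0.5 + 1e-13)
        with pytest.raises(SimplexError):
            SimplexState(-1e-6, 0.5, 0.5)


class TestRhs:
    @pytest.mark.parametrize(
        "state,params,expected",
        [
            # hand substitution: from an all-inefficient population only the
            # turnover and innovation terms act
            ((0, 1, 0), (0.01, 0.1, 0.75, 0.5, 0.1), (0.1, -0.11, 0.01)),
            # with c = 1 the knowledgeable-exchange terms vanish
            ((1 / 3, 1 / 3, 1 / 3), (0, 0, 1, 0.5, 0.1),
             (-1 / 15, 1 / 90, 1 / 18)),
            # every term carries a rate factor
            ((0.2, 0.3, 0.5), (0, 0, 0, 0, 0), (0.0, 0.0, 0.0)),
        ],
    )
    def test_hand_computed_values(self, state, params, expected):
        out = rhs(SimplexState(*state), ModelParams(*params))
        assert out == pytest.approx(expected, abs=1e-15)

    @given(state=simplex_states(), params=model_params())
    @settings(max_examples=300, derandomize=True)
    def test_conservation(self, state, params):
        dn, di, de = rhs(state, params)
        assert abs(dn + di + de) < 1e-14

    @given(params=model_params())
    @settings(max_examples=100, derandomize=True)
    def test_all_naive_is_a_fixed_point(self, params):
        assert rhs(SimplexState(1, 0, 0), params) == (0.0, 0.0, 0.0)

    @given(state=simplex_states(), params=model_params())
    @settings(max_examples=200, derandomize=True)
    def test_full_conservatism_matches_reduced_system(self, state, params):
        """With c = 1 the system reduces to innovation + turnover + naive
        learning only; compare against that hand-coded reduction."""
        p = ModelParams(params.mu, params.m, 1.0, params.se, params.si)
        n, i, e = state.n, state.i, state.e
        reduced = (
            p.m * i + p.m * e - n * e * p.se - n * i * p.si,
            -p.mu * i - p.m * i + n * i * p.si,
            p.mu * i - p.m * e + n * e * p.se,
        )
        assert rhs(state, p) == pytest.approx(reduced, abs=1e-15)

    @given(state=simplex_states(), params=model_params())
    @settings(max_examples=200, derandomize=True)
    def test_equal_learnability_without_innovation_is_exchange_symmetric(
        self, state, params
    ):
        """With se = si and mu = 0 the i and e compartments obey the same
        equation, so swapping (i, e) swaps (di, de)."""
        p = ModelParams(0.0, params.m, params.c, params.si, params.si)
        dn, di, de = rhs(state, p)
        swapped = SimplexState(state.n, state.e, state.i)
        dn2, di2, de2 = rhs(swapped, p)
        assert dn2 == pytest.approx(dn, abs=1e-15)
        assert di2 == pytest.approx(de, abs=1e-15)
        assert de2 == pytest.approx(di, abs=1e-15)


class TestFlowDecomposition:
    def test_all_inefficient_flows(self, headline_params):
        flows = flow_decomposition(SimplexState(0, 1, 0), headline_params)
        assert flows["innovation"] == pytest.approx(0.01)
        assert flows["turnover_i"] == pytest.approx(0.1)
        assert flows["turnover_e"] == 0.0
        assert all(
            flows[k] == 0.0
            for k in ("learn_from_i", "learn_from_e",
                      "exchange_i_to_e", "exchange_e_to_i")
        )

    @given(params=model_params())
    @settings(max_examples=50, derandomize=True)
    def test_all_naive_has_no_flows(self, params):
        flows = flow_decomposition(SimplexState(1, 0, 0), params)
        assert all(v == 0.0 for v in flows.values())

    def test_reconstructs_rhs_on_random_states(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n, i, e = rng.dirichlet((1, 1, 1))
            state = SimplexState(n, i, e)
            params = ModelParams(
                mu=rng.uniform(0, 0.1), m=rng.uniform(0, 0.5),
                c=rng.uniform(0, 1), se=rng.uniform(0, 1),
                si=rng.uniform(0, 1),
            )
            flows = flow_decomposition(state, params)
            assert all(v >= 0.0 for v in flows.values())
            assert flows_to_rhs(flows) == pytest.approx(
                rhs(state, params), abs=5e-16
            )
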