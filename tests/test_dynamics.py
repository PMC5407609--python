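"""Discrete evaluation, BooleCube/HillCube transforms and ODE integration."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import boolecube_corner_sum, random_rule
from qualnet.dynamics import (
    ContinuousModel,
    DuplicateOverrideWarning,
    SimulationParameters,
    boolecube,
    evaluate_boolean,
    hill,
    hillcube,
    integrate,
    normalized_hillcube,
    ode_rhs,
    simulate_boolean,
    synchronous_step,
)
from qualnet.io import parse_boolean_equations
from qualnet.model import Literal, NetworkError, UpdateRule


AND_AB = UpdateRule("T", ((Literal("A"), Literal("B")),))
OR_AB = UpdateRule("T", ((Literal("A"),), (Literal("B"),)))
A_NOT_B = UpdateRule("T", ((Literal("A"), Literal("B", negated=True)),))


class TestBooleanEvaluation:
    @pytest.mark.parametrize("rule,state,expected", [
        (AND_AB, {"A": 1, "B": 1}, 1),
        (AND_AB, {"A": 1, "B": 0}, 0),
        (OR_AB, {"A": 0, "B": 0}, 0),
        (OR_AB, {"A": 0, "B": 1}, 1),
        (A_NOT_B, {"A": 1, "B": 1}, 0),
        (A_NOT_B, {"A": 1, "B": 0}, 1),
    ])
    def test_sop_semantics(self, rule, state, expected):
        assert evaluate_boolean(rule, state) == expected

    def test_missing_regulator_raises(self):
        with pytest.raises(KeyError, match="lacks regulator"):
            evaluate_boolean(AND_AB, {"A": 1})


class TestSynchronousSimulation:
    def test_self_activator_fixed_point(self):
        net = parse_boolean_equations("X = X")
        res = simulate_boolean(net, {"X": 1})
        assert res.period == 1
        assert res.cycle == [{"X": 1}]

    def test_negative_two_loop_has_period_four(self):
        # A=!B, B=A from (0,0): (0,0)->(1,0)->(1,1)->(0,1)->(0,0)
        net = parse_boolean_equations("A = !B\nB = A")
        res = simulate_boolean(net, {"A": 0, "B": 0})
        assert res.period == 4
        assert res.cycle_start == 0
        expected = [(0, 0), (1, 0), (1, 1), (0, 1)]
        assert [(s["A"], s["B"]) for s in res.states] == expected

    def test_trajectory_inside_cycle_stays_inside(self):
        net = parse_boolean_equations("A = !B\nB = A")
        res = simulate_boolean(net, {"A": 1, "B": 0})  # a cycle state
        assert res.cycle_start == 0  # determinism: never leaves the cycle

    def test_inputs_and_clamps_held(self):
        net = parse_boolean_equations("B = A\nC = B")
        stepped = synchronous_step(
            net, {"A": 1, "B": 0, "C": 0}, clamps={"B": 0}
        )
        assert stepped == {"A": 1, "B": 0, "C": 0}


class TestBooleCube:
    def test_and_is_product(self):
        for a, b in itertools.product(np.linspace(0, 1, 5), repeat=2):
            assert boolecube(AND_AB, {"A": a, "B": b}) == pytest.approx(
                a * b, abs=1e-12
            )

    def test_or_is_inclusion_exclusion(self):
        for a, b in itertools.product(np.linspace(0, 1, 5), repeat=2):
            assert boolecube(OR_AB, {"A": a, "B": b}) == pytest.approx(
                a + b - a * b, abs=1e-12
            )

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_corner_sum_oracle(self, seed):
        rng = np.random.default_rng(seed)
        rule = random_rule(rng, 4)
        state = {r: float(rng.random()) for r in rule.regulators}
        assert boolecube(rule, state) == pytest.approx(
            boolecube_corner_sum(rule, state), abs=1e-12
        )

    def test_multilinearity_affine_in_each_coordinate(self):
        rng = np.random.default_rng(1)
        rule = random_rule(rng, 3)
        base = {r: float(rng.random()) for r in rule.regulators}
        for reg in rule.regulators:
            lo = boolecube(rule, {**base, reg: 0.0})
            hi = boolecube(rule, {**base, reg: 1.0})
            mid = boolecube(rule, {**base, reg: 0.3})
            assert mid == pytest.approx(lo + 0.3 * (hi - lo), abs=1e-12)

    def test_domain_violation_rejected(self):
        with pytest.raises(NetworkError):
            boolecube(AND_AB, {"A": 1.2, "B": 0.5})


class TestHill:
    def test_half_maximal_at_k(self):
        for n in (1, 2, 3, 8):
            assert hill(0.4, n, 0.4) == pytest.approx(0.5)

    def test_zero_at_zero(self):
        assert hill(0.0, 3, 0.5) == 0.0

    def test_saturation_below_one(self):
        assert hill(1.0, 3, 0.5) == pytest.approx(1 / 1.125)  # 0.888889

    def test_monotone_increasing(self):
        xs = np.linspace(0, 1, 50)
        assert np.all(np.diff(hill(xs, 3, 0.5)) > 0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(NetworkError):
            hill(0.5, -1, 0.5)
        with pytest.raises(NetworkError):
            hill(0.5, 3, 1.5)


class TestHillCube:
    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(seed=st.integers(0, 10_000), n_inputs=st.integers(1, 8))
    def test_normalized_equals_boolean_on_corners(self, seed, n_inputs):
        rule = random_rule(np.random.default_rng(seed), n_inputs)
        for corner in itertools.product((0, 1), repeat=len(rule.regulators)):
            state = dict(zip(rule.regulators, map(float, corner)))
            discrete = evaluate_boolean(rule, dict(zip(rule.regulators,
                                                       corner)))
            assert normalized_hillcube(rule, state) == pytest.approx(
                discrete, abs=1e-9
            )

    def test_unnormalized_identity_rule_saturates_below_one(self):
        ident = UpdateRule("T", ((Literal("A"),),))
        assert hillcube(ident, {"A": 1.0}) == pytest.approx(1 / 1.125)

    @pytest.mark.parametrize("seed", range(5))
    def test_normalized_composition_oracle(self, seed):
        # independent two-step route: normalize Hill transforms by hand,
        # then interpolate with the corner-sum oracle
        rng = np.random.default_rng(seed)
        rule = random_rule(rng, 4)
        params = SimulationParameters()
        state = {r: float(rng.random()) for r in rule.regulators}
        transformed = {
            r: hill(state[r], params.default_n, params.default_k)
            / hill(1.0, params.default_n, params.default_k)
            for r in rule.regulators
        }
        assert normalized_hillcube(rule, state, params) == pytest.approx(
            boolecube_corner_sum(rule, transformed), abs=1e-12
        )

    def test_monotone_rule_gives_monotone_transform(self):
        rule = OR_AB  # no inhibiting literal
        xs = np.linspace(0, 1, 21)
        vals = [normalized_hillcube(rule, {"A": x, "B": 0.3}) for x in xs]
        assert np.all(np.diff(vals) >= 0)

    def test_large_n_approaches_boolean_step(self):
        params = SimulationParameters(default_n=200)
        # well away from the threshold k=0.5 the rule is a step function
        assert normalized_hillcube(AND_AB, {"A": 0.9, "B": 0.8},
                                   params) == pytest.approx(1, abs=1e-6)
        assert normalized_hillcube(AND_AB, {"A": 0.9, "B": 0.2},
                                   params) == pytest.approx(0, abs=1e-6)


class TestParameters:
    def test_default_values(self):
        p = SimulationParameters()
        assert (p.default_n, p.default_k, p.default_tau) == (3.0, 0.5, 1.0)

    def test_override_precedence_edge_then_node_then_default(self):
        p = SimulationParameters(
            hill_overrides={("T", "A"): (20, 0.1), ("T", "*"): (5, 0.9)},
            tau_overrides={"T": 10.0},
        )
        assert p.resolve_hill("T", "A") == (20, 0.1)
        assert p.resolve_hill("T", "B") == (5, 0.9)
        assert p.resolve_hill("U", "A") == (3.0, 0.5)
        assert p.resolve_tau("T") == 10.0
        assert p.resolve_tau("U") == 1.0

    def test_duplicate_records_warn_and_later_wins(self):
        with pytest.warns(DuplicateOverrideWarning):
            p = SimulationParameters.from_records([
                {"target": "DGK", "source": "*", "n": 20, "k": 0.9},
                {"target": "DGK", "source": "*", "n": 3, "k": 0.9},
            ])
        assert p.resolve_hill("DGK", "X") == (3.0, 0.9)

    def test_yaml_round_trip(self):
        p = SimulationParameters(
            default_n=4,
            hill_overrides={("LCK", "MAPK1"): (20.0, 0.1)},
            tau_overrides={"LCK": 10.0},
        )
        q = SimulationParameters.from_yaml(p.to_yaml())
        assert q == p

    def test_packaged_tcell_parameter_file(self):
        from importlib.resources import files

        text = files("qualnet.data").joinpath("tcell_params.yaml").read_text()
        with pytest.warns(DuplicateOverrideWarning):
            p = SimulationParameters.from_yaml(text)
        assert p.resolve_hill("LCK", "MAPK1") == (20.0, 0.1)
        assert p.resolve_tau("LCK") == 10.0
        assert p.resolve_hill("DGK", "anything") == (3.0, 0.9)  # later wins

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            SimulationParameters(default_k=1.5)
        with pytest.raises(ValueError):
            SimulationParameters(default_tau=0)


class TestOde:
    def test_constant_drive_unit_derivative(self):
        net = parse_boolean_equations("X = A")
        dx = ode_rhs(net, None, {"A": 1}, {"A": 1.0, "X": 0.0})
        assert dx["X"] == pytest.approx(1.0)
        assert dx["A"] == 0.0

    def test_zero_derivative_at_drive_value(self):
        net = parse_boolean_equations("X = A")
        dx = ode_rhs(net, None, {"A": 1}, {"A": 1.0, "X": 1.0})
        assert dx["X"] == pytest.approx(0.0, abs=1e-12)

    def test_linear_relaxation_matches_closed_form(self):
        # X driven by a clamped-on input: x(t) = 1 - exp(-t)
        net = parse_boolean_equations("X = A")
        traj = integrate(
            net, initial={"A": 1.0, "X": 0.0}, clamps={"A": 1},
            t_end=5.0, grid_dt=0.5,
        )
        for t in (1.0, 2.0, 5.0):
            idx = int(round(t / 0.5))
            assert traj.column("X")[idx] == pytest.approx(
                1 - np.exp(-t), abs=1e-6
            )

    def test_all_zero_state_is_fixed_for_pure_activation(self):
        net = parse_boolean_equations("B = A\nC = A & B\nD = B | C")
        traj = integrate(net, t_end=20.0)
        assert np.all(traj.values == 0.0)

    def test_trajectory_stays_in_unit_cube(self, toy_net):
        x0 = {n: 0.0 for n in toy_net.nodes}
        x0.update(S1=1.0, S2=1.0)
        traj = integrate(toy_net, initial=x0, t_end=100.0)
        assert traj.values.min() >= 0.0 and traj.values.max() <= 1.0

    def test_vector_field_points_inward_on_boundary(self, toy_net):
        rng = np.random.default_rng(0)
        model = ContinuousModel(toy_net)
        for _ in range(20):
            x = rng.random(toy_net.n_nodes)
            i = int(rng.integers(toy_net.n_nodes))
            for bound, sign in ((0.0, 1), (1.0, -1)):
                x[i] = bound
                dx = model.rhs(0.0, x)
                assert sign * dx[i] >= -1e-12

    def test_clamped_node_constant_throughout(self, toy_net):
        x0 = {n: 0.0 for n in toy_net.nodes}
        x0.update(S1=1.0, S2=1.0)
        traj = integrate(toy_net, initial=x0, clamps={"LCK": 1}, t_end=50.0)
        assert np.all(traj.column("LCK") == 1.0)

    def test_tau_scales_relaxation_time(self):
        net = parse_boolean_equations("X = A")
        slow = SimulationParameters(tau_overrides={"X": 10.0})
        traj = integrate(
            net, params=slow, initial={"A": 1.0, "X": 0.0},
            clamps={"A": 1}, t_end=10.0, grid_dt=1.0,
        )
        assert traj.column("X")[-1] == pytest.approx(1 - np.exp(-1), abs=1e-6)
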