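import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from thermokin.graph import Condition, GraphError, Process, State, build_graph
from thermokin.fixtures import (
    ANTIPORTER_CONDITION,
    ANTIPORTER_CYCLE,
    ANTIPORTER_MARKER,
    make_antiporter,
)
from thermokin.kinetics import (
    KineticModel,
    apply_voltage,
    cycle_drive,
    edge_flux,
    node_balance,
    steady_state,
    turnover,
)
from thermokin.observables import microstate_probabilities
from thermokin.rates import consistent_rate_set


def gradient_condition(pH_in=7.4, pH_out=7.0, na_in=0.01, na_out=0.1, mv=0.0):
    return Condition(pH=pH_out, concentrations={"Na+": na_out},
                     pH_in=pH_in, pH_out=pH_out,
                     concentrations_in={"Na+": na_in},
                     concentrations_out={"Na+": na_out}, voltage_mV=mv)


@pytest.fixture(scope="module")
def antiporter_model(antiporter_rates):
    return KineticModel.from_rate_set(antiporter_rates)


@pytest.fixture(scope="module")
def electrogenic_model():
    import warnings

    g = make_antiporter(electrogenic=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        rs = consistent_rate_set(g, ANTIPORTER_CONDITION)
    return KineticModel.from_rate_set(rs)


class TestApplyVoltage:
    def test_zero_voltage_unchanged(self):
        assert apply_voltage(3.0, 5.0, 1.0, 0.0) == (3.0, 5.0)

    def test_zero_charge_unchanged(self):
        assert apply_voltage(3.0, 5.0, 0.0, 120.0) == (3.0, 5.0)

    def test_unit_charge_unit_thermal_voltage(self):
        kf, kb = apply_voltage(1.0, 1.0, 1.0, 25.693)
        assert kf == pytest.approx(math.exp(-0.5))
        assert kb == pytest.approx(math.exp(+0.5))

    def test_ratio_carries_full_electrostatic_energy(self):
        kf, kb = apply_voltage(7.0, 3.0, 2.0, 40.0)
        assert math.log(kf / kb) == pytest.approx(
            math.log(7.0 / 3.0) - 2.0 * 40.0 / 25.693)


class TestSteadyState:
    def test_two_state_closed_form(self):
        g = build_graph([State("A"), State("B")],
                        [Process("A", "B", "ratepair", value=2.0, sigma=0.1,
                                 value2=1.0, sigma2=0.1)])
        model = KineticModel.from_graph(g, Condition())
        p = steady_state(model.rate_matrix(Condition()))
        assert np.allclose(p, [1.0 / 3.0, 2.0 / 3.0], atol=1e-12)

    def test_generator_columns_sum_to_zero(self, antiporter_model):
        A = antiporter_model.rate_matrix(gradient_condition()).matrix
        assert np.allclose(A.sum(axis=0), 0.0, atol=1e-8 * np.abs(A).max())

    def test_boltzmann_limit_at_equilibrium(self, antiporter_model, antiporter_rates):
        p = steady_state(antiporter_model.rate_matrix(ANTIPORTER_CONDITION))
        boltzmann = np.array(list(
            microstate_probabilities(antiporter_rates.potentials).values()))
        assert np.allclose(p, boltzmann, atol=1e-10)

    def test_agrees_with_long_time_propagation(self, antiporter_model):
        from scipy.linalg import expm

        cond = gradient_condition()
        A = antiporter_model.rate_matrix(cond).matrix
        p0 = np.full(A.shape[0], 1.0 / A.shape[0])
        p_t = expm(A * 10.0) @ p0  # many multiples of the slowest timescale
        p_inf = steady_state(antiporter_model.rate_matrix(cond))
        assert np.allclose(p_t, p_inf, atol=1e-9)

    def test_agrees_with_ode_integration_small_system(self):
        g = build_graph(
            [State(n) for n in "ABC"],
            [Process("A", "B", "ratepair", value=2.0, sigma=0.1, value2=1.0,
                     sigma2=0.1),
             Process("B", "C", "ratepair", value=0.5, sigma=0.1, value2=3.0,
                     sigma2=0.1),
             Process("C", "A", "ratepair", value=1.5, sigma=0.1, value2=0.7,
                     sigma2=0.1)])
        model = KineticModel.from_graph(g, Condition())
        A = model.rate_matrix(Condition()).matrix
        sol = solve_ivp(lambda t, p: A @ p, (0.0, 200.0), [1.0, 0.0, 0.0],
                        rtol=1e-10, atol=1e-12)
        assert np.allclose(sol.y[:, -1], steady_state(model.rate_matrix(Condition())),
                           atol=1e-8)

    def test_reducible_matrix_names_absorbing_component(self):
        g = build_graph(
            [State("A"), State("B")],
            [Process("A", "B", "ratepair", value=1.0, sigma=0.1,
                     value2=1e-300, sigma2=0.1)])
        model = KineticModel.from_graph(g, Condition())
        rm = model.rate_matrix(Condition())
        rm.matrix[0, 1] = 0.0  # truly absorbing B
        with pytest.raises(GraphError, match="absorbing"):
            steady_state(rm)


class TestEdgeFlux:
    def test_equilibrium_fluxes_vanish(self, antiporter_model):
        p = steady_state(antiporter_model.rate_matrix(ANTIPORTER_CONDITION))
        flux = edge_flux(p, antiporter_model, ANTIPORTER_CONDITION)
        assert np.abs(flux["J"]).max() < 1e-10 * 3.2e7  # vs largest rate

    def test_kirchhoff_balance_at_steady_state(self, antiporter_model):
        cond = gradient_condition()
        p = steady_state(antiporter_model.rate_matrix(cond))
        flux = edge_flux(p, antiporter_model, cond)
        assert np.abs(node_balance(flux, antiporter_model.graph.names)).max() < 1e-8

    def test_single_cycle_carries_uniform_flux(self, antiporter_rates):
        # with the leak edge removed the graph is one cycle: every edge
        # carries the same net flux (perfect 1:1 proton:sodium coupling)
        import warnings

        g = make_antiporter(leak_scale=0.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            model = KineticModel.from_rate_set(
                consistent_rate_set(g, ANTIPORTER_CONDITION))
        cond = gradient_condition()
        p = steady_state(model.rate_matrix(cond))
        J = edge_flux(p, model, cond)["J"].to_numpy()
        assert np.allclose(J, J[0], rtol=1e-8)


class TestTurnover:
    def test_zero_at_equilibrium(self, antiporter_model):
        t = turnover(antiporter_model, ANTIPORTER_CONDITION, ANTIPORTER_MARKER)
        assert abs(t) < 1e-8

    def test_sign_matches_cycle_drive_for_ph_gradient(self, antiporter_model):
        cond = gradient_condition(pH_in=7.4, pH_out=7.0, na_in=0.1, na_out=0.1)
        chi = cycle_drive(antiporter_model, cond, ANTIPORTER_CYCLE).chi
        t = turnover(antiporter_model, cond, ANTIPORTER_MARKER)
        assert chi < 0 and t < 0

    def test_gradient_inversion_reverses_transport(self, antiporter_model):
        fwd = turnover(antiporter_model, gradient_condition(), ANTIPORTER_MARKER)
        rev = turnover(antiporter_model,
                       gradient_condition(pH_in=7.0, pH_out=7.4,
                                          na_in=0.1, na_out=0.01),
                       ANTIPORTER_MARKER)
        assert fwd > 0 > rev

    def test_stalling_at_large_membrane_potential(self, antiporter_model):
        t0 = turnover(antiporter_model, gradient_condition(), ANTIPORTER_MARKER)
        for mv in (300.0, -300.0):
            t = turnover(antiporter_model, gradient_condition(mv=mv),
                         ANTIPORTER_MARKER)
            assert abs(t) < 1e-2 * abs(t0)

    def test_unknown_marker_edge_rejected(self, antiporter_model):
        with pytest.raises(GraphError, match="marker"):
            turnover(antiporter_model, ANTIPORTER_CONDITION, "X->Y")


class TestCycleDrive:
    def test_consistent_rates_have_zero_drive_at_reference(self, antiporter_model):
        drive = cycle_drive(antiporter_model, ANTIPORTER_CONDITION,
                            ANTIPORTER_CYCLE)
        assert abs(drive.chi) < 1e-10
        assert abs(drive.intrinsic) < 1e-10

    def test_input_rates_carry_spurious_drive(self, antiporter):
        model = KineticModel.from_graph(antiporter, ANTIPORTER_CONDITION)
        drive = cycle_drive(model, ANTIPORTER_CONDITION, ANTIPORTER_CYCLE)
        # direct product of the printed input rates around the cycle
        assert drive.chi == pytest.approx(-0.235, abs=5e-4)
        assert drive.extrinsic == pytest.approx(0.0, abs=1e-12)

    def test_electroneutral_drive_is_voltage_independent(self, antiporter_model):
        chis = [cycle_drive(antiporter_model, gradient_condition(mv=mv),
                            ANTIPORTER_CYCLE).chi for mv in (-100.0, 0.0, 100.0)]
        assert np.allclose(chis, chis[0], atol=1e-12)

    def test_electrogenic_drive_affine_with_charge_slope(self, electrogenic_model):
        mvs = np.array([-100.0, -20.0, 60.0, 100.0])
        chis = np.array([
            cycle_drive(electrogenic_model, gradient_condition(mv=mv),
                        ANTIPORTER_CYCLE).chi for mv in mvs])
        slopes = np.diff(chis) / np.diff(mvs)
        # net charge per forward cycle is -1 (one +1 out, one +2 in), so
        # chi gains +beta*e*dPsi per unit potential
        assert np.allclose(slopes, 1.0 / 25.693, atol=1e-12)

    def test_open_walk_rejected(self, antiporter_model):
        with pytest.raises(GraphError, match="open walk"):
            cycle_drive(antiporter_model, ANTIPORTER_CONDITION,
                        ["IF(H+)", "OF(H+)", "OF(Na+)"])

    def test_decomposition_sums_to_total(self, antiporter_model):
        cond = gradient_condition(mv=37.0)
        drive = cycle_drive(antiporter_model, cond, ANTIPORTER_CYCLE)
        assert drive.chi == pytest.approx(drive.intrinsic + drive.extrinsic)
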