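"""Circuit algebra: resistances, Hill activation, Kirchhoff solve, calibration."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ephaptic import (
    CableSegment,
    CommonParams,
    NonPhysicalParameterError,
    ORNSpec,
    ParameterError,
    StimulusState,
    activation_fraction,
    cable_input_resistance,
    calibrate_resting,
    conductance_gain,
    dendrite_area_from_ratio,
    dendritic_resistance,
    ephaptic_delta_vm,
    input_resistance,
    solve_circuit,
    spike_lfp_ratio,
)
from ephaptic.circuit import resting_currents_closed_form

# strategies for randomized, physically valid circuit parameters
areas = st.floats(20.0, 400.0)
dend_areas = st.floats(5.0, 120.0)
gains = st.floats(0.0, 10.0)
ea = st.floats(40.0, 120.0)
rho_s_st = st.floats(5.0, 80.0)
rho_d_st = st.floats(3.0, 50.0)


def _random_model(E_A, rho_s, rho_d0, As1, Ad1, As2, Ad2):
    common = CommonParams(E_A=E_A, V_0=-60.0, rho_s=rho_s, rho_d0=rho_d0,
                          n=0.7, g_max=10.0)
    return calibrate_resting(common,
                             ORNSpec("o1", As1, Ad1, -5.0),
                             ORNSpec("o2", As2, Ad2, -3.0))


class TestActivation:
    @pytest.mark.parametrize("x, k, n, expected", [
        (-5.0, -5.0, 0.7, 0.5),            # midpoint of the Hill curve
        (1.0, 0.0, 0.7, 0.8336624691834381),
        (-np.inf, -5.0, 0.7, 0.0),
        (np.inf, -5.0, 0.7, 1.0),
    ])
    def test_values(self, x, k, n, expected):
        assert activation_fraction(x, k, n) == pytest.approx(expected, rel=1e-12)

    @given(st.floats(-12.0, 2.0), st.floats(-8.0, 0.0), st.floats(0.2, 2.0))
    @settings(deadline=None, derandomize=True)
    def test_monotone_and_bounded(self, x, k, n):
        f = activation_fraction(np.array([x, x + 0.5]), k, n)
        assert 0.0 <= f[0] <= f[1] <= 1.0

    def test_rejects_bad_inputs(self):
        with pytest.raises(ParameterError):
            activation_fraction(np.nan, -5.0, 0.7)
        with pytest.raises(ParameterError):
            activation_fraction(-5.0, np.inf, 0.7)
        with pytest.raises(ParameterError):
            activation_fraction(-5.0, -5.0, 0.0)

    @pytest.mark.parametrize("fraction, g_max, expected", [
        (0.0, 10.0, 0.0),
        (1.0, 10.0, 10.0),
        (0.5, 10.0, 5.0),     # the 50%-background activation state
    ])
    def test_conductance_gain(self, fraction, g_max, expected):
        assert conductance_gain(fraction, g_max) == expected

    def test_conductance_gain_rejects(self):
        with pytest.raises(ParameterError):
            conductance_gain(0.5, -1.0)
        with pytest.raises(ParameterError):
            conductance_gain(1.5, 10.0)


class TestResistances:
    @pytest.mark.parametrize("A_s, rho_s, expected", [
        (137.0, 30.0, 30.0 / 137.0),   # large "A" soma
        (75.0, 30.0, 0.4),             # small "B" soma
        (30.0, 30.0, 1.0),
    ])
    def test_input_resistance(self, A_s, rho_s, expected):
        assert input_resistance(A_s, rho_s) == pytest.approx(expected, rel=1e-12)

    def test_input_resistance_domain(self):
        with pytest.raises(ParameterError):
            input_resistance(-1.0, 30.0)
        with pytest.raises(ParameterError):
            input_resistance(0.0, 30.0)

    @pytest.mark.parametrize("g, expected", [
        (0.0, 0.68),
        (10.0, 0.68 / 11.0),
        (1e6, pytest.approx(0.0, abs=1e-6)),
    ])
    def test_dendritic_resistance(self, g, expected):
        assert dendritic_resistance(25.0, 17.0, g) == pytest.approx(expected, rel=1e-9)

    @given(gains, gains)
    @settings(deadline=None, derandomize=True)
    def test_dendritic_resistance_decreasing(self, g1, g2):
        lo, hi = sorted((g1, g2))
        assert dendritic_resistance(25.0, 17.0, hi) <= dendritic_resistance(25.0, 17.0, lo)

    def test_dendritic_resistance_domain(self):
        with pytest.raises(ParameterError):
            dendritic_resistance(25.0, 17.0, -0.1)


class TestCable:
    def test_unit_cable(self):
        seg = CableSegment(r_m=1.0, r_a=1.0, L=1.0)
        assert cable_input_resistance(seg) == pytest.approx(1.0 / math.tanh(1.0), rel=1e-12)

    def test_short_cable_approaches_lumped_limit(self):
        # l = 0.1: coth expansion gives relative error ~ l^2/3
        seg = CableSegment(r_m=100.0, r_a=1.0, L=1.0)
        assert seg.l == pytest.approx(0.1)
        lumped = seg.r_m / seg.L
        assert cable_input_resistance(seg) == pytest.approx(lumped, rel=0.004)

    def test_long_cable_approaches_semi_infinite(self):
        seg = CableSegment(r_m=1.0, r_a=1.0, L=50.0)
        assert cable_input_resistance(seg) == pytest.approx(seg.R_inf, rel=1e-12)

    @given(st.floats(0.01, 0.3))
    @settings(deadline=None, derandomize=True)
    def test_lumped_error_bound(self, l):
        seg = CableSegment(r_m=1.0, r_a=l * l, L=1.0)
        rel_err = abs(cable_input_resistance(seg) - seg.r_m / seg.L) / (seg.r_m / seg.L)
        assert rel_err <= l * l / 2.0

    def test_zero_length_rejected(self):
        with pytest.raises(ParameterError):
            CableSegment(r_m=1.0, r_a=1.0, L=0.0)


class TestSolveCircuit:
    def test_no_driving_force(self, common):
        # all batteries equal -> no currents, every node at E_A
        a = ORNSpec("a", 100.0, 30.0, -5.0)
        b = ORNSpec("b", 80.0, 20.0, -3.0)
        model = calibrate_resting(common, a, b)
        model = type(model)(common=model.common, orn1=a, orn2=b,
                            E_1=common.E_A, E_2=common.E_A)
        sol = solve_circuit(model, StimulusState())
        assert sol.I_A == sol.I_1 == sol.I_2 == pytest.approx(0.0, abs=1e-12)
        assert sol.V_A == sol.V_m1 == sol.V_m2 == pytest.approx(common.E_A)

    def test_ab4_resting_state(self, ab4):
        sol = solve_circuit(ab4, StimulusState())
        assert sol.V_A == pytest.approx(-30.8875, abs=1e-4)
        assert sol.V_m1 == pytest.approx(-60.0, abs=1e-9)
        assert sol.V_m2 == pytest.approx(-60.0, abs=1e-9)

    def test_ab4_saturated_orn1(self, ab4):
        sol = solve_circuit(ab4, StimulusState(g1=10.0))
        assert sol.V_A == pytest.approx(-48.530701, abs=1e-5)
        assert sol.V_m1 == pytest.approx(-52.559234, abs=1e-5)
        assert sol.V_m2 == pytest.approx(-66.534519, abs=1e-5)

    @given(ea, rho_s_st, rho_d_st, areas, dend_areas, areas, dend_areas, gains, gains)
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_closed_form_matches_direct(self, E_A, rho_s, rho_d0,
                                        As1, Ad1, As2, Ad2, g1, g2):
        model = _random_model(E_A, rho_s, rho_d0, As1, Ad1, As2, Ad2)
        stim = StimulusState(g1, g2)
        a = solve_circuit(model, stim, method="closed_form")
        b = solve_circuit(model, stim, method="direct")
        for name in ("V_A", "V_m1", "V_m2", "I_A", "I_1", "I_2"):
            va, vb = getattr(a, name), getattr(b, name)
            assert va == pytest.approx(vb, rel=1e-9, abs=1e-9)

    @given(ea, rho_s_st, rho_d_st, areas, dend_areas, areas, dend_areas, gains, gains)
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_current_conservation(self, E_A, rho_s, rho_d0,
                                  As1, Ad1, As2, Ad2, g1, g2):
        model = _random_model(E_A, rho_s, rho_d0, As1, Ad1, As2, Ad2)
        sol = solve_circuit(model, StimulusState(g1, g2))
        scale = max(abs(sol.I_A), abs(sol.I_1), abs(sol.I_2), 1e-30)
        assert abs(sol.I_A + sol.I_1 + sol.I_2) <= 1e-12 * scale

    @given(gains, gains)
    @settings(deadline=None, derandomize=True)
    def test_lfp_monotone_in_gain(self, ab4, g1, g2):
        lo, hi = sorted((g1, g2))
        v0 = solve_circuit(ab4, StimulusState()).V_A
        dlo = abs(solve_circuit(ab4, StimulusState(g1=lo)).V_A - v0)
        dhi = abs(solve_circuit(ab4, StimulusState(g1=hi)).V_A - v0)
        assert dhi >= dlo - 1e-12


class TestCalibration:
    @pytest.mark.parametrize("name, e1, e2", [
        ("ab3", -84.420046, -69.147308),
        ("ab4", -74.25, -77.125),
        ("ab5", -82.186235, -81.523959),
    ])
    def test_batteries(self, tables, name, e1, e2):
        m = tables.model(name)
        assert m.E_1 == pytest.approx(e1, abs=1e-5)
        assert m.E_2 == pytest.approx(e2, abs=1e-5)

    @pytest.mark.parametrize("name", ["ab3", "ab4", "ab5"])
    def test_resting_fixed_point(self, tables, name):
        m = tables.model(name)
        sol = solve_circuit(m, StimulusState())
        assert sol.V_m1 == pytest.approx(m.common.V_0, abs=1e-9)
        assert sol.V_m2 == pytest.approx(m.common.V_0, abs=1e-9)

    def test_symmetric_orns(self, symmetric_model):
        assert symmetric_model.E_1 == pytest.approx(symmetric_model.E_2, abs=1e-12)
        assert symmetric_model.resting.xi0 == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_currents_match_solve(self, ab4):
        I_A, I_1, I_2 = resting_currents_closed_form(ab4.common, ab4.resting)
        sol = solve_circuit(ab4, StimulusState())
        assert I_A == pytest.approx(sol.I_A, rel=1e-9)
        assert I_1 == pytest.approx(sol.I_1, rel=1e-9)
        assert I_2 == pytest.approx(sol.I_2, rel=1e-9)

    def test_requires_dendrite_areas(self, common):
        with pytest.raises(ParameterError):
            calibrate_resting(common, ORNSpec("a", 100.0, None, -5.0),
                              ORNSpec("b", 80.0, 20.0, -3.0))


class TestEphapticDeltaVm:
    def test_zero_field_change(self, ab4):
        assert ephaptic_delta_vm(0.0, ab4, 1) == (0.0, 0.0)

    def test_matches_difference_of_full_solves(self, ab4):
        base = solve_circuit(ab4, StimulusState())
        stim = solve_circuit(ab4, StimulusState(g1=10.0))
        d_va = stim.V_A - base.V_A
        d1, d2 = ephaptic_delta_vm(d_va, ab4, stimulated=1)
        assert d1 == pytest.approx(stim.V_m1 - base.V_m1, rel=1e-9)
        assert d2 == pytest.approx(stim.V_m2 - base.V_m2, rel=1e-9)

    def test_frozen_example(self, ab4):
        d1, d2 = ephaptic_delta_vm(-17.643201, ab4, stimulated=1)
        assert d1 == pytest.approx(7.440766, abs=1e-4)
        assert d2 == pytest.approx(-6.534519, abs=1e-4)

    def test_linearity_and_signs(self, ab4):
        d1, d2 = ephaptic_delta_vm(-5.0, ab4, 1)
        d1b, d2b = ephaptic_delta_vm(-10.0, ab4, 1)
        assert d1b == pytest.approx(2 * d1, rel=1e-12)
        assert d2b == pytest.approx(2 * d2, rel=1e-12)
        assert d1 > 0 and d2 < 0  # stimulated depolarizes, neighbor follows the field


class TestSlopeRatio:
    def test_symmetric_is_one(self, symmetric_model):
        assert spike_lfp_ratio(symmetric_model) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("name, r", [("ab3", 1.554290), ("ab4", 2.371837)])
    def test_reference_values(self, tables, name, r):
        assert spike_lfp_ratio(tables.model(name)) == pytest.approx(r, abs=1e-4)

    @pytest.mark.parametrize("name", ["ab3", "ab4", "ab5"])
    def test_area_from_ratio_round_trip(self, tables, name):
        m = tables.model(name)
        r = spike_lfp_ratio(m)
        a_d1 = dendrite_area_from_ratio(r, m.orn1, m.orn2, m.common)
        assert a_d1 == pytest.approx(m.orn1.A_d, rel=1e-9)

    def test_symmetric_inverse(self, common):
        a = ORNSpec("a", 100.0, None, -5.0)
        b = ORNSpec("b", 100.0, 30.0, -3.0)
        assert dendrite_area_from_ratio(1.0, a, b, common) == pytest.approx(30.0, rel=1e-12)

    def test_non_physical_ratio_rejected(self, ab4):
        with pytest.raises(NonPhysicalParameterError):
            dendrite_area_from_ratio(50.0, ab4.orn1, ab4.orn2, ab4.common)


class TestSizeAsymmetry:
    @given(st.floats(1.2, 3.0))
    @settings(deadline=None, derandomize=True, max_examples=25)
    def test_larger_neuron_larger_field_smaller_slope(self, common, factor):
        # ORN1 strictly larger in both soma and dendrite, all else equal
        small = ORNSpec("small", 80.0, 20.0, -4.0)
        big = ORNSpec("big", 80.0 * factor, 20.0 * factor, -4.0)
        m = calibrate_resting(common, big, small)
        v0 = solve_circuit(m, StimulusState()).V_A
        sat1 = abs(solve_circuit(m, StimulusState(g1=common.g_max)).V_A - v0)
        sat2 = abs(solve_circuit(m, StimulusState(g2=common.g_max)).V_A - v0)
        assert sat1 > sat2
        slope1 = m.R_in1 * (1 + 1 / (m.R_in2 + m.R_d(2)))
        slope2 = m.R_in2 * (1 + 1 / (m.R_in1 + m.R_d(1)))
        assert abs(slope1) < abs(slope2)
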