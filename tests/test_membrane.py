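"""Electroporation membrane physics: rate law, conductance law, current
interface and time stepping."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from localep.membrane import (
    electropore_conductance,
    equilibrium_density,
    integrate_density,
    membrane_current_density,
    pore_density_rate,
    step_density,
    step_membrane_state,
)
from localep.params import (
    InvalidInputError,
    MembraneParams,
    MembraneState,
    derived_pore_conductivity,
)


class TestPoreDensityRate:
    @pytest.mark.parametrize(
        "U, N, expected, rtol",
        [
            (0.0, 1.5e9, 0.0, 0.0),  # resting equilibrium: rate vanishes
            (0.0, 0.0, 1e9, 1e-12),  # bare creation rate alpha
            (1.0, 0.0, 1e9 * math.exp(16.0), 1e-12),  # alpha * e^(U/Vep)^2
        ],
    )
    def test_reference_values(self, membrane, U, N, expected, rtol):
        rate = pore_density_rate(U, N, membrane)
        assert rate == pytest.approx(expected, rel=rtol, abs=1e-30)

    @given(U=st.floats(-1.5, 1.5), N=st.floats(0.0, 1e16))
    @settings(max_examples=60, derandomize=True)
    def test_even_in_voltage(self, U, N):
        p = MembraneParams()
        assert pore_density_rate(U, N, p) == pore_density_rate(-U, N, p)

    def test_monotone_in_field_below_equilibrium(self, membrane):
        # for fixed N below equilibrium the creation rate grows with |U|
        N = 1e10
        us = np.linspace(0.1, 1.2, 15)
        rates = [pore_density_rate(u, N, membrane) for u in us]
        assert np.all(np.diff(rates) > 0)

    def test_rejects_non_finite_and_negative(self, membrane):
        with pytest.raises(InvalidInputError):
            pore_density_rate(float("nan"), 0.0, membrane)
        with pytest.raises(InvalidInputError):
            pore_density_rate(0.1, -1.0, membrane)


class TestElectroporeConductance:
    def test_zero_density_zero_conductance(self, membrane):
        assert electropore_conductance(0.0, membrane) == 0.0

    def test_pore_conductivity_is_log_mean(self):
        sigma_p = derived_pore_conductivity(1.5, 0.5)
        assert sigma_p == pytest.approx(1.0 / math.log(3.0), rel=1e-12)
        assert 0.5 < sigma_p < 1.5

    def test_reference_value(self):
        p = MembraneParams(r_p=1e-9, d_cm=5e-9,
                           sigma_p=derived_pore_conductivity(1.5, 0.5))
        g = electropore_conductance(1e13, p)
        expected = 1e13 * 2 * p.sigma_p * math.pi * 1e-18 / (math.pi * 1e-9 + 1e-8)
        assert g == pytest.approx(expected, rel=1e-12)
        assert g == pytest.approx(4.35e3, rel=5e-3)

    @given(N=st.floats(0, 1e18), scale=st.floats(0.1, 10))
    @settings(max_examples=40, derandomize=True)
    def test_linear_in_density(self, N, scale):
        p = MembraneParams()
        assert electropore_conductance(N * scale, p) == pytest.approx(
            scale * electropore_conductance(N, p), rel=1e-12, abs=1e-300
        )

    def test_negative_density_rejected(self, membrane):
        with pytest.raises(InvalidInputError):
            electropore_conductance(-1.0, membrane)


class TestMembraneCurrentDensity:
    @pytest.mark.parametrize(
        "U, Gep, dUdt, expected",
        [
            (0.0, 0.0, 0.0, 0.0),
            (0.1, 0.0, 0.0, 0.2),  # conductive term, G_cm = 2 S/m^2
            (0.0, 0.0, 1e6, 1e4),  # capacitive term, C_cm = 0.01 F/m^2
        ],
    )
    def test_reference_values(self, membrane, U, Gep, dUdt, expected):
        state = MembraneState(U_cm=U, N=membrane.N_0, G_ep=Gep)
        assert membrane_current_density(state, dUdt, membrane) == pytest.approx(
            expected, abs=1e-12
        )


class TestStepping:
    def test_resting_relaxation_matches_closed_form(self, membrane):
        # at U=0 the density relaxes as N0*(1 - exp(-(alpha/N0) t))
        k = membrane.alpha / membrane.N_0
        assert k == pytest.approx(2.0 / 3.0, rel=1e-12)
        N = 0.0
        t, dt = 0.0, 1e-3
        for _ in range(200):
            N = step_density(N, 0.0, dt, membrane)
            t += dt
        assert N == pytest.approx(membrane.N_0 * (1 - math.exp(-k * t)), rel=1e-9)

    @pytest.mark.parametrize("U", [0.3, 0.5, 0.7])
    def test_long_time_equilibrium(self, membrane, U):
        n_eq = equilibrium_density(U, membrane)
        state = MembraneState(U_cm=U, N=membrane.N_0, G_ep=0.0)
        # advance 40 relaxation times at constant voltage
        k = (membrane.alpha / membrane.N_0) * math.exp(
            (1 - membrane.q) * (U / membrane.V_ep) ** 2
        )
        for _ in range(40):
            state = step_membrane_state(state, U, 1.0 / k, membrane)
        assert state.N == pytest.approx(n_eq, rel=1e-6)

    def test_half_volt_equilibrium_value(self, membrane):
        assert equilibrium_density(0.5, membrane) == pytest.approx(
            membrane.N_0 * math.exp(membrane.q * 4.0), rel=1e-12
        )
        assert equilibrium_density(0.5, membrane) == pytest.approx(2.81e13, rel=5e-3)

    def test_monotone_approach_to_equilibrium(self, membrane):
        U = 0.5
        n_eq = equilibrium_density(U, membrane)
        N, prev = membrane.N_0, membrane.N_0
        for _ in range(50):
            N = step_density(N, U, 5e-3, membrane)
            assert prev <= N <= n_eq * (1 + 1e-12)
            prev = N

    def test_vanishing_step_is_identity_to_first_order(self, membrane):
        state = MembraneState(U_cm=0.4, N=1e11, G_ep=0.0)
        out = step_membrane_state(state, 0.4, 1e-15, membrane)
        assert out.N == pytest.approx(1e11, rel=1e-6)

    def test_invalid_dt_rejected(self, membrane):
        state = MembraneState()
        with pytest.raises(InvalidInputError):
            step_membrane_state(state, 0.1, 0.0, membrane)
        with pytest.raises(InvalidInputError):
            step_density(0.0, 0.1, -1e-3, membrane)

    def test_density_never_negative(self, membrane):
        # start far above equilibrium; the exact update must not undershoot
        N = 1e18
        for _ in range(30):
            N = step_density(N, 0.0, 10.0, membrane)
            assert N >= 0.0


class TestIntegratorOracle:
    def test_adaptive_integration_matches_rk4_reference(self, membrane):
        """Stiff adaptive integration agrees with a fixed-step 4th-order
        reference at 1 ns resolution over a 10 us window."""
        U0, U1 = 0.0, 0.6
        T = 10e-6

        def U_of_t(t):
            return U0 + (U1 - U0) * (t / T)

        # independent fixed-step RK4 oracle
        dt = 1e-9
        n = int(round(T / dt))
        N = float(membrane.N_0)
        for i in range(n):
            t = i * dt

            def f(tt, y):
                return pore_density_rate(U_of_t(tt), max(y, 0.0), membrane)

            k1 = f(t, N)
            k2 = f(t + dt / 2, N + dt / 2 * k1)
            k3 = f(t + dt / 2, N + dt / 2 * k2)
            k4 = f(t + dt, N + dt * k3)
            N += dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        ref = N

        adaptive = integrate_density(membrane.N_0, U_of_t, (0.0, T), membrane)
        assert adaptive == pytest.approx(ref, rel=1e-4)

    def test_interpolated_mode_consistent_with_frozen_for_constant_U(self, membrane):
        s = MembraneState(U_cm=0.5, N=membrane.N_0, G_ep=0.0)
        frozen = step_membrane_state(s, 0.5, 1e-4, membrane, mode="frozen")
        interp = step_membrane_state(s, 0.5, 1e-4, membrane, mode="interpolated")
        assert interp.N == pytest.approx(frozen.N, rel=1e-5)
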