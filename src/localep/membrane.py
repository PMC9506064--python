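"""Local electroporation physics of a membrane element.

A membrane element carries a transmembrane voltage ``U_cm = V_i - V_e``
and an areal density ``N`` of fixed-radius electropores.  Pores are
created and annihilated following the asymptotic electroporation model

    dN/dt = alpha * exp((U/V_ep)^2) * (1 - (N/N_0) * exp(-q (U/V_ep)^2))

and raise the membrane conductance by

    G_ep = N * 2 sigma_p pi r_p^2 / (pi r_p + 2 d_m),

the conductance of ``N`` parallel cylindrical pores including their
access resistance.  The normal current density across the element is

    n . J_e = (G_cm + G_ep) U_cm + C_cm dU_cm/dt .

For ``U_cm`` held constant the density ODE is *linear* in ``N`` and
relaxes exponentially toward the equilibrium
``N_eq = N_0 exp(q (U/V_ep)^2)``; the production time stepper uses that
closed form, which is exact and unconditionally stable no matter how
stiff the creation rate becomes.  An adaptive stiff integrator is kept
for time-varying (interpolated) voltage histories.
"""

from __future__ import annotations

import math
from typing import Callable

import numpy as np
from scipy.integrate import solve_ivp

from .params import InvalidInputError, MembraneParams, MembraneState

#: numerical ceiling on the electropore density (m^-2); orders of
#: magnitude above the self-limited densities the coupled model reaches
N_CLIP = 1e22

__all__ = [
    "N_CLIP",
    "pore_density_rate",
    "electropore_conductance",
    "membrane_current_density",
    "equilibrium_density",
    "step_density",
    "step_membrane_state",
    "integrate_density",
]


def _check_finite(name: str, value) -> None:
    if not np.all(np.isfinite(value)):
        raise InvalidInputError(f"{name} must be finite, got {value!r}")


def pore_density_rate(U_cm, N, params: MembraneParams):
    """Electropore creation rate dN/dt (m⁻² s⁻¹).

    Symmetric in the sign of ``U_cm``; vanishes at the resting
    equilibrium ``(U_cm, N) = (0, N_0)``.  Accepts scalars or arrays.
    """
    _check_finite("U_cm", U_cm)
    _check_finite("N", N)
    if np.any(np.asarray(N) < 0):
        raise InvalidInputError("N must be >= 0")
    u2 = (np.asarray(U_cm, dtype=float) / params.V_ep) ** 2
    N = np.asarray(N, dtype=float)
    rate = params.alpha * np.exp(u2) * (1.0 - (N / params.N_0) * np.exp(-params.q * u2))
    return rate if rate.ndim else float(rate)


def electropore_conductance(N, params: MembraneParams):
    """Electroporation conductance G_ep (S/m²); linear in ``N``."""
    _check_finite("N", N)
    if np.any(np.asarray(N) < 0):
        raise InvalidInputError("N must be >= 0")
    N = np.asarray(N, dtype=float)
    g = N * 2.0 * params.sigma_p * math.pi * params.r_p**2 / (
        math.pi * params.r_p + 2.0 * params.d_cm
    )
    return g if g.ndim else float(g)


def membrane_current_density(state: MembraneState, dUdt: float, params: MembraneParams) -> float:
    """Normal electric current density across the membrane (A/m²).

    Positive current flows outward (from intracellular to extracellular)
    when ``U_cm = V_i - V_e`` is positive.
    """
    _check_finite("dUdt", dUdt)
    return (params.G_cm + state.G_ep) * state.U_cm + params.C_cm * dUdt


def equilibrium_density(U_cm, params: MembraneParams):
    """Stationary pore density N_eq = N_0 exp(q (U/V_ep)^2) at constant U_cm."""
    u2 = (np.asarray(U_cm, dtype=float) / params.V_ep) ** 2
    n = params.N_0 * np.exp(params.q * u2)
    return n if n.ndim else float(n)


def step_density(N, U_cm, dt: float, params: MembraneParams):
    """Advance pore density over ``dt`` with ``U_cm`` frozen (exact).

    With constant voltage the rate law is dN/dt = k (N_eq - N) with
    k = (alpha/N_0) exp((1-q)(U/V_ep)^2), so

        N(t+dt) = N_eq + (N - N_eq) exp(-k dt).

    Vectorised over elements.
    """
    if dt <= 0:
        raise InvalidInputError(f"dt must be > 0, got {dt}")
    _check_finite("U_cm", U_cm)
    _check_finite("N", N)
    u2 = (np.asarray(U_cm, dtype=float) / params.V_ep) ** 2
    N = np.asarray(N, dtype=float)
    # Exponents are clipped so extreme transient voltages (which occur
    # as intermediate iterates of coupled field solvers) cannot
    # overflow; N_CLIP is far above any physically reachable density,
    # where the conductance feedback has long since clamped growth.
    log_nclip = math.log(N_CLIP)
    kdt = dt * (params.alpha / params.N_0) * np.exp(
        np.clip((1.0 - params.q) * u2, -700.0, 500.0)
    )
    decay = np.exp(-np.minimum(kdt, 500.0))
    # creation term N_eq*(1-exp(-k dt)); for k dt -> 0 it must reduce to
    # alpha*exp(u^2)*dt exactly (note N_eq*k == alpha*exp(u^2)), which is
    # evaluated in log space to survive the cancellation k -> 0 under a
    # huge N_eq
    log_create_small = np.minimum(math.log(params.alpha * dt) + u2, log_nclip)
    log_neq = np.minimum(math.log(params.N_0) + params.q * u2, log_nclip)
    create = np.where(
        kdt > 1e-8,
        np.exp(log_neq) * (-np.expm1(-np.minimum(kdt, 500.0))),
        np.exp(log_create_small),
    )
    out = np.clip(N * decay + create, 0.0, N_CLIP)
    return out if out.ndim else float(out)


def integrate_density(
    N0: float,
    U_of_t: Callable[[float], float],
    t_span: tuple[float, float],
    params: MembraneParams,
    rtol: float = 1e-6,
    atol: float = 1.0,
) -> float:
    """Integrate the density ODE under a time-varying voltage history.

    Uses an adaptive implicit (BDF) scheme; ``atol`` is in pores/m², so
    the default 1 m⁻² is far below any physical density.
    """
    def rhs(t, y):
        return [pore_density_rate(U_of_t(t), max(y[0], 0.0), params)]

    sol = solve_ivp(rhs, t_span, [N0], method="BDF", rtol=rtol, atol=atol)
    if not sol.success:  # pragma: no cover - BDF on a linear-ish ODE
        raise RuntimeError(f"density integration failed: {sol.message}")
    return float(max(sol.y[0, -1], 0.0))


def step_membrane_state(
    state: MembraneState,
    U_cm_next: float,
    dt: float,
    params: MembraneParams,
    mode: str = "frozen",
) -> MembraneState:
    """Advance a membrane element state over one field-solver step.

    Parameters
    ----------
    mode : {"frozen", "interpolated"}
        ``frozen`` (default) holds the voltage at ``U_cm_next`` for the
        whole step and uses the exact exponential update;
        ``interpolated`` ramps linearly from ``state.U_cm`` to
        ``U_cm_next`` and integrates adaptively.
    """
    if dt <= 0:
        raise InvalidInputError(f"dt must be > 0, got {dt}")
    _check_finite("U_cm_next", U_cm_next)
    if mode == "frozen":
        N = step_density(state.N, U_cm_next, dt, params)
    elif mode == "interpolated":
        u0, u1 = state.U_cm, U_cm_next
        N = integrate_density(
            state.N, lambda t: u0 + (u1 - u0) * (t / dt), (0.0, dt), params
        )
    else:
        raise InvalidInputError(f"unknown stepping mode {mode!r}")
    return MembraneState(
        U_cm=float(U_cm_next), N=float(N), G_ep=electropore_conductance(N, params)
    )
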