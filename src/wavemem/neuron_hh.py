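"""Biophysical single-compartment pyramidal neuron (Hodgkin-Huxley type).

This is the conductance-based counterpart of the integrate-and-fire unit:
a layer-5 pyramidal cell model with Na/K spike currents, leak, a
high-threshold calcium current (CaL), a calcium-activated nonspecific
cation current (CAN) that produces a realistic afterdepolarization, a
calcium-dependent afterhyperpolarization (AHP), and single-pool
intracellular calcium dynamics.  It is used as a single-cell proof of
concept: an initial suprathreshold current pulse loads the "memory"
(raises calcium, turning on CAN), after which a subthreshold 8 Hz
oscillation is enough to keep the cell firing once per cycle; halving the
oscillation amplitude lets the activity die out.

Units: time ms, voltage mV, currents uA/cm^2, conductances mS/cm^2,
capacitance uF/cm^2, calcium uM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = [
    "HHParams",
    "HHState",
    "HHTrace",
    "hh_derivatives",
    "injection_current",
    "simulate_hh",
    "steady_state_init",
    "surf_vol_ratio",
    "IntegrationError",
]


class IntegrationError(RuntimeError):
    """Raised when the Euler integration blows up (|V| > 200 mV)."""


@dataclass(frozen=True)
class HHParams:
    # membrane
    c_m: float = 1.0
    # leak
    g_l: float = 0.05
    v_l: float = -70.0
    # sodium
    g_na: float = 24.0
    v_na: float = 55.0
    theta_m: float = -30.0
    sigma_m: float = 9.5
    theta_h: float = -53.0
    sigma_h: float = -7.0
    theta_ht: float = -40.5
    sigma_ht: float = -6.0
    # potassium
    g_k: float = 3.0
    v_k: float = -90.0
    theta_n: float = -30.0
    sigma_n: float = 10.0
    theta_nt: float = -27.0
    sigma_nt: float = -15.0
    # high-threshold calcium
    g_cal: float = 0.0045
    v_cal: float = 150.0
    v_half_cal: float = -12.0
    k_cal: float = 7.0
    alpha_cal: float = 0.6
    beta_cal: float = -0.02
    # calcium-activated nonspecific cation current
    g_can: float = 0.025
    v_can: float = 30.0
    alpha_can: float = 0.0056
    beta_can: float = 0.0125
    # afterhyperpolarization
    g_ahp: float = 0.2
    v_ahp: float = -90.0
    alpha_ahp: float = 0.05
    beta_ahp: float = 0.2
    # calcium dynamics
    faraday: float = 96500.0
    r0: float = 4.0
    r1: float = 0.025
    ca0: float = 0.1
    tau_ca: float = 100.0
    #: dimensionless multiplier on the electro-diffusive conversion from
    #: calcium current to shell concentration change.  The published
    #: parameter set leaves the unit convention of this conversion open;
    #: the default is calibrated so that a single spike raises shell
    #: calcium by a few tenths of a uM, which puts the cell in the
    #: bistable regime (event pulse loads, subthreshold 8 Hz oscillation
    #: sustains one spike per cycle, half amplitude loses it).
    ca_influx_scale: float = 20.0
    # three-mode injection protocol
    a_event: float = 0.65
    a_osc_delay: float = 0.55
    f_osc_delay: float = 8.0
    psi_osc_delay: float = 0.0

    def __post_init__(self) -> None:
        if self.c_m <= 0:
            raise ValueError("membrane capacitance must be positive")
        if self.tau_ca <= 0:
            raise ValueError("tau_ca must be positive")
        for name in ("g_l", "g_na", "g_k", "g_cal", "g_can", "g_ahp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass
class HHState:
    v: float
    h: float
    n: float
    x_cal: float
    x_can: float
    x_ahp: float
    ca: float


@dataclass
class HHTrace:
    """Full trajectory of a Hodgkin-Huxley run."""

    t: np.ndarray
    v: np.ndarray
    h: np.ndarray
    n: np.ndarray
    x_cal: np.ndarray
    x_can: np.ndarray
    x_ahp: np.ndarray
    ca: np.ndarray
    spike_times: np.ndarray

    def spike_count(self, t0: float, t1: float) -> int:
        """Number of detected spikes with t0 <= t < t1 (ms)."""
        return int(np.sum((self.spike_times >= t0) & (self.spike_times < t1)))


def surf_vol_ratio(params: HHParams) -> float:
    """Surface-to-volume ratio of the submembrane calcium shell [1/um].

    ``r0`` is the cell radius and ``r1`` the shell thickness; the ratio
    controls how much a given calcium current changes the shell
    concentration.
    """
    r0, r1 = params.r0, params.r1
    return (1.0 / r1) / (1.0 - r1 / r0 + r1 * r1 / (3.0 * r0 * r0))


def _ca_flux_coeff(params: HHParams) -> float:
    # uM/ms of shell calcium per uA/cm^2 of inward calcium current:
    # I[uA/cm^2] -> 1e-2 A/m^2; SurfVol[1/um] -> 1e6 1/m; /(2F) gives
    # mol m^-3 s^-1, numerically equal to uM/ms; ca_influx_scale absorbs
    # the model's effective-shell convention (see HHParams).
    return (params.ca_influx_scale * 1.0e4 * surf_vol_ratio(params)
            / (2.0 * params.faraday))


def injection_current(t: float, params: HHParams) -> float:
    """Three-mode injected current (uA/cm^2).

    Quiescent until 20 ms; a constant event pulse ``a_event`` for
    20 < t < 220 ms; a sinusoid of amplitude ``a_osc_delay`` at
    ``f_osc_delay`` Hz for 220 <= t < 1220 ms; the same sinusoid at half
    amplitude from 1220 ms on.  Sinusoid arguments take t in seconds
    (frequencies are in Hz).
    """
    if t <= 20.0:
        return 0.0
    if t < 220.0:
        return params.a_event
    amp = params.a_osc_delay if t < 1220.0 else 0.5 * params.a_osc_delay
    return amp * math.sin(2.0 * math.pi * params.f_osc_delay * t / 1000.0 + params.psi_osc_delay)


def _gates_inf(params: HHParams, v: float, ca: float):
    p = params
    m_inf = 1.0 / (1.0 + math.exp(-(v - p.theta_m) / p.sigma_m))
    h_inf = 1.0 / (1.0 + math.exp(-(v - p.theta_h) / p.sigma_h))
    n_inf = 1.0 / (1.0 + math.exp(-(v - p.theta_n) / p.sigma_n))
    x_cal_inf = 1.0 / (1.0 + math.exp(-(v - p.v_half_cal) / p.k_cal))
    x_can_inf = p.alpha_can * ca / (p.alpha_can * ca + p.beta_can)
    x_ahp_inf = p.alpha_ahp * ca / (p.alpha_ahp * ca + p.beta_ahp)
    return m_inf, h_inf, n_inf, x_cal_inf, x_can_inf, x_ahp_inf


def hh_derivatives(state: HHState, params: HHParams, i_inj: float) -> HHState:
    """Right-hand side of the seven-dimensional ODE system.

    Returns an ``HHState`` whose fields hold time-derivatives.  The CaL
    activation uses the rate form ``dx/dt = (x_inf - x) * (alpha + beta*V)/10``,
    algebraically identical to dividing by the voltage-dependent time
    constant ``tau = 10/(alpha + beta*V)`` wherever that constant is
    positive, but finite and well behaved at the voltage where the
    denominator changes sign (briefly visited at spike peaks).
    """
    p = params
    v, ca = state.v, state.ca
    m_inf, h_inf, n_inf, x_cal_inf, x_can_inf, x_ahp_inf = _gates_inf(p, v, ca)

    i_l = p.g_l * (v - p.v_l)
    i_na = p.g_na * m_inf**3 * state.h * (v - p.v_na)
    i_k = p.g_k * state.n**4 * (v - p.v_k)
    i_cal = p.g_cal * state.x_cal**2 * (v - p.v_cal)
    i_can = p.g_can * state.x_can * (v - p.v_can)
    i_ahp = p.g_ahp * state.x_ahp**2 * (v - p.v_ahp)

    tau_h = 0.37 + 2.78 / (1.0 + math.exp(-(v - p.theta_ht) / p.sigma_ht))
    tau_n = 0.37 + 1.85 / (1.0 + math.exp(-(v - p.theta_nt) / p.sigma_nt))
    tau_can = 1.0 / (p.alpha_can * ca + p.beta_can)
    tau_ahp = 1.0 / (p.alpha_ahp * ca + p.beta_ahp)

    dv = (-(i_l + i_na + i_k + i_cal + i_can + i_ahp) + i_inj) / p.c_m
    dh = (h_inf - state.h) / tau_h
    dn = (n_inf - state.n) / tau_n
    dx_cal = (x_cal_inf - state.x_cal) * (p.alpha_cal + p.beta_cal * v) / 10.0
    dx_can = (x_can_inf - state.x_can) / tau_can
    dx_ahp = (x_ahp_inf - state.x_ahp) / tau_ahp
    dca = -_ca_flux_coeff(p) * i_cal + (p.ca0 - ca) / p.tau_ca
    return HHState(v=dv, h=dh, n=dn, x_cal=dx_cal, x_can=dx_can, x_ahp=dx_ahp, ca=dca)


def steady_state_init(params: HHParams, v: float = -70.0) -> HHState:
    """Initial state: clamped voltage with gates at their fixed points and
    calcium at its baseline."""
    _, h_inf, n_inf, x_cal_inf, x_can_inf, x_ahp_inf = _gates_inf(params, v, params.ca0)
    return HHState(
        v=v, h=h_inf, n=n_inf, x_cal=x_cal_inf,
        x_can=x_can_inf, x_ahp=x_ahp_inf, ca=params.ca0,
    )


@njit(cache=True)
def _hh_kernel(par, y0, n_steps, dt, record_stride, i_mode, i_const):
    # par layout: see _pack_params
    (c_m, g_l, v_l, g_na, v_na, th_m, si_m, th_h, si_h, th_ht, si_ht,
     g_k, v_k, th_n, si_n, th_nt, si_nt,
     g_cal, v_cal, vh_cal, k_cal, a_cal, b_cal,
     g_can, v_can, a_can, b_can,
     g_ahp, v_ahp, a_ahp, b_ahp,
     ca0, tau_ca, k_flux,
     a_event, a_osc, f_osc, psi_osc) = (
        par[0], par[1], par[2], par[3], par[4], par[5], par[6], par[7], par[8],
        par[9], par[10], par[11], par[12], par[13], par[14], par[15], par[16],
        par[17], par[18], par[19], par[20], par[21], par[22], par[23], par[24],
        par[25], par[26], par[27], par[28], par[29], par[30], par[31], par[32],
        par[33], par[34], par[35], par[36], par[37])

    v, h, n, x_cal, x_can, x_ahp, ca = y0[0], y0[1], y0[2], y0[3], y0[4], y0[5], y0[6]

    n_rec = n_steps // record_stride + 1
    rec = np.empty((n_rec, 7))
    spikes = np.empty(n_steps // 200 + 8)  # >= 2 ms separation bounds count
    n_spk = 0
    last_spike = -1.0e9
    fail_step = -1

    j = 0
    for k in range(n_steps + 1):
        t = k * dt
        if k % record_stride == 0 and j < n_rec:
            rec[j, 0] = v
            rec[j, 1] = h
            rec[j, 2] = n
            rec[j, 3] = x_cal
            rec[j, 4] = x_can
            rec[j, 5] = x_ahp
            rec[j, 6] = ca
            j += 1
        if k == n_steps:
            break

        # injected current
        if i_mode == 0:  # three-mode protocol
            if t <= 20.0:
                i_inj = 0.0
            elif t < 220.0:
                i_inj = a_event
            else:
                amp = a_osc if t < 1220.0 else 0.5 * a_osc
                i_inj = amp * math.sin(2.0 * math.pi * f_osc * t / 1000.0 + psi_osc)
        else:  # constant current
            i_inj = i_const

        m_inf = 1.0 / (1.0 + math.exp(-(v - th_m) / si_m))
        h_inf = 1.0 / (1.0 + math.exp(-(v - th_h) / si_h))
        n_inf = 1.0 / (1.0 + math.exp(-(v - th_n) / si_n))
        x_cal_inf = 1.0 / (1.0 + math.exp(-(v - vh_cal) / k_cal))
        x_can_inf = a_can * ca / (a_can * ca + b_can)
        x_ahp_inf = a_ahp * ca / (a_ahp * ca + b_ahp)

        i_l = g_l * (v - v_l)
        i_na = g_na * m_inf * m_inf * m_inf * h * (v - v_na)
        i_k = g_k * n * n * n * n * (v - v_k)
        i_cal = g_cal * x_cal * x_cal * (v - v_cal)
        i_can = g_can * x_can * (v - v_can)
        i_ahp = g_ahp * x_ahp * x_ahp * (v - v_ahp)

        tau_h = 0.37 + 2.78 / (1.0 + math.exp(-(v - th_ht) / si_ht))
        tau_n = 0.37 + 1.85 / (1.0 + math.exp(-(v - th_nt) / si_nt))

        v_new = v + dt * ((-(i_l + i_na + i_k + i_cal + i_can + i_ahp) + i_inj) / c_m)
        h += dt * (h_inf - h) / tau_h
        n += dt * (n_inf - n) / tau_n
        x_cal += dt * (x_cal_inf - x_cal) * (a_cal + b_cal * v) / 10.0
        x_can += dt * (x_can_inf - x_can) / (a_can * ca + b_can)
        x_ahp += dt * (x_ahp_inf - x_ahp) / (a_ahp * ca + b_ahp)
        ca += dt * (-k_flux * i_cal + (ca0 - ca) / tau_ca)

        # spike detection: upward 0 mV crossing, >= 2 ms dead time
        t_new = t + dt
        if v < 0.0 <= v_new and (t_new - last_spike) >= 2.0:
            if n_spk < spikes.shape[0]:
                spikes[n_spk] = t_new
                n_spk += 1
            last_spike = t_new
        v = v_new

        if not (-200.0 < v < 200.0) or v != v:
            fail_step = k
            break

    return rec[:j], spikes[:n_spk], fail_step


def _pack_params(p: HHParams) -> np.ndarray:
    return np.array([
        p.c_m, p.g_l, p.v_l, p.g_na, p.v_na, p.theta_m, p.sigma_m, p.theta_h,
        p.sigma_h, p.theta_ht, p.sigma_ht, p.g_k, p.v_k, p.theta_n, p.sigma_n,
        p.theta_nt, p.sigma_nt, p.g_cal, p.v_cal, p.v_half_cal, p.k_cal,
        p.alpha_cal, p.beta_cal, p.g_can, p.v_can, p.alpha_can, p.beta_can,
        p.g_ahp, p.v_ahp, p.alpha_ahp, p.beta_ahp, p.ca0, p.tau_ca,
        _ca_flux_coeff(p), p.a_event, p.a_osc_delay, p.f_osc_delay,
        p.psi_osc_delay,
    ])


def simulate_hh(
    params: HHParams | None = None,
    t_stop: float = 2000.0,
    dt: float = 0.01,
    *,
    i_const: float | None = None,
    init: HHState | None = None,
    record_stride: int = 10,
) -> HHTrace:
    """Integrate the model with forward Euler.

    By default the three-mode injection protocol is applied (event pulse,
    full-amplitude oscillation, half-amplitude oscillation); pass
    ``i_const`` for a constant current instead.  ``record_stride``
    subsamples the stored trajectory (spike detection always runs at full
    resolution).

    Raises :class:`IntegrationError` if the voltage leaves (-200, 200) mV.
    """
    if params is None:
        params = HHParams()
    if dt <= 0:
        raise ValueError("dt must be positive")
    if init is None:
        init = steady_state_init(params)
    y0 = np.array([init.v, init.h, init.n, init.x_cal, init.x_can, init.x_ahp, init.ca])
    n_steps = int(round(t_stop / dt))
    i_mode = 0 if i_const is None else 1
    rec, spikes, fail_step = _hh_kernel(
        _pack_params(params), y0, n_steps, dt, record_stride, i_mode,
        0.0 if i_const is None else float(i_const),
    )
    if fail_step >= 0:
        raise IntegrationError(
            f"voltage diverged at step {fail_step} (t = {fail_step * dt:.3f} ms)"
        )
    t = np.arange(rec.shape[0]) * (dt * record_stride)
    return HHTrace(
        t=t, v=rec[:, 0], h=rec[:, 1], n=rec[:, 2], x_cal=rec[:, 3],
        x_can=rec[:, 4], x_ahp=rec[:, 5], ca=rec[:, 6], spike_times=spikes,
    )
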