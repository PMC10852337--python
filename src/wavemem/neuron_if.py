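"""Current-based integrate-and-fire neuron with a resettable afterdepolarization.

The unit is the Lisman–Idiart working-memory neuron: a leaky
integrate-and-fire membrane driven by voltage-equivalent input currents
(resistance folded in, so every "current" is expressed in mV), plus an
afterdepolarization (ADP) that restarts at each spike and peaks
``tau_adp`` milliseconds later with amplitude ``a_adp``.  Spike-threshold
variability is modeled as a Gaussian offset redrawn after every spike,
which stands in for synaptic background noise in the low-rate regime.

All times are in milliseconds and all voltages in millivolts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "IFParams",
    "IFState",
    "psp_kernel",
    "adp_current",
    "draw_threshold",
    "step_if",
]

#: sentinel for "this neuron has never spiked"
NEVER = -np.inf


@dataclass(frozen=True)
class IFParams:
    """Fixed single-neuron parameters.

    Defaults are the model's standard operating point: excitatory membrane
    constant 15 ms, fast 2 ms interneurons, ADP peaking at 140 ms with
    7 mV, rest -60 mV, base threshold -50 mV, reset -70 mV, 3 ms
    refractory period, PSP decay 1 ms (excitatory) / 10 ms (inhibitory),
    and threshold noise N(0, 0.5 mV).
    """

    tau_m_e: float = 15.0
    tau_m_i: float = 2.0
    v_rest: float = -60.0
    v_thresh_base: float = -50.0
    v_reset: float = -70.0
    t_ref: float = 3.0
    tau_adp: float = 140.0
    a_adp: float = 7.0
    tau_psp_e: float = 1.0
    tau_psp_i: float = 10.0
    noise_mu: float = 0.0
    noise_sigma: float = 0.5

    def __post_init__(self) -> None:
        for name in ("tau_m_e", "tau_m_i", "t_ref", "tau_adp", "tau_psp_e", "tau_psp_i"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if not (self.v_reset < self.v_rest < self.v_thresh_base):
            raise ValueError(
                "require v_reset < v_rest < v_thresh_base, got "
                f"{self.v_reset}, {self.v_rest}, {self.v_thresh_base}"
            )
        if self.a_adp < 0:
            raise ValueError(f"a_adp must be nonnegative, got {self.a_adp}")
        if self.noise_sigma < 0:
            raise ValueError(f"noise_sigma must be nonnegative, got {self.noise_sigma}")


@dataclass
class IFState:
    """Mutable per-neuron state.

    ``t_last_spike`` is ``-inf`` while the neuron has never fired.  ``eta``
    is the current threshold offset; it is drawn at initialization and
    redrawn immediately after each spike of this neuron.
    """

    v: float
    t_last_spike: float = NEVER
    eta: float = 0.0
    refractory_until: float = NEVER

    @property
    def never_spiked(self) -> bool:
        return not np.isfinite(self.t_last_spike)


def psp_kernel(t, tau_psp: float):
    """Postsynaptic-potential kernel ``H(t) * exp(-t/tau_psp)``.

    Accepts scalars or arrays; returns 0 for negative lags.
    """
    if tau_psp <= 0:
        raise ValueError(f"tau_psp must be positive, got {tau_psp}")
    t = np.asarray(t, dtype=float)
    out = np.where(t >= 0.0, np.exp(-np.clip(t, 0.0, None) / tau_psp), 0.0)
    if out.ndim == 0:
        return float(out)
    return out


def adp_current(t, t_star, params: IFParams):
    """Afterdepolarization input at time ``t`` for a last spike at ``t_star``.

    ``A * x * exp(1 - x)`` with ``x = (t - t_star)/tau_adp``: zero at the
    spike, maximal (exactly ``a_adp``) one ADP time constant later, then
    decaying.  Returns 0 if the neuron never spiked (``t_star = -inf`` or
    None).
    """
    if t_star is None:
        return 0.0 if np.ndim(t) == 0 else np.zeros(np.shape(t))
    t = np.asarray(t, dtype=float)
    t_star = np.asarray(t_star, dtype=float)
    with np.errstate(invalid="ignore", over="ignore"):
        x = (t - t_star) / params.tau_adp
        val = params.a_adp * x * np.exp(1.0 - x)
    out = np.where(np.isfinite(t_star) & (x > 0.0), val, 0.0)
    if out.ndim == 0:
        return float(out)
    return out


def draw_threshold(rng: np.random.Generator, params: IFParams, size=None):
    """Draw a firing threshold: base plus Gaussian offset eta.

    One draw is consumed per neuron at initialization and one more after
    each of that neuron's spikes.
    """
    eta = rng.normal(params.noise_mu, params.noise_sigma, size=size)
    return params.v_thresh_base + eta


def step_if(
    state: IFState,
    params: IFParams,
    i_total: float,
    t: float,
    dt: float,
    rng: np.random.Generator,
    *,
    tau_m: float | None = None,
) -> tuple[IFState, bool]:
    """Advance one neuron by one forward-Euler step of length ``dt``.

    ``i_total`` is the full voltage-equivalent input (synaptic + ADP +
    informational + oscillatory) evaluated at time ``t``.  During the
    refractory period the membrane is clamped at ``v_reset`` and no
    threshold test occurs.  A spike emitted on this step is stamped at
    ``t + dt`` (the end of the step); the threshold offset is then redrawn.

    Returns the updated state (mutated in place) and a spike flag.  This
    scalar kernel defines the semantics that the vectorized network engine
    reproduces.
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    if tau_m is None:
        tau_m = params.tau_m_e
    if t < state.refractory_until:
        state.v = params.v_reset
        return state, False
    state.v += dt / tau_m * (-(state.v - params.v_rest) + i_total)
    threshold = params.v_thresh_base + state.eta
    if state.v >= threshold:
        t_spike = t + dt
        state.v = params.v_reset
        state.t_last_spike = t_spike
        state.refractory_until = t_spike + params.t_ref
        state.eta = float(rng.normal(params.noise_mu, params.noise_sigma))
        return state, True
    return state, False


def init_state(params: IFParams, rng: np.random.Generator) -> IFState:
    """Fresh state at rest with an initial threshold offset drawn from noise."""
    eta = float(rng.normal(params.noise_mu, params.noise_sigma))
    return IFState(v=params.v_rest, eta=eta)
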