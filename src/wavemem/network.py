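"""Modular network assembly: connectivity, oscillatory drives, stimuli.

The network is a line of ``M`` modules, each holding an equal share of the
excitatory principal cells and inhibitory interneurons.  Within a module,
connections are "modular" (E->E, E->I, I->E); across modules only the
"global" E->I and I->E classes exist; there are no I->I connections and no
autapses.  Every allowed pair is connected with a weight drawn uniformly
between 0 and the class scale, signed by the presynaptic type.

Unspecific oscillatory drives are sinusoids shared by all neurons of a
module, with a fixed per-module phase gradient ``psi_osc`` that turns the
oscillation into a traveling wave sweeping the module line.  Several
components (e.g. a theta and an alpha) share a single amplitude budget
``a_max``: their amplitude fractions must not sum past 1, modeling
oscillations that compete for the power of a common source.

Informational stimuli are Gaussian current pulses delivered synchronously
to the neurons coding an item in *all* modules; which module captures an
item is decided by the phase of the traveling wave, not by wiring.

Neuron indexing convention: excitatory neurons come first (0..n_ex-1),
then inhibitory (n_ex..n-1); within each block, modules are contiguous.
Module indices in code are 0-based.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "NetworkConfig",
    "DriveComponent",
    "DriveSpec",
    "Stimulus",
    "StimulusSet",
    "build_connectivity",
    "oscillatory_input",
    "informational_input",
    "input_phase",
    "default_item_patterns",
    "stimulus_times_from_phase",
]

#: default absolute amplitude budget of the oscillatory source [mV].
#: Chosen so that a half-budget drive is subthreshold on its own after
#: membrane filtering at theta frequency (response ~4 mV against a 10 mV
#: rest-to-threshold gap) while drive plus the ADP peak is suprathreshold
#: by well under a millivolt: cyclic reactivation must sit close to its
#: margin, because both the loading phase gate and erasure by beat
#: interference live off that margin.  See docs/methods.md.
DEFAULT_A_MAX = 10.0

#: default informational-pulse amplitude [mV].  Calibrated so that pulse
#: plus near-peak drive fires pattern members while pulse plus off-peak
#: drive stays subthreshold: loading *requires* phase-gated firing (a
#: pulse strong enough to fire members at any drive phase would activate
#: every module and no module could win an item).
DEFAULT_A_INF = 19.0


class ConfigurationError(ValueError):
    """Invalid network / drive / stimulus configuration."""


@dataclass(frozen=True)
class NetworkConfig:
    """Network size, modular structure and connection-class weight scales."""

    n_ex: int = 400
    n_inh: int = 100
    m_modules: int = 4
    w_ei_global: float = 1.12
    w_ie_global: float = -0.112
    w_ee_mod: float = 0.70
    w_ei_mod: float = 4.5
    w_ie_mod: float = -0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ex % self.m_modules or self.n_inh % self.m_modules:
            raise ConfigurationError(
                f"n_ex={self.n_ex} and n_inh={self.n_inh} must both be "
                f"divisible by m_modules={self.m_modules}"
            )
        if self.w_ie_global > 0 or self.w_ie_mod > 0:
            raise ConfigurationError("inhibitory weight scales must be <= 0")
        if self.w_ei_global < 0 or self.w_ei_mod < 0 or self.w_ee_mod < 0:
            raise ConfigurationError("excitatory weight scales must be >= 0")

    @property
    def n(self) -> int:
        return self.n_ex + self.n_inh

    @property
    def ex_per_module(self) -> int:
        return self.n_ex // self.m_modules

    @property
    def inh_per_module(self) -> int:
        return self.n_inh // self.m_modules

    def module_of(self) -> np.ndarray:
        """Module index (0-based) of every neuron."""
        ex = np.repeat(np.arange(self.m_modules), self.ex_per_module)
        inh = np.repeat(np.arange(self.m_modules), self.inh_per_module)
        return np.concatenate([ex, inh]).astype(np.int32)

    def is_excitatory(self) -> np.ndarray:
        out = np.zeros(self.n, dtype=bool)
        out[: self.n_ex] = True
        return out


def build_connectivity(config: NetworkConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """Dense signed weight matrix ``W[pre, post]``.

    Within-module pairs use the modular class scales, cross-module pairs
    the global ones; I->I pairs and the diagonal are zero.  Magnitudes are
    ``Uniform(0, |W_class|)`` with the presynaptic sign.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n
    mod = config.module_of()
    exc = config.is_excitatory()

    u = rng.uniform(0.0, 1.0, size=(n, n))
    same_mod = mod[:, None] == mod[None, :]
    pre_e = exc[:, None]
    post_e = exc[None, :]

    scale = np.zeros((n, n))
    scale[pre_e & post_e & same_mod] = config.w_ee_mod
    scale[pre_e & ~post_e & same_mod] = config.w_ei_mod
    scale[pre_e & ~post_e & ~same_mod] = config.w_ei_global
    scale[~pre_e & post_e & same_mod] = config.w_ie_mod
    scale[~pre_e & post_e & ~same_mod] = config.w_ie_global
    w = u * scale
    np.fill_diagonal(w, 0.0)
    return w


def default_item_patterns(config: NetworkConfig, n_items: int, labels=None) -> dict[str, np.ndarray]:
    """Disjoint item ensembles: each item owns an equal block of excitatory
    neurons in every module.

    With the default network (400 excitatory, 4 modules, 4 items) each
    item has 25 dedicated neurons per module, 100 in total.
    """
    per_mod = config.ex_per_module
    if per_mod % n_items:
        raise ConfigurationError(
            f"{per_mod} excitatory neurons per module not divisible by {n_items} items"
        )
    k = per_mod // n_items
    if labels is None:
        labels = [chr(ord("A") + i) for i in range(n_items)]
    patterns: dict[str, np.ndarray] = {}
    for p, lab in enumerate(labels):
        idx = [
            np.arange(m * per_mod + p * k, m * per_mod + (p + 1) * k)
            for m in range(config.m_modules)
        ]
        patterns[lab] = np.concatenate(idx).astype(np.int64)
    return patterns


@dataclass(frozen=True)
class DriveComponent:
    """One sinusoidal component of the oscillatory source.

    ``fraction`` is the share of the common amplitude budget; ``psi_osc``
    the traveling-wave phase advance per module [rad]; the component is
    silent before ``onset_ms`` and starts there with phase
    ``onset_phase``.
    """

    f_hz: float
    fraction: float
    psi_osc: float = 0.0
    onset_ms: float = 0.0
    onset_phase: float = 0.0

    def __post_init__(self) -> None:
        if self.f_hz <= 0:
            raise ConfigurationError(f"frequency must be positive, got {self.f_hz}")
        if not 0.0 <= self.fraction <= 1.0:
            raise ConfigurationError(f"fraction must be in [0, 1], got {self.fraction}")


@dataclass(frozen=True)
class DriveSpec:
    """Oscillatory drive: components sharing the amplitude budget ``a_max``."""

    components: tuple[DriveComponent, ...]
    a_max: float = DEFAULT_A_MAX

    def __post_init__(self) -> None:
        object.__setattr__(self, "components", tuple(self.components))
        if self.a_max < 0:
            raise ConfigurationError("a_max must be nonnegative")
        # components never switch off, so the budget need only be checked
        # at each onset instant
        for t0 in {c.onset_ms for c in self.components}:
            total = sum(c.fraction for c in self.components if c.onset_ms <= t0)
            if total > 1.0 + 1e-9:
                raise ConfigurationError(
                    f"amplitude fractions active at t={t0} ms sum to {total:.3f} > 1"
                )

    @classmethod
    def theta(cls, f_hz: float = 8.0, fraction: float = 0.5, psi_osc: float = 0.9,
              a_max: float = DEFAULT_A_MAX) -> "DriveSpec":
        """Single-component theta drive at half budget (the standard
        maintenance condition)."""
        return cls(components=(DriveComponent(f_hz=f_hz, fraction=fraction, psi_osc=psi_osc),),
                   a_max=a_max)

    def with_component(self, comp: DriveComponent) -> "DriveSpec":
        return DriveSpec(components=self.components + (comp,), a_max=self.a_max)


def oscillatory_input(t, module: int, drive: DriveSpec):
    """Oscillatory input [mV] to module ``module`` (0-based) at time(s) ``t`` [ms].

    Sum over components active at ``t`` of
    ``fraction * a_max * sin(2 pi f (t - onset)/1000 + onset_phase - module * psi_osc)``.

    A positive phase gradient ``psi_osc`` is a *lag*: module ``m`` repeats
    module 0's waveform ``m * psi_osc / (2 pi f)`` seconds later, so the
    wave sweeps the module line in index order.  (This is the convention
    the input-phase bookkeeping requires: the anticipation of a fixed
    stimulus time relative to module ``m``'s peak grows by ``psi_osc``
    per module.)
    """
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    for c in drive.components:
        phase = (2.0 * math.pi * c.f_hz * (t - c.onset_ms) / 1000.0
                 + c.onset_phase - module * c.psi_osc)
        out = out + np.where(t >= c.onset_ms, c.fraction * drive.a_max * np.sin(phase), 0.0)
    if out.ndim == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class Stimulus:
    """One informational Gaussian pulse: ``label`` selects the item
    pattern, ``t_a`` [ms] is the pulse center."""

    label: str
    t_a: float


@dataclass(frozen=True)
class StimulusSet:
    """Ordered informational stimuli plus pulse shape parameters.

    ``sigma_gamma`` (default 4 ms) models the temporal jitter of the
    upstream ensemble; when generated from a presentation rate
    ``f_gamma``, successive items are spaced by one gamma period.
    """

    items: tuple[Stimulus, ...] = ()
    a_inf: float = DEFAULT_A_INF
    sigma_gamma: float = 4.0
    f_gamma: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "items", tuple(self.items))
        if self.sigma_gamma <= 0:
            raise ConfigurationError("sigma_gamma must be positive")

    @classmethod
    def sequence(cls, labels, t_first: float, f_gamma: float,
                 a_inf: float = DEFAULT_A_INF, sigma_gamma: float = 4.0) -> "StimulusSet":
        """Items presented at rate ``f_gamma`` starting at ``t_first``."""
        if f_gamma <= 0:
            raise ConfigurationError("f_gamma must be positive")
        items = tuple(
            Stimulus(label=lab, t_a=t_first + p * 1000.0 / f_gamma)
            for p, lab in enumerate(labels)
        )
        return cls(items=items, a_inf=a_inf, sigma_gamma=sigma_gamma, f_gamma=f_gamma)


def informational_input(t, neuron: int, stimuli: StimulusSet,
                        patterns: dict[str, np.ndarray]):
    """Informational input [mV] to one neuron: the sum of the Gaussian
    pulses of every item whose pattern contains it, zero otherwise."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    for stim in stimuli.items:
        if neuron in patterns[stim.label]:
            out = out + stimuli.a_inf * np.exp(
                -((t - stim.t_a) ** 2) / (2.0 * stimuli.sigma_gamma**2)
            )
    if out.ndim == 0:
        return float(out)
    return out


def input_phase(p: int, m: int, phi_i: float, f_osc: float, f_gamma: float,
                psi_osc: float) -> float:
    """Input phase of the p-th item in module m (both 1-based) [rad].

    ``phi_i - (p-1) * 2 pi f_osc / f_gamma + (m-1) * psi_osc``, where
    ``phi_i`` is the input phase of the first item in the first module.
    Positive means the stimulus anticipates the oscillation peak of that
    module.
    """
    if f_gamma == 0:
        raise ValueError("f_gamma must be nonzero")
    if p < 1 or m < 1:
        raise ValueError("item and module indices are 1-based")
    phi_gamma = 2.0 * math.pi * f_osc / f_gamma
    return phi_i - (p - 1) * phi_gamma + (m - 1) * psi_osc


def stimulus_times_from_phase(phi_i: float, f_theta: float, f_gamma: float,
                              n_items: int, onset_ms: float = 0.0,
                              onset_phase: float = 0.0,
                              tau_m: float | None = 15.0) -> np.ndarray:
    """Pulse centers [ms] such that the first item anticipates the first
    *excitability* peak of module 0 by ``phi_i`` radians and successive
    items follow at the gamma period.

    The window of opportunity for firing is set by the membrane response
    to the drive, not by the drive itself: a leaky membrane with time
    constant ``tau_m`` tracks a sinusoid with a phase lag
    ``atan(2 pi f tau_m)`` (about 0.65 rad, 12.8 ms, at 8 Hz for the
    15 ms excitatory membrane).  Input phases are therefore measured on
    that excitability wave; pass ``tau_m=None`` to reference the raw
    drive instead.
    """
    period = 1000.0 / f_theta
    omega = 2.0 * math.pi * f_theta / 1000.0
    # first peak of sin(2 pi f (t - onset)/1000 + onset_phase) at phase pi/2
    k = math.ceil((onset_phase - math.pi / 2.0) / (2.0 * math.pi))
    t_peak = onset_ms + (math.pi / 2.0 - onset_phase + 2.0 * math.pi * k) * period / (2.0 * math.pi)
    if tau_m is not None:
        t_peak += math.atan(omega * tau_m) / omega
    t_first = t_peak - phi_i * period / (2.0 * math.pi)
    return t_first + np.arange(n_items) * 1000.0 / f_gamma
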