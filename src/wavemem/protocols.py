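"""Scripted experiments: load, maintain, erase, and parameter sweeps.

Each protocol builds the network and drives, runs the Euler engine, and
reduces the raster with the metrics module:

* ``load_protocol`` presents a gamma-rate sequence of items against a
  theta traveling wave and checks the order-matched allocation (item p
  won by module p) over the loading cycle and the two cycles after it.
* ``maintain_protocol`` tracks per-item participation and the order
  parameter over many theta cycles after a load.
* ``erase_protocol`` loads, maintains for four theta cycles, switches on
  an alpha component that shares the amplitude budget with theta, and
  measures the order parameter on the next three cycles.
* ``erase_sweep`` randomizes alpha amplitude, onset phase and frequency
  over many erase runs and fits per-covariate logistic curves.
* ``sweep_maps`` scans the (phase gradient, input phase) plane for the
  best presentation frequency and the storage quality it achieves.

All protocols are deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import SpikeRaster, run_simulation
from .metrics import (
    CycleWindows,
    MetricParams,
    assign_cycles,
    best_gamma,
    erase_statistics,
    first_spikes,
    item_module_counts,
    loading_suitability,
    order_parameter,
)
from .neuron_if import IFParams
from .network import (
    DriveComponent,
    DriveSpec,
    NetworkConfig,
    Stimulus,
    StimulusSet,
    default_item_patterns,
    stimulus_times_from_phase,
)

__all__ = [
    "Fixture",
    "make_fixture",
    "LoadResult",
    "load_protocol",
    "MaintainResult",
    "maintain_protocol",
    "EraseResult",
    "erase_protocol",
    "erase_sweep",
    "erase_frequency_transition",
    "sweep_maps",
]

F_THETA_DEFAULT = 8.0
PSI_OSC_DEFAULT = 0.9
PHI_I_DEFAULT = 0.8
F_GAMMA_DEFAULT = 50.0

#: theta cycles simulated before the loading cycle so that the membranes
#: are entrained to the drive's steady state when the first item arrives
#: (the buffer operates on an ongoing oscillation, not a cold start).
WARMUP_CYCLES = 1


@dataclass
class Fixture:
    """A fully specified, seeded simulation setup."""

    name: str
    config: NetworkConfig
    drive: DriveSpec
    stimuli: StimulusSet
    params: IFParams
    labels: list[str]
    seed: int


def make_fixture(name: str, seed: int = 0) -> Fixture:
    """Preset setups: ``paper-default`` (500 neurons, 4 modules, 4 items),
    ``tiny`` (40 neurons, 2 modules, 2 items; runs full protocols in
    seconds) and ``single-neuron`` (one excitatory cell, no synapses)."""
    params = IFParams()
    if name == "paper-default":
        config = NetworkConfig(seed=seed)
        labels = ["A", "B", "C", "D"]
    elif name == "tiny":
        config = NetworkConfig(n_ex=32, n_inh=8, m_modules=2, seed=seed)
        labels = ["A", "B"]
    elif name == "single-neuron":
        config = NetworkConfig(n_ex=1, n_inh=0, m_modules=1, seed=seed)
        labels = ["A"]
    else:
        raise ValueError(
            f"unknown fixture '{name}'; available: paper-default, tiny, single-neuron"
        )
    drive = DriveSpec.theta(f_hz=F_THETA_DEFAULT, fraction=0.5, psi_osc=PSI_OSC_DEFAULT)
    t_stim = stimulus_times_from_phase(PHI_I_DEFAULT, F_THETA_DEFAULT,
                                       F_GAMMA_DEFAULT, len(labels))
    stimuli = StimulusSet(
        items=tuple(Stimulus(lab, t) for lab, t in zip(labels, t_stim)),
        f_gamma=F_GAMMA_DEFAULT,
    )
    return Fixture(name=name, config=config, drive=drive, stimuli=stimuli,
                   params=params, labels=labels, seed=seed)


def _module_shift_ms(psi_osc: float, f_theta: float) -> float:
    return psi_osc * 1000.0 / (2.0 * math.pi * f_theta)


@dataclass
class LoadResult:
    raster: SpikeRaster
    windows: CycleWindows
    labels: list[str]
    counts: dict[int, np.ndarray]  # cycle -> item x module table
    suitability: int               # binary l(f|g) from the loading cycle
    allocated: bool                # order-matched win in cycles 0..2
    drive: DriveSpec
    stimuli: StimulusSet
    config: NetworkConfig


def load_protocol(
    seed: int = 0,
    *,
    config: NetworkConfig | None = None,
    params: IFParams | None = None,
    f_gamma: float = F_GAMMA_DEFAULT,
    phi_i: float = PHI_I_DEFAULT,
    psi_osc: float = PSI_OSC_DEFAULT,
    f_theta: float = F_THETA_DEFAULT,
    theta_fraction: float = 0.5,
    g: float = 2.0,
    n_cycles: int = 3,
    a_inf: float | None = None,
    a_max: float | None = None,
    drive_to_inh: bool = False,
    dt: float = 0.01,
    count_mode: str = "neurons",
) -> LoadResult:
    """Present one item per module as a gamma-rate sequence and measure
    the allocation.

    Returns counts for the loading cycle (z = 0) and the ``n_cycles - 1``
    cycles after it; ``suitability`` applies the dominance level ``g`` to
    the loading cycle, ``allocated`` requires the order-matched win in
    every measured cycle.
    """
    if config is None:
        config = NetworkConfig(seed=seed)
    if params is None:
        params = IFParams()
    labels = [chr(ord("A") + i) for i in range(config.m_modules)]
    drive_kwargs = {} if a_max is None else {"a_max": a_max}
    drive = DriveSpec.theta(f_hz=f_theta, fraction=theta_fraction, psi_osc=psi_osc,
                            **drive_kwargs)
    period = 1000.0 / f_theta
    t_warm = WARMUP_CYCLES * period
    t_stim = stimulus_times_from_phase(phi_i, f_theta, f_gamma, len(labels)) + t_warm
    kwargs = {} if a_inf is None else {"a_inf": a_inf}
    stimuli = StimulusSet.sequence(labels, t_stim[0], f_gamma, **kwargs)

    shift = _module_shift_ms(psi_osc, f_theta)
    # cover the window of the last module's last measured cycle
    t_stop = (t_warm + period / 4.0 + (n_cycles - 1) * period
              + (config.m_modules - 1) * shift + period / 2.0 + 5.0)
    raster = run_simulation(config, drive, stimuli, t_stop, dt=dt, seed=seed,
                            params=params, drive_to_inh=drive_to_inh)
    windows = assign_cycles(drive, t_warm, t_stop, config.m_modules)
    counts = {z: item_module_counts(raster, windows, z, labels, mode=count_mode)
              for z in range(n_cycles)}
    suit = loading_suitability(counts[0], g=g)
    allocated = all(loading_suitability(counts[z], g=g) == 1 for z in range(n_cycles))
    return LoadResult(raster=raster, windows=windows, labels=labels, counts=counts,
                      suitability=suit, allocated=allocated, drive=drive,
                      stimuli=stimuli, config=config)


@dataclass
class MaintainResult:
    raster: SpikeRaster
    windows: CycleWindows
    labels: list[str]
    report: pd.DataFrame  # one row per cycle: os, frac_<item>...


def maintain_protocol(
    seed: int = 0,
    *,
    config: NetworkConfig | None = None,
    params: IFParams | None = None,
    n_cycles: int = 8,
    theta_fraction: float = 0.5,
    f_theta: float = F_THETA_DEFAULT,
    psi_osc: float = PSI_OSC_DEFAULT,
    phi_i: float = PHI_I_DEFAULT,
    f_gamma: float = F_GAMMA_DEFAULT,
    a_max: float | None = None,
    drive_to_inh: bool = False,
    dt: float = 0.01,
    metric_params: MetricParams = MetricParams(),
) -> MaintainResult:
    """Load once, then let the theta wave reactivate the stored items for
    ``n_cycles`` cycles; report per-cycle participation and ``Os``."""
    if config is None:
        config = NetworkConfig(seed=seed)
    if params is None:
        params = IFParams()
    labels = [chr(ord("A") + i) for i in range(config.m_modules)]
    drive_kwargs = {} if a_max is None else {"a_max": a_max}
    drive = DriveSpec.theta(f_hz=f_theta, fraction=theta_fraction, psi_osc=psi_osc,
                            **drive_kwargs)
    period = 1000.0 / f_theta
    t_warm = WARMUP_CYCLES * period
    t_stim = stimulus_times_from_phase(phi_i, f_theta, f_gamma, len(labels)) + t_warm
    stimuli = StimulusSet.sequence(labels, t_stim[0], f_gamma)

    shift = _module_shift_ms(psi_osc, f_theta)
    t_stop = (t_warm + period / 4.0 + (n_cycles - 1) * period
              + (config.m_modules - 1) * shift + period / 2.0 + 5.0)
    raster = run_simulation(config, drive, stimuli, t_stop, dt=dt, seed=seed,
                            params=params, drive_to_inh=drive_to_inh)
    windows = assign_cycles(drive, t_warm, t_stop, config.m_modules)
    rows = []
    for z in range(min(n_cycles, windows.n_cycles())):
        row = {"cycle": z,
               "os": order_parameter(raster, windows, z, labels,
                                     params=metric_params)}
        for p, lab in enumerate(labels):
            members = np.flatnonzero((raster.item == lab) & raster.is_exc
                                     & (raster.module == p))
            n_active = len(first_spikes(raster, windows, z, members, p))
            row[f"frac_{lab}"] = n_active / len(members) if len(members) else 0.0
        rows.append(row)
    return MaintainResult(raster=raster, windows=windows, labels=labels,
                          report=pd.DataFrame(rows))


@dataclass
class EraseResult:
    f_alpha: float
    a_alpha: float          # alpha amplitude fraction of the budget
    onset_phase: float      # theta phase [rad] at which alpha switches on
    onset_ms: float
    os_cycles: tuple[float, float, float]  # Os on cycles 1', 2', 3'
    mean_os: float
    p_erase: int
    raster: SpikeRaster | None = None

    def as_row(self) -> dict:
        return {"f_alpha": self.f_alpha, "a_alpha": self.a_alpha,
                "onset_phase": self.onset_phase, "onset_ms": self.onset_ms,
                "os_1": self.os_cycles[0], "os_2": self.os_cycles[1],
                "os_3": self.os_cycles[2], "mean_os": self.mean_os,
                "p_erase": self.p_erase}


def erase_protocol(
    seed: int = 0,
    *,
    f_alpha: float = 12.0,
    a_alpha: float = 0.5,
    onset_phase: float = 0.0,
    config: NetworkConfig | None = None,
    params: IFParams | None = None,
    f_theta: float = F_THETA_DEFAULT,
    psi_osc: float = PSI_OSC_DEFAULT,
    phi_i: float = PHI_I_DEFAULT,
    f_gamma: float = F_GAMMA_DEFAULT,
    n_maintain: int = 4,
    a_max: float | None = None,
    theta_fraction: float | None = None,
    drive_to_inh: bool = False,
    dt: float = 0.01,
    keep_raster: bool = False,
    metric_params: MetricParams = MetricParams(),
) -> EraseResult:
    """Load, maintain for ``n_maintain`` theta cycles, then switch on an
    alpha component and measure the order parameter on the next three
    cycles.

    Theta and alpha compete for the amplitude budget: theta runs at
    fraction ``1 - a_alpha`` throughout and alpha joins at ``a_alpha``
    (equal split by default); pass ``theta_fraction`` explicitly to
    decouple the two (e.g. for a theta-only control).  Alpha onset happens at the first time
    after the maintenance epoch at which the module-0 theta phase equals
    ``onset_phase``; alpha starts there with phase 0 and inherits theta's
    propagation speed (``psi_alpha = psi_osc * f_alpha / f_theta``).
    ``p_erase`` is 1 iff the mean order parameter over the three
    post-onset cycles falls below 0.5.
    """
    if config is None:
        config = NetworkConfig(seed=seed)
    if params is None:
        params = IFParams()
    if not 0.0 <= a_alpha <= 1.0:
        raise ValueError("a_alpha must be a fraction of the budget in [0, 1]")
    labels = [chr(ord("A") + i) for i in range(config.m_modules)]
    if theta_fraction is None:
        theta_fraction = 1.0 - a_alpha

    period = 1000.0 / f_theta
    shift = _module_shift_ms(psi_osc, f_theta)
    t_warm = WARMUP_CYCLES * period
    t_peak0 = t_warm + period / 4.0  # loading-cycle peak, module 0
    # maintenance epoch: cycles 1..n_maintain; alpha joins after the
    # module-0 window of the last maintenance cycle closes
    t_ready = t_peak0 + n_maintain * period + period / 2.0
    # first time >= t_ready where module-0 theta phase == onset_phase
    omega = 2.0 * math.pi * f_theta / 1000.0
    k = math.ceil((omega * t_ready - onset_phase) / (2.0 * math.pi))
    t_onset = (onset_phase + 2.0 * math.pi * k) / omega

    theta = DriveComponent(f_hz=f_theta, fraction=theta_fraction, psi_osc=psi_osc)
    # alpha switches on phase-matched to theta: at t_onset the theta phase
    # in module 0 is onset_phase, and alpha starts at that same phase, so
    # the two components begin constructively aligned and the beat valley
    # develops at tau_min = 1/(2 |fa - ft|) after onset
    alpha = DriveComponent(f_hz=f_alpha, fraction=a_alpha,
                           psi_osc=psi_osc * f_alpha / f_theta,
                           onset_ms=t_onset, onset_phase=onset_phase)
    drive_kwargs = {} if a_max is None else {"a_max": a_max}
    drive = DriveSpec(components=(theta, alpha), **drive_kwargs)

    t_stim = stimulus_times_from_phase(phi_i, f_theta, f_gamma, len(labels)) + t_warm
    stimuli = StimulusSet.sequence(labels, t_stim[0], f_gamma)

    # cycles 1'..3' start at the first module-0 theta peak at/after onset
    z1 = int(math.ceil((t_onset - t_peak0) / period))
    t_stop = (t_peak0 + (z1 + 2) * period + (config.m_modules - 1) * shift
              + period / 2.0 + 5.0)
    raster = run_simulation(config, drive, stimuli, t_stop, dt=dt, seed=seed,
                            params=params, drive_to_inh=drive_to_inh)
    windows = assign_cycles(drive, t_warm, t_stop, config.m_modules)
    os_cycles = tuple(
        order_parameter(raster, windows, z, labels, params=metric_params)
        for z in (z1, z1 + 1, z1 + 2)
    )
    mean_os = float(np.mean(os_cycles))
    return EraseResult(f_alpha=f_alpha, a_alpha=a_alpha, onset_phase=onset_phase,
                       onset_ms=t_onset, os_cycles=os_cycles, mean_os=mean_os,
                       p_erase=int(mean_os < 0.5),
                       raster=raster if keep_raster else None)


def erase_sweep(
    n_runs: int = 60,
    seed: int = 0,
    *,
    a_range: tuple[float, float] = (0.35, 0.65),
    onset_range: tuple[float, float] = (0.0, 2.0 * math.pi),
    f_range: tuple[float, float] = (8.0, 13.0),
    config: NetworkConfig | None = None,
    dt: float = 0.01,
    **protocol_kwargs,
) -> tuple[pd.DataFrame, dict]:
    """Randomized erase experiment: sample the three alpha parameters
    uniformly, run the erase protocol per draw, and fit one logistic
    curve of ``P_erase`` against each covariate.

    The reference experiment uses 1200 runs; the default here is a
    desk-scale 60 (configurable).  Returns the per-run table and the
    fits; with ``n_runs = 0`` both are empty.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_runs):
        a_alpha = float(rng.uniform(*a_range))
        onset = float(rng.uniform(*onset_range))
        f_alpha = float(rng.uniform(*f_range))
        run_seed = int(rng.integers(0, 2**31 - 1))
        res = erase_protocol(seed=run_seed, f_alpha=f_alpha, a_alpha=a_alpha,
                             onset_phase=onset, config=config, dt=dt,
                             **protocol_kwargs)
        rows.append(res.as_row())
    df = pd.DataFrame(rows)
    if df.empty:
        return df, {}
    df, fits = erase_statistics(df)
    return df, fits


def sweep_maps(
    psi_values,
    phi_values,
    seed: int = 0,
    *,
    g: float = 2.0,
    f_sweep=None,
    n_reps: int = 5,
    config: NetworkConfig | None = None,
    f_theta: float = F_THETA_DEFAULT,
    dt: float = 0.01,
    os_cycles: int = 3,
) -> pd.DataFrame:
    """Map the best presentation frequency and the storage quality over a
    (psi_osc, phi_i) grid.

    For each cell, the loading cycle is simulated across ``f_sweep``
    presentation frequencies (default 34..100 Hz in 3 Hz steps, a
    coarsened version of the 1 Hz reference sweep) to find the
    suitability-weighted best frequency; cells with no suitable frequency
    get ``NaN``.  Where defined, the order parameter is averaged over the
    first ``os_cycles`` cycles (stimulation included) and ``n_reps``
    seeds.  Returns a long-format table (psi_osc, phi_i, f_gamma_best,
    mean_os).
    """
    if f_sweep is None:
        f_sweep = np.arange(34.0, 101.0, 3.0)
    rng = np.random.default_rng(seed)
    rows = []
    for psi in psi_values:
        for phi in phi_values:
            cell_seed = int(rng.integers(0, 2**31 - 1))
            suit = {}
            for f in f_sweep:
                res = load_protocol(seed=cell_seed, config=config, f_gamma=float(f),
                                    phi_i=float(phi), psi_osc=float(psi),
                                    f_theta=f_theta, g=g, n_cycles=1, dt=dt)
                suit[float(f)] = res.suitability
            fbest = best_gamma(suit)
            mean_os = np.nan
            if fbest is not None:
                os_vals = []
                for _ in range(n_reps):
                    rep_seed = int(rng.integers(0, 2**31 - 1))
                    res = load_protocol(seed=rep_seed, config=config,
                                        f_gamma=fbest, phi_i=float(phi),
                                        psi_osc=float(psi), f_theta=f_theta,
                                        g=g, n_cycles=os_cycles, dt=dt)
                    labels = res.labels
                    os_vals.append(np.mean([
                        order_parameter(res.raster, res.windows, z, labels)
                        for z in range(os_cycles)
                    ]))
                mean_os = float(np.mean(os_vals))
            rows.append({"psi_osc": float(psi), "phi_i": float(phi),
                         "f_gamma_best": np.nan if fbest is None else fbest,
                         "mean_os": mean_os})
    return pd.DataFrame(rows)


def erase_frequency_transition(
    freqs=None,
    n_seeds: int = 10,
    seed: int = 0,
    *,
    a_alpha: float = 0.5,
    config: NetworkConfig | None = None,
    dt: float = 0.01,
    **protocol_kwargs,
) -> tuple[pd.DataFrame, float | None]:
    """Locate the alpha frequency at which erasure starts to dominate.

    For every frequency on the grid (default 8 to 13 Hz in 0.5 Hz steps)
    the erase protocol is run ``n_seeds`` times with random onset phases
    and equal theta/alpha amplitude fractions; outcomes are binarized at
    the order-parameter threshold 0.5.  Returns the per-frequency table
    (frequency, erased fraction) and the first grid frequency whose
    erased fraction exceeds one half (``None`` if no frequency crosses).
    """
    if freqs is None:
        freqs = np.arange(8.0, 13.01, 0.5)
    rng = np.random.default_rng(seed)
    rows = []
    transition = None
    for f in freqs:
        outcomes = []
        for _ in range(n_seeds):
            onset = float(rng.uniform(0.0, 2.0 * math.pi))
            run_seed = int(rng.integers(0, 2**31 - 1))
            res = erase_protocol(seed=run_seed, f_alpha=float(f), a_alpha=a_alpha,
                                 onset_phase=onset, config=config, dt=dt,
                                 **protocol_kwargs)
            outcomes.append(res.p_erase)
        frac = float(np.mean(outcomes))
        if transition is None and frac > 0.5:
            transition = float(f)
        rows.append({"f_alpha": float(f), "erased_fraction": frac,
                     "n_runs": n_seeds})
    return pd.DataFrame(rows), transition
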