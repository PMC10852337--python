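"""Quantitative measures of loading, maintenance and erasure.

Spikes are grouped into theta cycles per module: each module's analysis
windows are centered on that module's theta peaks (the traveling wave
shifts them by ``psi_osc`` per module) and span one theta period.

Loading quality is a binary suitability: every item must dominate its
order-matched module by a factor ``g`` over its count in any other
module.  Maintenance quality is the order parameter ``Os`` in [0, 1], the
product of the item-averaged within-item synchrony ``O_syn`` (high when
all of an item's neurons fire tightly together) and the pair-averaged
between-item asynchrony ``O_asyn`` (high when distinct items fire well
separated in time).  Erasure is binarized at ``Os < 0.5`` averaged over
the three cycles after alpha onset, and summarized with per-covariate
logistic fits.

The beat analytics predict which alpha frequencies interfere with a theta
of frequency ``f_theta``: superposing the two drives produces an
amplitude envelope with its first minimum at ``tau_min = 1/(2|fa - ft|)``
seconds; erasure is expected when that minimum covers the window where
the afterdepolarization is near its peak.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .engine import SpikeRaster
from .neuron_if import IFParams
from .network import DriveSpec

__all__ = [
    "MetricParams",
    "CycleWindows",
    "assign_cycles",
    "item_module_counts",
    "loading_suitability",
    "best_gamma",
    "first_spikes",
    "o_syn",
    "o_asyn",
    "order_parameter",
    "erase_statistics",
    "tau_min",
    "alpha_band_for_interference",
]


@dataclass(frozen=True)
class MetricParams:
    """Order-parameter constants: ``delta_t`` is the nominal time between
    the reactivations of two sequential items [ms]; the betas shape the
    synchrony / asynchrony penalties."""

    beta_s: float = 1.0
    beta_a: float = 1.0
    delta_t: float = 20.0

    def __post_init__(self) -> None:
        if self.delta_t <= 0:
            raise ValueError("delta_t must be positive")


@dataclass(frozen=True)
class CycleWindows:
    """Per-module theta-cycle windows.

    ``peaks[m][z]`` is the time of module ``m``'s theta peak for cycle
    ``z``; the window of cycle ``z`` is the half-open interval
    ``[peak - T/2, peak + T/2)`` with ``T`` one theta period.  Cycle 0 is
    the first peak at or after the start of the analysis interval of
    module 0.
    """

    peaks: tuple[tuple[float, ...], ...]
    period: float

    def window(self, module: int, z: int) -> tuple[float, float]:
        peak = self.peaks[module][z]
        return peak - self.period / 2.0, peak + self.period / 2.0

    def n_cycles(self, module: int = 0) -> int:
        return len(self.peaks[module])


def theta_component(drive: DriveSpec):
    """The maintenance (theta) component of a drive: the earliest-onset
    component; ties broken by lowest frequency."""
    if not drive.components:
        raise ValueError("drive has no components")
    return min(drive.components, key=lambda c: (c.onset_ms, c.f_hz))


def assign_cycles(drive: DriveSpec, t_start: float, t_stop: float,
                  n_modules: int) -> CycleWindows:
    """Theta-peak times and cycle windows per module over an interval.

    Windows are centered on each module's theta peaks; the traveling wave
    delays module ``m``'s peaks by ``m * psi_osc/(2 pi f)`` relative to
    module 0.  Cycle indices are aligned across modules: cycle ``z`` of
    module ``m`` is the peak at ``peak_0(z) + m * psi/(2 pi f)``, so a
    cycle is one full sweep of the wave over the module line.  Cycle 0 is
    module 0's first peak at or after ``t_start``.
    """
    c = theta_component(drive)
    period = 1000.0 / c.f_hz
    base = _peak_times(c, t_start, t_stop)
    peaks: list[tuple[float, ...]] = []
    for m in range(n_modules):
        shift = m * c.psi_osc * period / (2.0 * math.pi)
        peaks.append(tuple(t + shift for t in base))
    return CycleWindows(peaks=tuple(peaks), period=period)


def _peak_times(c, t_start: float, t_stop: float) -> list[float]:
    """Module-0 peak times of one drive component in [t_start, t_stop)."""
    period = 1000.0 / c.f_hz
    # peaks of sin(2 pi f (t-onset)/1000 + phase0) at phase pi/2 + 2 pi k
    k0 = math.ceil((2.0 * math.pi * c.f_hz * (t_start - c.onset_ms) / 1000.0
                    + c.onset_phase - math.pi / 2.0) / (2.0 * math.pi))
    out = []
    k = k0
    while True:
        t = c.onset_ms + (math.pi / 2.0 - c.onset_phase
                          + 2.0 * math.pi * k) * period / (2.0 * math.pi)
        if t >= t_stop:
            break
        if t >= t_start:
            out.append(t)
        k += 1
    return out


def item_module_counts(raster: SpikeRaster, windows: CycleWindows, z: int,
                       labels: list[str], mode: str = "neurons") -> np.ndarray:
    """Item x module activity counts for cycle ``z``.

    ``counts[i, j]`` is the number of distinct neurons of item ``i``
    firing in module ``j`` during module ``j``'s cycle-``z`` window
    (``mode='spikes'`` counts spikes instead).
    """
    n_modules = len(windows.peaks)
    counts = np.zeros((len(labels), n_modules), dtype=np.int64)
    neuron_item = raster.item
    neuron_mod = raster.module
    for j in range(n_modules):
        t0, t1 = windows.window(j, z)
        sel = (raster.times >= t0) & (raster.times < t1)
        firing = raster.neurons[sel]
        firing = firing[(neuron_mod[firing] == j) & raster.is_exc[firing]]
        for i, lab in enumerate(labels):
            members = firing[neuron_item[firing] == lab]
            counts[i, j] = len(np.unique(members)) if mode == "neurons" else len(members)
    return counts


def loading_suitability(counts: np.ndarray, g: float = 2.0) -> int:
    """Binary loading suitability of an item x module count table.

    1 iff every item's count in its order-matched module strictly exceeds
    ``g`` times its count in each other module (ties lose: a winner must
    beat the level, not meet it).
    """
    counts = np.asarray(counts)
    if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
        raise ValueError(f"counts must be square (items = modules), got {counts.shape}")
    if g <= 1:
        raise ValueError(f"dominance level g must exceed 1, got {g}")
    n = counts.shape[0]
    for i in range(n):
        for j in range(n):
            if j != i and not counts[i, i] - g * counts[i, j] > 0:
                return 0
    return 1


def best_gamma(suitability: dict[float, int]) -> float | None:
    """Suitability-weighted mean presentation frequency.

    ``sum_f l(f) * f / sum_f l(f)`` over a swept grid; ``None`` when no
    frequency is suitable.
    """
    num = sum(f * l for f, l in suitability.items())
    den = sum(suitability.values())
    if den == 0:
        return None
    return num / den


def first_spikes(raster: SpikeRaster, windows: CycleWindows, z: int,
                 members: np.ndarray, module: int) -> np.ndarray:
    """First spike time in module ``module``'s cycle-``z`` window for each
    member neuron that fires in it (neurons outside ``module`` ignored)."""
    t0, t1 = windows.window(module, z)
    members = np.asarray(members)
    members = members[raster.module[members] == module]
    sel = (raster.times >= t0) & (raster.times < t1) & np.isin(raster.neurons, members)
    times, neurons = raster.times[sel], raster.neurons[sel]
    order = np.argsort(times, kind="stable")
    seen: dict[int, float] = {}
    for t, i in zip(times[order], neurons[order]):
        if i not in seen:
            seen[i] = t
    return np.array(sorted(seen.values()))


def o_syn(raster: SpikeRaster, windows: CycleWindows, z: int, item: str,
          module: int, params: MetricParams = MetricParams()) -> float:
    """Within-item synchrony in [0, 1] for one item evaluated in one module.

    ``(n/N) * [1 - (2 sigma / delta_t)^beta_s]_+`` where ``n`` of the
    item's ``N`` member neurons in that module fire in the cycle window
    and ``sigma`` is the population standard deviation of their first
    spike times.  0 if no member fires.
    """
    members = np.flatnonzero((raster.item == item) & raster.is_exc
                             & (raster.module == module))
    n_total = len(members)
    if n_total == 0:
        return 0.0
    t_first = first_spikes(raster, windows, z, members, module)
    n = len(t_first)
    if n == 0:
        return 0.0
    sigma = float(np.std(t_first))  # population SD (divisor n)
    bracket = 1.0 - (2.0 * sigma / params.delta_t) ** params.beta_s
    return (n / n_total) * max(bracket, 0.0)


def _phi(x: float, beta_a: float) -> float:
    if x == 0.0:
        return 0.0
    if x >= 1.0:
        return 1.0
    return x**beta_a


def o_asyn(raster: SpikeRaster, windows: CycleWindows, z: int,
           item_a: str, module_a: int, item_b: str, module_b: int,
           params: MetricParams = MetricParams()) -> float:
    """Between-item asynchrony in [0, 1] for a pair of items.

    ``phi(|<t_A> - <t_B>| / delta_t)`` with the means over first spikes in
    each item's window; saturates at 1 for separations of ``delta_t`` or
    more.  An item with no spikes in the cycle contributes 0 (failed
    storage).
    """
    members_a = np.flatnonzero((raster.item == item_a) & raster.is_exc
                               & (raster.module == module_a))
    members_b = np.flatnonzero((raster.item == item_b) & raster.is_exc
                               & (raster.module == module_b))
    ta = first_spikes(raster, windows, z, members_a, module_a)
    tb = first_spikes(raster, windows, z, members_b, module_b)
    if len(ta) == 0 or len(tb) == 0:
        return 0.0
    sep = abs(float(np.mean(ta)) - float(np.mean(tb))) / params.delta_t
    return _phi(sep, params.beta_a)


def order_parameter(raster: SpikeRaster, windows: CycleWindows, z: int,
                    items: list[str], modules: list[int] | None = None,
                    params: MetricParams = MetricParams()) -> float:
    """Combined storage quality ``Os(z)`` in [0, 1].

    The product of the item-averaged synchrony and the pair-averaged
    asynchrony; each item is evaluated in its assigned module (by default
    item ``p`` in module ``p``, the order-matched allocation).
    """
    m = len(items)
    if m < 2:
        raise ValueError("order parameter needs at least two items")
    if modules is None:
        modules = list(range(m))
    syn = np.mean([
        o_syn(raster, windows, z, it, mod, params)
        for it, mod in zip(items, modules)
    ])
    pairs = []
    for a in range(m):
        for b in range(a + 1, m):
            pairs.append(o_asyn(raster, windows, z, items[a], modules[a],
                                items[b], modules[b], params))
    return float(syn * np.mean(pairs))


@dataclass
class LogisticFit:
    """One-covariate logistic fit of the binarized erase outcome."""

    covariate: str
    intercept: float
    slope: float
    slope_se: float | None
    saturated: bool

    def predict(self, x) -> np.ndarray:
        z = self.intercept + self.slope * np.asarray(x, dtype=float)
        return 1.0 / (1.0 + np.exp(-z))


def erase_statistics(runs: pd.DataFrame,
                     covariates=("a_alpha", "onset_phase", "f_alpha"),
                     os_column: str = "mean_os") -> tuple[pd.DataFrame, dict[str, LogisticFit]]:
    """Binarize erase outcomes and fit one logistic curve per covariate.

    ``P_erase = 1`` iff the mean order parameter over the three
    post-onset cycles is below 0.5.  Fits are unpenalized maximum
    likelihood (covariates standardized internally, curves reported on
    the natural scale).  Degenerate outcomes (all erased or none) yield a
    saturated fit pinned at the constant, with a warning.
    """
    runs = runs.copy()
    runs["p_erase"] = (runs[os_column] < 0.5).astype(int)
    fits: dict[str, LogisticFit] = {}
    y = runs["p_erase"].to_numpy(float)
    for cov in covariates:
        if cov not in runs.columns:
            continue
        x = runs[cov].to_numpy(float)
        if len(np.unique(y)) < 2:
            p = float(y.mean()) if len(y) else 0.5
            warnings.warn(f"degenerate erase outcomes for '{cov}': fit saturated")
            logit = math.log(p / (1 - p)) if 0 < p < 1 else (30.0 if p >= 1 else -30.0)
            fits[cov] = LogisticFit(cov, logit, 0.0, None, True)
            continue
        mu, sd = float(x.mean()), float(x.std())
        sd = sd if sd > 0 else 1.0
        xs = (x - mu) / sd
        import statsmodels.api as sm
        model = sm.Logit(y, sm.add_constant(xs))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = model.fit(disp=0, maxiter=200)
            b0, b1 = res.params
            se1 = float(res.bse[1]) * (1.0 / sd) if np.isfinite(res.bse[1]) else None
            fits[cov] = LogisticFit(cov, float(b0 - b1 * mu / sd), float(b1 / sd),
                                    se1, False)
        except Exception:  # perfect separation and friends
            warnings.warn(f"logistic fit for '{cov}' did not converge; reported saturated")
            fits[cov] = LogisticFit(cov, 0.0, 0.0, None, True)
    return runs, fits


def tau_min(f_alpha: float, f_theta: float) -> float:
    """Time to the first minimum of the theta-alpha beat envelope [s]:
    half the inverse beat frequency."""
    if f_alpha == f_theta:
        raise ValueError("beat undefined for equal frequencies")
    return 1.0 / (2.0 * abs(f_alpha - f_theta))


def adp_window(level: float, params: IFParams = IFParams()) -> tuple[float, float]:
    """Time window [ms] after a spike where the afterdepolarization
    exceeds ``level`` (fraction of its peak), by root finding on
    ``x e^(1-x) = level``."""
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    f = lambda x: x * math.exp(1.0 - x) - level
    x_lo = brentq(f, 1e-12, 1.0)
    # upper root: x e^(1-x) decays below any level by x = 1 - ln(level) + margin
    hi = 2.0
    while f(hi) > 0:
        hi *= 2.0
    x_hi = brentq(f, 1.0, hi)
    return x_lo * params.tau_adp, x_hi * params.tau_adp


def alpha_band_for_interference(
    f_theta: float,
    params: IFParams = IFParams(),
    level: float = 0.85,
    beat_minimum_index: int = 1,
    adp_onset_offset_ms: float = 0.0,
) -> tuple[float, float, float] | None:
    """Alpha frequencies whose beat minimum lands on the ADP peak window.

    Solves for the window where the ADP exceeds ``level`` of its peak and
    maps the ``k``-th beat envelope minimum, at ``(2k-1)/(2|fa-ft|)``
    seconds after onset, into it.  ``adp_onset_offset_ms`` shifts the ADP
    clock relative to the beat onset (the convention is protocol
    dependent, so it is exposed rather than fixed).  Returns
    ``(f_min, f_max, f_mean)`` in Hz, or ``None`` if no alpha above theta
    can reach the window.
    """
    if beat_minimum_index < 1:
        raise ValueError("beat_minimum_index must be >= 1")
    t_lo, t_hi = adp_window(level, params)
    t_lo += adp_onset_offset_ms
    t_hi += adp_onset_offset_ms
    if t_hi <= 0:
        return None
    t_lo = max(t_lo, 1e-9)
    k = beat_minimum_index
    half_periods = (2 * k - 1) * 500.0  # (2k-1)/2 beat periods, in ms*Hz
    df_min = half_periods / t_hi
    df_max = half_periods / t_lo
    f_min = f_theta + df_min
    f_max = f_theta + df_max
    return f_min, f_max, 0.5 * (f_min + f_max)
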