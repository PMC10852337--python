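# Methods

`wavemem` simulates a modular spiking-network model of multi-item working
memory in which items are held by *cyclic reactivation*: neurons that
recently fired carry a transient afterdepolarization (ADP), and an
unspecific subthreshold oscillation in the theta band re-fires exactly
those neurons once per cycle.  A second oscillation in the alpha band,
sharing the same power source, interferes with theta and can destroy the
stored content.  This note documents the model equations as implemented,
the calibrated parameters and why they have the values they do, what the
shipped experiments do and do not demonstrate, and the known limitations.

## 1. Neuron models

### Integrate-and-fire unit (network model)

Each neuron is a current-based leaky integrate-and-fire unit,

    tau_m dV/dt = -(V - V_rest) + I_total(t),

with all inputs expressed as voltage equivalents (mV; the membrane
resistance is folded into the input amplitudes).  Excitatory principal
cells have `tau_m = 15 ms`, inhibitory interneurons `tau_m = 2 ms`;
`V_rest = -60 mV`, base threshold `-50 mV`, reset `-70 mV`, absolute
refractory period 3 ms (during which the membrane is clamped at the reset
value and no threshold test occurs).  A spike on an integration step is
stamped at the end of the step.

`I_total` is the sum of four terms:

* **Synaptic input** — every presynaptic spike contributes
  `W_ij * exp(-(t - t_spike)/tau_psp)` with `tau_psp = 1 ms` for
  excitatory and `10 ms` for inhibitory presynaptic neurons.  The engine
  maintains two exponentially decaying accumulators per postsynaptic
  neuron (one per kernel class) that are bumped by `W_ij` at each spike;
  the explicit double sum over the spike history is retained as the test
  oracle for this scheme.  A spike affects other neurons from the next
  step on (no conduction delay); contributions never need explicit
  truncation because the accumulators decay exactly.
* **Afterdepolarization** — principal cells carry
  `A_ADP * x * exp(1 - x)` with `x = (t - t_last_spike)/tau_ADP`,
  `A_ADP = 7 mV`, `tau_ADP = 140 ms`; the ADP clock restarts at each
  spike and the kernel peaks exactly `tau_ADP` after it with value
  exactly `A_ADP`.  It exceeds 85 % of its peak between roughly 75 and
  236 ms after a spike; this *viability window* is what ties reactivation
  to the theta period.
* **Informational stimuli** — Gaussian current pulses
  `A_inf * exp(-(t - t_A)^2 / (2 sigma_gamma^2))`, `sigma_gamma = 4 ms`,
  delivered to the neurons coding an item in *all* modules
  simultaneously.
* **Oscillatory drive** — see §2.

Spike-threshold noise stands in for background synaptic noise: each
neuron's threshold is `-50 mV + eta` with `eta ~ N(0, 0.5 mV)`, redrawn
at initialization and after each of that neuron's spikes.  By default the
noise applies to interneurons as well (configurable).

### Biophysical unit (single-cell demonstration)

The conductance-based counterpart is a single-compartment layer-5
pyramidal cell with Na/K spike currents, leak, a high-threshold calcium
current (CaL), a calcium-activated nonspecific cation current (CAN), a
calcium-gated afterhyperpolarization (AHP), and a single submembrane
calcium pool with 100 ms clearance.  Here the ADP is not stereotyped but
emergent: spikes admit calcium through CaL, calcium activates CAN (an
inward current at subthreshold voltages), and the resulting depolarizing
tail plays the role the analytic ADP kernel plays in the network model.

Two numerical choices deserve note:

* **CaL kinetics.**  The activation time constant of CaL is voltage
  dependent, `tau = 10/(0.6 - 0.02 V)`, which changes sign at +30 mV.  The
  integrator uses the algebraically identical rate form
  `dx/dt = (x_inf - x)(0.6 - 0.02 V)/10`, which is finite and well
  behaved everywhere.  With the default parameters the spike peak is
  ~+25 mV, so the two forms coincide on every shipped protocol.
* **Charge-to-concentration conversion.**  The electro-diffusive
  conversion from calcium current density to shell-concentration change,
  `dCa/dt ∝ (Surf/Vol) I_CaL / 2F`, is dimensionally fixed only once a
  unit convention for the effective shell is chosen, and the standard
  SI reading yields per-spike transients (~0.005 uM) two orders of
  magnitude below the half-activation scale of the CAN and AHP gates
  (2.2 and 4 uM).  The conversion therefore carries an explicit
  calibration multiplier `ca_influx_scale` (default 20, i.e. roughly
  0.1–0.3 uM admitted per spike).  The default is the only decade in a
  scan over 10–2400 that yields all four target behaviors at once:
  firing during the event pulse, exactly one spike per cycle of the
  full-amplitude 8 Hz drive, silence after the amplitude halves, and
  silence without the event pulse.

The single-cell protocol injects 0.65 uA/cm² for 20–220 ms, a 0.55 uA/cm²
8 Hz sinusoid for 220–1220 ms, and the same sinusoid at half amplitude
thereafter.  Euler integration at `dt = 0.01 ms`; spikes are upward 0 mV
crossings with a 2 ms dead time; initial state is `V = -70 mV` with gates
at their fixed points and calcium at baseline (steady-state
initialization avoids onset transients).

## 2. Network, traveling-wave drive and stimulus geometry

The default network has 400 excitatory and 100 inhibitory neurons in
`M = 4` linearly arranged modules.  Connection classes (uniform weights
on `[0, W]`, signed by presynaptic type): within a module E→E (0.70),
E→I (4.5), I→E (−0.8); across modules E→I (1.12) and I→E (−0.112); no
I→I, no autapses.  Each item owns a disjoint block of 25 excitatory
neurons per module (overlapping patterns are supported through explicit
pattern maps).

The oscillatory drive is a sum of sinusoidal components sharing one
amplitude budget `A_max`; component `c` contributes
`fraction_c * A_max * sin(2 pi f_c (t - onset_c)/1000 + phase_c - m psi_c)`
to module `m`.  The per-module phase term is a *lag*: module `m` repeats
module 0's waveform `m psi/(2 pi f)` seconds later, so the wave sweeps
the module line in index order — the geometry that lets a timed item
sequence map onto the module sequence.  Active fractions may never sum
past 1 (the components compete for a common power source).  The drive
targets principal cells; a flag extends it to interneurons (off by
default — in this implementation interneuron drive destroys maintenance
at every tested amplitude, because each reactivation volley then recruits
a network-wide inhibition wave).

**Input phase convention.**  The phase of a stimulus is measured against
the *excitability wave* — the membrane response to the drive — not the
raw drive.  A 15 ms membrane tracks an 8 Hz sinusoid with gain 0.80 and
lag `atan(2 pi f tau_m)` ≈ 0.65 rad (12.8 ms); windows of maximal
excitability are correspondingly delayed.  This is not cosmetic: with
phases referenced to the raw drive, order-matched allocation at the
standard operating point fails for every informational amplitude, because
the stimulus lands too early in its target module's window.  The
bookkeeping formula for the phase of item `p` in module `m` is
`phi_i - (p-1) * 2 pi f_osc / f_gamma + (m-1) psi_osc` (1-based indices,
positive = stimulus anticipates the peak).

All protocols precede the loading cycle with one warm-up theta cycle so
the membranes are entrained to the drive's steady state when the first
item arrives.

## 3. Calibrated amplitudes

Two drive amplitudes are not fixed by the parameter tables and were
calibrated once, then frozen:

* `A_max = 10 mV` (oscillatory budget).  At the standard half-budget
  theta this gives a ~4 mV membrane response against the 10 mV
  rest-to-threshold gap: subthreshold alone, and *barely* suprathreshold
  together with the 7 mV ADP peak.  The margin is deliberately tight —
  loading requires the drive to gate stimulus-evoked firing by phase, and
  erasure by beat interference only works if reactivation lives close to
  its margin.  Larger budgets make maintenance more robust but let
  ensembles survive any interference; smaller ones fail to maintain.
* `A_inf = 19 mV` (informational pulses, ~8 mV filtered response).
  Strong enough that a pulse arriving 0.8 rad before its module's
  excitability peak fires the pattern, weak enough that a pulse at an
  off-peak module stays subthreshold.  A pulse able to fire members at
  *any* phase would activate every module and no module could win an
  item, so phase-gated firing is a requirement of the loading operation,
  not a tuning accident.

At the frozen point: order-matched allocation succeeds 10/10 seeds at the
standard operating point; theta-only maintenance holds `Os >= 0.5` for at
least 7 cycles on all tested seeds at fraction 0.5 (fraction 0.35 cannot
maintain; 0.65 is marginal — the workable amplitude range is narrower
than in the reference experiment).

## 4. Protocols and metrics

* **Load** (`load_protocol`): four items presented at `f_gamma = 50 Hz`
  with first-item phase `phi_i = 0.8 rad` against an 8 Hz theta wave
  with `psi_osc = 0.9 rad/module`.  Activity is counted per (item,
  module) in theta-cycle windows — one full period, centered on each
  module's excitability peak, half-open to the right, cycle indices
  aligned across modules.  Loading suitability is the strict dominance
  product: every item's count in its order-matched module must exceed
  `g = 2` times its count in every other module (ties lose).  The best
  presentation frequency is the suitability-weighted mean over a swept
  grid (reference grid 34–100 Hz in 1 Hz steps; the shipped maps default
  to 3 Hz steps).  Counts are distinct neurons by default (spike-count
  mode available).
* **Maintain** (`maintain_protocol`): after a load, per-cycle
  participation `n_a(z)/N_a` and the order parameter are tracked.  The
  order parameter `Os(z)` is the product of (i) the item-averaged
  within-item synchrony `(n/N) [1 - (2 sigma/Delta_t)]_+` — `sigma` the
  population SD of each member's *first* spike in the cycle window,
  `Delta_t = 20 ms` — and (ii) the pair-averaged between-item asynchrony
  `min(|<t_A> - <t_B>|/Delta_t, 1)`.  Each item is evaluated in its
  order-matched module (the ensemble the load operation creates); an
  item with no spikes in a cycle contributes zero.
* **Erase** (`erase_protocol`): load, maintain four theta cycles, then
  switch on an alpha component.  Theta and alpha compete for the budget:
  theta runs at `1 - a_alpha` throughout and alpha joins at `a_alpha`
  (equal split by default).  The onset parameter is the module-0 theta
  phase at which alpha switches on, and alpha starts *phase-matched* —
  at that same phase — so the beat envelope starts constructively and
  reaches its first minimum `tau_min = 1/(2 |f_alpha - f_theta|)` after
  onset.  (With a free initial alpha phase, half of all near-theta
  alphas would start anti-phased and erase immediately, which is neither
  the analytic picture nor the reported low-band behavior.)  `Os` is
  measured on the three cycles starting at the first theta peak at or
  after onset; the run is binarized as erased when the mean is below
  0.5.
* **Sweeps**: `erase_frequency_transition` locates the alpha frequency
  at which the erased fraction of random-onset runs first exceeds one
  half (0.5 Hz grid, 10 repetitions per frequency by default);
  `erase_sweep` randomizes amplitude fraction, onset phase and frequency
  jointly (reference size 1200 runs; desk preset 60) and fits
  unpenalized per-covariate logistic curves (standardized internally,
  reported on natural scales; degenerate outcomes produce a flagged
  saturated fit); `sweep_maps` scans the `(psi_osc, phi_i)` plane for
  the best presentation frequency and the storage quality it achieves
  (reference: 50 repetitions per cell; desk preset 5).

Problem sizes shipped in the tests and the acceptance script — the
500-neuron network, 10 seeds per condition, a 0.5 Hz frequency grid, a
60-run randomized sweep, two-cell phase maps at 6 Hz frequency steps —
are the package's desk-scale defaults; the larger reference sizes are
plain function arguments.

## 5. Beat analytics

For two components at `f_theta` and `f_alpha` the combined amplitude
envelope reaches its k-th minimum `(2k-1)/(2 |f_alpha - f_theta|)`
seconds after a constructive start.  `alpha_band_for_interference` maps
those minima into the ADP viability window (the interval where the ADP
exceeds a given fraction of its peak, found by root-finding on
`x e^(1-x) = level`): for theta at 8 Hz, level 0.85 and the first
minimum, alpha in ≈ [10.1, 14.7] Hz places its beat valley on the ADP
peak.  The published analysis prints a slightly different band
(10.4–15.5 Hz) under an unstated offset convention between the ADP clock
and the beat onset; the operation exposes that offset and the minimum
index as parameters instead of hard-coding either.

## 6. What the erase experiments show — and what they do not

The implemented model reproduces a sharp erase transition: at the frozen
operating point, 8–9 Hz alpha leaves memories intact (erased fraction
0.0), and the erased fraction jumps above one half at 9.5–10 Hz (stable
across independent seed streams; the reference transition is ~10 Hz).
The mechanism is *beat stranding*: when the first envelope minimum falls
inside the measured cycles and the next envelope maximum lies beyond the
ADP viability window (~330 ms), the ensemble cannot re-fire and its ADP
tags expire.

Above ~11 Hz the implementation departs from the reference result.
Faster beats put an envelope maximum back inside every viability window,
and the ensembles survive by *phase-sliding*: they re-fire coherently at
the combined-oscillation maxima (about every 250 ms at 12 Hz) rather
than at theta peaks, and every theta-cycle window still catches a
synchronized volley, so `Os` stays above 0.5 in most runs
(erased fraction ~0.1–0.4 at 12–13 Hz instead of ~1).  This failure mode
is robust here: it persists for every oscillation budget from 9 to
16 mV, for either alpha phase-gradient convention (shared propagation
speed or shared gradient), and cannot be cured by driving interneurons
(which destroys maintenance outright).  The corresponding acceptance
tests (12 Hz erasure; amplitude-independence of erasure, which in this
implementation is confounded by theta weakening as alpha strengthens
under the shared budget) are left failing rather than weakened.
Consequences for users: treat the erase operation as reliable in the
9.5–11 Hz band, and interpret high-alpha results with the sliding
caveat in mind.

## 7. Synthetic data and realism

All inputs are generated in code — connectivity from seeded uniform
draws, drives and stimuli from closed-form waveforms, noise from seeded
Gaussians.  The generator reproduces the *structure* of the study
conditions (modular all-to-all connectivity, deterministic drive
waveforms, per-spike threshold noise) but none of the irregularities of
real tissue: no conduction delays, no synaptic failures or short-term
plasticity, no heterogeneous cell parameters, no background spiking.
Passing tests therefore demonstrate the internal consistency of the
mechanism at its operating point, not robustness of the phenomenon in
biological noise regimes.

## 8. Numerical and engineering notes

* Forward Euler at `dt = 0.01 ms` throughout (the reference step).  With
  threshold noise disabled, halving the step changes per-cycle event
  counts by well under 5 %; with noise enabled trajectories diverge by
  RNG-path effects, not discretization.
* Simulations are deterministic given a seed; the seed drives both the
  connectivity draw and the threshold-noise stream.  The inner loops are
  numba-compiled; a one-second default-network run takes on the order of
  a second on one core after JIT warm-up.
* Spike buffers are pre-sized from the refractory bound
  `N * t_stop / t_ref`; non-finite membrane values abort with the
  failing step index.
* Cycle windows partition the analysis interval per module; a spike on a
  boundary belongs to the later window.
* The command-line interface (`wavemem simulate / load-sweep / erase /
  erase-sweep / maps / hh-demo / fixture`) wraps the protocol functions;
  outputs are tab-separated text tables plus a YAML manifest (seed,
  parameters, wall time) per artifact.

## 9. Known limitations

* The maintained amplitude range is narrower than the reference
  experiment's 0.35–0.65 budget fractions (see §3), which confounds the
  amplitude covariate of the randomized erase sweep.
* High-alpha erasure is not reproduced (§6).
* The connectivity class list is reconstructed from the description of
  global vs modular connections; within-module pairs draw only from the
  modular classes (global and modular scales are not summed).
* Whether interneurons receive informational input is untested biology;
  here they do not (patterns contain principal cells only).
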