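# Methods

`blgamma` is a biophysical model of the basolateral amygdala (BL) network:
conductance-based multicompartment neurons, plastic synapses with
distance-dependent wiring, naturalistic afferent drive, a line-source
forward model of the local field potential (LFP), and the analysis
algorithms used to characterize gamma oscillations. This note documents the
model, its numerical choices, the calibration of quantities that are not
fixed by published parameter tables, and what the synthetic study
conditions do and do not establish.

## Cell models

Three archetypes are defined in declarative YAML configs
(`blgamma/configs/`):

* **PN_A / PN_C** — principal neurons with a soma (24.75 x 25 um), an
  apical dendrite (3 x 270 um, glutamatergic synapses) and a second
  dendrite (5 x 555 um) included to match passive properties. Each
  dendrite is split into proximal and distal electrical compartments so
  conductance densities can differ along it (five electrical nodes per
  cell). Channels: I_Na, I_DR, I_M, I_H, I_Ca, I_Nap, I_A and, at the
  soma, a slow calcium-gated AHP current (I_sAHP). The two PN types differ
  only in somatic I_sAHP density (50 vs 0.2 mS/cm^2), which produces
  adapting vs continuously firing responses (last/first interspike-interval
  ratio, cutoff 1.5).
* **FSI** — fast-spiking interneuron: soma (15 x 15 um) + dendrite
  (10 x 150 um), carrying only fast Na/K currents.

Membrane dynamics follow the Hodgkin–Huxley formalism,
`C_m dV/dt = -g_L(V-E_L) - g_c(V-V_nbr) - Σ I_int - Σ I_syn + I_inj`, with
each intrinsic current `I = gbar m^p h^q (V - E)` and first-order gating
`dx/dt = (x_inf - x)/tau_x`.

Passive parameters: C_m = 2.4 uF/cm^2 (PN) / 1.0 (FSI), R_a = 150 Ohm-cm,
E_L = -75 mV (PN). The PN leak density follows the specific membrane
resistance R_m = 55 kOhm-cm^2 (0.018182 mS/cm^2); with the full channel
set this reproduces the reported passive outcomes — V_rest = -70.3 mV,
R_in = 140 MOhm, tau_m = 29 ms — measured exactly as the virtual
experiment does it: equilibrate, apply a -20 pA 500-ms somatic step, take
R_in from the steady deflection and tau_m from a free-amplitude single
exponential over the first 200 ms of the charging curve (the full response
is multi-exponential because I_M/I_H relax slowly; the fit window is a
fixed convention of the measurement, stated here because single-exponential
fits of multi-exponential responses depend on it).

**Stand-ins and calibration.** Four quantities are not fixed by published
tables and were calibrated once against published cell-level outcomes, not
against network behavior:

* *I_A kinetics* — transient A-type scheme: activation sigmoid midpoint
  -50 mV (slope 15, tau 2 ms), inactivation midpoint -83 mV (slope 4,
  tau 20 ms). The inactivation midpoint is the lever that sets V_rest and
  R_in jointly; -83 mV lands both on the reported values.
* *FSI channel kinetics and densities* — fast-spiking Na/K scheme
  (temperature factor 5 on the recovery gates) with g_Na = 160,
  g_DR = 200 mS/cm^2, E_L = -70 mV, calibrated to the two published
  constraints — spike half-width < 1 ms (measured ~0.43 ms) and
  non-adapting repetitive firing (ISI ratio ~1.0 across 60-300 pA) — and
  additionally required to keep spiking under the sustained synaptic
  conductance load of a strongly driven network (weaker densities enter
  depolarization block, which collapses inhibition network-wide).
* *Calcium influx constant* — the somatic pool obeys
  `d[Ca]/dt = -k * I_Ca - [Ca]/1000 ms` in arbitrary units; k = 0.001
  makes PN_A adapt (ratio ~2.0 on a 500-ms 200-pA step) while PN_C stays
  continuous, with resting [Ca] well below the sAHP activation range.
* *Reversal potentials* — E_Na = +45, E_K = -80, E_H = -45, E_Ca = +120 mV
  (standard values; not printed in the parameter tables).

The sAHP gate depends on log10([Ca]^2); the argument is floored at 1e-10.

## Synapses

AMPA, NMDA and GABA_A receptors follow pulse-driven first-order kinetics:
each presynaptic spike opens a transmitter gate for 1 ms, during which the
open fraction relaxes toward `alpha/(alpha+beta)`; it then decays at rate
`beta`. Parameter tables specify rise/decay time constants; the mapping
sets `beta = 1/tau_decay` and chooses `alpha` so the saturating rise
reproduces the dual-exponential's 10-90% rise time. For NMDA
(tau_rise = 3.7 ms) the rise is necessarily truncated at the 1-ms pulse;
the decay is exact. The NMDA magnesium block is
`s(V) = 1/(1 + 0.33 exp(-0.06 V))`. Per-connection weights are drawn from
a normal distribution using the tabulated (mean, spread) read as
(mean, SD) — a "variance" reading is selectable in config — truncated at
5% of the mean.

Short-term depression uses two factors (d1 fast, d2 slow; per-spike
constants 0.9/0.95, recovery 40/70 ms) whose product is floored at the
class limit (0.5-0.7); it applies to AMPA and GABA_A conductances only
(NMDA carries no plasticity; no facilitating class exists by default,
though the facilitation factor F is implemented). Glutamatergic synapses
sit on the PN apical dendrite (proximal compartment) and the FSI dendrite;
GABAergic synapses on somata.

FSI–FSI electrical coupling uses ohmic gap junctions; the conductance is
calibrated by root finding on a two-cell virtual experiment so the
steady-state coupling coefficient (dV_B/dV_A under a -50 pA step) equals
0.05, giving ~0.12 nS.

## Network construction

The full model places 27,000 somata (64% PN_A, 26% PN_C, 10% FSI)
uniformly in a 1.4-mm cube with >25-um spacing (rejection sampling on a
uniform grid index; identical to brute force) and isotropic random
dendrite orientations. Wiring: PN->PN Bernoulli with distance-binned
probabilities 3/2/1/0.5% (<50/50-100/100-200/200-600 um); PN-FSI pairs
within 300 um draw one mutually exclusive outcome (FSI->PN 34%, PN->FSI
12%, reciprocal 16%); FSI-FSI pairs within 300 um couple electrically with
8% probability and form chemical contacts conditioned on coupling
(50%/25% vs 19%/3% uni/bidirectional). Delays are
`distance/(1 mm/ms) + 0.8 ms + U(-0.1, 0.1) ms + dt`. Each of 1,800
afferents contacts 40 random PNs plus, with probability 0.3% per pair,
each FSI within 300 um of those PNs. Realized full-scale statistics:
24.9 ± 9.4 excitatory and 42.7 inhibitory inputs per PN, 215.8 ± 57
excitatory inputs per FSI, 2.96 ± 1.72 extrinsic inputs per PN (~95%
coverage, ~6 FSIs per afferent). The FSI<-FSI in-degree realized under
the mutually-exclusive reading is 13.3; a published value of 21.6 would
require roughly per-direction draws — the reading used here is stated in
the wiring module and the difference affects no reported quantity.

## Afferent drive and background noise

Surrogate afferent trains combine the rate profile of one donor unit
(rescaled to 1-Hz mean) with the mean rate of another, realized as
inhomogeneous Poisson on a 1-ms grid. Because no donor recordings ship
with the package, a synthetic donor pool stands in: log-normal mean rates
(median 1.5 Hz, sigma 0.8 — heavy tail to ~10 Hz) and exponentiated-OU
rate profiles with a 100-ms correlation time. These reproduce plausible
low-rate, positively skewed, temporally correlated cortical unit activity
but none of the cross-correlation structure of real simultaneously
recorded ensembles; results that depend on afferent correlation structure
(e.g., absolute low-frequency LFP power) are therefore outside what the
fixtures can test.

Background synaptic bombardment is an Ornstein-Uhlenbeck point-conductance
pair per cell (PN: 3.2 ± 3 nS excitatory / 21 ± 8 nS inhibitory; FSI:
1.2 ± 0.1 / 5.7 ± 2.6 nS; tau 2.728 / 10.49 ms), advanced with the exact
discretization so the stationary SD equals the tabulated value; negative
excursions are clamped at use time only.

## Simulation engine

Fixed time step dt = 50 us. Gating variables advance by exponential Euler
on precomputed lookup tables (0.02-mV grid); the voltage update is
Crank-Nicolson with conductances frozen over the step, solved directly on
each cell's compartment tree (Hines elimination). Backward Euler was
rejected: its first-order error drifted spike times by ~0.2 ms per
interspike interval against a tolerance-controlled reference solution
(LSODA; an independent implementation kept as the oracle in the test
suite — agreement is exact in spike count and within 0.5 ms in spike time
over a 1-s 200-pA step).

Spikes are upward somatic crossings of -20 mV with a 2-ms refractory
period, delivered to postsynaptic targets at per-edge delays (one pending
event per synapse suffices because the maximum delay is below the
refractory period; the engine asserts this). Background noise uses
counter-based per-cell RNG streams (splitmix64 of cell index and step), so
runs are bit-reproducible under a seed and a cell's noise stream does not
depend on the number of other cells. Recording: somatic V at 1 ms, spike
times at dt, and per-compartment membrane current (capacitive + ionic +
synaptic + background; axial, gap and electrode currents excluded)
averaged over 1-ms windows — the ionic part is evaluated at the step
midpoint so per-cell current totals obey Kirchhoff to machine precision.
A somatic voltage clamp replaces the soma's equation with V = V_hold and
reports the amplifier current (inward positive), used to separate EPSCs
(hold -75 mV) and IPSCs (hold 0 mV).

## LFP forward model

Each compartment is a finite line source in a homogeneous medium
(sigma = 0.3 S/m): soma and dendrites lie along the cell's orientation
axis (apical dendrite +u, second dendrite -u, soma a short centered
segment). The radial coordinate is clamped at max(1 um, segment radius)
near the axis. Potentials superpose linearly at 1-ms resolution; per-cell
decomposition is available. Because the model fills the anatomical volume
at ~9,840 neurons/mm^3 while tissue holds 2.5e4-2e5, the LFP is scaled by
(tissue/model)^0.67, i.e. 1.9-7.5; the midpoint 4.7 is the default. The
0.67 exponent is an empirical full-scale fit; at reduced scale the package
can re-estimate it by cell-count subsampling but does not assert it. A
9x9x9 electrode grid spans the cuboid at 125-um spacing with 200-um
margins; near-edge electrodes' Z-scored gamma envelopes are multiplied by
the ratio of their gamma-band spectral fraction (area above a 1/f^a fit,
normalized by total area) to the center electrode's.

## Analysis conventions

* Morlet spectrograms: 7-cycle wavelets, 1-256 Hz in quarter octaves.
* Welch spectra: 500-ms Hamming windows, 250-ms steps.
* Band phase/amplitude: zero-phase Butterworth (order 4 for the 60-80-Hz
  burst band; order 2 for entrainment bands) + Hilbert transform.
* Single-electrode bursts: envelope > mean + 2 SD; duration is the span
  around the peak above 25% of it.
* Spatiotemporal bursts: 4-D watershed on the Z-scored, edge-corrected
  gamma envelope discretized into 0.1 bins, connectivity = adjacency along
  each axis (6-neighborhood in space, no diagonals). Maxima shallower than
  two amplitude bins are suppressed (morphological h-maxima) before
  flooding: discretization alone still over-segments moving bursts through
  sub-bin ripples as they pass between electrode sites. A burst must peak
  above 2 Z; members are trimmed at 25% of the peak. Features: peak Z,
  duration, volume (distinct sites reaching 2 Z), centroid path length and
  net start-to-end displacement (the path accumulates centroid jitter on
  noisy fields; the net displacement is the jitter-robust summary), speed
  = path/duration, and the debiased pairwise phase-locking value over the
  3x3x3 neighborhood of the peak — PLV^2 estimated as
  (n R^2 - 1)/(n - 1), which is unbiased under independence.
* Entrainment: resultant vector length (>=10 spikes) and pairwise phase
  consistency PPC = (n R^2 - 1)/(n - 1) (>=2 spikes), spikes restricted to
  cells within 300 um of the electrode.
* Spike coherence: FFTs of Hann-windowed, lag-limited (±100 ms) cross-
  and autocorrelations of 1-ms binned trains;
  `Coherence = XCorr/sqrt(ACorr_a ACorr_b)`; its inverse FFT is the
  autocorrelation-corrected cross-correlation (positive lag = second train
  follows the first).
* Gamma peak frequency: maximum of the Welch spectrum after dividing out a
  1/f^a power-law fit (fit excludes 30-100 Hz), searched within the gamma
  band 40-100 Hz. The band restriction matters at reduced scale, where a
  separate slow-gamma bump near 38 Hz (see below) can exceed the mid-gamma
  bump in a whole-spectrum argmax.

## Reduced-scale standard conditions

Network-level results run on a density-preserving 1,000-cell model (box
edge 467 um, 67 afferents; all probabilities, ranges and synaptic
parameters unchanged). Two corrections define the standard operating
point:

1. **In-degree compensation.** Box clipping cuts realized in-degrees far
   below full scale (e.g. 24.6 vs 42.6 inhibitory inputs per PN). The
   weights of the inhibitory-loop classes (PN->FSI, FSI->PN, FSI->FSI)
   are multiplied by full-scale/realized mean in-degree, preserving each
   cell's per-class total synaptic conductance. The PN->PN class is left
   uncompensated: its ratio (~4.5x) makes the reduced network epileptic
   (runaway PN firing that locks FSIs into NMDA-mediated depolarization
   block), and recurrent PN excitation plays only a modest role in gamma
   generation.
2. **Background rebalancing.** OU conductance means are scaled per
   archetype (PN: excitatory x1.2, inhibitory x1.3) so population rates
   stay in vivo-like (PNs ~0.8-1 Hz, FSIs ~35-45 Hz). The same
   procedure — proportional adjustment until rates match the unperturbed
   model within 10% — runs automatically after connection ablations.

Under these conditions the reduced model produces intermittent gamma
bursts with a spectral peak at 58-66 Hz across seeds (10-s runs), PING-like
phase ordering, and the directional ablation and competition effects. The
reduced model also expresses a slow-gamma bump near 38 Hz tied to the PNs'
Nap-dependent intrinsic (high-threshold-oscillation-like) dynamics, which
the full-scale model is not expected to show at the same strength; this is
a known reduced-scale artifact.

Problem sizes used by the test suite and the acceptance script: single
cells for all cell-level measurements; the full 27,000-cell graph for
wiring statistics (construction only, ~1 min); 1,000 cells x 10 s for the
spontaneous gamma measurement; 1,000 cells x 2.5-3 s for ablation and
competition directional checks. These sizes were chosen so each
network-level quantity is estimated from at least ~150 gamma cycles.

## Known limitations

* The FSI channel kinetics, I_A kinetics, reversal potentials and calcium
  influx constant are calibrated stand-ins; quantities that depend on
  their fine structure (exact FSI f-I slope, A-current pharmacology) are
  not predictions of this implementation.
* Surrogate afferents reproduce rate statistics, not the cross-correlation
  structure of real cortical ensembles; absolute low-frequency LFP power
  is therefore underestimated by construction.
* Reduced-scale runs reproduce directions and frequencies, not full-scale
  absolute magnitudes (e.g., absolute gamma power, burst spatial extents
  in electrode counts).
* The 4-D burst path length over-estimates travel on noisy envelope
  fields (centroid jitter); use the net displacement for translation
  claims.
* Gap junctions couple somata only; dendro-dendritic coupling is not
  modeled.
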