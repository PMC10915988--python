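# Methods

This note documents the model, the numerical choices, and the limits of
what the shipped defaults and tests demonstrate.

## Model overview

`swdsim` implements a conductance-based corticothalamic network for
studying absence-seizure spike-and-wave discharges (SWDs): 900
single-compartment Hodgkin–Huxley-style neurons in six sectors — four
cortical layers (L2/3, L4, L5, L6), each split into a 100-cell excitatory
subsector (a mixture of regular-spiking, intrinsically bursting,
early-firing, repetitive-bursting and network-driver classes) and a
50-cell subsector of fast-spiking interneurons, plus first-order and
higher-order thalamic sectors of 100 thalamocortical (TC) relay neurons
reciprocally coupled to 50 reticular (NRT) neurons each. Connectivity is
topographic: neurons occupy pseudo-random positions on one row per
subsector, and each projection contacts the targets within a radius `P`
around the source's matched position, never itself and at most once per
pair. A `scale` divisor shrinks every subsector and radius for desk-scale
work (the default experiments use scale 5, i.e. 180 neurons).

## Ionic currents

All kinetics are standard published single-compartment formulations:

- Fast spikes: Traub–Miles Na⁺/K⁺ with a per-class threshold shift `VT`.
- Spike-frequency adaptation / burst termination: slow non-inactivating
  K⁺ current (I_M) with a per-class peak time constant.
- Low-threshold Ca²⁺ (I_T): relay-type kinetics for TC and cortical
  bursting classes; reticular-type kinetics (more depolarised activation,
  slower inactivation) for NRT cells. I_T underlies rebound bursting and
  is the target of the `g_T` manipulations.
- Anomalous rectifier (I_h) in TC cells (small), persistent Na⁺ in NRT
  cells, and a Ca²⁺-activated non-selective cation current (I_CAN) in
  TC/NRT gated by a leaky intracellular Ca²⁺ pool filled by I_T influx.
  The NRT Ca²⁺ pool decays slowly (2.5 s) so that I_CAN integrates
  bursting over seconds; this is the model's seizure-termination
  mechanism and the reason blocking NRT `g_CAN` is catalogued as a
  status-producing manipulation.
- Leaks: a non-specific leak (g_leak, E_leak) and a K⁺ leak (g_KL,
  reversal E_K). `g_KL` sets each class's resting polarisation and is the
  proxy through which increased tonic GABA-A inhibition of TC cells is
  modelled; a distinct always-on Cl⁻ conductance (`g_tonic`, reversal
  E_Cl) provides the direct extrasynaptic GABA-A route, so both
  manipulations named in the experiment catalogue exist independently.

Maximal conductances per class were tuned once so that each of the 11
classes expresses its defining firing signature under a standard
current-clamp protocol (see `signature_protocol` /
`classify_firing_signature`): RS → regular spiking, IB/EF → onset burst,
RIB/ND/SIB → repetitive bursting, FS → fast spiking, TC/NRT → rebound
burst on release from hyperpolarisation. The classifier's criteria are:
burst = ≥2 spikes at ISIs ≤ 10 ms; rebound burst = burst within 350 ms of
release from a ≥100 ms period below −75 mV imposed by negative injected
current (the 350 ms window accommodates the reticular LTS, which ignites
~250 ms after release under these kinetics); fast spiking = ISI CV < 0.2
with < 20% adaptation at > 40 Hz; repetitive bursting = ≥3 bursts.

## Synapses

AMPA and phasic GABA-A are conductance-based, peak-normalised
bi-exponential gates (rise 0.5 ms; decay 2.5 ms / 7 ms) aggregated per
postsynaptic neuron; presynaptic spikes arrive through per-connection
latencies (config ranges per projection) via a circular delay buffer.
GABA-B uses a two-stage G-protein cascade per postsynaptic cell:
transmitter trace → receptor fraction r → G-protein s, with conductance
∝ s⁴/(s⁴ + K_d). The per-spike transmitter increment is small, so tonic
presynaptic firing leaves the cascade nearly silent while spike bursts
produce a large, slow IPSP — the burst selectivity on which the SWD
"wave" depends (property-tested: the burst/single-spike charge ratio
exceeds 10 and the event-count ratio). Tonic extrasynaptic GABA-A is a
constant Cl⁻ conductance on TC cells. NMDA receptors and short-term
plasticity are omitted.

## Integration

Fixed-step integration (default dt = 0.025 ms, upper bound 0.05 ms) with
exponential-Euler updates for gating variables and for the membrane
potential on the instantaneous total conductance. Gating steady states
and rate factors are pre-tabulated per cell class on a 0.05 mV grid and
linearly interpolated inside a numba-compiled kernel; interpolation is
clamped at the grid edges. Background drive is an independent Poisson
train of AMPA events per neuron (rate and amplitude per population,
seeded). Spike detection is an upward crossing of 0 mV with a 2 ms
refractory period. Determinism: a (network hash, config, seed) triple
reproduces results bit-exactly; halving dt changes population rates by
less than 5% on a 5 s benchmark. The EEG proxy is the negated sum of
AMPA, GABA-A and GABA-B currents onto cortical excitatory neurons,
averaged into 1 ms bins and mean-subtracted — a standard point-neuron
field approximation; its absolute scale is arbitrary.

## Vigilance states and perturbations

Two configured states scale the K⁺ leak and background drive network-wide:
`wake` (depolarised, strongly driven) and `sleep_wake_transition` (the
default, the seizure-prone regime). Perturbations are multiplicative
scalings of one conductance over one population from an onset time
onward: intrinsic conductances (g_KL, g_T, g_CAN, g_eGABAa) scale
per-neuron parameters; receptor manipulations (g_GABAa, g_AMPA, g_GABAb)
scale the postsynaptic receptor gain of the named population. Scale 0
removes the current entirely. The scenario catalogue registers 30 named
manipulations (tonic-inhibition ladders, cortical GABA-A/AMPA scalings,
SIB substitution in L5/L6, reticular and higher-order T-current
increases, and the block/boost composites on top of the two control
scenarios), each with its expected electrographic outcome.

## Analysis stack

- SWD bandpass: minimum-order Butterworth with passband edges ±2 Hz and
  stopband edges ±4 Hz around the centre frequency, 0.5 dB ripple, 65 dB
  attenuation, applied forward–backward (zero phase). When the centre
  frequency is low enough that the nominal lower stop edge is ≤ 0 Hz, the
  design clips it to half the lower passband edge; the response still
  vanishes toward DC.
- Hilbert phase and a windowed phase-synchronisation index
  PSI(t) = |⟨e^{iΔφ}⟩_{1 s}| with an additional 1 s moving average.
- Ictal segmentation: the 2–10 Hz Hilbert envelope (smoothed 250 ms) must
  exceed a robust baseline (median + 4 × lower-sided-MAD sigma; a
  quiet-quintile fallback anchors the threshold when rhythmic activity
  dominates the recording) for ≥ 0.75 s, gaps < 0.5 s merged, ≥ 3 EEG
  spike peaks required. Spike peaks are local maxima separated by ≥ 60%
  of the dominant period; the dominant frequency is the inverse median
  inter-peak interval; cycle boundaries are midpoints between peaks,
  extended half a period at the edges. A recording whose envelope stays
  above threshold for > 90% of its duration is flagged as status.
- Spike-triggered AP histograms (STAP) in all-AP and first-AP-per-cycle
  variants, with 5 ms bins centred on multiples of 5 ms over ±125 ms;
  negative lags mean the AP precedes the EEG spike.
- Burst/tonic/silent classification per neuron-cycle (burst = ≥2 APs at
  ISI ≤ 10 ms), with bootstrap confidence intervals over cycles;
  period-normalised averaging via linear resampling to the class-mean
  duration; pooled AP–EEG cross-correlation with a circular-shuffle
  confidence band.

## Synthetic ground truth

The fixtures module emulates ictal EEG morphology — each cycle a sharp
Gaussian transient plus a slower opposing half-sine — embedded in 1/f
(pink) background noise, together with spike trains phase-locked to the
cycles at configurable per-population lags, jitter and firing modes.
These are test instruments: they validate that the analysis stack
recovers seizure counts exactly, frequencies within 5%, lags within 5 ms
and firing-mode proportions, independently of the simulator. Passing
these tests demonstrates the correctness of the analyses, not the
realism of the simulated EEG.

## What the shipped network does and does not reproduce

The shipped defaults were frozen at a desynchronised, seizure-free
sleep–wake-transition baseline in which every manipulated conductance
responds in the physiologically expected direction (e.g. a 5% increase
of TC_FO g_KL lowers TC_FO tonic firing by ~20–30%; a 25% reduction of
TC_HO g_KL roughly triples TC_HO firing; blocks remove their currents
exactly). At desk scale (180 neurons, 3–5 synaptic contacts per
projection), however, the network does not reliably convert the 5%
tonic-inhibition increase into discrete large-amplitude ~4 Hz
spike-and-wave seizures: the ≤1 mV coherent shift this perturbation
produces on 20 TC cells is small compared with the fluctuation-driven
synchronisation threshold of populations this small, and the
seizure/no-seizure bistability of the full-size system did not survive
the five-fold scale-down in this implementation. Scenario verdicts and
the seizure-frequency, timing and abolition analyses therefore run end
to end but may detect no ictal events under the shipped defaults; the
acceptance script reports such quantities as null rather than
substituting values. Desk-scale amplitude claims are qualitative
throughout.

## Problem sizes used

Structural checks build the full 900-neuron network; all dynamical tests
and the acceptance script use the 180-neuron desk scale with 6–60 s test
runs and 120 s acceptance runs, three seeds derived from the base seed.
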