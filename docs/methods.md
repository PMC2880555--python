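# Methods

`columnet` simulates a modular attractor-memory network of neocortical
layer 2/3 and ships the experiment protocols and analyses used to
characterize its bistable oscillatory regime.  This note documents the
model, its parameters and units, the numerical choices, what the
synthetic inputs emulate, and the known limitations.

## Network architecture

The circuit is organized in two modular levels:

* **Minicolumn** — 30 pyramidal cells, 1 basket cell, 2 RSNP
  (regular-spiking non-pyramidal, double-bouquet-like) interneurons, all
  sharing stimulus selectivity.  Pyramidal cells connect to 25% of the
  other pyramidal cells of their minicolumn (single bouton per ordered
  pair, self-connections removed).
* **Hypercolumn** — 49 minicolumns sharing a basket-cell pool.  Each
  pyramidal cell drives the eight closest basket cells of its
  hypercolumn (2-D distance between minicolumn centres, ties broken by
  lowest cell index); each basket cell inhibits 70% of the pyramidal
  cells, and 70% of the other basket cells when basket-basket coupling
  is enabled.  Basket inhibition targets the soma.

The standard network has 9 hypercolumns — 14,553 neurons — on a 1.5 mm
square grid (21 x 21 minicolumn sites, each hypercolumn a contiguous
7 x 7 block; the grid layout inside the stated bounding box is our
choice).  Pyramidal cells of a minicolumn share x, y and spread uniquely
over 500 µm of z; interneurons sit at the z-centre.

**Memory patterns** are non-overlapping: pattern *p* consists of the
*p*-th minicolumn of every hypercolumn (49 patterns).  Long-range
excitation is pattern-specific: every pyramidal cell receives exactly 90
synapses from same-pattern pyramidal cells in other hypercolumns
(sampled without replacement, uniformly over that pool), with local to
global EPSP magnitudes 3:1.  RSNP cells receive long-range excitation
from *dissimilar*-pattern pyramidal cells and inhibit the second apical
compartment of their own minicolumn's pyramidal cells — disynaptic
long-range inhibition between patterns.

The RSNP long-range in-degree is 30 per cell, drawn from the union of
all dissimilar-pattern distant pyramidal cells.  The per-dissimilar-
pattern reading (30 for each of the 48 other patterns) is available as
`rsnp_lr_per_pattern`; the default was chosen to keep the standard
network's total connection count at its stated ~1.8–1.9 million (the
per-pattern reading yields ~3.1 million).

## Neuron models

Multi-compartment conductance-based cells (Hodgkin-Huxley / Rall):
pyramidal cells have 6 compartments (soma, basal, initial segment,
apical1–3 in a chain, all attached to the soma except the apical chain);
interneurons have 3 (soma, dendrite, initial segment).  Per compartment,

    c_m dV/dt = g_m (E_leak − V) + Σ g_core (V_nbr − V) + g_ext (E_ex − V)
                + I_channels + I_syn + I_inj

with units mV, ms, nS, nF, pA.  Core (axial) conductances appear
symmetrically in both coupled compartments (charge conservation), and
scale — together with c_m, g_m and all channel conductances — with the
cell's size factor, drawn uniformly from ±10% around 1.  Passive time
constants are therefore size-invariant, while rheobase scales with size.

Active currents: transient Na⁺ and delayed-rectifier K⁺ (soma + initial
segment, Traub-Miles-style rate functions), a high-voltage-activated
Ca²⁺ current and a Ca²⁺-dependent K⁺ (afterhyperpolarization) current on
the soma.  A single exponentially decaying calcium pool per compartment
integrates inward Ca current; NMDA-receptor current feeds the pool at a
reduced scale (0.15) so that persistent activity is not terminated by
adaptation.  The exact channel kinetics of the original model were not
available; the standard forms used here were *calibrated* against the
stated single-cell targets instead:

* adaptation ordering — pyramidal (index ≈ 5 at 30 pA) > RSNP (≈ 1.3) >
  basket (≈ 1.0), where the index is last ISI / first ISI over a 1 s step;
* a single pyramidal cell under the standard background noise source
  alone fires near 8 s⁻¹ with ⟨CV2⟩ near 0.69.

These two anchors pull in opposite directions: the sub-Poisson CV2 at
8 s⁻¹ requires adaptation on the ISI timescale, while attractor
persistence requires that adaptation not overwhelm recurrent drive.
The shipped parameters sit at the calibrated compromise; the cell JSON
documents under `columnet/data/cells/` are the single source of truth.

## Synapses

Conductance-based, instantaneous rise, single-exponential decay:
τ_AMPA = τ_GABA = 6 ms, τ_NMDA = 150 ms; E = 0 mV (AMPA/NMDA) and
−85 mV (GABA_A).  Robustness knobs expose τ_GABA up to 25 ms and E_GABA
up to −70 mV.  Synapses formed by pyramidal cells (AMPA and NMDA)
are *fully saturating*: a presynaptic spike resets the decayed
conductance to the single-spike peak rather than summing — the strictest
reading of saturation.  GABA_A and background-noise AMPA sum linearly.
NMDA receptors carry a Jahr-Stevens magnesium block
(1 mM Mg²⁺, 1/(1 + [Mg]/3.57 · e^(−V/16.13))); the specific sigmoid is a
standard choice recorded in configuration, any monotone gate of this
shape supports the reported dynamics.  Excitatory inputs (recurrent and
noise) land on the second apical and basal compartments of pyramidal
cells (one of the two per contact, uniformly at random) and on the
dendrite of interneurons; RSNP output targets apical2; basket output
targets somata.  Delays are distance-based: |Δx|/0.2 m s⁻¹ + 0.5 ms.

## Noise and layer-4 input

Every pyramidal cell receives an independent 300 s⁻¹ Poisson source
through weak non-saturating AMPA synapses (0.08 nS, ~10× smaller than
local pyr–pyr) onto apical2 and basal.  Implementation-wise the source
is split into two 150 s⁻¹ sub-sources, one per target compartment —
statistically identical to one source whose events choose a compartment
by coin flip (Poisson thinning).  Each minicolumn also owns five
layer-4-like Poisson input cells, silent unless their minicolumn is
stimulated (60–100 s⁻¹; protocols use the 80 s⁻¹ midpoint), wired
feedforward at 50% to the minicolumn's pyramidal cells.

## Simulation engine

Fixed-step integration, dt = 0.05 ms by default.  Every compartment is
locally linear in V given the instantaneous conductances, so V is
advanced by an exponential-Euler update toward A/B; the axial coupling
term uses a midpoint fixed-point corrector (two iterations), making the
cable part second-order accurate — passive multi-compartment transients
match dense matrix-exponential solutions to ≲0.3% at dt = 0.05 ms.
Gates advance exactly toward their voltage-dependent steady states.
Synaptic conductances aggregate per (compartment, receptor kind) and
decay with one scalar factor per kind per step; saturating synapses keep
a lazily updated per-edge state touched only on spikes.  Delayed
deliveries run through a ring buffer of per-tick event buckets — no
conductance changes before spike time + delay.  Spikes are soma
upward crossings of 0 mV with a 1.5 ms lockout.  Poisson sources are
realized per step as Bernoulli events with p = 1 − exp(−rate·dt).
Noise, stimulus, connectivity and size randomness draw from independent
named substreams fanned out of one root seed, so toggling one source
never reshuffles another and identical configurations reproduce
identical spike data bit-for-bit.

## Protocols

**Bistability** (three phases): ground phase with no stimulus — no
pattern may activate spontaneously; a 300 ms partial cue (layer-4 drive
to the pattern's minicolumns in 5 of 9 hypercolumns at full scale, half
the hypercolumns otherwise); a ≥3 s persistence phase.  The original
stability criteria are not stated quantitatively; ours are: *ground
stable* — no pattern's pyramidal rate exceeds 5× the all-pattern average
(with a 0.5 s⁻¹ floor) for more than 200 ms; *completed* — uncued
pattern minicolumns reach ≥50% of the cued minicolumns' rate within
500 ms of cue offset; *persisted* — foreground rate stays above an
absolute floor (2 s⁻¹) and above 2× the background rate in every 500 ms
bin.  A gain passes when every tested seed passes; the scan reports the
lower/upper boundaries of the passing gain range, their ratio, and the
fraction of active states stable at mid-range.

**Current balance**: a cell is held hyperpolarized (−0.2 nA somatic
injection) so it cannot spike while the network runs; the basket
conductance g_FS is then the only unknown in the somatic flux balance
and is solved per recorded sample (including the capacitive term from
the sampled dV/dt).  Excitatory current is the dendritic core influx
plus somatic excitatory synaptic current; inhibitory current is the
solved GABA_A term; their sum is the net current.  The solved g_FS can
be validated against the engine's recorded somatic GABA conductance.

**Modularity scan**: bistable-range scans across (hypercolumns,
pyramidal cells per minicolumn) cases holding the foreground population
≈270 cells, with RSNP cells and basket-basket connections removed for
comparability with non-modular models.  The full-scale scan is hours of
compute; the scan machinery is exercised at desk scale through a
dependency-injected trial runner.

## Analyses

* **CV2** — mean over n of 2|ISI_{n+1} − ISI_n| / (ISI_{n+1} + ISI_n);
  0 for clock-like trains, 1 for Poisson, bounded by 2; rate-independent
  in the network's dynamic range (unlike CV).  Population ⟨CV2⟩ is the
  unweighted mean of per-cell means; cells with fewer than 3 spikes are
  excluded and reported.
* **Synthetic LFP** — population mean of (V_soma − V_apical1),
  mean-subtracted; a dipole proxy justified by the geometric alignment
  of apical dendrites.  "First dendritic compartment" is the first
  apical compartment above the soma.
* **Spectrogram** — short-time Fourier power, Hann window, 250 ms /
  80% overlap by default (the original analysis parameters are unstated;
  these resolve beta-to-gamma transitions at the few-hundred-ms scale).
  Oscillation frequency is the Welch-spectrum peak within a band
  (default 10–80 Hz), flagged as absent when the peak does not rise
  above 2× the median in-band power.

## Scaled-down study conditions

The full 14,553-cell network is built and counted in seconds, but
multi-second simulations of it are hours of single-CPU compute.  The
dynamical test conditions therefore use the `mini` preset: 6
hypercolumns × 12 minicolumns × 20 pyramidal cells (1,656 neurons).
Long-range in-degrees are rescaled to the smaller same-pattern pools
(37 of 100 distant cells, matching the full network's 90-of-240
fraction) and the local density is raised to preserve the per-cell local
in-degree (~7).

Two scale adaptations proved necessary, and both are instructive about
the full-scale mechanism:

1. **Recurrent drive is carried by long-range NMDA.**  At desk scale the
   per-cycle winner-take-all fluctuations are relatively large (patterns
   of 120 cells instead of 2,430), and any appreciable fast (AMPA)
   recurrence lets the random winner of one oscillation cycle recruit
   its own pattern within that same cycle — spontaneous retrieval.  The
   slow NMDA conductance (τ = 150 ms) integrates over several cycles, so
   retrieval requires sustained, multi-hypercolumn coincidence — the
   modular stabilization argument — which a 300 ms cue provides and a
   single-cycle fluctuation does not.  The active state then shows the
   signature dynamics: one pattern active in all hypercolumns, the
   hypercolumns oscillating out of phase with one another.
2. **Tonic somatic inhibition sets the bistable operating point.**  The
   overall level of inhibition is the knob that makes the network
   bistable; in the preset a constant 0.75 nS GABA_A conductance on the
   pyramidal somata raises the spontaneous-retrieval threshold above the
   background-noise fluctuations while leaving cue-driven layer-4 input
   (~60 pA) and the active state's saturated NMDA drive (~100 pA) well
   above it.

With these settings (seeds checked independently) the desk-scale network
shows: a ground state stable for the full 3 s pre-cue phase; partial-cue
pattern completion; persistence for ≥3 s after cue offset at ~12 s⁻¹
foreground rates; background rates below ground rates; and a faster,
much stronger LFP oscillation in the active state (~20–22 Hz) than in
ground.  The trade-off of the tonic operating point is a much quieter
ground state (~0.01 s⁻¹ versus the full model's 0.5–1 s⁻¹ beta-
oscillating ground): the ground-versus-active *per-hypercolumn spike
count conservation* of the full-scale regime does not hold here, and its
test is expected to fail at desk scale.  Passing desk-scale tests
demonstrates mechanism and implementation correctness, not quantitative
agreement at full scale.

**Initialization.**  Identical initial conditions (all cells at rest,
empty synapses, empty calcium pools) produce an artificial synchronized
first-spike wave that saturates the NMDA synapses network-wide and hands
an arbitrary pattern a fully formed attractor state.  Protocol runs
therefore start with a small uniform membrane-potential jitter (±2 mV)
and ramp the background noise in linearly over 0.5 s, letting the
network settle into its ground state; the engine also supports exact
warm starts (`final_state` / `init_state`) for state-continuation
experiments.

## Known limitations

* Channel kinetics are calibrated stand-ins, not the original (and
  unavailable) parameter tables; single-cell targets, not channel
  constants, are the contract.
* No synaptic depression/facilitation (deliberately disabled in the
  modelled experiments), no gap junctions, no overlapping patterns.
* The LFP is a two-point dipole proxy, not a volume-conductor model.
* Bernoulli-per-step Poisson realization caps sources at one event per
  dt (rate error < 1% at 300 s⁻¹ with dt = 0.05 ms).
* The desk-scale bistable regime needs a quiet ground state (see above);
  the living 0.5–1 s⁻¹ beta-oscillating ground and the per-hypercolumn
  output conservation between states are full-scale phenomena this
  package's desk-scale runs do not reproduce.
* Parallel/large-scale execution is out of scope; the engine is a
  single-process vectorized NumPy loop.
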