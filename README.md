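# columnet

A simulator for a modular attractor-memory network of neocortical layer
2/3, built for studying how **bistable persistent activity**, **irregular
single-cell firing** and **beta/gamma population oscillations** coexist in
a cortical working-memory circuit.

The model organizes conductance-based multi-compartment neurons —
pyramidal cells, fast-spiking basket cells and regular-spiking
non-pyramidal (RSNP) interneurons — into minicolumns (30 pyramidal + 1
basket + 2 RSNP cells) and hypercolumns (49 minicolumns sharing a
basket-cell pool).  Non-overlapping memory patterns link one minicolumn
per hypercolumn through long-range AMPA/NMDA excitation; basket cells
provide soma-targeting winner-take-all feedback within each hypercolumn,
and RSNP cells dendrite-targeting disynaptic inhibition between patterns.
The standard network is 9 hypercolumns: 14,553 neurons and ~1.9 million
synaptic connections.

Each compartment follows a Hodgkin-Huxley/Rall current balance,

    c_m dV/dt = g_m (E_leak − V) + Σ g_core (V_nbr − V) + g_ext (E_ex − V)
                + I_channels + I_syn + I_inj ,

with Na⁺/K⁺ spike currents, a high-voltage-activated Ca²⁺ current and a
Ca²⁺-dependent K⁺ adaptation current.  Glutamatergic synapses formed by
pyramidal cells are *saturating* (repetitive firing cannot exceed the
single-spike peak conductance); τ_AMPA = τ_GABA = 6 ms, τ_NMDA = 150 ms.
Every pyramidal cell is driven by an independent 300 s⁻¹ Poisson noise
source (0.08 nS AMPA), which alone makes it fire at ≈8 s⁻¹ with local
ISI variability ⟨CV2⟩ ≈ 0.69, where

    CV2 = mean over n of 2 |ISI_{n+1} − ISI_n| / (ISI_{n+1} + ISI_n).

The package implements the experiment protocols (three-phase bistability
test and gain scans, modularity scan, somatic current-balance
measurement, ground-state f-I) and the analyses (CV2, population rates,
synthetic LFP = population-averaged soma-minus-apical-dendrite potential,
spectrograms, oscillation frequencies).

## Worked example

Drive one pyramidal cell with the standard background noise source
(`examples/single_cell_noise_drive.py`):

```text
spikes: 239 over 30 s
mean rate: 7.97 /s   (target regime ~8 /s)
CV2: 0.692      (1 = Poisson-like, 0 = clock-like)
```

The cell fires at ~8 s⁻¹, and its spike train is irregular but
sub-Poisson — the noise-driven operating point of the network's ground
state.  Build the full network and check its structure
(`examples/network_counts.py`):

```text
cells: 14553
synaptic connections: 1,905,075 (expected 1,906,046 ± 467)
```

Run the cue/persistence protocol on the desk-scale `mini` preset
(`examples/bistability_demo.py`): a 300 ms layer-4 cue to part of one
pattern completes the pattern and leaves it persistently active while
background cells fall silent:

```text
gain 1.0, seed 1
  ground stable : True
  completed     : True
  persisted     : True
  PASS          : True
  ground rate   : 0.01 /s (all pyramidal)
  foreground    : 11.65 /s
  background    : 0.00 /s
```

The cued pattern's ~12 s⁻¹ persistent firing outlives the cue by
seconds while every competing pattern stays off — the working-memory
attractor.  (At desk scale the stable ground state is much quieter than
the full model's 0.5–1 s⁻¹; see `docs/methods.md`.)

Other examples: `adaptation_and_fi.py` (adaptation indices and f-I
curves), `current_balance.py` (solving the basket conductance from the
somatic flux balance of a hyperpolarized cell), `lfp_and_spectrogram.py`
(synthetic LFP spectral analysis).

A thin CLI wraps the same calls: `columnet build`, `columnet simulate`,
`columnet protocol bistability|table1|balance`, `columnet analyze
cv2|freq`, `columnet cell fi-curve|adapt`, `columnet fixture`.

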