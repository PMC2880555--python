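"""Conductance-based synapse kinetics.

Three receptor kinds: AMPA and voltage-gated NMDA (glutamatergic, formed by
pyramidal cells), and GABA_A (formed by the interneurons).  A synaptic
event makes the conductance jump and then decay exponentially with the
receptor time constant (instantaneous rise):

    tau_AMPA = 6 ms, tau_GABA = 6 ms, tau_NMDA = 150 ms
    E_AMPA = E_NMDA = 0 mV, E_GABA = -85 mV

Synapses formed by pyramidal cells are *fully saturating*: during
repetitive firing the conductance can only sum up to the peak conductance
produced by a single presynaptic spike (each spike resets the decayed
conductance to ``g_peak`` rather than adding to it).  Background-noise AMPA
synapses and GABA_A synapses sum linearly.

Conduction delays are distance-based: Euclidean distance / 0.2 m/s axonal
conduction speed, plus a fixed 0.5 ms synaptic delay.

NMDA receptors carry a voltage-dependent Mg2+ block modelled with the
standard physiological sigmoid (Jahr-Stevens form); the gate multiplies the
NMDA conductance at the postsynaptic membrane potential.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "SYNAPSE_KINDS",
    "TAU_DEFAULT",
    "E_REV_DEFAULT",
    "AXONAL_SPEED_UM_PER_MS",
    "SYNAPTIC_DELAY_MS",
    "SynapseSpec",
    "SynapseState",
    "on_presynaptic_spike",
    "conductance_at",
    "nmda_gate",
    "conduction_delay",
]

SYNAPSE_KINDS = ("AMPA", "NMDA", "GABA_A")

TAU_DEFAULT = {"AMPA": 6.0, "NMDA": 150.0, "GABA_A": 6.0}   # ms
E_REV_DEFAULT = {"AMPA": 0.0, "NMDA": 0.0, "GABA_A": -85.0}  # mV

#: 0.2 m/s in simulation units (µm per ms)
AXONAL_SPEED_UM_PER_MS = 200.0
#: fixed synaptic (transmission) delay, ms
SYNAPTIC_DELAY_MS = 0.5

MIN_DELAY_MS = 0.5


@dataclass(frozen=True)
class SynapseSpec:
    """Static parameters of one synapse."""

    kind: str
    g_peak: float                 # nS
    tau_decay: float | None = None   # ms; kind default when None
    E_rev: float | None = None       # mV; kind default when None
    saturating: bool = True
    target_compartment: str = "soma"
    delay: float = MIN_DELAY_MS      # ms

    def __post_init__(self):
        if self.kind not in SYNAPSE_KINDS:
            raise ValueError(f"unknown synapse kind {self.kind!r}")
        if self.g_peak < 0:
            raise ValueError("g_peak must be non-negative")
        if self.tau_decay is None:
            object.__setattr__(self, "tau_decay", TAU_DEFAULT[self.kind])
        if self.E_rev is None:
            object.__setattr__(self, "E_rev", E_REV_DEFAULT[self.kind])
        if self.tau_decay <= 0:
            raise ValueError("tau_decay must be positive")
        if self.delay < MIN_DELAY_MS:
            raise ValueError(f"delay must be >= {MIN_DELAY_MS} ms")


@dataclass(frozen=True)
class SynapseState:
    """Lazily updated kinetic state: conductance at the last event time."""

    g: float = 0.0       # nS at time t_last
    t_last: float = 0.0  # ms

    def __post_init__(self):
        if self.g < 0:
            raise ValueError("conductance must be non-negative")


def conductance_at(state: SynapseState, spec: SynapseSpec, t: float) -> float:
    """Conductance at time ``t`` >= last update (single exponential decay)."""
    dt = t - state.t_last
    if dt < 0:
        raise ValueError("time runs backwards: t earlier than last update")
    return state.g * float(np.exp(-dt / spec.tau_decay))


def on_presynaptic_spike(
    state: SynapseState, spec: SynapseSpec, t: float
) -> SynapseState:
    """Update the synapse for a presynaptic spike arriving at time ``t``.

    The conductance is first decayed to ``t``; a saturating synapse is then
    reset to ``g_peak`` (so repetitive firing can never exceed the
    single-spike peak), a non-saturating synapse adds ``g_peak`` on top.
    """
    g_now = conductance_at(state, spec, t)
    if spec.saturating:
        g_new = spec.g_peak
    else:
        g_new = g_now + spec.g_peak
    return replace(state, g=g_new, t_last=float(t))


# -- NMDA magnesium block ----------------------------------------------------

#: Jahr-Stevens Mg block parameters: 1 / (1 + [Mg]/K * exp(-V/Vs))
NMDA_MG_MM = 1.0
NMDA_MG_K = 3.57     # mM
NMDA_MG_VSLOPE = 16.13  # mV


def nmda_gate(V):
    """Voltage-dependent NMDA Mg-block gate, a monotone sigmoid in [0, 1].

    Vectorized over ``V`` (mV).
    """
    V = np.asarray(V, dtype=float)
    out = 1.0 / (1.0 + (NMDA_MG_MM / NMDA_MG_K) * np.exp(-V / NMDA_MG_VSLOPE))
    return out if out.ndim else float(out)


# -- conduction delay --------------------------------------------------------

def conduction_delay(pre_pos, post_pos) -> float | np.ndarray:
    """Axonal + synaptic delay (ms) between two positions (µm triples).

    delay = |pre - post| / 0.2 m/s + 0.5 ms.  Vectorized when given arrays
    of shape (n, 3).
    """
    pre = np.asarray(pre_pos, dtype=float)
    post = np.asarray(post_pos, dtype=float)
    dist = np.sqrt(np.sum((pre - post) ** 2, axis=-1))
    d = dist / AXONAL_SPEED_UM_PER_MS + SYNAPTIC_DELAY_MS
    return d if np.ndim(d) else float(d)
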