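"""Multi-compartment conductance-based model neurons.

Three cell classes populate the network: layer 2/3 pyramidal cells
(6 compartments: soma, basal dendrite, axon initial segment and a chain of
three apical dendrites), fast-spiking soma-targeting basket cells and
regular-spiking non-pyramidal (RSNP) dendrite-targeting interneurons (both
3 compartments: soma, dendrite, initial segment).

Each compartment obeys a current-balance (cable) equation

    c_m dV/dt = g_m (E_leak - V) + sum_nbr g_core (V_nbr - V)
                + g_ext (E_ex - V) + I_channels + I_syn + I_inj

with Hodgkin-Huxley style active currents (transient Na+, delayed-rectifier
K+, high-voltage-activated Ca2+ and Ca2+-dependent K+) on the excitable
compartments.  Spike-frequency adaptation is produced by a single
exponentially decaying calcium pool per compartment that drives the KCa
(afterhyperpolarization) current; NMDA receptor current feeds the pool at a
reduced scale (15% by default) so that memory states are not terminated by
adaptation.

Units throughout: mV, ms, nS, nF, pA.  Note nS * mV = pA and
tau_m [ms] = 1000 * c_m [nF] / g_m [nS].

Baseline parameter sets are shipped as JSON documents (one per cell type,
``columnet/data/cells``).  They were tuned so that, qualitatively,
pyramidal cells adapt strongly, RSNP cells moderately and basket cells
hardly at all, and quantitatively so that a single pyramidal cell driven
only by the standard background noise source fires near 8 spikes/s with a
local ISI variability <CV2> near 0.69 (see ``columnet.protocols``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping

import numpy as np

__all__ = [
    "COMPARTMENT_LABELS",
    "CELL_TYPES",
    "CompartmentSpec",
    "ChannelSet",
    "NeuronSpec",
    "baseline_neuron",
    "build_neuron",
    "compartment_derivative",
    "characterize_adaptation",
    "AdaptationResult",
]

COMPARTMENT_LABELS = (
    "soma",
    "basal",
    "initial_segment",
    "apical1",
    "apical2",
    "apical3",
)

CELL_TYPES = ("pyramidal", "basket", "RSNP")

#: number of compartments per cell type (pyramidal: soma + basal + initial
#: segment + 3 apical; interneurons: soma + dendrite + initial segment)
N_COMPARTMENTS = {"pyramidal": 6, "basket": 3, "RSNP": 3}

SIZE_FACTOR_RANGE = (0.9, 1.1)


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CompartmentSpec:
    """Passive properties of one compartment.

    ``g_core_neighbors`` maps a neighbouring compartment's label to the core
    (axial) conductance linking the two; the same value must appear in the
    neighbour's map (charge conservation across the junction).
    """

    label: str
    c_m: float              # nF
    g_m: float              # nS
    E_leak: float           # mV
    g_core_neighbors: Mapping[str, float] = field(default_factory=dict)
    g_ext: float = 0.0      # nS, tonic non-specific excitatory conductance
    E_ex: float = 0.0       # mV

    def __post_init__(self):
        if self.label not in COMPARTMENT_LABELS:
            raise ValueError(f"unknown compartment label {self.label!r}")
        if not (self.c_m > 0 and self.g_m > 0):
            raise ValueError("c_m and g_m must be positive")
        if any(g < 0 for g in self.g_core_neighbors.values()):
            raise ValueError("core conductances must be non-negative")


@dataclass(frozen=True)
class ChannelSet:
    """Active-channel maximal conductances (per compartment label, nS) and
    calcium-pool parameters shared by all compartments of the cell.

    ``ca_alpha`` converts inward Ca current (pA) to pool increments
    (pool-units/ms/pA); ``ca_tau`` is the pool decay time constant (ms).
    ``nmda_ca_scale`` is the fraction of NMDA current admitted to the pool
    (0.15: reduced calcium influx through NMDA receptors so adaptation does
    not terminate persistent activity).
    """

    g_na: Mapping[str, float] = field(default_factory=dict)
    g_k: Mapping[str, float] = field(default_factory=dict)
    g_ca: Mapping[str, float] = field(default_factory=dict)
    g_kca: Mapping[str, float] = field(default_factory=dict)
    ca_alpha: float = 0.0
    ca_tau: float = 300.0
    nmda_ca_scale: float = 0.15
    E_na: float = 50.0
    E_k: float = -90.0
    E_ca: float = 150.0

    def __post_init__(self):
        for name in ("g_na", "g_k", "g_ca", "g_kca"):
            gmap = getattr(self, name)
            if any(g < 0 for g in gmap.values()):
                raise ValueError(f"{name} conductances must be non-negative")
        if self.ca_tau <= 0:
            raise ValueError("ca_tau must be positive")


@dataclass(frozen=True)
class NeuronSpec:
    """A complete cell: ordered compartments, channels, size factor."""

    cell_type: str
    compartments: tuple[CompartmentSpec, ...]
    channels: ChannelSet
    size_factor: float = 1.0

    def __post_init__(self):
        if self.cell_type not in CELL_TYPES:
            raise ValueError(f"unknown cell type {self.cell_type!r}")
        n_expected = N_COMPARTMENTS[self.cell_type]
        if len(self.compartments) != n_expected:
            raise ValueError(
                f"{self.cell_type} requires {n_expected} compartments, "
                f"got {len(self.compartments)}"
            )
        lo, hi = SIZE_FACTOR_RANGE
        if not (lo <= self.size_factor <= hi):
            raise ValueError(
                f"size_factor {self.size_factor} outside [{lo}, {hi}]"
            )
        labels = [c.label for c in self.compartments]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate compartment labels")
        by_label = {c.label: c for c in self.compartments}
        for comp in self.compartments:
            for nbr, g in comp.g_core_neighbors.items():
                if nbr not in by_label:
                    raise ValueError(
                        f"{comp.label} references unknown neighbour {nbr!r}"
                    )
                g_back = by_label[nbr].g_core_neighbors.get(comp.label)
                if g_back is None or not np.isclose(g_back, g):
                    raise ValueError(
                        f"asymmetric core conductance {comp.label}<->{nbr}"
                    )

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(c.label for c in self.compartments)

    def compartment(self, label: str) -> CompartmentSpec:
        for c in self.compartments:
            if c.label == label:
                return c
        raise KeyError(label)


# ---------------------------------------------------------------------------
# baseline parameter sets
# ---------------------------------------------------------------------------

def _load_cell_json(cell_type: str) -> dict:
    fname = f"{cell_type.lower()}.json"
    ref = resources.files("columnet.data.cells").joinpath(fname)
    with ref.open("r") as fh:
        return json.load(fh)


def _spec_from_dict(doc: dict) -> NeuronSpec:
    cores: dict[str, dict[str, float]] = {}
    for key, g in doc.get("core", {}).items():
        a, b = key.split("-")
        cores.setdefault(a, {})[b] = float(g)
        cores.setdefault(b, {})[a] = float(g)
    comps = []
    for label, p in doc["compartments"].items():
        comps.append(
            CompartmentSpec(
                label=label,
                c_m=float(p["c_m"]),
                g_m=float(p["g_m"]),
                E_leak=float(p["E_leak"]),
                g_core_neighbors=cores.get(label, {}),
                g_ext=float(p.get("g_ext", doc.get("g_ext", 0.0))),
                E_ex=float(p.get("E_ex", doc.get("E_ex", 0.0))),
            )
        )
    ch = doc.get("channels", {})
    channels = ChannelSet(
        g_na=ch.get("g_na", {}),
        g_k=ch.get("g_k", {}),
        g_ca=ch.get("g_ca", {}),
        g_kca=ch.get("g_kca", {}),
        ca_alpha=float(ch.get("ca_alpha", 0.0)),
        ca_tau=float(ch.get("ca_tau", 300.0)),
        nmda_ca_scale=float(ch.get("nmda_ca_scale", 0.15)),
        E_na=float(ch.get("E_na", 50.0)),
        E_k=float(ch.get("E_k", -90.0)),
        E_ca=float(ch.get("E_ca", 150.0)),
    )
    return NeuronSpec(
        cell_type=doc["cell_type"], compartments=tuple(comps), channels=channels
    )


_BASELINE_CACHE: dict[str, NeuronSpec] = {}


def baseline_neuron(cell_type: str) -> NeuronSpec:
    """The versioned baseline parameter set for a cell type (size_factor 1)."""
    if cell_type not in CELL_TYPES:
        raise ValueError(f"unknown cell type {cell_type!r}")
    if cell_type not in _BASELINE_CACHE:
        _BASELINE_CACHE[cell_type] = _spec_from_dict(_load_cell_json(cell_type))
    return _BASELINE_CACHE[cell_type]


def build_neuron(
    cell_type: str,
    size_factor: float = 1.0,
    rng: np.random.Generator | None = None,
) -> NeuronSpec:
    """Instantiate a neuron, scaling membrane-area quantities by its size.

    All cells of a type share one parameter set except size, which varies
    +/-10% uniformly.  If ``rng`` is given and ``size_factor`` is None the
    factor is drawn from U(0.9, 1.1).  The size factor scales c_m, g_m,
    every channel maximal conductance and the core conductances (cross
    section scales with cell size), so the passive time constant c_m/g_m is
    size-invariant.
    """
    if size_factor is None:
        if rng is None:
            raise ValueError("need rng to draw size_factor")
        size_factor = float(rng.uniform(*SIZE_FACTOR_RANGE))
    lo, hi = SIZE_FACTOR_RANGE
    if not (lo <= size_factor <= hi):
        raise ValueError(f"size_factor {size_factor} outside [{lo}, {hi}]")
    base = baseline_neuron(cell_type)
    s = float(size_factor)
    comps = tuple(
        replace(
            c,
            c_m=c.c_m * s,
            g_m=c.g_m * s,
            g_ext=c.g_ext * s,
            g_core_neighbors={k: g * s for k, g in c.g_core_neighbors.items()},
        )
        for c in base.compartments
    )
    ch = base.channels
    channels = replace(
        ch,
        g_na={k: g * s for k, g in ch.g_na.items()},
        g_k={k: g * s for k, g in ch.g_k.items()},
        g_ca={k: g * s for k, g in ch.g_ca.items()},
        g_kca={k: g * s for k, g in ch.g_kca.items()},
    )
    return NeuronSpec(
        cell_type=cell_type,
        compartments=comps,
        channels=channels,
        size_factor=s,
    )


# ---------------------------------------------------------------------------
# gating kinetics (Traub-Miles style rate functions, all vectorized over V)
# ---------------------------------------------------------------------------

def _lin_exp(x: np.ndarray) -> np.ndarray:
    """x / (1 - exp(-x)), continuous through x = 0."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < 1e-7
    safe = np.where(small, 1.0, x)
    return np.where(small, 1.0 + x / 2.0, safe / (-np.expm1(-safe)))


def na_m_rates(V):
    a = 0.32 * 4.0 * _lin_exp((V + 54.0) / 4.0)
    b = 0.28 * 5.0 * _lin_exp(-(V + 27.0) / 5.0)
    return a, b


def na_h_rates(V):
    a = 0.128 * np.exp(-(np.asarray(V, float) + 50.0) / 18.0)
    b = 4.0 / (1.0 + np.exp(-(np.asarray(V, float) + 27.0) / 5.0))
    return a, b


def k_n_rates(V):
    a = 0.032 * 5.0 * _lin_exp((V + 52.0) / 5.0)
    b = 0.5 * np.exp(-(np.asarray(V, float) + 57.0) / 40.0)
    return a, b


def ca_s_inf(V):
    """Steady-state activation of the high-voltage-activated Ca current."""
    return 1.0 / (1.0 + np.exp(-(np.asarray(V, float) + 20.0) / 9.0))


CA_S_TAU = 1.5  # ms, voltage-independent HVA activation time constant


def gate_steady_state(V):
    """Steady-state values of all gates at voltage V (used to initialize)."""
    am, bm = na_m_rates(V)
    ah, bh = na_h_rates(V)
    an, bn = k_n_rates(V)
    return {
        "m": am / (am + bm),
        "h": ah / (ah + bh),
        "n": an / (an + bn),
        "s": ca_s_inf(V),
    }


# ---------------------------------------------------------------------------
# reference derivative (single neuron; the engine has a vectorized twin)
# ---------------------------------------------------------------------------

def channel_currents(spec: NeuronSpec, V: np.ndarray, gates: dict) -> np.ndarray:
    """Active channel current per compartment (pA, positive = inward)."""
    ch = spec.channels
    I = np.zeros(len(spec.compartments))
    for i, comp in enumerate(spec.compartments):
        lbl = comp.label
        v = V[i]
        g_na = ch.g_na.get(lbl, 0.0)
        if g_na:
            I[i] += g_na * gates["m"][i] ** 3 * gates["h"][i] * (ch.E_na - v)
        g_k = ch.g_k.get(lbl, 0.0)
        if g_k:
            I[i] += g_k * gates["n"][i] ** 4 * (ch.E_k - v)
        g_ca = ch.g_ca.get(lbl, 0.0)
        if g_ca:
            I[i] += g_ca * gates["s"][i] ** 2 * (ch.E_ca - v)
        g_kca = ch.g_kca.get(lbl, 0.0)
        if g_kca:
            I[i] += g_kca * gates["ca"][i] * (ch.E_k - v)
    return I


def compartment_derivative(
    state: dict,
    spec: NeuronSpec,
    syn_current: np.ndarray | None = None,
    inj_current: np.ndarray | None = None,
) -> dict:
    """Time derivative of the full single-neuron state.

    ``state`` maps ``V`` (mV, one entry per compartment in spec order) and
    gate arrays ``m, h, n, s, ca`` to values.  ``syn_current`` and
    ``inj_current`` are per-compartment currents in pA (positive = inward).
    Returns a dict of the same shape with d/dt values (per ms).

    This is the readable reference implementation of the current-balance
    equation; the simulation engine implements the same dynamics in
    vectorized form and is cross-checked against this in the test suite.
    """
    n = len(spec.compartments)
    V = np.asarray(state["V"], dtype=float)
    if V.shape != (n,):
        raise ValueError(f"state V must have shape ({n},)")
    if not np.all(np.isfinite(V)):
        raise FloatingPointError("non-finite voltage in state")
    syn = np.zeros(n) if syn_current is None else np.asarray(syn_current, float)
    inj = np.zeros(n) if inj_current is None else np.asarray(inj_current, float)

    gates = {k: np.asarray(state[k], dtype=float) for k in ("m", "h", "n", "s", "ca")}
    I_chan = channel_currents(spec, V, gates)

    idx = {c.label: i for i, c in enumerate(spec.compartments)}
    dV = np.zeros(n)
    for i, comp in enumerate(spec.compartments):
        I = comp.g_m * (comp.E_leak - V[i])
        for nbr, g in comp.g_core_neighbors.items():
            I += g * (V[idx[nbr]] - V[i])
        I += comp.g_ext * (comp.E_ex - V[i])
        I += I_chan[i] + syn[i] + inj[i]
        # pA / nF = 1e-3 mV/ms
        dV[i] = 1e-3 * I / comp.c_m

    am, bm = na_m_rates(V)
    ah, bh = na_h_rates(V)
    an, bn = k_n_rates(V)
    d = {
        "V": dV,
        "m": am * (1 - gates["m"]) - bm * gates["m"],
        "h": ah * (1 - gates["h"]) - bh * gates["h"],
        "n": an * (1 - gates["n"]) - bn * gates["n"],
        "s": (ca_s_inf(V) - gates["s"]) / CA_S_TAU,
    }
    # calcium pool: inward Ca-channel current feeds it, then exponential decay
    ch = spec.channels
    dca = -gates["ca"] / ch.ca_tau
    for i, comp in enumerate(spec.compartments):
        g_ca = ch.g_ca.get(comp.label, 0.0)
        if g_ca and ch.ca_alpha:
            i_ca = g_ca * gates["s"][i] ** 2 * (ch.E_ca - V[i])
            dca[i] += ch.ca_alpha * max(i_ca, 0.0)
    d["ca"] = dca
    return d


def initial_state(spec: NeuronSpec, V0: float | None = None) -> dict:
    """Resting state with gates at steady state for V0 (default E_leak)."""
    n = len(spec.compartments)
    if V0 is None:
        V = np.array([c.E_leak for c in spec.compartments])
    else:
        V = np.full(n, float(V0))
    g = gate_steady_state(V)
    return {
        "V": V,
        "m": np.asarray(g["m"], float).reshape(n),
        "h": np.asarray(g["h"], float).reshape(n),
        "n": np.asarray(g["n"], float).reshape(n),
        "s": np.asarray(g["s"], float).reshape(n),
        "ca": np.zeros(n),
    }


# ---------------------------------------------------------------------------
# single-cell characterization
# ---------------------------------------------------------------------------

@dataclass
class AdaptationResult:
    """Spike response of a cell to a current step.

    ``adaptation_index`` is last ISI / first ISI (1 = non-adapting, > 1 =
    adapting); ``None`` when fewer than 3 spikes were emitted (flagged by
    ``valid = False``).
    """

    spike_times: np.ndarray
    adaptation_index: float | None
    valid: bool


def characterize_adaptation(
    spec: NeuronSpec,
    step_current: float,
    duration: float = 1000.0,
    dt: float = 0.05,
) -> AdaptationResult:
    """Apply a somatic current step (pA) and measure spike-frequency
    adaptation as the ratio of the last to the first inter-spike interval.

    Pyramidal cells adapt strongly (index well above 1), RSNP cells show
    intermediate adaptation and basket cells almost none (index near 1).
    """
    from .engine import simulate_single_cell

    spikes, _ = simulate_single_cell(
        spec, duration=duration, dt=dt, i_inj=step_current
    )
    if len(spikes) < 3:
        return AdaptationResult(np.asarray(spikes), None, False)
    isis = np.diff(spikes)
    return AdaptationResult(
        np.asarray(spikes), float(isis[-1] / isis[0]), True
    )
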