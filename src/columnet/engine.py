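"""Fixed-step simulation engine for the compartmental network.

Integration uses exponential-Euler updates: the membrane equation of every
compartment is locally linear in V given the instantaneous conductances
(channel gates, synaptic conductances and neighbour voltages held over one
step), so V relaxes exactly toward A/B with rate B/c; Hodgkin-Huxley gates
are advanced the same way toward their voltage-dependent steady states.
Default dt = 0.05 ms.

Synaptic conductances are aggregated per (compartment, receptor kind);
because every synapse of a kind shares one decay constant, the aggregate
decays with a single scalar factor per step, and individual saturating
synapses keep only a lazily updated (conductance, last-event-time) pair
touched when a presynaptic spike arrives.  Delayed deliveries run through
a ring buffer of event buckets, one per dt tick, so no conductance changes
before spike time + conduction delay (causality).

Spikes are detected as upward threshold crossings of the soma potential
(default 0 mV) with a 1.5 ms lockout against the wiggles of the
Hodgkin-Huxley spike shape.

Background noise and layer-4 stimulus spike trains are Poisson processes
realized per step as Bernoulli events with p = 1 - exp(-rate dt), drawn
from dedicated seed substreams so recording choices never perturb the
dynamics.

Units: mV, ms, nS, nF, pA (public current-injection API: nA).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp

from . import cells as _cells
from ._rng import substream
from .cells import NeuronSpec, build_neuron
from .network import TARGET_CODE, Network
from .synapses import nmda_gate

__all__ = [
    "SimulationConfig",
    "SpikeData",
    "TraceData",
    "SimulationResult",
    "CurrentInjection",
    "PatternStimulus",
    "inject_current",
    "stimulate_pattern",
    "simulate",
    "simulate_cells",
    "simulate_single_cell",
    "IntegrationError",
]

_KINDS = ("ampa", "nmda", "gaba")
_KIND_IDX = {k: i for i, k in enumerate(_KINDS)}


class IntegrationError(RuntimeError):
    """Raised when the state diverges; carries the last finite time (ms)."""

    def __init__(self, t_last_good: float):
        super().__init__(
            f"non-finite state encountered; last good time {t_last_good:.3f} ms"
        )
        self.t_last_good = t_last_good


# ---------------------------------------------------------------------------
# configuration and result containers
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    duration: float               # ms
    dt: float = 0.05              # ms
    sample_interval: float = 1.0  # ms, trace recording cadence
    record_cells: Sequence[int] = ()
    spike_threshold: float = 0.0  # mV at the soma
    lockout: float = 1.5          # ms refractory guard for detection
    check_every: int = 2000       # steps between divergence checks
    #: uniform per-compartment jitter (mV) around E_leak at t=0; breaks the
    #: artificial synchrony of identical initial conditions that would
    #: otherwise ignite an attractor through one giant startup volley
    v_init_jitter: float = 0.0
    #: linear ramp-in of the background noise rate over this many ms, so a
    #: network walks gently into its balanced state instead of receiving
    #: full drive before the inhibition loop and adaptation have settled
    noise_ramp_ms: float = 0.0
    #: initial value of the adaptation calcium pool (pool units); a nonzero
    #: value starts cells pre-adapted, avoiding the over-excitable window
    #: before spike-driven calcium reaches its steady state
    ca_init: float = 0.0

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.dt > 0.1:
            raise ValueError("dt > 0.1 ms is outside the stability guard")
        if self.duration <= 0:
            raise ValueError("duration must be positive")


@dataclass
class SpikeData:
    """Spike events as parallel (cell id, time ms) arrays, time-ordered."""

    cell_ids: np.ndarray
    times: np.ndarray
    n_cells: int
    duration: float

    def times_of(self, cell_id: int) -> np.ndarray:
        return self.times[self.cell_ids == cell_id]

    def trains(self, cell_subset: Sequence[int]) -> list[np.ndarray]:
        return [self.times_of(c) for c in cell_subset]

    def count(self, cell_subset=None, t_start=None, t_stop=None) -> int:
        m = np.ones(len(self.times), dtype=bool)
        if cell_subset is not None:
            m &= np.isin(self.cell_ids, cell_subset)
        if t_start is not None:
            m &= self.times >= t_start
        if t_stop is not None:
            m &= self.times < t_stop
        return int(np.count_nonzero(m))

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({"cell_id": self.cell_ids, "t_ms": self.times})

    def save_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


@dataclass
class TraceData:
    """Uniformly sampled per-(cell, compartment, variable) series."""

    dt_sample: float
    series: dict  # (cell_id, label, var) -> np.ndarray

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.series.values()))) if self.series else 0

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.dt_sample

    def get(self, cell_id: int, label: str = "soma", var: str = "V") -> np.ndarray:
        try:
            return self.series[(cell_id, label, var)]
        except KeyError:
            raise KeyError(
                f"no recorded trace for cell {cell_id}, {label}, {var}"
            ) from None

    def cells(self) -> list[int]:
        return sorted({k[0] for k in self.series})

    def save_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as fh:
            fh.attrs["dt_sample_ms"] = self.dt_sample
            for (cell, label, var), arr in self.series.items():
                fh.create_dataset(f"traces/{cell}/{label}/{var}", data=arr)


@dataclass
class SimulationResult:
    spikes: SpikeData
    traces: TraceData
    #: final dynamical state (voltages, gates, calcium, synaptic
    #: aggregates); feed back via ``SimulationConfig.init_state`` /
    #: ``simulate(..., init_state=...)`` to continue a run
    final_state: dict | None = None


# ---------------------------------------------------------------------------
# stimuli
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CurrentInjection:
    cell_id: int
    amplitude_nA: float
    t_start: float
    t_stop: float


def inject_current(
    cell_id: int, amplitude_nA: float, window: tuple[float, float]
) -> CurrentInjection:
    """Schedule a somatic current injection (nA) over ``window`` (ms)."""
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("injection window must have positive length")
    return CurrentInjection(int(cell_id), float(amplitude_nA), float(t0), float(t1))


@dataclass(frozen=True)
class PatternStimulus:
    """Layer-4 Poisson drive to one pattern's minicolumns in a subset of
    hypercolumns (the partial-cue protocol stimulates 5 of 9)."""

    pattern_id: int
    hypercolumns: tuple[int, ...]
    onset: float
    duration: float
    rate: float  # s^-1 per layer-4 cell


def stimulate_pattern(
    network: Network,
    pattern_id: int,
    hypercolumn_subset: Sequence[int] | None = None,
    onset: float = 0.0,
    duration: float = 300.0,
    rate: float | None = None,
) -> PatternStimulus:
    spec = network.spec
    if not (0 <= pattern_id < spec.n_patterns):
        raise ValueError(f"pattern {pattern_id} does not exist")
    if hypercolumn_subset is None:
        hypercolumn_subset = range(spec.n_hypercolumns)
    subset = tuple(int(h) for h in hypercolumn_subset)
    if len(subset) == 0:
        raise ValueError("hypercolumn subset must be non-empty")
    if any(h < 0 or h >= spec.n_hypercolumns for h in subset):
        raise ValueError("hypercolumn subset out of range")
    return PatternStimulus(
        pattern_id=int(pattern_id),
        hypercolumns=subset,
        onset=float(onset),
        duration=float(duration),
        rate=float(rate if rate is not None else spec.layer4.rate),
    )


# ---------------------------------------------------------------------------
# compilation: specs -> flat arrays
# ---------------------------------------------------------------------------

class _Compiled:
    """Flat-array form of a set of cells plus receptor edges and sources."""

    def __init__(self, neuron_specs: list[NeuronSpec]):
        n_cells = len(neuron_specs)
        offsets = np.zeros(n_cells + 1, dtype=np.int64)
        for i, spec in enumerate(neuron_specs):
            offsets[i + 1] = offsets[i] + len(spec.compartments)
        nC = int(offsets[-1])

        c_m = np.empty(nC)
        g_leak = np.empty(nC)
        E_leak = np.empty(nC)
        g_ext = np.zeros(nC)
        E_ex = np.zeros(nC)
        gNa = np.zeros(nC)
        gK = np.zeros(nC)
        gCa = np.zeros(nC)
        gKCa = np.zeros(nC)
        ca_alpha = np.zeros(nC)
        ca_tau = np.full(nC, 300.0)
        nmda_ca = np.zeros(nC)
        E_na = np.full(nC, 50.0)
        E_k = np.full(nC, -90.0)
        E_ca = np.full(nC, 150.0)
        soma_idx = np.empty(n_cells, dtype=np.int64)
        comp_cell = np.empty(nC, dtype=np.int64)
        label_of_comp: list[str] = []
        comp_of: list[dict[str, int]] = []

        rows, cols, vals = [], [], []
        for i, spec in enumerate(neuron_specs):
            base = int(offsets[i])
            idx = {c.label: base + j for j, c in enumerate(spec.compartments)}
            comp_of.append(idx)
            ch = spec.channels
            for j, comp in enumerate(spec.compartments):
                k = base + j
                comp_cell[k] = i
                label_of_comp.append(comp.label)
                c_m[k] = comp.c_m
                g_leak[k] = comp.g_m
                E_leak[k] = comp.E_leak
                g_ext[k] = comp.g_ext
                E_ex[k] = comp.E_ex
                gNa[k] = ch.g_na.get(comp.label, 0.0)
                gK[k] = ch.g_k.get(comp.label, 0.0)
                gCa[k] = ch.g_ca.get(comp.label, 0.0)
                gKCa[k] = ch.g_kca.get(comp.label, 0.0)
                ca_alpha[k] = ch.ca_alpha
                ca_tau[k] = ch.ca_tau
                nmda_ca[k] = ch.nmda_ca_scale
                E_na[k] = ch.E_na
                E_k[k] = ch.E_k
                E_ca[k] = ch.E_ca
                if comp.label == "soma":
                    soma_idx[i] = k
                for nbr, g in comp.g_core_neighbors.items():
                    rows.append(k)
                    cols.append(idx[nbr])
                    vals.append(g)

        W = sp.csr_matrix(
            (np.asarray(vals), (np.asarray(rows), np.asarray(cols))),
            shape=(nC, nC),
        )
        g_core_sum = np.asarray(W.sum(axis=1)).ravel()

        self.n_cells = n_cells
        self.nC = nC
        self.offsets = offsets
        self.c_m = c_m
        self.g_leak = g_leak
        self.E_leak = E_leak
        self.gNa, self.gK, self.gCa, self.gKCa = gNa, gK, gCa, gKCa
        self.ca_alpha, self.ca_tau, self.nmda_ca = ca_alpha, ca_tau, nmda_ca
        self.E_na, self.E_k, self.E_ca = E_na, E_k, E_ca
        self.soma_idx = soma_idx
        self.comp_cell = comp_cell
        self.label_of_comp = label_of_comp
        self.comp_of = comp_of
        self.W = W
        self.B_const = g_leak + g_ext + g_core_sum
        self.A_const = g_leak * E_leak + g_ext * E_ex
        # receptor edges (filled by attach_edges)
        self.edge_post = np.zeros(0, dtype=np.int64)
        self.edge_g = np.zeros(0)
        self.edge_kind = np.zeros(0, dtype=np.int8)
        self.edge_sat = np.zeros(0, dtype=bool)
        self.edge_dticks = np.zeros(0, dtype=np.int64)
        self.out_groups: list[list[tuple[int, np.ndarray]]] = [
            [] for _ in range(n_cells)
        ]
        self.n_sources = 0
        self.src_out_groups: list[list[tuple[int, np.ndarray]]] = []
        # noise
        self.noise_comp = np.zeros(0, dtype=np.int64)
        self.noise_rate = np.zeros(0)
        self.noise_g = 0.0
        # receptor parameters
        self.tau = {"ampa": 6.0, "nmda": 150.0, "gaba": 6.0}
        self.E_syn = {"ampa": 0.0, "nmda": 0.0, "gaba": -85.0}

    # -- compartment lookup -------------------------------------------
    def comp_index(self, cell_id: int, label: str) -> int:
        idx = self.comp_of[cell_id]
        if label not in idx:
            # interneurons: any dendritic target maps to their dendrite
            if label in ("apical1", "apical2", "apical3") and "basal" in idx:
                return idx["basal"]
            raise KeyError(f"cell {cell_id} has no compartment {label!r}")
        return idx[label]

    def resolve_target(self, cell_ids, target_codes) -> np.ndarray:
        labels = {v: k for k, v in TARGET_CODE.items()}
        out = np.empty(len(cell_ids), dtype=np.int64)
        for i, (c, tc) in enumerate(zip(cell_ids, target_codes)):
            out[i] = self.comp_index(int(c), labels[int(tc)])
        return out

    # -- wiring --------------------------------------------------------
    def attach_edges(
        self,
        pre_ids: np.ndarray,
        post_comp: np.ndarray,
        g_peak: np.ndarray,
        kind: np.ndarray,
        saturating: np.ndarray,
        delay_ms: np.ndarray,
        dt: float,
        n_sources: int = 0,
    ) -> None:
        """Install receptor edges.  ``pre_ids`` may exceed the cell count:
        those index external spike sources (layer-4 cells)."""
        order = np.argsort(pre_ids, kind="stable")
        self.edge_post = np.asarray(post_comp)[order]
        self.edge_g = np.asarray(g_peak, float)[order]
        self.edge_kind = np.asarray(kind, np.int8)[order]
        self.edge_sat = np.asarray(saturating, bool)[order]
        dticks = np.maximum(1, np.rint(np.asarray(delay_ms)[order] / dt)).astype(
            np.int64
        )
        self.edge_dticks = dticks
        pre_sorted = np.asarray(pre_ids)[order]
        self.n_sources = n_sources
        self.out_groups = [[] for _ in range(self.n_cells)]
        self.src_out_groups = [[] for _ in range(n_sources)]
        if len(pre_sorted) == 0:
            return
        starts = np.searchsorted(
            pre_sorted, np.arange(self.n_cells + n_sources + 1)
        )
        for c in range(self.n_cells + n_sources):
            lo, hi = starts[c], starts[c + 1]
            if lo == hi:
                continue
            eidx = np.arange(lo, hi)
            sub = dticks[lo:hi]
            groups = []
            for dt_tick in np.unique(sub):
                groups.append((int(dt_tick), eidx[sub == dt_tick]))
            if c < self.n_cells:
                self.out_groups[c] = groups
            else:
                self.src_out_groups[c - self.n_cells] = groups

    def attach_noise(self, comp_idx, rates, g_peak) -> None:
        self.noise_comp = np.asarray(comp_idx, dtype=np.int64)
        self.noise_rate = np.asarray(rates, float)
        self.noise_g = float(g_peak)


def _compile_network(network: Network, dt: float) -> _Compiled:
    spec = network.spec
    type_names = {0: "pyramidal", 1: "basket", 2: "RSNP"}
    specs = [
        build_neuron(type_names[int(tc)], float(s))
        for tc, s in zip(network.geometry.cell_type_code, network.size_factors)
    ]
    model = _Compiled(specs)
    sp_syn = spec.synapse
    model.tau = {
        "ampa": sp_syn.tau_ampa, "nmda": sp_syn.tau_nmda, "gaba": sp_syn.tau_gaba
    }
    model.E_syn = {"ampa": sp_syn.e_ampa, "nmda": 0.0, "gaba": sp_syn.e_gaba}

    # expand connection rows (+ layer-4 rows) into receptor edges
    tables = [network.connectivity, network.layer4.edges]
    pre_l, comp_l, g_l, kind_l, sat_l, delay_l = [], [], [], [], [], []
    for tbl in tables:
        if len(tbl) == 0:
            continue
        post_comp = model.resolve_target(tbl.post, tbl.target)
        for kname, g_arr, sat in (
            ("ampa", tbl.g_ampa, sp_syn.ampa_saturating),
            ("nmda", tbl.g_nmda, sp_syn.nmda_saturating),
            ("gaba", tbl.g_gaba, False),
        ):
            m = g_arr > 0
            if not np.any(m):
                continue
            pre_l.append(tbl.pre[m])
            comp_l.append(post_comp[m])
            g_l.append(g_arr[m])
            kind_l.append(np.full(m.sum(), _KIND_IDX[kname], dtype=np.int8))
            sat_l.append(np.full(m.sum(), sat, dtype=bool))
            delay_l.append(tbl.delay_ms[m])
    if pre_l:
        model.attach_edges(
            np.concatenate(pre_l),
            np.concatenate(comp_l),
            np.concatenate(g_l),
            np.concatenate(kind_l),
            np.concatenate(sat_l),
            np.concatenate(delay_l),
            dt=dt,
            n_sources=network.layer4.n_cells,
        )
    else:
        model.attach_edges(
            np.zeros(0, np.int64), np.zeros(0, np.int64), np.zeros(0),
            np.zeros(0, np.int8), np.zeros(0, bool), np.zeros(0), dt=dt,
            n_sources=network.layer4.n_cells,
        )

    if len(network.noise):
        comp_idx = model.resolve_target(network.noise.cell_ids, network.noise.target)
        model.attach_noise(comp_idx, network.noise.rate, network.noise.g_peak)

    # tonic somatic inhibition on pyramidal cells (constant conductance)
    g_tonic = sp_syn.pyr_tonic_gaba
    if g_tonic > 0:
        pyr_soma = model.soma_idx[network.geometry.cells_of_type("pyramidal")]
        model.B_const[pyr_soma] += g_tonic
        model.A_const[pyr_soma] += g_tonic * sp_syn.e_gaba
    return model


# ---------------------------------------------------------------------------
# the integration loop
# ---------------------------------------------------------------------------

def _run(
    model: _Compiled,
    config: SimulationConfig,
    injections: Sequence[CurrentInjection] = (),
    source_rate_schedule=None,
    noise_rng: np.random.Generator | None = None,
    stim_rng: np.random.Generator | None = None,
    init_state: dict | None = None,
) -> SimulationResult:
    """Advance the compiled model and return spikes + traces.

    ``source_rate_schedule``: callable tick -> per-source Poisson rate
    array (s^-1) for the external spike sources, or None when there are no
    sources to drive.
    """
    dt = config.dt
    n_steps = int(round(config.duration / dt))
    nC = model.nC

    if init_state is not None:
        V = init_state["V"].copy()
        m, h = init_state["m"].copy(), init_state["h"].copy()
        n_gate, s_gate = init_state["n"].copy(), init_state["s"].copy()
        ca = init_state["ca"].copy()
        G = init_state["G"].copy()
    else:
        V = model.E_leak.copy()
        if config.v_init_jitter > 0:
            jit_rng = (
                noise_rng if noise_rng is not None else np.random.default_rng(0)
            )
            V = V + jit_rng.uniform(
                -config.v_init_jitter, config.v_init_jitter, nC
            )
        g0 = _cells.gate_steady_state(V)
        m, h, n_gate, s_gate = (
            np.asarray(g0[k], float).copy() for k in "mhns"
        )
        ca = np.full(nC, float(config.ca_init))
        G = np.zeros((3, nC))  # ampa, nmda, gaba aggregates

    decay = np.array([np.exp(-dt / model.tau[k]) for k in _KINDS])
    tau_arr = np.array([model.tau[k] for k in _KINDS])
    E_ampa, E_gaba = model.E_syn["ampa"], model.E_syn["gaba"]

    # saturating-edge lazy state
    sat_ids = np.flatnonzero(model.edge_sat)
    e_g_last = np.zeros(len(model.edge_post))
    e_t_last = np.full(len(model.edge_post), -1e18)

    # injections -> (comp, pA, tick0, tick1)
    inj_compiled = []
    for inj in injections:
        if inj.cell_id < 0 or inj.cell_id >= model.n_cells:
            raise KeyError(f"unknown cell {inj.cell_id}")
        if inj.t_stop > config.duration + 1e-9:
            raise ValueError("injection window extends beyond the run")
        inj_compiled.append(
            (
                int(model.soma_idx[inj.cell_id]),
                inj.amplitude_nA * 1000.0,
                int(round(inj.t_start / dt)),
                int(round(inj.t_stop / dt)),
            )
        )

    # ring buffer for delayed deliveries (+2: network spikes are timestamped
    # at the end of their detection step, so their events land one tick on)
    max_dtick = int(model.edge_dticks.max()) if len(model.edge_dticks) else 1
    L = max_dtick + 2
    buckets: list[list[np.ndarray]] = [[] for _ in range(L)]

    # recording setup
    rec_cells = list(config.record_cells)
    rec_comp: list[int] = []
    rec_keys: list[tuple[int, str, str]] = []
    for cid in rec_cells:
        if cid < 0 or cid >= model.n_cells:
            raise KeyError(f"cannot record unknown cell {cid}")
        for k in range(model.offsets[cid], model.offsets[cid + 1]):
            rec_comp.append(int(k))
            rec_keys.append((cid, model.label_of_comp[k], "V"))
    rec_comp_arr = np.asarray(rec_comp, dtype=np.int64)
    sample_every = max(1, int(round(config.sample_interval / dt)))
    n_samples = n_steps // sample_every + 1
    v_rec = np.empty((n_samples, len(rec_comp_arr)))
    g_rec = np.empty((3, n_samples, len(rec_comp_arr)))
    sample_i = 0

    noise_p = -np.expm1(-model.noise_rate * 1e-3 * dt) if len(model.noise_comp) else None

    spike_cells: list[np.ndarray] = []
    spike_times: list[np.ndarray] = []
    lockout_until = np.full(model.n_cells, -np.inf)
    vs_prev = V[model.soma_idx].copy()
    thr = config.spike_threshold

    for step in range(n_steps):
        t = step * dt

        # --- deliver due synaptic events -----------------------------
        slot = buckets[step % L]
        if slot:
            for eidx in slot:
                sat = model.edge_sat[eidx]
                if np.any(sat):
                    ei = eidx[sat]
                    gd = e_g_last[ei] * np.exp(
                        -(t - e_t_last[ei]) / tau_arr[model.edge_kind[ei]]
                    )
                    delta = model.edge_g[ei] - gd
                    np.add.at(
                        G, (model.edge_kind[ei], model.edge_post[ei]), delta
                    )
                    e_g_last[ei] = model.edge_g[ei]
                    e_t_last[ei] = t
                if np.any(~sat):
                    ei = eidx[~sat]
                    np.add.at(
                        G,
                        (model.edge_kind[ei], model.edge_post[ei]),
                        model.edge_g[ei],
                    )
            slot.clear()

        # --- noise events --------------------------------------------
        if noise_p is not None:
            p_eff = noise_p
            if config.noise_ramp_ms > 0 and t < config.noise_ramp_ms:
                p_eff = noise_p * (t / config.noise_ramp_ms)
            hits = noise_rng.random(len(noise_p)) < p_eff
            if np.any(hits):
                np.add.at(G[0], model.noise_comp[hits], model.noise_g)

        # --- external source (layer-4) spikes ------------------------
        if source_rate_schedule is not None:
            rates = source_rate_schedule(step)
            if rates is not None:
                p = rates * (1e-3 * dt)
                fired_src = np.flatnonzero(stim_rng.random(len(p)) < p)
                if len(fired_src):
                    spike_cells.append(model.n_cells + fired_src)
                    spike_times.append(np.full(len(fired_src), t))
                    for s_id in fired_src:
                        for dt_tick, eidx in model.src_out_groups[s_id]:
                            buckets[(step + dt_tick) % L].append(eidx)

        # --- record ---------------------------------------------------
        if step % sample_every == 0:
            v_rec[sample_i] = V[rec_comp_arr]
            g_rec[:, sample_i, :] = G[:, rec_comp_arr]
            sample_i += 1

        # --- synaptic and channel conductances ------------------------
        bg = nmda_gate(V)
        g_nmda_eff = G[1] * bg
        gna_eff = model.gNa * (m * m * m) * h
        gk_eff = model.gK * (n_gate ** 2) ** 2
        gca_eff = model.gCa * s_gate * s_gate
        gkca_eff = model.gKCa * ca

        B = (
            model.B_const
            + G[0]
            + g_nmda_eff
            + G[2]
            + gna_eff
            + gk_eff
            + gca_eff
            + gkca_eff
        )
        A = (
            model.A_const
            + model.W @ V
            + G[0] * E_ampa
            + G[2] * E_gaba
            + gna_eff * model.E_na
            + (gk_eff + gkca_eff) * model.E_k
            + gca_eff * model.E_ca
        )
        for comp, amp, t0, t1 in inj_compiled:
            if t0 <= step < t1:
                A[comp] += amp

        # --- integrate V (exponential Euler with a midpoint corrector
        # on the axial coupling term, second order for the cable part) ---
        E_step = np.exp(-dt * B / (1000.0 * model.c_m))
        Vinf = A / B
        V_pred = Vinf + (V - Vinf) * E_step
        for _ in range(2):  # fixed-point iterations on the midpoint coupling
            A_corr = A + model.W @ ((V_pred - V) * 0.5)
            Vinf = A_corr / B
            V_pred = Vinf + (V - Vinf) * E_step
        V = V_pred

        # --- gates -----------------------------------------------------
        am, bm = _cells.na_m_rates(V)
        ah, bh = _cells.na_h_rates(V)
        an, bn = _cells.k_n_rates(V)
        for gate, a_r, b_r in ((m, am, bm), (h, ah, bh), (n_gate, an, bn)):
            tau_g = 1.0 / (a_r + b_r)
            inf_g = a_r * tau_g
            gate += (inf_g - gate) * -np.expm1(-dt / tau_g)
        s_gate += (_cells.ca_s_inf(V) - s_gate) * -np.expm1(-dt / _cells.CA_S_TAU)

        # --- calcium pool ---------------------------------------------
        i_ca = gca_eff * (model.E_ca - V)
        i_nmda = g_nmda_eff * (0.0 - V)
        influx = model.ca_alpha * (
            np.maximum(i_ca, 0.0) + model.nmda_ca * np.maximum(i_nmda, 0.0)
        )
        ca = ca * np.exp(-dt / model.ca_tau) + influx * dt

        # --- spike detection and event scheduling ---------------------
        vs = V[model.soma_idx]
        fired = (vs > thr) & (vs_prev <= thr) & (t >= lockout_until)
        if np.any(fired):
            ids = np.flatnonzero(fired)
            lockout_until[ids] = t + config.lockout
            spike_cells.append(ids.copy())
            spike_times.append(np.full(len(ids), t + dt))
            for c in ids:
                for dt_tick, eidx in model.out_groups[c]:
                    # spike time is t + dt; deliver at spike time + delay
                    buckets[(step + 1 + dt_tick) % L].append(eidx)
        vs_prev = vs

        # --- decay synaptic aggregates --------------------------------
        G *= decay[:, None]

        if step % config.check_every == 0 and not np.all(np.isfinite(V)):
            raise IntegrationError(t)

    if not np.all(np.isfinite(V)):
        raise IntegrationError(n_steps * dt)

    if spike_cells:
        sc = np.concatenate(spike_cells)
        st = np.concatenate(spike_times)
        order = np.argsort(st, kind="stable")
        sc, st = sc[order], st[order]
    else:
        sc = np.zeros(0, dtype=np.int64)
        st = np.zeros(0)
    spikes = SpikeData(
        cell_ids=sc, times=st, n_cells=model.n_cells, duration=config.duration
    )

    series = {}
    for j, key in enumerate(rec_keys):
        series[key] = v_rec[:sample_i, j].copy()
        cid, label, _ = key
        for ki, kname in enumerate(_KINDS):
            series[(cid, label, f"g_{kname}")] = g_rec[ki, :sample_i, j].copy()
    traces = TraceData(dt_sample=sample_every * dt, series=series)
    final_state = {
        "V": V, "m": m, "h": h, "n": n_gate, "s": s_gate, "ca": ca, "G": G,
    }
    return SimulationResult(spikes=spikes, traces=traces,
                            final_state=final_state)


# ---------------------------------------------------------------------------
# public entry points
# ---------------------------------------------------------------------------

def simulate(
    network: Network,
    stimuli: Sequence = (),
    config: SimulationConfig | None = None,
    init_state: dict | None = None,
) -> SimulationResult:
    """Simulate a built network under a stimulus schedule.

    ``stimuli`` may mix :class:`CurrentInjection` and
    :class:`PatternStimulus` entries.  Deterministic given the network's
    seeds and the configuration.
    """
    if config is None:
        config = SimulationConfig(duration=1000.0)
    model = _compile_network(network, config.dt)

    injections = [s for s in stimuli if isinstance(s, CurrentInjection)]
    pattern_stims = [s for s in stimuli if isinstance(s, PatternStimulus)]

    spec = network.spec
    l4 = network.layer4
    schedule = None
    if pattern_stims and l4.n_cells:
        windows = []
        for ps in pattern_stims:
            mcs = network.patterns.minicolumns(ps.pattern_id)
            sel = mcs[np.isin(network.geometry.mc_hc[mcs], ps.hypercolumns)]
            src_mask = np.isin(l4.mc_of_cell, sel)
            windows.append(
                (
                    int(round(ps.onset / config.dt)),
                    int(round((ps.onset + ps.duration) / config.dt)),
                    src_mask,
                    ps.rate,
                )
            )

        def schedule(step):
            rates = None
            for tick0, tick1, mask, rate in windows:
                if tick0 <= step < tick1:
                    if rates is None:
                        rates = np.zeros(l4.n_cells)
                    rates[mask] += rate
            return rates

    noise_rng = substream(spec.seeds["noise"], "noise")
    stim_rng = substream(spec.seeds["stimulus"], "stimulus")
    return _run(
        model,
        config,
        injections=injections,
        source_rate_schedule=schedule,
        noise_rng=noise_rng,
        stim_rng=stim_rng,
        init_state=init_state,
    )


def simulate_cells(
    neuron_specs: Sequence[NeuronSpec],
    duration: float,
    dt: float = 0.05,
    i_inj_pA: Sequence[float] | float = 0.0,
    noise_rate: float = 0.0,
    noise_g: float = 0.08,
    noise_seed: int = 0,
    record: bool = True,
    sample_interval: float = 1.0,
) -> SimulationResult:
    """Simulate unconnected cells (constant somatic current and/or the
    standard background noise source onto apical2+basal).

    The workhorse for single-cell characterization and the noise-only
    calibration runs; all cells share the run but interact with nothing.
    """
    specs = list(neuron_specs)
    model = _Compiled(specs)
    model.attach_edges(
        np.zeros(0, np.int64), np.zeros(0, np.int64), np.zeros(0),
        np.zeros(0, np.int8), np.zeros(0, bool), np.zeros(0), dt=dt,
    )
    if noise_rate > 0:
        comp_idx, rates = [], []
        for cid, spec in enumerate(specs):
            targets = (
                ("apical2", "basal") if spec.cell_type == "pyramidal"
                else ("basal",)
            )
            for lbl in targets:
                comp_idx.append(model.comp_index(cid, lbl))
                rates.append(noise_rate / len(targets))
        model.attach_noise(comp_idx, rates, noise_g)

    config = SimulationConfig(
        duration=duration,
        dt=dt,
        sample_interval=sample_interval,
        record_cells=range(len(specs)) if record else (),
    )
    amps = np.broadcast_to(np.asarray(i_inj_pA, float), (len(specs),))
    injections = [
        CurrentInjection(c, a / 1000.0, 0.0, duration)
        for c, a in enumerate(amps)
        if a != 0.0
    ]
    return _run(
        model,
        config,
        injections=injections,
        noise_rng=substream(noise_seed, "noise"),
    )


def simulate_single_cell(
    spec: NeuronSpec,
    duration: float,
    dt: float = 0.05,
    i_inj: float = 0.0,
    noise_rate: float = 0.0,
    noise_seed: int = 0,
):
    """One cell; returns (spike times array, TraceData).  ``i_inj`` in pA."""
    res = simulate_cells(
        [spec], duration=duration, dt=dt, i_inj_pA=i_inj,
        noise_rate=noise_rate, noise_seed=noise_seed,
    )
    return res.spikes.times_of(0), res.traces
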