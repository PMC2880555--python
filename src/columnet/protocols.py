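"""Experiment protocols: bistability testing and range scans, the
modularity scan, current-balance measurement, ground-state f-I curves and
NMDA-block runs.

The bistability protocol has three phases: a ground-stability phase (no
stimulus; no memory pattern may activate spontaneously), a 300 ms partial
cue (layer-4 drive to one pattern's minicolumns in a subset of the
hypercolumns, 5 of 9 at full scale), and a persistence phase (the
completed pattern must remain active, with the cue removed, for 3 s —
longer than any adaptive mechanism in the network).  A parameter setting
is *bistable* when the protocol passes for every tested seed.

"Ground stable" is operationalized as: no pattern's pyramidal rate exceeds
5x the all-pattern average for more than 200 ms.  "Pattern completed":
the uncued pattern minicolumns reach at least 50% of the cued minicolumns'
rate within 500 ms of cue offset.  "Persisted": in every 500 ms bin of the
persistence phase the foreground rate stays above an absolute floor and
above a multiple of the background rate.

Current balance is measured on a cell injected with a hyperpolarizing
somatic current so that it does not spike; the basket (GABA_A) conductance
g_FS is then the only unknown in the somatic flux balance

    c dV/dt = I_inj + g_m (E_leak - V) + sum g_core (V_dend - V)
              + g_FS (E_GABA - V) + I_exc_soma

and is solved per time step from the recorded voltages.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .analysis import oscillation_frequency, synthetic_lfp
from .cells import build_neuron
from .engine import (
    CurrentInjection,
    SimulationConfig,
    SimulationResult,
    inject_current,
    simulate,
    stimulate_pattern,
)
from .network import Network, NetworkSpec, build_network

__all__ = [
    "BistabilityCriteria",
    "BistabilityTrial",
    "BistabilityResult",
    "BalanceResult",
    "pattern_rate_matrix",
    "test_bistability",
    "scan_bistable_range",
    "modularity_scan",
    "measure_current_balance",
    "solve_somatic_balance",
    "fi_in_ground_state",
    "nmda_block_run",
]


# ---------------------------------------------------------------------------
# state classification
# ---------------------------------------------------------------------------

@dataclass
class BistabilityCriteria:
    """Thresholds operationalizing ground/active state stability."""

    ground_ratio: float = 5.0        # pattern rate vs all-pattern average
    ground_max_excursion_ms: float = 200.0
    completion_fraction: float = 0.5  # uncued vs cued minicolumn rate
    completion_window_ms: float = 500.0
    persist_min_rate: float = 2.0     # s^-1 absolute foreground floor
    persist_ratio: float = 2.0        # foreground vs background rate
    persist_bin_ms: float = 500.0
    classify_bin_ms: float = 50.0


def pattern_rate_matrix(
    network: Network, spikes, bin_ms: float, window: tuple[float, float]
):
    """Per-pattern pyramidal population rate (s^-1): (edges, n_pat x n_bins)."""
    spec = network.spec
    t0, t1 = window
    edges = np.arange(t0, t1 + 1e-9, bin_ms)
    n_bins = len(edges) - 1
    rates = np.zeros((spec.n_patterns, n_bins))
    pyr_mask = network.geometry.cell_type_code[
        np.minimum(spikes.cell_ids, network.n_cells - 1)
    ] == 0
    is_net = spikes.cell_ids < network.n_cells
    sel = is_net & pyr_mask
    cid = spikes.cell_ids[sel]
    t = spikes.times[sel]
    pat = network.patterns.mc_pattern[network.geometry.cell_mc[cid]]
    n_cells_per_pattern = spec.n_hypercolumns * spec.n_pyr_per_mc
    for p in range(spec.n_patterns):
        tp = t[pat == p]
        counts, _ = np.histogram(tp, bins=edges)
        rates[p] = counts / (bin_ms * 1e-3) / n_cells_per_pattern
    return edges, rates


def _mc_pyr_rate(network, spikes, mcs, window):
    t0, t1 = window
    cells = np.concatenate([network.pyr_cells_of_mc(int(m)) for m in mcs])
    n = spikes.count(cell_subset=cells, t_start=t0, t_stop=t1)
    return n / ((t1 - t0) * 1e-3) / len(cells)


# ---------------------------------------------------------------------------
# bistability protocol
# ---------------------------------------------------------------------------

@dataclass
class BistabilityTrial:
    gain: float
    seed: int
    passed: bool
    ground_stable: bool
    completed: bool
    persisted: bool
    ground_rate: float            # all-pyramidal rate in phase 1 (s^-1)
    foreground_rate: float | None  # persistence-phase foreground rate
    background_rate: float | None
    simulation: SimulationResult | None = None
    network: Network | None = None


def _spec_with(spec: NetworkSpec, gain: float, seed: int) -> NetworkSpec:
    seeds = {k: (int(v) + seed * 7919) % 2**31 for k, v in spec.seeds.items()}
    return replace(spec, excitation_gain=float(gain), seeds=seeds)


def test_bistability(
    spec: NetworkSpec,
    gain: float,
    seed: int = 0,
    phases_ms: tuple[float, float, float] = (3000.0, 300.0, 3000.0),
    pattern_id: int = 0,
    cued_hypercolumns: Sequence[int] | None = None,
    criteria: BistabilityCriteria | None = None,
    dt: float = 0.05,
    keep_simulation: bool = False,
    record_foreground: int = 0,
    noise_ramp_ms: float = 0.0,
) -> BistabilityTrial:
    """Run the three-phase protocol at one recurrent-excitation gain.

    PASS requires a stable ground state, completion of the partially cued
    pattern and persistence of the completed pattern for the full third
    phase.  A simulation divergence raises; it is not a FAIL.
    """
    if gain < 0:
        raise ValueError("gain must be non-negative")
    crit = criteria or BistabilityCriteria()
    spec = _spec_with(spec, gain, seed)
    network = build_network(spec)
    t_ground, t_cue, t_persist = phases_ms
    duration = t_ground + t_cue + t_persist

    if cued_hypercolumns is None:
        n_cue = max(1, int(round(spec.n_hypercolumns * 5.0 / 9.0)))
        cued_hypercolumns = range(n_cue)
    cue = stimulate_pattern(
        network, pattern_id, cued_hypercolumns, onset=t_ground, duration=t_cue
    )
    rec: list[int] = []
    if record_foreground:
        fg_mcs = network.patterns.minicolumns(pattern_id)
        fg_all = np.concatenate(
            [network.pyr_cells_of_mc(int(m)) for m in fg_mcs]
        )
        rec = fg_all[:record_foreground].tolist()
    config = SimulationConfig(
        duration=duration, dt=dt, record_cells=rec, v_init_jitter=2.0,
        noise_ramp_ms=noise_ramp_ms,
    )
    result = simulate(network, [cue], config)
    spikes = result.spikes

    # phase 1: ground-state stability
    bin_ms = crit.classify_bin_ms
    edges, rates = pattern_rate_matrix(network, spikes, bin_ms, (0.0, t_ground))
    avg = rates.mean(axis=0, keepdims=True)
    hot = rates > crit.ground_ratio * np.maximum(avg, 0.5)
    max_run = 0
    for p in range(rates.shape[0]):
        run = best = 0
        for flag in hot[p]:
            run = run + 1 if flag else 0
            best = max(best, run)
        max_run = max(max_run, best)
    ground_stable = max_run * bin_ms <= crit.ground_max_excursion_ms
    pyr_cells = network.geometry.cells_of_type("pyramidal")
    ground_rate = (
        spikes.count(cell_subset=pyr_cells, t_start=0.0, t_stop=t_ground)
        / (t_ground * 1e-3) / len(pyr_cells)
    )

    # phase 2/3: completion within the window after cue offset
    cue_off = t_ground + t_cue
    pat_mcs = network.patterns.minicolumns(pattern_id)
    hc_of_mc = network.geometry.mc_hc[pat_mcs]
    cued_mcs = pat_mcs[np.isin(hc_of_mc, list(cue.hypercolumns))]
    uncued_mcs = pat_mcs[~np.isin(hc_of_mc, list(cue.hypercolumns))]
    cw = (cue_off, min(cue_off + crit.completion_window_ms, duration))
    cued_rate = _mc_pyr_rate(network, spikes, cued_mcs, cw)
    if len(uncued_mcs):
        uncued_rate = _mc_pyr_rate(network, spikes, uncued_mcs, cw)
        completed = (
            cued_rate > 0
            and uncued_rate >= crit.completion_fraction * cued_rate
            and uncued_rate >= crit.persist_min_rate
        )
    else:  # full cue: completion reduces to activation of the cued cells
        completed = cued_rate >= crit.persist_min_rate
        uncued_rate = cued_rate

    # phase 3: persistence
    fg_cells = np.concatenate([network.pyr_cells_of_mc(int(m)) for m in pat_mcs])
    bg_mask = np.ones(network.n_cells, dtype=bool)
    bg_mask[fg_cells] = False
    bg_cells = np.flatnonzero(
        bg_mask & (network.geometry.cell_type_code == 0)
    )
    persisted = completed
    nb = int(np.ceil(t_persist / crit.persist_bin_ms))
    for b in range(nb):
        w0 = cue_off + b * crit.persist_bin_ms
        w1 = min(w0 + crit.persist_bin_ms, duration)
        fg = _mc_pyr_rate(network, spikes, pat_mcs, (w0, w1))
        bg = (
            spikes.count(cell_subset=bg_cells, t_start=w0, t_stop=w1)
            / ((w1 - w0) * 1e-3) / max(len(bg_cells), 1)
        )
        if fg < crit.persist_min_rate or fg < crit.persist_ratio * max(bg, 1e-9):
            persisted = False
            break
    fg_rate = _mc_pyr_rate(network, spikes, pat_mcs, (cue_off, duration))
    bg_rate = (
        spikes.count(cell_subset=bg_cells, t_start=cue_off, t_stop=duration)
        / (t_persist * 1e-3) / max(len(bg_cells), 1)
    )

    return BistabilityTrial(
        gain=float(gain),
        seed=int(seed),
        passed=bool(ground_stable and completed and persisted),
        ground_stable=bool(ground_stable),
        completed=bool(completed),
        persisted=bool(persisted),
        ground_rate=float(ground_rate),
        foreground_rate=float(fg_rate),
        background_rate=float(bg_rate),
        simulation=result if keep_simulation else None,
        network=network if keep_simulation else None,
    )


# ---------------------------------------------------------------------------
# range scan
# ---------------------------------------------------------------------------

@dataclass
class BistabilityResult:
    """Outcome of a gain-grid scan."""

    lower_boundary: float | None
    upper_boundary: float | None
    bistability_ratio: float | None
    active_state_stability: float | None  # fraction stable at mid-range
    trials: list = field(default_factory=list)  # (gain, seed, passed)

    @property
    def empty(self) -> bool:
        return self.lower_boundary is None


def scan_bistable_range(
    spec: NetworkSpec,
    gain_grid: Sequence[float],
    seeds: Sequence[int] = (0,),
    stability_seeds: Sequence[int] | None = None,
    tester: Callable | None = None,
    **test_kwargs,
) -> BistabilityResult:
    """Scan a monotone gain grid; a gain passes when every seed passes.

    ``tester(spec, gain, seed)`` must return an object with ``passed`` and
    ``persisted`` attributes (dependency injection point: the default is
    :func:`test_bistability`; tests may substitute cheap stand-ins).
    The active-state stability fraction is measured at mid-range over
    ``stability_seeds`` (defaults to ``seeds``) as the fraction of trials
    whose active state persisted the full 3 s.
    """
    grid = np.asarray(list(gain_grid), dtype=float)
    if len(grid) == 0 or np.any(np.diff(grid) <= 0):
        raise ValueError("gain grid must be strictly increasing")
    if tester is None:
        tester = lambda s, g, sd: test_bistability(s, g, sd, **test_kwargs)

    trials = []
    passing = []
    for gain in grid:
        ok = True
        for sd in seeds:
            tr = tester(spec, float(gain), int(sd))
            trials.append((float(gain), int(sd), bool(tr.passed)))
            if not tr.passed:
                ok = False
                break
        if ok:
            passing.append(float(gain))

    if not passing:
        return BistabilityResult(None, None, None, None, trials)

    lower, upper = min(passing), max(passing)
    mid = passing[len(passing) // 2]
    stab_seeds = seeds if stability_seeds is None else stability_seeds
    n_stable = n_tot = 0
    for sd in stab_seeds:
        tr = tester(spec, mid, int(sd))
        n_tot += 1
        n_stable += bool(tr.persisted)
    return BistabilityResult(
        lower_boundary=lower,
        upper_boundary=upper,
        bistability_ratio=upper / lower,
        active_state_stability=n_stable / n_tot if n_tot else None,
        trials=trials,
    )


def modularity_scan(
    cases: Sequence[tuple[int, int]],
    base_spec: NetworkSpec | None = None,
    gain_grid: Sequence[float] = tuple(np.arange(0.5, 1.501, 0.05).round(3)),
    seeds: Sequence[int] = (0,),
    tester: Callable | None = None,
    foreground_tolerance: float = 0.05,
    **scan_kwargs,
) -> list[dict]:
    """Scan bistable ranges across (n_hypercolumns, pyr_per_mc) cases that
    hold the foreground population size approximately constant.

    RSNP cells and basket-basket connections are removed for comparability
    with non-modular models.  Each report row carries the bistable range,
    ratio, stability fraction and, when the tester exposes simulations,
    the foreground rates and oscillation frequencies at the boundaries.
    """
    if base_spec is None:
        base_spec = NetworkSpec()
    sizes = [n_hc * n_pyr for n_hc, n_pyr in cases]
    ref = sizes[0]
    for s in sizes:
        if abs(s - ref) > foreground_tolerance * ref:
            raise ValueError(
                f"foreground sizes differ beyond {foreground_tolerance:.0%}: {sizes}"
            )

    rows = []
    for n_hc, n_pyr in cases:
        spec_case = replace(
            base_spec,
            n_hypercolumns=int(n_hc),
            n_pyr_per_mc=int(n_pyr),
            rsnp_enabled=False,
            basket_basket_enabled=False,
        )
        res = scan_bistable_range(
            spec_case, gain_grid, seeds=seeds, tester=tester, **scan_kwargs
        )
        row = {
            "n_hypercolumns": int(n_hc),
            "pyr_per_mc": int(n_pyr),
            "foreground_size": int(n_hc * n_pyr),
            "lower_boundary": res.lower_boundary,
            "upper_boundary": res.upper_boundary,
            "bistability_ratio": res.bistability_ratio,
            "active_state_stability": res.active_state_stability,
        }
        if not res.empty and tester is None:
            freqs, rates = [], []
            for gain in (res.lower_boundary, res.upper_boundary):
                tr = test_bistability(
                    spec_case, gain, int(seeds[0]), keep_simulation=True,
                    **{k: v for k, v in scan_kwargs.items()
                       if k in ("phases_ms", "dt", "criteria",
                                "cued_hypercolumns", "pattern_id")},
                )
                rates.append(tr.foreground_rate)
                freqs.append(_active_state_frequency(tr))
            row["foreground_rate_lo"], row["foreground_rate_hi"] = rates
            row["freq_lo_hz"], row["freq_hi_hz"] = freqs
        rows.append(row)
    return rows


def _active_state_frequency(trial: BistabilityTrial) -> float | None:
    """Oscillation frequency of the foreground LFP during persistence."""
    if trial.simulation is None or trial.network is None:
        return None
    net = trial.network
    mcs = net.patterns.minicolumns(0)
    cells = np.concatenate([net.pyr_cells_of_mc(int(m)) for m in mcs])
    rec = [c for c in cells if (c, "soma", "V") in trial.simulation.traces.series]
    if not rec:
        return None
    lfp = synthetic_lfp(trial.simulation.traces, rec)
    return oscillation_frequency(lfp)


# ---------------------------------------------------------------------------
# current balance
# ---------------------------------------------------------------------------

@dataclass
class BalanceResult:
    """Somatic current decomposition (pA) with the solved basket-synapse
    conductance g_FS (nS).  ``net = excitatory + inhibitory`` by
    construction; ``residual`` is the flux-balance residual including the
    capacitive term (should be ~0)."""

    t: np.ndarray
    excitatory: np.ndarray
    inhibitory: np.ndarray
    net: np.ndarray
    g_fs: np.ndarray
    i_inj_nA: float
    window_means: dict
    valid: bool
    residual: np.ndarray


def solve_somatic_balance(
    v_soma: np.ndarray,
    v_neighbors: dict,
    g_core: dict,
    g_m: float,
    e_leak: float,
    i_inj_pA: float,
    e_gaba: float = -85.0,
    c_m: float | None = None,
    dt_ms: float = 1.0,
    i_exc_soma: np.ndarray | float = 0.0,
):
    """Solve the somatic flux balance for the basket conductance g_FS.

    All somatic fluxes are known from recorded voltages except the GABA_A
    conductance: setting the flux sum to the capacitive current (zero in
    quasi-steady state) leaves g_FS as the only unknown.  Returns
    (g_fs, I_exc, I_inh, net) arrays in nS/pA.
    """
    v_soma = np.asarray(v_soma, float)
    leak = g_m * (e_leak - v_soma)
    core = np.zeros_like(v_soma)
    for lbl, vn in v_neighbors.items():
        core = core + g_core[lbl] * (np.asarray(vn, float) - v_soma)
    i_cap = (
        1000.0 * c_m * np.gradient(v_soma, dt_ms) if c_m is not None else 0.0
    )
    drive = v_soma - e_gaba
    if np.any(np.abs(drive) < 1e-6):
        raise ZeroDivisionError("soma at the GABA reversal; g_FS unidentifiable")
    g_fs = (i_inj_pA + leak + core + i_exc_soma - i_cap) / drive
    i_inh = g_fs * (e_gaba - v_soma)
    i_exc = core + np.asarray(i_exc_soma) * np.ones_like(v_soma)
    net = i_exc + i_inh
    return g_fs, i_exc, i_inh, net


def measure_current_balance(
    network: Network,
    cell_id: int,
    i_inj_nA: float = -0.2,
    windows: dict | None = None,
    duration: float | None = None,
    stimuli: Sequence = (),
    dt: float = 0.05,
    include_capacitive: bool = True,
) -> BalanceResult:
    """Hyperpolarize a cell, simulate the network, and decompose the
    somatic current into excitatory (dendritic core influx + somatic
    excitatory synapses) and inhibitory (solved basket GABA_A) parts.

    ``windows`` maps state names (e.g. ground/foreground/background) to
    (t0, t1) intervals; per-window mean currents are reported.  The
    measurement is flagged invalid when the cell spikes despite the
    hyperpolarization.
    """
    if windows is None:
        windows = {"all": (0.0, duration or 1000.0)}
    if duration is None:
        duration = max(t1 for _, t1 in windows.values())
    inj = inject_current(cell_id, i_inj_nA, (0.0, duration))
    config = SimulationConfig(
        duration=duration, dt=dt, record_cells=[cell_id], sample_interval=1.0,
        v_init_jitter=2.0,
    )
    result = simulate(network, list(stimuli) + [inj], config)
    traces = result.traces

    tc = int(network.geometry.cell_type_code[cell_id])
    type_name = {0: "pyramidal", 1: "basket", 2: "RSNP"}[tc]
    spec = build_neuron(type_name, float(network.size_factors[cell_id]))
    soma = spec.compartment("soma")

    v_soma = traces.get(cell_id, "soma", "V")
    v_nbr = {
        lbl: traces.get(cell_id, lbl, "V")
        for lbl in soma.g_core_neighbors
    }
    syn = network.spec.synapse
    i_exc_soma = (
        traces.get(cell_id, "soma", "g_ampa") * (syn.e_ampa - v_soma)
        + traces.get(cell_id, "soma", "g_nmda") * (0.0 - v_soma)
    )
    g_fs, i_exc, i_inh, net = solve_somatic_balance(
        v_soma,
        v_nbr,
        dict(soma.g_core_neighbors),
        soma.g_m,
        soma.E_leak,
        i_inj_nA * 1000.0,
        e_gaba=syn.e_gaba,
        c_m=soma.c_m if include_capacitive else None,
        dt_ms=traces.dt_sample,
        i_exc_soma=i_exc_soma,
    )
    # residual of the full balance using the *recorded* GABA conductance
    g_gaba_rec = traces.get(cell_id, "soma", "g_gaba")
    residual = g_fs - g_gaba_rec

    spiked = len(result.spikes.times_of(cell_id)) > 0
    t = traces.t
    means = {}
    for name, (t0, t1) in windows.items():
        m = (t >= t0) & (t < t1)
        means[name] = {
            "excitatory": float(i_exc[m].mean()),
            "inhibitory": float(i_inh[m].mean()),
            "net": float(net[m].mean()),
            "g_fs": float(g_fs[m].mean()),
        }
    return BalanceResult(
        t=t,
        excitatory=i_exc,
        inhibitory=i_inh,
        net=net,
        g_fs=g_fs,
        i_inj_nA=float(i_inj_nA),
        window_means=means,
        valid=not spiked,
        residual=residual,
    )


# ---------------------------------------------------------------------------
# f-I in ground state and NMDA block
# ---------------------------------------------------------------------------

def fi_in_ground_state(
    network: Network,
    cell_ids: Sequence[int],
    current_grid_pA: Sequence[float],
    duration: float = 2000.0,
    settle_ms: float = 500.0,
    dt: float = 0.05,
) -> dict:
    """Firing rate of selected cells vs injected somatic current while the
    network sits in its ground state (one run per current level; rates
    measured after a settling period)."""
    currents = np.asarray(list(current_grid_pA), float)
    rates = {int(c): [] for c in cell_ids}
    for amp in currents:
        injections = [
            inject_current(int(c), amp / 1000.0, (0.0, duration))
            for c in cell_ids
        ]
        config = SimulationConfig(duration=duration, dt=dt, v_init_jitter=2.0)
        res = simulate(network, injections, config)
        for c in cell_ids:
            n = res.spikes.count(
                cell_subset=[int(c)], t_start=settle_ms, t_stop=duration
            )
            rates[int(c)].append(n / ((duration - settle_ms) * 1e-3))
    return {"current_pA": currents, "rate_hz": {c: np.array(r) for c, r in rates.items()}}


def nmda_block_run(
    spec: NetworkSpec,
    ampa_compensation_gain: float,
    gain: float = 1.0,
    seed: int = 0,
    remove_noise: bool = False,
    **test_kwargs,
) -> BistabilityTrial:
    """Bistability protocol with NMDA receptors blocked and recurrent AMPA
    conductances multiplied by a compensation factor (optionally also with
    the background noise removed)."""
    syn = dataclasses.replace(
        spec.synapse,
        pyr_pyr_local_ampa=spec.synapse.pyr_pyr_local_ampa * ampa_compensation_gain,
        pyr_pyr_global_ampa=spec.synapse.pyr_pyr_global_ampa * ampa_compensation_gain,
        pyr_rsnp_ampa=spec.synapse.pyr_rsnp_ampa * ampa_compensation_gain,
    )
    blocked = replace(
        spec,
        nmda_enabled=False,
        synapse=syn,
        noise_enabled=spec.noise_enabled and not remove_noise,
    )
    return test_bistability(blocked, gain=gain, seed=seed, **test_kwargs)
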