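"""Construction of the modular hypercolumn/minicolumn network.

The architecture: ``n_hypercolumns`` modules, each containing
``n_minicolumns_per_hc`` minicolumns of 30 pyramidal cells, one basket cell
and two RSNP interneurons (defaults).  Minicolumns sit on a two-dimensional
square grid with a 1.5 mm side (hypercolumns occupy contiguous blocks);
pyramidal cells of a minicolumn share x, y and are uniquely spread along
500 µm of z; interneurons sit at the minicolumn's z-centre.

Memory patterns are non-overlapping: pattern ``p`` is the ``p``-th
minicolumn of every hypercolumn, giving as many patterns as minicolumns
per hypercolumn.

Projection rules (densities/in-degrees are configuration, defaults from the
standard model):

* local pyr->pyr: 25% pairwise within a minicolumn (AMPA + NMDA, saturating);
* pyr->basket: each pyramidal cell contacts the eight closest basket cells
  of its own hypercolumn (pure AMPA);
* basket->pyr: 70% within the hypercolumn, onto the soma (GABA_A);
* basket->basket: 70% within the hypercolumn (when enabled);
* RSNP->pyr: within the home minicolumn, onto the second apical compartment;
* long-range pyr->pyr: every pyramidal cell receives a fixed number (90) of
  synapses from same-pattern pyramidal cells in other hypercolumns, with
  local:global EPSP magnitudes 3:1;
* long-range pyr->RSNP: RSNP cells receive synapses from distant
  dissimilar-pattern pyramidal cells (disynaptic long-range inhibition).

Excitatory inputs (including background noise) land on the second apical
and basal dendritic compartments of pyramidal cells and on the dendrite of
interneurons; basket output targets somata; RSNP output targets the second
apical compartment.  All edges carry distance-based conduction delays.

Connections are generated reproducibly from the ``connectivity`` seed
substream; no self-edges; at most one connection (bouton) per ordered cell
pair per projection.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._rng import resolve_seeds, substream
from .synapses import conduction_delay

__all__ = [
    "ConnectivityParams",
    "SynapseParams",
    "NoiseParams",
    "Layer4Params",
    "GeometryParams",
    "NetworkSpec",
    "Geometry",
    "PatternSet",
    "ConnectivityTable",
    "Layer4Population",
    "NoiseBindings",
    "Network",
    "layout",
    "build_patterns",
    "build_connectivity",
    "count_cells",
    "count_synapses",
    "expected_synapse_counts",
    "attach_noise",
    "build_layer4",
    "build_network",
    "PROJECTIONS",
    "CELL_TYPE_CODES",
]

CELL_TYPE_CODES = {"pyramidal": 0, "basket": 1, "RSNP": 2}

PROJECTIONS = (
    "pyr_pyr_local",
    "pyr_basket",
    "basket_pyr",
    "basket_basket",
    "rsnp_pyr",
    "pyr_pyr_global",
    "pyr_rsnp_global",
    "l4_pyr",
)
PROJ_CODE = {name: i for i, name in enumerate(PROJECTIONS)}

#: projections whose conductances count as recurrent excitation and are
#: scaled by ``excitation_gain`` (feedback inhibition and feedforward input
#: are deliberately left untouched)
GAIN_SCALED_PROJECTIONS = ("pyr_pyr_local", "pyr_pyr_global", "pyr_rsnp_global")

_TARGET_LABELS = ("soma", "basal", "apical2")
TARGET_CODE = {lbl: i for i, lbl in enumerate(_TARGET_LABELS)}


# ---------------------------------------------------------------------------
# parameter blocks
# ---------------------------------------------------------------------------

@dataclass
class ConnectivityParams:
    local_pyr_pyr_p: float = 0.25
    n_closest_baskets: int = 8
    basket_pyr_p: float = 0.70
    basket_basket_p: float = 0.70
    rsnp_pyr_p: float = 0.70
    lr_pyr_in_degree: int = 90
    rsnp_lr_in_degree: int = 30
    #: if True, each RSNP receives ``rsnp_lr_in_degree`` synapses per
    #: dissimilar pattern instead of in total
    rsnp_lr_per_pattern: bool = False


@dataclass
class SynapseParams:
    """Receptor time constants/reversals and per-projection peak
    conductances (nS).  ``gain_overrides`` multiplies individual projection
    conductances by name (e.g. ``{"basket_pyr": 1.2}``)."""

    tau_ampa: float = 6.0
    tau_nmda: float = 150.0
    tau_gaba: float = 6.0
    e_ampa: float = 0.0
    e_gaba: float = -85.0
    ampa_saturating: bool = True
    nmda_saturating: bool = True
    pyr_pyr_local_ampa: float = 0.8
    pyr_pyr_local_nmda: float = 0.17
    #: local:global EPSP ratio is 3:1 -> global conductances are local / 3
    pyr_pyr_global_ampa: float = 0.8 / 3.0
    pyr_pyr_global_nmda: float = 0.17 / 3.0
    pyr_basket_ampa: float = 0.6
    pyr_rsnp_ampa: float = 0.5
    pyr_rsnp_nmda: float = 0.1
    basket_pyr_gaba: float = 2.5
    basket_basket_gaba: float = 1.0
    rsnp_pyr_gaba: float = 1.5
    l4_pyr_ampa: float = 1.2
    #: tonic somatic GABA_A conductance on pyramidal cells (nS): the
    #: "overall inhibition" level that places the network in its bistable
    #: regime by raising the spontaneous-retrieval threshold
    pyr_tonic_gaba: float = 0.0
    gain_overrides: dict = field(default_factory=dict)

    def projection_g(self, projection: str) -> tuple[float, float, float]:
        """(g_ampa, g_nmda, g_gaba) for one connection of the projection."""
        gain = self.gain_overrides.get(projection, 1.0)
        table = {
            "pyr_pyr_local": (self.pyr_pyr_local_ampa, self.pyr_pyr_local_nmda, 0.0),
            "pyr_pyr_global": (self.pyr_pyr_global_ampa, self.pyr_pyr_global_nmda, 0.0),
            "pyr_basket": (self.pyr_basket_ampa, 0.0, 0.0),
            "pyr_rsnp_global": (self.pyr_rsnp_ampa, self.pyr_rsnp_nmda, 0.0),
            "basket_pyr": (0.0, 0.0, self.basket_pyr_gaba),
            "basket_basket": (0.0, 0.0, self.basket_basket_gaba),
            "rsnp_pyr": (0.0, 0.0, self.rsnp_pyr_gaba),
            "l4_pyr": (self.l4_pyr_ampa, 0.0, 0.0),
        }
        ga, gn, gg = table[projection]
        return ga * gain, gn * gain, gg * gain


@dataclass
class NoiseParams:
    rate: float = 300.0   # s^-1 per pyramidal cell
    g_peak: float = 0.08  # nS, ~10x smaller than local pyr->pyr


@dataclass
class Layer4Params:
    cells_per_mc: int = 5
    connectivity_p: float = 0.5
    rate: float = 80.0  # s^-1 during stimulation (60-100 range midpoint)


@dataclass
class GeometryParams:
    grid_side_um: float = 1500.0
    mc_diameter_um: float = 30.0
    pyr_z_spread_um: float = 500.0


@dataclass
class NetworkSpec:
    """Architecture of one network instance."""

    n_hypercolumns: int = 9
    n_minicolumns_per_hc: int = 49
    n_pyr_per_mc: int = 30
    n_basket_per_mc: int = 1
    n_rsnp_per_mc: int = 2
    excitation_gain: float = 1.0
    basket_basket_enabled: bool = True
    rsnp_enabled: bool = True
    nmda_enabled: bool = True
    noise_enabled: bool = True
    seeds: dict = field(default_factory=lambda: resolve_seeds(None))
    connectivity: ConnectivityParams = field(default_factory=ConnectivityParams)
    synapse: SynapseParams = field(default_factory=SynapseParams)
    noise: NoiseParams = field(default_factory=NoiseParams)
    layer4: Layer4Params = field(default_factory=Layer4Params)
    geometry: GeometryParams = field(default_factory=GeometryParams)

    def __post_init__(self):
        if self.n_hypercolumns < 1 or self.n_minicolumns_per_hc < 1:
            raise ValueError("need at least one hypercolumn and minicolumn")
        if self.n_pyr_per_mc < 1:
            raise ValueError("n_pyr_per_mc must be >= 1")
        if self.excitation_gain < 0:
            raise ValueError("excitation_gain must be non-negative")
        self.seeds = resolve_seeds(self.seeds)

    # -- derived counts ------------------------------------------------
    @property
    def n_minicolumns(self) -> int:
        return self.n_hypercolumns * self.n_minicolumns_per_hc

    @property
    def cells_per_mc(self) -> int:
        return (
            self.n_pyr_per_mc
            + self.n_basket_per_mc
            + (self.n_rsnp_per_mc if self.rsnp_enabled else 0)
        )

    @property
    def n_patterns(self) -> int:
        return self.n_minicolumns_per_hc


def count_cells(spec: NetworkSpec) -> int:
    """Number of model neurons (excludes layer-4 generators and noise
    sources): n_hc * n_mc * (pyr + basket + rsnp)."""
    return spec.n_minicolumns * spec.cells_per_mc


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

@dataclass
class Geometry:
    """Realized cell positions (µm) and the cell/minicolumn index tables."""

    params: GeometryParams
    mc_centers: np.ndarray      # (n_mc, 2) x, y in µm
    positions: np.ndarray       # (n_cells, 3) x, y, z in µm
    cell_type_code: np.ndarray  # (n_cells,) 0 pyr / 1 basket / 2 RSNP
    cell_hc: np.ndarray         # (n_cells,)
    cell_mc: np.ndarray         # (n_cells,) global minicolumn index
    mc_hc: np.ndarray           # (n_mc,) hypercolumn of each minicolumn
    mc_local: np.ndarray        # (n_mc,) index of the mc within its hc

    @property
    def n_cells(self) -> int:
        return len(self.positions)

    def cells_of_type(self, type_name: str) -> np.ndarray:
        return np.flatnonzero(self.cell_type_code == CELL_TYPE_CODES[type_name])


def _block_grid(n: int) -> int:
    return int(np.ceil(np.sqrt(n)))


def layout(spec: NetworkSpec) -> Geometry:
    """Place minicolumns on the square grid and assign cell positions.

    Hypercolumns occupy contiguous square blocks of grid sites (e.g. the
    standard 9 x 49 network tiles a 21 x 21 grid with 7 x 7 blocks).
    """
    gp = spec.geometry
    hc_side = _block_grid(spec.n_hypercolumns)
    mc_side = _block_grid(spec.n_minicolumns_per_hc)
    n_grid = hc_side * mc_side
    if spec.n_minicolumns > n_grid * n_grid:
        raise ValueError("more minicolumns than grid sites")
    spacing = gp.grid_side_um / n_grid

    n_mc = spec.n_minicolumns
    mc_centers = np.empty((n_mc, 2))
    mc_hc = np.empty(n_mc, dtype=np.int64)
    mc_local = np.empty(n_mc, dtype=np.int64)
    for hc in range(spec.n_hypercolumns):
        bx, by = hc % hc_side, hc // hc_side
        for loc in range(spec.n_minicolumns_per_hc):
            gx = bx * mc_side + loc % mc_side
            gy = by * mc_side + loc // mc_side
            m = hc * spec.n_minicolumns_per_hc + loc
            mc_centers[m] = ((gx + 0.5) * spacing, (gy + 0.5) * spacing)
            mc_hc[m] = hc
            mc_local[m] = loc

    per_mc = spec.cells_per_mc
    n_cells = n_mc * per_mc
    positions = np.empty((n_cells, 3))
    type_code = np.empty(n_cells, dtype=np.int64)
    cell_hc = np.repeat(mc_hc, per_mc)
    cell_mc = np.repeat(np.arange(n_mc), per_mc)

    n_pyr = spec.n_pyr_per_mc
    if n_pyr > 1:
        z_pyr = np.linspace(
            -gp.pyr_z_spread_um / 2, gp.pyr_z_spread_um / 2, n_pyr
        )
    else:
        z_pyr = np.zeros(1)
    codes = [0] * n_pyr + [1] * spec.n_basket_per_mc
    if spec.rsnp_enabled:
        codes += [2] * spec.n_rsnp_per_mc
    codes = np.asarray(codes, dtype=np.int64)
    z_all = np.concatenate([z_pyr, np.zeros(per_mc - n_pyr)])
    for m in range(n_mc):
        sl = slice(m * per_mc, (m + 1) * per_mc)
        positions[sl, 0] = mc_centers[m, 0]
        positions[sl, 1] = mc_centers[m, 1]
        positions[sl, 2] = z_all
        type_code[sl] = codes

    return Geometry(
        params=gp,
        mc_centers=mc_centers,
        positions=positions,
        cell_type_code=type_code,
        cell_hc=cell_hc,
        cell_mc=cell_mc,
        mc_hc=mc_hc,
        mc_local=mc_local,
    )


# ---------------------------------------------------------------------------
# patterns
# ---------------------------------------------------------------------------

@dataclass
class PatternSet:
    """Non-overlapping memory patterns: pattern p = the p-th minicolumn of
    every hypercolumn."""

    n_patterns: int
    mc_pattern: np.ndarray  # (n_mc,) pattern index of each minicolumn

    def minicolumns(self, pattern: int) -> np.ndarray:
        if not (0 <= pattern < self.n_patterns):
            raise ValueError(f"pattern {pattern} out of range")
        return np.flatnonzero(self.mc_pattern == pattern)


def build_patterns(spec: NetworkSpec, geometry: Geometry) -> PatternSet:
    return PatternSet(
        n_patterns=spec.n_patterns, mc_pattern=geometry.mc_local.copy()
    )


# ---------------------------------------------------------------------------
# connectivity
# ---------------------------------------------------------------------------

@dataclass
class ConnectivityTable:
    """Realized directed connections (one row per bouton).

    A connection carries up to three receptor components (AMPA, NMDA,
    GABA_A peak conductances in nS, already gain-scaled); the engine turns
    these into conductance channels.
    """

    pre: np.ndarray          # (n_edges,) presynaptic cell id
    post: np.ndarray         # (n_edges,) postsynaptic cell id
    projection: np.ndarray   # (n_edges,) PROJ_CODE
    target: np.ndarray       # (n_edges,) TARGET_CODE of the post compartment
    delay_ms: np.ndarray     # (n_edges,)
    g_ampa: np.ndarray       # (n_edges,) nS
    g_nmda: np.ndarray
    g_gaba: np.ndarray

    def __len__(self) -> int:
        return len(self.pre)

    def edges_of(self, projection: str) -> np.ndarray:
        return np.flatnonzero(self.projection == PROJ_CODE[projection])

    def to_dataframe(self):
        import pandas as pd

        proj_names = np.array(PROJECTIONS)
        tgt_names = np.array(_TARGET_LABELS)
        return pd.DataFrame(
            {
                "pre_id": self.pre,
                "post_id": self.post,
                "projection": proj_names[self.projection],
                "target_compartment": tgt_names[self.target],
                "delay_ms": self.delay_ms,
                "g_ampa_nS": self.g_ampa,
                "g_nmda_nS": self.g_nmda,
                "g_gaba_nS": self.g_gaba,
            }
        )

    def save_tsv(self, path) -> None:
        """Export as (optionally gzipped, by extension) TSV."""
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def _bernoulli_pairs(rng, n_pre, n_post, p, exclude_diag):
    """Index pairs (i, j) with i->j realized at probability p."""
    mask = rng.random((n_pre, n_post)) < p
    if exclude_diag:
        np.fill_diagonal(mask, False)
    return np.nonzero(mask)


class _EdgeAccumulator:
    def __init__(self):
        self.pre, self.post, self.proj, self.tgt = [], [], [], []
        self.ga, self.gn, self.gg = [], [], []

    def add(self, pre, post, projection, target_codes, g):
        pre = np.asarray(pre, dtype=np.int64)
        post = np.asarray(post, dtype=np.int64)
        if pre.size == 0:
            return
        self.pre.append(pre)
        self.post.append(post)
        self.proj.append(np.full(pre.size, PROJ_CODE[projection], dtype=np.int16))
        tgt = np.asarray(target_codes, dtype=np.int8)
        if tgt.ndim == 0:
            tgt = np.full(pre.size, tgt, dtype=np.int8)
        self.tgt.append(tgt)
        ga, gn, gg = g
        self.ga.append(np.full(pre.size, ga))
        self.gn.append(np.full(pre.size, gn))
        self.gg.append(np.full(pre.size, gg))

    def build(self, positions, l4_positions=None) -> ConnectivityTable:
        if not self.pre:
            z = np.zeros(0)
            return ConnectivityTable(
                z.astype(np.int64), z.astype(np.int64), z.astype(np.int16),
                z.astype(np.int8), z, z, z, z,
            )
        pre = np.concatenate(self.pre)
        post = np.concatenate(self.post)
        n_cells = len(positions)
        if l4_positions is not None and len(l4_positions):
            all_pos = np.vstack([positions, l4_positions])
        else:
            all_pos = positions
        delay = conduction_delay(all_pos[pre], all_pos[post])
        return ConnectivityTable(
            pre=pre,
            post=post,
            projection=np.concatenate(self.proj),
            target=np.concatenate(self.tgt),
            delay_ms=np.atleast_1d(delay),
            g_ampa=np.concatenate(self.ga),
            g_nmda=np.concatenate(self.gn),
            g_gaba=np.concatenate(self.gg),
        )


def _exc_targets(rng, n):
    """Split excitatory contacts uniformly between apical2 and basal."""
    return np.where(
        rng.random(n) < 0.5, TARGET_CODE["apical2"], TARGET_CODE["basal"]
    ).astype(np.int8)


def build_connectivity(
    spec: NetworkSpec,
    geometry: Geometry,
    patterns: PatternSet,
    rng: np.random.Generator | None = None,
) -> ConnectivityTable:
    """Realize every projection rule; deterministic given the rng state."""
    if rng is None:
        rng = substream(spec.seeds["connectivity"], "connectivity")
    cp = spec.connectivity
    sp = spec.synapse
    gain = spec.excitation_gain

    def proj_g(name):
        ga, gn, gg = sp.projection_g(name)
        if name in GAIN_SCALED_PROJECTIONS:
            ga, gn = ga * gain, gn * gain
        if not spec.nmda_enabled:
            gn = 0.0
        return ga, gn, gg

    per_mc = spec.cells_per_mc
    n_pyr = spec.n_pyr_per_mc
    n_mc = spec.n_minicolumns
    acc = _EdgeAccumulator()

    def mc_cells(m, type_code):
        base = m * per_mc
        if type_code == 0:
            return base + np.arange(n_pyr)
        if type_code == 1:
            return base + n_pyr + np.arange(spec.n_basket_per_mc)
        if not spec.rsnp_enabled:
            return np.zeros(0, dtype=np.int64)
        return base + n_pyr + spec.n_basket_per_mc + np.arange(spec.n_rsnp_per_mc)

    # (a) local pyr->pyr, probability per ordered pair, no self-edges
    g_local = proj_g("pyr_pyr_local")
    for m in range(n_mc):
        cells = mc_cells(m, 0)
        i, j = _bernoulli_pairs(rng, n_pyr, n_pyr, cp.local_pyr_pyr_p, True)
        acc.add(cells[i], cells[j], "pyr_pyr_local",
                _exc_targets(rng, i.size), g_local)

    # (b) pyr->basket: eight closest basket cells within the hypercolumn
    # (distance between minicolumn centres; ties broken by lowest cell id)
    g_pb = proj_g("pyr_basket")
    basket_ids_all = geometry.cells_of_type("basket")
    for hc in range(spec.n_hypercolumns):
        hc_mcs = np.flatnonzero(geometry.mc_hc == hc)
        baskets = basket_ids_all[np.isin(geometry.cell_mc[basket_ids_all], hc_mcs)]
        b_xy = geometry.positions[baskets, :2]
        k = min(cp.n_closest_baskets, len(baskets))
        for m in hc_mcs:
            d = np.linalg.norm(b_xy - geometry.mc_centers[m], axis=1)
            order = np.lexsort((baskets, d))  # distance, then lowest id
            chosen = baskets[order[:k]]
            pyrs = mc_cells(m, 0)
            pre = np.repeat(pyrs, k)
            post = np.tile(chosen, n_pyr)
            keep = pre != post
            acc.add(pre[keep], post[keep], "pyr_basket",
                    TARGET_CODE["basal"], g_pb)

    # (c) basket->pyr and (d) basket->basket within the hypercolumn
    g_bp = proj_g("basket_pyr")
    g_bb = proj_g("basket_basket")
    pyr_ids_all = geometry.cells_of_type("pyramidal")
    for hc in range(spec.n_hypercolumns):
        hc_mcs = np.flatnonzero(geometry.mc_hc == hc)
        baskets = basket_ids_all[np.isin(geometry.cell_mc[basket_ids_all], hc_mcs)]
        pyrs = pyr_ids_all[np.isin(geometry.cell_mc[pyr_ids_all], hc_mcs)]
        i, j = _bernoulli_pairs(rng, len(baskets), len(pyrs), cp.basket_pyr_p, False)
        acc.add(baskets[i], pyrs[j], "basket_pyr", TARGET_CODE["soma"], g_bp)
        if spec.basket_basket_enabled and len(baskets) > 1:
            i, j = _bernoulli_pairs(
                rng, len(baskets), len(baskets), cp.basket_basket_p, True
            )
            acc.add(baskets[i], baskets[j], "basket_basket",
                    TARGET_CODE["soma"], g_bb)

    # (e) RSNP->pyr within the home minicolumn, onto apical2
    if spec.rsnp_enabled:
        g_rp = proj_g("rsnp_pyr")
        for m in range(n_mc):
            rsnps = mc_cells(m, 2)
            pyrs = mc_cells(m, 0)
            i, j = _bernoulli_pairs(rng, len(rsnps), n_pyr, cp.rsnp_pyr_p, False)
            acc.add(rsnps[i], pyrs[j], "rsnp_pyr", TARGET_CODE["apical2"], g_rp)

    # (f) long-range pyr->pyr: fixed in-degree from same-pattern cells in
    # other hypercolumns
    g_gl = proj_g("pyr_pyr_global")
    if spec.n_hypercolumns > 1 and cp.lr_pyr_in_degree > 0:
        for m in range(n_mc):
            pat = patterns.mc_pattern[m]
            hc = geometry.mc_hc[m]
            src_mcs = np.flatnonzero(
                (patterns.mc_pattern == pat) & (geometry.mc_hc != hc)
            )
            pool = np.concatenate([mc_cells(sm, 0) for sm in src_mcs])
            if cp.lr_pyr_in_degree > len(pool):
                raise ValueError(
                    "long-range pyr in-degree exceeds the same-pattern pool "
                    f"({cp.lr_pyr_in_degree} > {len(pool)})"
                )
            for post in mc_cells(m, 0):
                pre = rng.choice(pool, size=cp.lr_pyr_in_degree, replace=False)
                acc.add(pre, np.full(pre.size, post), "pyr_pyr_global",
                        _exc_targets(rng, pre.size), g_gl)

    # (g) long-range pyr->RSNP from distant dissimilar-pattern pyramidal
    # cells (in total by default; per dissimilar pattern when configured)
    if spec.rsnp_enabled and spec.n_hypercolumns > 1 and cp.rsnp_lr_in_degree > 0:
        g_pr = proj_g("pyr_rsnp_global")
        for m in range(n_mc):
            pat = patterns.mc_pattern[m]
            hc = geometry.mc_hc[m]
            for post in mc_cells(m, 2):
                if cp.rsnp_lr_per_pattern:
                    pres = []
                    for other in range(patterns.n_patterns):
                        if other == pat:
                            continue
                        src_mcs = np.flatnonzero(
                            (patterns.mc_pattern == other) & (geometry.mc_hc != hc)
                        )
                        pool = np.concatenate([mc_cells(sm, 0) for sm in src_mcs])
                        if cp.rsnp_lr_in_degree > len(pool):
                            raise ValueError("RSNP in-degree exceeds pool")
                        pres.append(rng.choice(
                            pool, size=cp.rsnp_lr_in_degree, replace=False))
                    pre = np.concatenate(pres) if pres else np.zeros(0, np.int64)
                else:
                    src_mcs = np.flatnonzero(
                        (patterns.mc_pattern != pat) & (geometry.mc_hc != hc)
                    )
                    pool = np.concatenate([mc_cells(sm, 0) for sm in src_mcs])
                    if cp.rsnp_lr_in_degree > len(pool):
                        raise ValueError("RSNP in-degree exceeds pool")
                    pre = rng.choice(
                        pool, size=cp.rsnp_lr_in_degree, replace=False
                    )
                acc.add(pre, np.full(pre.size, post), "pyr_rsnp_global",
                        TARGET_CODE["basal"], g_pr)

    return acc.build(geometry.positions)


# ---------------------------------------------------------------------------
# expected synapse counts (closed form)
# ---------------------------------------------------------------------------

def expected_synapse_counts(spec: NetworkSpec) -> dict:
    """Closed-form expectation (and binomial variance) per projection.

    Fixed in-degree projections have zero variance; Bernoulli projections
    contribute n p (1 - p).
    """
    cp = spec.connectivity
    n_mc = spec.n_minicolumns
    n_pyr = spec.n_pyr_per_mc
    n_pyr_total = n_mc * n_pyr
    nb_hc = spec.n_minicolumns_per_hc * spec.n_basket_per_mc
    npyr_hc = spec.n_minicolumns_per_hc * n_pyr
    n_hc = spec.n_hypercolumns

    out: dict[str, dict] = {}

    def put(name, mean, var):
        out[name] = {"mean": float(mean), "var": float(var)}

    n_pairs = n_mc * n_pyr * (n_pyr - 1)
    p = cp.local_pyr_pyr_p
    put("pyr_pyr_local", n_pairs * p, n_pairs * p * (1 - p))

    k = min(cp.n_closest_baskets, nb_hc)
    put("pyr_basket", n_pyr_total * k, 0.0)

    n_pairs = n_hc * nb_hc * npyr_hc
    p = cp.basket_pyr_p
    put("basket_pyr", n_pairs * p, n_pairs * p * (1 - p))

    if spec.basket_basket_enabled:
        n_pairs = n_hc * nb_hc * (nb_hc - 1)
        p = cp.basket_basket_p
        put("basket_basket", n_pairs * p, n_pairs * p * (1 - p))
    else:
        put("basket_basket", 0.0, 0.0)

    if spec.rsnp_enabled:
        n_pairs = n_mc * spec.n_rsnp_per_mc * n_pyr
        p = cp.rsnp_pyr_p
        put("rsnp_pyr", n_pairs * p, n_pairs * p * (1 - p))
    else:
        put("rsnp_pyr", 0.0, 0.0)

    if n_hc > 1:
        put("pyr_pyr_global", n_pyr_total * cp.lr_pyr_in_degree, 0.0)
    else:
        put("pyr_pyr_global", 0.0, 0.0)

    if spec.rsnp_enabled and n_hc > 1:
        n_rsnp_total = n_mc * spec.n_rsnp_per_mc
        mult = (spec.n_patterns - 1) if cp.rsnp_lr_per_pattern else 1
        put("pyr_rsnp_global", n_rsnp_total * cp.rsnp_lr_in_degree * mult, 0.0)
    else:
        put("pyr_rsnp_global", 0.0, 0.0)

    total = sum(v["mean"] for v in out.values())
    var = sum(v["var"] for v in out.values())
    out["total"] = {"mean": total, "var": var}
    return out


def count_synapses(table: ConnectivityTable, spec: NetworkSpec | None = None):
    """Realized connection count, with the closed-form expectation report
    when the spec is provided."""
    realized = len(table)
    if spec is None:
        return realized
    report = expected_synapse_counts(spec)
    for name in PROJECTIONS:
        if name == "l4_pyr":
            continue
        report.setdefault(name, {"mean": 0.0, "var": 0.0})
        report[name]["realized"] = int(np.sum(table.projection == PROJ_CODE[name]))
    report["total"]["realized"] = realized
    return realized, report


# ---------------------------------------------------------------------------
# noise and layer-4 input
# ---------------------------------------------------------------------------

@dataclass
class NoiseBindings:
    """Per-pyramidal-cell independent Poisson noise sources.

    Each cell's 300 /s source is split into two equal-rate sub-sources,
    one per excitatory target compartment (apical2, basal) — statistically
    identical to one source whose events pick a compartment at random.
    Conductances are non-saturating AMPA.
    """

    cell_ids: np.ndarray     # (n_src,) target pyramidal cell
    target: np.ndarray       # (n_src,) TARGET_CODE
    rate: np.ndarray         # (n_src,) s^-1
    g_peak: float            # nS

    def __len__(self):
        return len(self.cell_ids)


def attach_noise(spec: NetworkSpec, geometry: Geometry) -> NoiseBindings:
    if not spec.noise_enabled:
        z = np.zeros(0, dtype=np.int64)
        return NoiseBindings(z, z.astype(np.int8), np.zeros(0), spec.noise.g_peak)
    pyr = geometry.cells_of_type("pyramidal")
    cell_ids = np.repeat(pyr, 2)
    target = np.tile(
        np.array([TARGET_CODE["apical2"], TARGET_CODE["basal"]], dtype=np.int8),
        len(pyr),
    )
    rate = np.full(len(cell_ids), spec.noise.rate / 2.0)
    return NoiseBindings(cell_ids, target, rate, spec.noise.g_peak)


@dataclass
class Layer4Population:
    """Layer-4-like Poisson input cells: five per minicolumn, silent unless
    their minicolumn is stimulated; feedforward AMPA onto the minicolumn's
    pyramidal cells at 50% connectivity."""

    first_id: int            # ids follow the network cells
    mc_of_cell: np.ndarray   # (n_l4,) minicolumn of each input cell
    edges: ConnectivityTable

    @property
    def n_cells(self) -> int:
        return len(self.mc_of_cell)

    def cells_of_mc(self, mc: int) -> np.ndarray:
        return self.first_id + np.flatnonzero(self.mc_of_cell == mc)


def build_layer4(
    spec: NetworkSpec,
    geometry: Geometry,
    rng: np.random.Generator | None = None,
) -> Layer4Population:
    if rng is None:
        rng = substream(spec.seeds["connectivity"], "connectivity")
        rng = np.random.default_rng(rng.integers(2**31))  # sub-derived
    n_mc = spec.n_minicolumns
    k = spec.layer4.cells_per_mc
    first_id = geometry.n_cells
    mc_of_cell = np.repeat(np.arange(n_mc), k)
    l4_pos = np.column_stack(
        [geometry.mc_centers[mc_of_cell], np.zeros(n_mc * k)]
    )
    g = spec.synapse.projection_g("l4_pyr")
    acc = _EdgeAccumulator()
    per_mc = spec.cells_per_mc
    for m in range(n_mc):
        l4 = first_id + np.flatnonzero(mc_of_cell == m)
        pyrs = m * per_mc + np.arange(spec.n_pyr_per_mc)
        i, j = _bernoulli_pairs(
            rng, k, spec.n_pyr_per_mc, spec.layer4.connectivity_p, False
        )
        acc.add(l4[i], pyrs[j], "l4_pyr", _exc_targets(rng, i.size), g)
    edges = acc.build(geometry.positions, l4_pos)
    return Layer4Population(first_id=first_id, mc_of_cell=mc_of_cell, edges=edges)


# ---------------------------------------------------------------------------
# whole-network assembly
# ---------------------------------------------------------------------------

@dataclass
class Network:
    """A fully realized network ready for simulation."""

    spec: NetworkSpec
    geometry: Geometry
    patterns: PatternSet
    connectivity: ConnectivityTable
    noise: NoiseBindings
    layer4: Layer4Population
    size_factors: np.ndarray  # (n_cells,)

    @property
    def n_cells(self) -> int:
        return self.geometry.n_cells

    def pyr_cells_of_mc(self, mc: int) -> np.ndarray:
        base = mc * self.spec.cells_per_mc
        return base + np.arange(self.spec.n_pyr_per_mc)


def build_network(spec: NetworkSpec) -> Network:
    """Build geometry, patterns, connectivity, noise and layer-4 input from
    the spec, reproducibly from its seeds."""
    geometry = layout(spec)
    patterns = build_patterns(spec, geometry)
    conn_rng = substream(spec.seeds["connectivity"], "connectivity")
    connectivity = build_connectivity(spec, geometry, patterns, conn_rng)
    noise = attach_noise(spec, geometry)
    layer4 = build_layer4(spec, geometry, conn_rng)
    size_rng = substream(spec.seeds["size"], "size")
    size_factors = size_rng.uniform(0.9, 1.1, geometry.n_cells)
    return Network(
        spec=spec,
        geometry=geometry,
        patterns=patterns,
        connectivity=connectivity,
        noise=noise,
        layer4=layer4,
        size_factors=size_factors,
    )
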