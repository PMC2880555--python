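"""Configuration schema, shipped presets and run provenance.

Network configurations are JSON documents with a ``schema_version`` and up
to three sections: ``network`` (architecture + synapse parameters),
``simulation`` (dt, duration, recording) and ``protocol``.  Missing keys
resolve to the standard defaults, so an empty document is exactly the
``standard9`` network; unknown keys raise descriptive validation errors.

Presets
-------
``standard9``
    the full model: 9 hypercolumns x 49 minicolumns x (30 pyr + 1 basket
    + 2 RSNP) = 14,553 cells.
``table1_hc9`` / ``table1_hc4`` / ``table1_hc1``
    the modularity-scan variants (9/4/1 hypercolumns with 30/67/270
    pyramidal cells per minicolumn, RSNP cells and basket-basket
    connections removed) that hold the foreground population near 270.
``mini``
    a desk-scale network (4 hypercolumns x 8 minicolumns x 15 pyramidal
    cells) with long-range in-degrees rescaled to the smaller pools,
    used by the scaled-down dynamical tests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path

from ._rng import resolve_seeds
from .engine import SimulationConfig
from .network import (
    ConnectivityParams,
    GeometryParams,
    Layer4Params,
    NetworkSpec,
    NoiseParams,
    SynapseParams,
)

__all__ = [
    "SCHEMA_VERSION",
    "PRESETS",
    "get_preset",
    "spec_to_dict",
    "spec_from_dict",
    "load_config",
    "save_config",
    "config_hash",
    "RunManifest",
]

SCHEMA_VERSION = 1

_SECTION_TYPES = {
    "connectivity": ConnectivityParams,
    "synapse": SynapseParams,
    "noise": NoiseParams,
    "layer4": Layer4Params,
    "geometry": GeometryParams,
}


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def _standard9() -> NetworkSpec:
    return NetworkSpec()


def _table1(n_hc: int, n_pyr: int) -> NetworkSpec:
    return NetworkSpec(
        n_hypercolumns=n_hc,
        n_pyr_per_mc=n_pyr,
        rsnp_enabled=False,
        basket_basket_enabled=False,
    )


def _mini() -> NetworkSpec:
    # Desk-scale network (1,656 neurons).  Long-range in-degree rescaled to
    # the smaller same-pattern pool (37 of 100 distant cells, matching the
    # full network's 90-of-240 fraction); the local density raised so the
    # local in-degree (~7) matches the full-scale value.  Recurrent drive
    # is carried mainly by long-range NMDA: at this scale fast recurrent
    # conductances let single-cycle winner fluctuations self-amplify, while
    # the slow coincidence-gated NMDA keeps retrieval dependent on several
    # hypercolumns being co-active, the modular stabilization mechanism.
    return NetworkSpec(
        n_hypercolumns=6,
        n_minicolumns_per_hc=12,
        n_pyr_per_mc=20,
        connectivity=ConnectivityParams(
            local_pyr_pyr_p=0.38,
            lr_pyr_in_degree=37,
            rsnp_lr_in_degree=8,
            rsnp_lr_per_pattern=True,
        ),
        synapse=SynapseParams(
            pyr_pyr_local_ampa=0.05,
            pyr_pyr_local_nmda=0.1,
            pyr_pyr_global_ampa=0.05,
            pyr_pyr_global_nmda=0.45,
            pyr_rsnp_ampa=0.5,
            pyr_rsnp_nmda=0.3,
            pyr_basket_ampa=4.0,
            basket_pyr_gaba=8.0,
            basket_basket_gaba=2.0,
            rsnp_pyr_gaba=4.0,
            pyr_tonic_gaba=0.75,
        ),
    )


PRESETS = {
    "standard9": _standard9,
    "table1_hc9": lambda: _table1(9, 30),
    "table1_hc4": lambda: _table1(4, 67),
    "table1_hc1": lambda: _table1(1, 270),
    "mini": _mini,
}


def get_preset(name: str) -> NetworkSpec:
    try:
        return PRESETS[name]()
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None


# ---------------------------------------------------------------------------
# (de)serialization
# ---------------------------------------------------------------------------

def spec_to_dict(spec: NetworkSpec) -> dict:
    return dataclasses.asdict(spec)


def _build_section(cls, doc: dict, path: str):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(doc) - fields
    if unknown:
        raise ValueError(
            f"unknown keys {sorted(unknown)} in config section {path!r}; "
            f"valid keys: {sorted(fields)}"
        )
    return cls(**doc)


def spec_from_dict(doc: dict) -> NetworkSpec:
    doc = dict(doc)
    kwargs = {}
    for name, cls in _SECTION_TYPES.items():
        if name in doc:
            kwargs[name] = _build_section(cls, doc.pop(name), f"network.{name}")
    if "seeds" in doc:
        kwargs["seeds"] = resolve_seeds(doc.pop("seeds"))
    top_fields = {f.name for f in dataclasses.fields(NetworkSpec)}
    unknown = set(doc) - top_fields
    if unknown:
        raise ValueError(
            f"unknown keys {sorted(unknown)} in config section 'network'; "
            f"valid keys: {sorted(top_fields)}"
        )
    kwargs.update(doc)
    return NetworkSpec(**kwargs)


def load_config(path) -> tuple[NetworkSpec, SimulationConfig | None, dict | None]:
    """Load a config document; returns (network spec, simulation config or
    None, protocol dict or None) with all defaults applied."""
    text = Path(path).read_text().strip()
    doc = json.loads(text) if text else {}
    if not isinstance(doc, dict):
        raise ValueError("config root must be a JSON object")
    version = doc.pop("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ValueError(f"unsupported schema_version {version}")
    preset = doc.pop("preset", None)
    net_doc = doc.pop("network", {})
    sim_doc = doc.pop("simulation", None)
    protocol = doc.pop("protocol", None)
    if doc:
        raise ValueError(f"unknown top-level keys {sorted(doc)}")
    if preset is not None:
        if net_doc:
            base = dataclasses.asdict(get_preset(preset))

            def merge(dst, src):
                for k, v in src.items():
                    if isinstance(v, dict) and isinstance(dst.get(k), dict):
                        merge(dst[k], v)
                    else:
                        dst[k] = v

            merge(base, net_doc)
            net_doc = base
        else:
            net_doc = dataclasses.asdict(get_preset(preset))
    spec = spec_from_dict(net_doc)
    sim = None
    if sim_doc is not None:
        fields = {f.name for f in dataclasses.fields(SimulationConfig)}
        unknown = set(sim_doc) - fields
        if unknown:
            raise ValueError(f"unknown keys {sorted(unknown)} in 'simulation'")
        sim = SimulationConfig(**sim_doc)
    return spec, sim, protocol


def save_config(spec: NetworkSpec, path, simulation: SimulationConfig | None = None,
                protocol: dict | None = None) -> None:
    doc = {"schema_version": SCHEMA_VERSION, "network": spec_to_dict(spec)}
    if simulation is not None:
        doc["simulation"] = dataclasses.asdict(simulation)
    if protocol is not None:
        doc["protocol"] = protocol
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def config_hash(spec: NetworkSpec) -> str:
    """Stable content hash of a resolved network configuration."""
    canon = json.dumps(spec_to_dict(spec), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# provenance
# ---------------------------------------------------------------------------

@dataclass
class RunManifest:
    """Everything needed to regenerate a result directory."""

    config_hash: str
    seeds: dict
    preset: str | None
    code_version: str
    created_utc: str

    @classmethod
    def for_run(cls, spec: NetworkSpec, preset: str | None = None) -> "RunManifest":
        from . import __version__

        return cls(
            config_hash=config_hash(spec),
            seeds=dict(spec.seeds),
            preset=preset,
            code_version=__version__,
            created_utc=time.strftime("%Y-%m-%dT%H:%M:%SZ", time.gmtime()),
        )

    def save(self, path) -> None:
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=2) + "\n"
        )

    @classmethod
    def load(cls, path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))
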