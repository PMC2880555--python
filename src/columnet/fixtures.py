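"""Deterministic fixture generation for tests and examples.

Everything is generated programmatically from a seed — no downloads, no
binary data.  Fixture kinds:

``poisson_trains``
    i.i.d. homogeneous Poisson spike trains (spike TSV).
``regular_trains``
    perfectly regular (clock-like) trains, CV2 = 0 by construction.
``toy_two_compartment_cell``
    a synthetic two-compartment passive cell parameter document used to
    exercise the current-balance algebra against closed forms.
``mini_network``
    a ready-to-simulate desk-scale network configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np
import pandas as pd

from ._rng import substream

__all__ = [
    "FixtureSpec",
    "generate_fixture",
    "poisson_train",
    "poisson_trains",
    "regular_train",
]

FIXTURE_KINDS = (
    "poisson_trains",
    "regular_trains",
    "toy_two_compartment_cell",
    "mini_network",
)


@dataclass(frozen=True)
class FixtureSpec:
    kind: str
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.kind not in FIXTURE_KINDS:
            raise ValueError(
                f"unknown fixture kind {self.kind!r}; valid: {FIXTURE_KINDS}"
            )


def poisson_train(
    rate_hz: float, duration_ms: float, rng: np.random.Generator
) -> np.ndarray:
    """One homogeneous Poisson spike train (times in ms)."""
    if rate_hz <= 0:
        return np.zeros(0)
    n_expected = rate_hz * duration_ms * 1e-3
    n_draw = int(n_expected + 5 * np.sqrt(n_expected) + 10)
    isis = rng.exponential(1000.0 / rate_hz, size=n_draw)
    t = np.cumsum(isis)
    while t[-1] < duration_ms:
        extra = rng.exponential(1000.0 / rate_hz, size=n_draw)
        t = np.concatenate([t, t[-1] + np.cumsum(extra)])
    return t[t < duration_ms]


def poisson_trains(
    rate_hz: float, n: int, duration_ms: float, seed: int = 0
) -> list[np.ndarray]:
    rng = substream(seed, "fixture")
    return [poisson_train(rate_hz, duration_ms, rng) for _ in range(n)]


def regular_train(rate_hz: float, duration_ms: float, t0: float = 0.0) -> np.ndarray:
    isi = 1000.0 / rate_hz
    return np.arange(t0 + isi, duration_ms, isi)


def _trains_to_tsv(trains, path):
    cell = np.concatenate([np.full(len(t), i) for i, t in enumerate(trains)])
    times = np.concatenate(trains) if trains else np.zeros(0)
    order = np.argsort(times, kind="stable")
    pd.DataFrame({"cell_id": cell[order].astype(int), "t_ms": times[order]}).to_csv(
        path, sep="\t", index=False
    )


def generate_fixture(spec: FixtureSpec, out_dir) -> list[Path]:
    """Materialize a fixture on disk; returns the written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    p = spec.params
    if spec.kind == "poisson_trains":
        trains = poisson_trains(
            p.get("rate_hz", 10.0), p.get("n", 10),
            p.get("duration_ms", 10_000.0), spec.seed,
        )
        path = out / "poisson_trains.tsv"
        _trains_to_tsv(trains, path)
        return [path]
    if spec.kind == "regular_trains":
        trains = [
            regular_train(p.get("rate_hz", 10.0), p.get("duration_ms", 10_000.0))
            for _ in range(p.get("n", 10))
        ]
        path = out / "regular_trains.tsv"
        _trains_to_tsv(trains, path)
        return [path]
    if spec.kind == "toy_two_compartment_cell":
        # synthetic stand-in cell: two passive compartments with known
        # parameters so balance solutions have closed forms
        doc = {
            "synthetic": True,
            "soma": {"c_m": 0.005, "g_m": 0.5, "E_leak": -65.0},
            "dendrite": {"c_m": 0.004, "g_m": 0.4, "E_leak": -65.0},
            "g_core": 10.0,
            "units": {"c_m": "nF", "g": "nS", "V": "mV"},
        }
        path = out / "toy_two_compartment_cell.json"
        path.write_text(json.dumps(doc, indent=2) + "\n")
        return [path]
    if spec.kind == "mini_network":
        from .config import get_preset, save_config

        path = out / "mini_network.json"
        save_config(get_preset("mini"), path)
        return [path]
    raise AssertionError("unreachable")
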