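"""Seed management: one root seed fanned into named, independent substreams.

Every stochastic component of the package (connectivity wiring, cell-size
jitter, background noise, stimulus spike generation) draws from its own
substream so that toggling or re-recording one source never reshuffles
another.  Substreams are derived with :class:`numpy.random.SeedSequence`
using a fixed name -> key mapping, so results are reproducible across runs
and platforms for a given root seed.
"""

from __future__ import annotations

import numpy as np

# Fixed fan-out keys; never reorder or renumber (would silently change all
# published results for a given root seed).
_STREAM_KEYS = {
    "connectivity": 1,
    "size": 2,
    "noise": 3,
    "stimulus": 4,
    "fixture": 5,
}


def substream(root_seed: int, name: str) -> np.random.Generator:
    """Return an independent Generator for the named stream.

    Parameters
    ----------
    root_seed : int
        Root seed of the run (kept below 2**31 by convention).
    name : str
        One of ``connectivity``, ``size``, ``noise``, ``stimulus``,
        ``fixture``.
    """
    try:
        key = _STREAM_KEYS[name]
    except KeyError:
        raise ValueError(
            f"unknown stream {name!r}; expected one of {sorted(_STREAM_KEYS)}"
        ) from None
    ss = np.random.SeedSequence(int(root_seed), spawn_key=(key,))
    return np.random.default_rng(ss)


def resolve_seeds(seeds: dict | int | None) -> dict:
    """Normalize a seed specification to the four named stream seeds.

    Accepts either a single root integer (fanned out) or a dict with any of
    the keys ``connectivity``, ``size``, ``noise``, ``stimulus`` (missing
    keys default to 0).
    """
    names = ("connectivity", "size", "noise", "stimulus")
    if seeds is None:
        return {n: 0 for n in names}
    if isinstance(seeds, (int, np.integer)):
        return {n: int(seeds) for n in names}
    out = {n: int(seeds.get(n, 0)) for n in names}
    unknown = set(seeds) - set(names)
    if unknown:
        raise ValueError(f"unknown seed keys: {sorted(unknown)}")
    return out
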