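"""Derived quantities: CV2 spike-train variability, population rates,
synthetic LFP, spectrograms and oscillation frequencies.

CV2 is a *local* measure of inter-spike-interval variability that compares
each ISI to the one that follows,

    CV2_n = 2 |ISI_{n+1} - ISI_n| / (ISI_{n+1} + ISI_n),

averaged over n.  It is 0 for a perfectly regular train, 1 for a Poisson
train, bounded by 2, and — unlike the classical CV — not rate-dependent in
the dynamical range of the network, which is why it is the variability
statistic of choice here.

The synthetic LFP is a dipole proxy: the population average of the
potential difference between the soma and the first apical dendritic
compartment (geometrically aligned apical dendrites dominate the dipole
moment), mean-subtracted.  Spectrograms are short-time Fourier power
(Hann window, 250 ms / 80% overlap by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.signal

from .engine import SpikeData, TraceData

__all__ = [
    "cv2",
    "CV2Result",
    "population_cv2",
    "LFPSignal",
    "synthetic_lfp",
    "spectrogram",
    "oscillation_frequency",
    "rate_histogram",
]

MIN_SPIKES_FOR_CV2 = 3  # need >= 2 ISIs


def cv2(spike_times: np.ndarray) -> float:
    """Mean CV2 of one spike train (requires at least 3 spikes).

    Raises ValueError for shorter trains; callers that aggregate over
    populations exclude (and count) such cells instead.
    """
    t = np.asarray(spike_times, dtype=float)
    if len(t) < MIN_SPIKES_FOR_CV2:
        raise ValueError(
            f"CV2 undefined for fewer than {MIN_SPIKES_FOR_CV2} spikes"
        )
    isi = np.diff(t)
    if np.any(isi <= 0):
        raise ValueError("spike times must be strictly increasing")
    num = 2.0 * np.abs(isi[1:] - isi[:-1])
    den = isi[1:] + isi[:-1]
    return float(np.mean(num / den))


@dataclass
class CV2Result:
    """Population CV2: per-cell means and their unweighted average."""

    per_cell: dict            # cell id -> mean CV2
    mean: float | None        # <CV2>; None when no cell qualifies
    n_isis: dict              # cell id -> number of ISIs used
    excluded: list            # cell ids with fewer than 3 spikes

    @property
    def empty(self) -> bool:
        return self.mean is None


def population_cv2(
    spike_data: SpikeData,
    cell_subset: Sequence[int],
    window: tuple[float, float] | None = None,
) -> CV2Result:
    """<CV2> over a cell population: per-cell mean CV2 first, then the
    unweighted mean over qualifying cells (cells with < 3 spikes in the
    window are excluded and reported)."""
    if window is not None:
        t0, t1 = window
        if t1 <= t0:
            raise ValueError("empty analysis window")
    per_cell, n_isis, excluded = {}, {}, []
    for cid in cell_subset:
        t = spike_data.times_of(int(cid))
        if window is not None:
            t = t[(t >= t0) & (t < t1)]
        if len(t) < MIN_SPIKES_FOR_CV2:
            excluded.append(int(cid))
            continue
        per_cell[int(cid)] = cv2(t)
        n_isis[int(cid)] = len(t) - 1
    mean = float(np.mean(list(per_cell.values()))) if per_cell else None
    return CV2Result(per_cell=per_cell, mean=mean, n_isis=n_isis, excluded=excluded)


@dataclass
class LFPSignal:
    """Mean-subtracted population dipole signal (mV)."""

    signal: np.ndarray
    dt_sample: float  # ms
    cells: tuple

    @property
    def fs(self) -> float:
        """Sampling frequency in Hz."""
        return 1000.0 / self.dt_sample

    @property
    def t(self) -> np.ndarray:
        return np.arange(len(self.signal)) * self.dt_sample


def synthetic_lfp(traces: TraceData, cell_subset: Sequence[int]) -> LFPSignal:
    """Average of (V_soma - V_apical1) over the population, mean-subtracted.

    Requires soma and first-apical voltage traces for every cell in the
    subset (interneurons lack apical compartments and cannot contribute).
    """
    cells = tuple(int(c) for c in cell_subset)
    if not cells:
        raise ValueError("need at least one cell")
    acc = None
    for cid in cells:
        vs = traces.get(cid, "soma", "V")
        va = traces.get(cid, "apical1", "V")
        d = vs - va
        acc = d if acc is None else acc + d
    sig = acc / len(cells)
    sig = sig - sig.mean()
    return LFPSignal(signal=sig, dt_sample=traces.dt_sample, cells=cells)


def spectrogram(
    signal: LFPSignal | np.ndarray,
    window_ms: float = 250.0,
    overlap_fraction: float = 0.8,
    dt_sample: float | None = None,
):
    """Short-time Fourier power of the signal.

    Returns (frequencies Hz, segment times s, power matrix f x t).  Hann
    window; frequency resolution 1 / window.
    """
    if isinstance(signal, LFPSignal):
        x = signal.signal
        fs = signal.fs
    else:
        if dt_sample is None:
            raise ValueError("dt_sample required for a bare array")
        x = np.asarray(signal, float)
        fs = 1000.0 / dt_sample
    nperseg = int(round(window_ms * fs / 1000.0))
    if nperseg > len(x):
        raise ValueError("window longer than signal")
    f, t, Sxx = scipy.signal.spectrogram(
        x,
        fs=fs,
        window="hann",
        nperseg=nperseg,
        noverlap=int(overlap_fraction * nperseg),
        detrend="constant",
        scaling="spectrum",
        mode="psd",
    )
    return f, t, Sxx


def oscillation_frequency(
    signal: LFPSignal | np.ndarray,
    band_hz: tuple[float, float] = (10.0, 80.0),
    dt_sample: float | None = None,
    window_ms: float = 500.0,
    min_peak_ratio: float = 2.0,
) -> float | None:
    """Frequency (Hz) of maximum average spectral power within a band.

    Returns None (no-oscillation flag) when the in-band peak does not rise
    above ``min_peak_ratio`` times the median in-band power.
    """
    if isinstance(signal, LFPSignal):
        x, fs = signal.signal, signal.fs
    else:
        if dt_sample is None:
            raise ValueError("dt_sample required for a bare array")
        x, fs = np.asarray(signal, float), 1000.0 / dt_sample
    if len(x) < fs:  # need >= 1 s of signal
        raise ValueError("need at least 1 s of signal")
    nperseg = min(len(x), int(round(window_ms * fs / 1000.0)))
    f, pxx = scipy.signal.welch(
        x, fs=fs, window="hann", nperseg=nperseg, detrend="constant"
    )
    lo, hi = band_hz
    sel = (f >= lo) & (f <= hi)
    if not np.any(sel):
        raise ValueError("band contains no frequency bins")
    p = pxx[sel]
    med = np.median(p)
    if med <= 0 or p.max() < min_peak_ratio * med:
        return None
    return float(f[sel][np.argmax(p)])


def rate_histogram(
    spike_data: SpikeData,
    cell_subset: Sequence[int],
    bin_ms: float,
    window: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Population rate per bin: spikes / time / number of cells (s^-1).

    Returns (bin edges ms, rates).
    """
    if window is None:
        window = (0.0, spike_data.duration)
    t0, t1 = window
    if bin_ms > t1 - t0:
        raise ValueError("bin longer than window")
    cell_subset = np.asarray(list(cell_subset))
    m = np.isin(spike_data.cell_ids, cell_subset)
    t = spike_data.times[m]
    t = t[(t >= t0) & (t < t1)]
    edges = np.arange(t0, t1 + bin_ms * 0.5, bin_ms)
    counts, _ = np.histogram(t, bins=edges)
    rates = counts / (bin_ms * 1e-3) / max(len(cell_subset), 1)
    return edges, rates
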