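import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from columnet.analysis import (
    LFPSignal,
    cv2,
    oscillation_frequency,
    population_cv2,
    rate_histogram,
    spectrogram,
    synthetic_lfp,
)
from columnet.engine import SpikeData, TraceData
from columnet.fixtures import poisson_train, regular_train


def spikes_from_trains(trains, duration):
    cells = np.concatenate([np.full(len(t), i) for i, t in enumerate(trains)])
    times = np.concatenate(trains)
    order = np.argsort(times, kind="stable")
    return SpikeData(cells[order], times[order], len(trains), duration)


class TestCV2:
    def test_regular_train_is_zero(self):
        assert cv2(regular_train(10.0, 5000.0)) == 0.0

    def test_hand_computed_sequence(self):
        # ISIs [10, 30, 10] -> pairwise CV2 values [1.0, 1.0] -> mean 1.0
        assert cv2(np.array([0.0, 10.0, 40.0, 50.0])) == pytest.approx(1.0)

    def test_formula_on_small_example(self):
        # ISIs [10, 20]: 2|20-10|/30 = 2/3
        assert cv2(np.array([0.0, 10.0, 30.0])) == pytest.approx(2.0 / 3.0)

    def test_short_train_rejected(self):
        with pytest.raises(ValueError):
            cv2(np.array([1.0, 2.0]))

    def test_poisson_train_is_one(self, rng):
        t = np.cumsum(rng.exponential(10.0, size=20_000))
        assert cv2(t) == pytest.approx(1.0, abs=0.02)

    @settings(max_examples=60, deadline=None)
    @given(st.lists(st.floats(1e-3, 1e3), min_size=2, max_size=50))
    def test_bounded_zero_to_two(self, isis):
        t = np.cumsum(np.asarray(isis))
        assert 0.0 <= cv2(np.concatenate([[0.0], t])) <= 2.0

    def test_rate_independence_under_thinning(self, rng):
        # thinning a Poisson train leaves a Poisson train: CV2 stays ~1
        t = np.cumsum(rng.exponential(5.0, size=40_000))
        thinned = t[rng.random(len(t)) < 0.1]
        assert cv2(thinned) == pytest.approx(1.0, abs=0.03)


class TestPopulationCV2:
    def test_regular_population(self):
        trains = [regular_train(8.0, 3000.0, t0=i) for i in range(5)]
        data = spikes_from_trains(trains, 3000.0)
        res = population_cv2(data, range(5))
        assert res.mean == pytest.approx(0.0)
        assert not res.excluded

    def test_poisson_population_near_one(self, rng):
        trains = [np.cumsum(rng.exponential(20.0, 3000)) for _ in range(8)]
        data = spikes_from_trains(trains, float(max(t[-1] for t in trains)) + 1)
        res = population_cv2(data, range(8))
        assert res.mean == pytest.approx(1.0, abs=0.05)

    def test_matches_bruteforce_recomputation(self, rng):
        trains = [np.sort(rng.uniform(0, 1000, rng.integers(5, 40)))
                  for _ in range(6)]
        data = spikes_from_trains(trains, 1000.0)
        res = population_cv2(data, range(6))
        # independent per-cell recomputation straight from the raw trains
        vals = []
        for t in trains:
            isi = np.diff(t)
            vals.append(np.mean(
                [2 * abs(isi[i + 1] - isi[i]) / (isi[i + 1] + isi[i])
                 for i in range(len(isi) - 1)]
            ))
        assert res.mean == pytest.approx(np.mean(vals))

    def test_short_trains_excluded_and_counted(self):
        trains = [regular_train(10.0, 2000.0), np.array([5.0, 10.0])]
        data = spikes_from_trains(trains, 2000.0)
        res = population_cv2(data, [0, 1])
        assert res.excluded == [1]
        assert res.mean == pytest.approx(0.0)

    def test_no_qualifying_cells_flagged_empty(self):
        data = spikes_from_trains([np.array([1.0])], 10.0)
        res = population_cv2(data, [0])
        assert res.empty


def traces_from_arrays(per_cell: dict, dt=1.0):
    series = {}
    for cid, comp_map in per_cell.items():
        for label, arr in comp_map.items():
            series[(cid, label, "V")] = np.asarray(arr, float)
    return TraceData(dt_sample=dt, series=series)


class TestSyntheticLFP:
    def test_uniform_resting_potential_gives_zero(self):
        n = 500
        tr = traces_from_arrays(
            {0: {"soma": np.full(n, -65.0), "apical1": np.full(n, -65.0)},
             1: {"soma": np.full(n, -65.0), "apical1": np.full(n, -65.0)}}
        )
        lfp = synthetic_lfp(tr, [0, 1])
        assert np.allclose(lfp.signal, 0.0)

    def test_signal_is_mean_subtracted(self, rng):
        n = 1000
        tr = traces_from_arrays(
            {0: {"soma": rng.normal(-60, 2, n), "apical1": rng.normal(-62, 2, n)}}
        )
        lfp = synthetic_lfp(tr, [0])
        assert abs(lfp.signal.mean()) < 1e-12

    def test_sinusoidal_dipole_peaks_at_drive_frequency(self):
        # 40 Hz sinusoidal soma-dendrite potential difference
        t = np.arange(0, 3000.0, 1.0)  # ms
        dip = 2.0 * np.sin(2 * np.pi * 40.0 * t / 1000.0)
        tr = traces_from_arrays(
            {0: {"soma": -60.0 + dip, "apical1": np.full(len(t), -60.0)}}
        )
        lfp = synthetic_lfp(tr, [0])
        assert oscillation_frequency(lfp, band_hz=(10, 80)) == pytest.approx(
            40.0, abs=2.5
        )

    def test_linearity_over_populations(self, rng):
        n = 400
        mk = lambda: {"soma": rng.normal(-60, 1, n), "apical1": rng.normal(-61, 1, n)}
        tr = traces_from_arrays({0: mk(), 1: mk(), 2: mk()})
        raw = lambda cells: np.mean(
            [tr.get(c, "soma") - tr.get(c, "apical1") for c in cells], axis=0
        )
        union = raw([0, 1, 2])
        weighted = (2 * raw([0, 1]) + 1 * raw([2])) / 3
        assert union == pytest.approx(weighted)

    def test_missing_compartment_is_data_error(self):
        tr = traces_from_arrays({0: {"soma": np.zeros(10)}})
        with pytest.raises(KeyError):
            synthetic_lfp(tr, [0])


class TestSpectralTools:
    def test_pure_tone_dominates_every_slice(self):
        t = np.arange(0, 4000.0, 1.0)
        sig = np.sin(2 * np.pi * 20.0 * t / 1000.0)
        f, ts, S = spectrogram(sig, window_ms=250, overlap_fraction=0.8,
                               dt_sample=1.0)
        peak = f[np.argmax(S, axis=0)]
        assert np.all(np.abs(peak - 20.0) <= 4.0)

    def test_parseval_power_equals_variance(self, rng):
        # total spectral power per slice equals the time-domain variance of
        # the segment, corrected for the Hann window's incoherent gain
        import scipy.signal

        sig = rng.normal(0, 1.0, 5000)
        f, ts, S = spectrogram(sig, window_ms=500, overlap_fraction=0.0,
                               dt_sample=1.0)
        w = scipy.signal.get_window("hann", 500)
        gain = len(w) * np.sum(w**2) / np.sum(w) ** 2
        total = S.sum(axis=0)
        assert np.mean(total) == pytest.approx(np.var(sig) * gain, rel=0.05)

    def test_window_longer_than_signal_rejected(self):
        with pytest.raises(ValueError):
            spectrogram(np.zeros(100), window_ms=250, dt_sample=1.0)

    def test_oscillation_frequency_simple_and_mixture(self):
        t = np.arange(0, 5000.0, 1.0)
        s20 = np.sin(2 * np.pi * 20 * t / 1000)
        assert oscillation_frequency(s20, dt_sample=1.0) == pytest.approx(20, abs=2)
        mix = 2 * s20 + 1 * np.sin(2 * np.pi * 45 * t / 1000)
        assert oscillation_frequency(mix, dt_sample=1.0) == pytest.approx(20, abs=2)

    def test_flat_spectrum_flags_no_oscillation(self, rng):
        sig = rng.normal(0, 1, 60_000)
        assert oscillation_frequency(sig, dt_sample=1.0, window_ms=2000) is None


class TestRateHistogram:
    def test_empty_spike_set(self):
        data = SpikeData(np.zeros(0, int), np.zeros(0), 5, 1000.0)
        edges, rates = rate_histogram(data, range(5), bin_ms=100.0)
        assert np.all(rates == 0)
        assert len(rates) == len(edges) - 1

    def test_homogeneous_poisson_mean_rate(self, rng):
        r, n, T = 20.0, 20, 20_000.0
        trains = [poisson_train(r, T, rng) for _ in range(n)]
        data = spikes_from_trains(trains, T)
        _, rates = rate_histogram(data, range(n), bin_ms=200.0)
        assert rates.mean() == pytest.approx(r, rel=0.05)

    def test_bin_longer_than_window_rejected(self):
        data = SpikeData(np.zeros(0, int), np.zeros(0), 1, 100.0)
        with pytest.raises(ValueError):
            rate_histogram(data, [0], bin_ms=500.0)
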