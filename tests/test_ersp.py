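"""ERSP / ERD module: preprocessing, epoching, spectral power, the index."""

import numpy as np
import pytest

from neurobalance import ersp
from neurobalance.recordings import EEGRecording, Event, TrialTiming
from neurobalance.synthetic import simulate_eeg_trials


def make_recording(x: np.ndarray, fs: float, events=()) -> EEGRecording:
    return EEGRecording(x[np.newaxis], fs, ["Cz"], list(events))


def direct_dft_ersp(data: np.ndarray, fs: float, win_s: float = 0.5,
                    hop_divisor: int = 16) -> np.ndarray:
    """Brute-force oracle: windowed DFT magnitudes squared from the definition.

    For each trial and frame start s, F[f] = sum_m x[s+m] w[m] e^{-2 pi i f m / M};
    the surface is the mean over trials of |F|^2.
    """
    n_trials, n_times = data.shape
    M = int(round(win_s * fs))
    hop = max(1, M // hop_divisor)
    w = 0.5 - 0.5 * np.cos(2 * np.pi * np.arange(M) / M)  # periodic Hann
    starts = range(0, n_times - M + 1, hop)
    n_freqs = M // 2 + 1
    out = np.zeros((n_freqs, len(starts)))
    for k in range(n_trials):
        for j, s in enumerate(starts):
            seg = data[k, s : s + M] * w
            for fi in range(n_freqs):
                F = np.sum(seg * np.exp(-2j * np.pi * fi * np.arange(M) / M))
                out[fi, j] += np.abs(F) ** 2
    return out / n_trials


class TestPreprocess:
    def test_dc_rejected_sine_passed_length_quartered(self):
        # 0.05 Hz high-pass edge -> tens-of-seconds transient, so judge the
        # steady state of a long recording away from the edges
        fs = 1024.0
        t = np.arange(int(80 * fs)) / fs
        rec = make_recording(np.ones_like(t) + np.sin(2 * np.pi * 10 * t), fs)
        out = ersp.preprocess(rec)
        assert out.fs == 256.0
        assert abs(out.n_samples - rec.n_samples // 4) <= 1
        skip = int(20 * out.fs)
        interior = out.samples[0][skip:-skip]
        # DC (outside 0.05-35 Hz) suppressed; the 10 Hz component survives
        assert np.abs(interior.mean()) < 0.05
        amp = np.sqrt(2) * (interior - interior.mean()).std()
        assert amp == pytest.approx(1.0, rel=0.05)

    def test_band_above_output_nyquist_rejected(self):
        rec = make_recording(np.zeros(4096), 1024.0)
        with pytest.raises(ValueError, match="Nyquist"):
            ersp.preprocess(rec, band=(0.05, 200.0), fs_out=256.0)

    def test_non_integer_ratio_resamples_with_warning(self, caplog):
        fs = 1000.0
        rec = make_recording(np.sin(2 * np.pi * 5 * np.arange(8000) / fs), fs)
        with caplog.at_level("WARNING", logger="neurobalance.ersp"):
            out = ersp.preprocess(rec, fs_out=256.0)
        assert out.fs == 256.0
        assert any("non-integer" in r.message for r in caplog.records)


class TestEpoch:
    def test_all_events_fit(self):
        fs = 100.0
        events = [Event(2.0 + 7 * k, 5.5, "move") for k in range(10)]
        rec = make_recording(np.zeros(int(fs * 75)), fs, events)
        ep = ersp.epoch(rec, window=(-1.0, 5.0))
        assert ep.n_trials == 10
        assert ep.n_times == 600
        assert ep.t0_index == 100

    def test_ramp_rows_are_verbatim_slices(self):
        fs = 100.0
        x = np.arange(int(fs * 20)) / fs  # x(t) = t
        rec = make_recording(x, fs, [Event(5.0, 1.0, "move")])
        ep = ersp.epoch(rec, window=(-1.0, 5.0))
        np.testing.assert_allclose(ep.data[0], x[400:1000])
        # first sample is the ramp at onset + window start
        assert ep.data[0, 0] == pytest.approx(4.0)

    def test_edge_event_dropped_with_count(self, caplog):
        fs = 100.0
        events = [Event(2.0 + 7 * k, 5.5, "move") for k in range(9)]
        events.append(Event(69.5, 5.5, "move"))  # 0.5 s from the end
        rec = make_recording(np.zeros(int(fs * 70)), fs, events)
        with caplog.at_level("WARNING", logger="neurobalance.ersp"):
            ep = ersp.epoch(rec, window=(-1.0, 5.0))
        assert ep.n_trials == 9
        assert ep.n_dropped == 1


class TestComputeErsp:
    def test_zero_epochs_give_zero_power(self):
        ep = ersp.Epochs(np.zeros((3, 512)), 256.0, (-1.0, 1.0), "Cz")
        grid = ersp.compute_ersp(ep)
        assert np.all(grid.power == 0)

    def test_identical_trials_equal_single_trial(self, rng):
        x = rng.standard_normal(512)
        single = ersp.compute_ersp(
            ersp.Epochs(x[np.newaxis], 256.0, (-1.0, 1.0), "Cz"))
        triple = ersp.compute_ersp(
            ersp.Epochs(np.tile(x, (3, 1)), 256.0, (-1.0, 1.0), "Cz"))
        np.testing.assert_allclose(triple.power, single.power, rtol=1e-12)

    def test_matches_direct_dft_oracle(self, rng):
        """Trial-mean STFT power equals the brute-force windowed DFT."""
        data = rng.standard_normal((2, 512))
        ep = ersp.Epochs(data, 256.0, (-1.0, 1.0), "Cz")
        grid = ersp.compute_ersp(ep)
        oracle = direct_dft_ersp(data, 256.0)
        np.testing.assert_allclose(grid.power, oracle,
                                   rtol=1e-10, atol=1e-10 * oracle.max())

    def test_trial_count_weighted_concatenation(self, rng):
        """ERSP of concatenated trial sets is the count-weighted mean."""
        a = rng.standard_normal((2, 512))
        b = rng.standard_normal((3, 512))
        mk = lambda d: ersp.compute_ersp(
            ersp.Epochs(d, 256.0, (-1.0, 1.0), "Cz"))
        combined = mk(np.vstack([a, b])).power
        weighted = (2 * mk(a).power + 3 * mk(b).power) / 5
        np.testing.assert_allclose(combined, weighted, rtol=1e-12)

    def test_frequency_above_nyquist_rejected(self):
        ep = ersp.Epochs(np.zeros((1, 512)), 256.0, (-1.0, 1.0), "Cz")
        with pytest.raises(ValueError, match="Nyquist"):
            ersp.compute_ersp(ep, freqs=np.array([200.0]))

    def test_morlet_alternative_runs(self, rng):
        ep = ersp.Epochs(rng.standard_normal((2, 512)), 256.0,
                         (-1.0, 1.0), "Cz")
        grid = ersp.compute_ersp(ep, freqs=np.arange(10.0, 30.0, 2.0),
                                 method="morlet")
        assert grid.power.shape[0] == 10
        assert np.all(grid.power >= 0)


def toy_grid(power: np.ndarray, times: np.ndarray) -> ersp.ERSPGrid:
    power = np.atleast_2d(power)
    return ersp.ERSPGrid(power, np.arange(power.shape[0], dtype=float) + 10.0,
                         times, n_trials=1)


class TestBaselineNormalize:
    def test_hand_example(self):
        """Baseline bins (2, 4) -> baseline 3; task bins (5, 1) -> (2, -2)."""
        grid = toy_grid(np.array([2.0, 4.0, 5.0, 1.0]),
                        np.array([-0.8, -0.3, 0.2, 0.7]))
        out = ersp.baseline_normalize(grid, baseline_window=(-1.0, 0.0))
        np.testing.assert_allclose(out.power[0], [-1.0, 1.0, 2.0, -2.0])
        np.testing.assert_allclose(out.baseline_per_freq, [3.0])
        assert out.n_baseline_bins == 2

    def test_constant_grid_normalizes_to_zero(self):
        grid = toy_grid(np.full((3, 8), 7.5), np.linspace(-1, 1, 8))
        out = ersp.baseline_normalize(grid)
        np.testing.assert_allclose(out.power, 0.0)

    def test_baseline_mean_identically_zero(self, rng):
        """Per-frequency mean over baseline bins is 0 for arbitrary grids."""
        for _ in range(100):
            nf, nt = rng.integers(1, 12), rng.integers(4, 40)
            times = np.sort(rng.uniform(-1.0, 2.0, nt))
            grid = ersp.ERSPGrid(rng.uniform(0, 100, (nf, nt)),
                                 rng.uniform(1, 40, nf), times, n_trials=1)
            lo = rng.uniform(-1.0, 0.5)
            hi = lo + rng.uniform(0.1, 1.0)
            mask = (times >= lo) & (times < hi)
            if not mask.any():
                continue
            out = ersp.baseline_normalize(grid, baseline_window=(lo, hi))
            resid = out.power[:, mask].mean(axis=1)
            assert np.max(np.abs(resid)) < 1e-12 * max(grid.power.max(), 1.0)

    def test_double_normalization_rejected(self):
        grid = toy_grid(np.ones(4), np.array([-0.8, -0.3, 0.2, 0.7]))
        out = ersp.baseline_normalize(grid)
        with pytest.raises(ValueError, match="already"):
            ersp.baseline_normalize(out)

    def test_empty_baseline_rejected(self):
        grid = toy_grid(np.ones(4), np.array([0.2, 0.4, 0.6, 0.8]))
        with pytest.raises(ValueError, match="no time bins"):
            ersp.baseline_normalize(grid, baseline_window=(-1.0, 0.0))


class TestErdIndex:
    def normalized_grid(self, values, freqs, times):
        grid = ersp.ERSPGrid(np.asarray(values, dtype=float),
                             np.asarray(freqs, dtype=float),
                             np.asarray(times, dtype=float),
                             n_trials=1, normalized=True)
        return grid

    def test_mean_of_negative_bins_only(self):
        grid = self.normalized_grid([[-2.0, -1.0, 0.5, 1.0]], [18.0],
                                    [0.1, 0.3, 0.5, 0.7])
        idx = ersp.erd_index(grid)
        assert idx.value == pytest.approx(-1.5)
        assert idx.n_negative_bins == 2
        assert not idx.empty_flag

    def test_all_positive_sets_empty_flag(self):
        grid = self.normalized_grid([[0.5, 1.0]], [18.0], [0.1, 0.5])
        idx = ersp.erd_index(grid)
        assert idx.value == 0.0
        assert idx.empty_flag

    def test_empty_rectangle_rejected(self):
        grid = self.normalized_grid([[-1.0]], [40.0], [0.5])
        with pytest.raises(ValueError, match="no bins"):
            ersp.erd_index(grid, band=(15.0, 23.0))

    def test_unnormalized_grid_rejected(self):
        grid = ersp.ERSPGrid(np.ones((1, 4)), [18.0],
                             [0.1, 0.3, 0.5, 0.7], n_trials=1)
        with pytest.raises(ValueError, match="normalized"):
            ersp.erd_index(grid)


class TestSimulatedErdChain:
    def chain(self, depth: float, seed: int = 11) -> float:
        rec = simulate_eeg_trials(TrialTiming(), n_trials=30, fs=256.0,
                                  erd_depth=depth, seed=seed)
        ep = ersp.epoch(rec)
        grid = ersp.baseline_normalize(ersp.compute_ersp(ep))
        return ersp.erd_index(grid).value

    def test_injected_desynchronization_is_detected(self):
        assert self.chain(0.5) < 0

    def test_deeper_suppression_gives_lower_index(self):
        shallow, deep = self.chain(0.2), self.chain(0.8)
        assert deep < shallow < 0
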