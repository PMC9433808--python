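"""Hemoglobin features: filtering, epoching, averaging, scalar summaries."""

import numpy as np
import pytest
from scipy import signal

from neurobalance import fnirs
from neurobalance.recordings import Event, FNIRSRecording, TrialTiming
from neurobalance.synthetic import (
    NoiseSpec,
    SENSORIMOTOR_CHANNELS,
    double_gamma_hrf,
    simulate_fnirs_session,
)


def sinusoid_recording(freq: float, fs: float = 20.0,
                       duration_s: float = 400.0) -> FNIRSRecording:
    t = np.arange(int(duration_s * fs)) / fs
    x = np.sin(2 * np.pi * freq * t)[np.newaxis]
    return FNIRSRecording(x, -x / 3, fs, ["S1-D1"])


class TestBandpassHemo:
    def test_cardiac_component_suppressed(self):
        out = fnirs.bandpass_hemo(sinusoid_recording(1.1))
        interior = out.hbo[0][2000:-2000]
        assert np.sqrt(2) * interior.std() < 0.05

    def test_hemodynamic_band_passed(self):
        out = fnirs.bandpass_hemo(sinusoid_recording(0.05))
        interior = out.hbo[0][2000:-2000]
        assert np.sqrt(2) * interior.std() == pytest.approx(1.0, rel=0.10)

    def test_zero_input_zero_output(self):
        rec = FNIRSRecording(np.zeros((2, 8000)), np.zeros((2, 8000)), 20.0,
                             ["S1-D1", "S1-D2"])
        out = fnirs.bandpass_hemo(rec)
        assert np.all(out.hbo == 0) and np.all(out.hbr == 0)

    def test_short_recording_rejected(self):
        rec = FNIRSRecording(np.zeros((1, 200)), np.zeros((1, 200)), 20.0,
                             ["S1-D1"])
        with pytest.raises(ValueError, match="time constants"):
            fnirs.bandpass_hemo(rec)


def step_recording(n_ch: int = 2, fs: float = 10.0) -> FNIRSRecording:
    """Baseline level 2, task level 5 from onset at t = 20 s."""
    n = int(60 * fs)
    x = np.full((n_ch, n), 2.0)
    x[:, int(20 * fs):] = 5.0
    names = [f"S1-D{i + 1}" for i in range(n_ch)]
    return FNIRSRecording(x, -x / 3, fs, names, [Event(20.0, 5.5, "move")])


class TestEpochAndCorrect:
    def test_constant_channel_corrects_to_zero(self):
        n = 1200
        rec = FNIRSRecording(np.full((1, n), 3.3), np.full((1, n), -1.1),
                             10.0, ["S1-D1"], [Event(60.0, 5.5, "move")])
        ep = fnirs.epoch_and_correct(rec, channels=("S1-D1",))
        np.testing.assert_allclose(ep.hbo, 0.0, atol=1e-12)
        np.testing.assert_allclose(ep.hbt, 0.0, atol=1e-12)

    def test_step_baseline_subtraction(self):
        rec = step_recording()
        ep = fnirs.epoch_and_correct(rec, channels=("S1-D1", "S1-D2"))
        # baseline mean 2 subtracted: task samples read 3.0
        assert ep.hbo[0, 0, -1] == pytest.approx(3.0)
        b0, b1 = 0, int(2 * rec.fs)
        np.testing.assert_allclose(ep.hbo[:, :, b0:b1].mean(axis=2), 0.0,
                                   atol=1e-12)

    def test_shapes_and_zero_mean_baselines(self):
        rec = simulate_fnirs_session(n_trials=12, seed=4, lead_in_s=3.0)
        ep = fnirs.epoch_and_correct(rec)
        n_win = int(round(12.0 * rec.fs))
        assert ep.hbo.shape == (8, 12, n_win)
        assert ep.channels_used == list(SENSORIMOTOR_CHANNELS)
        b1 = int(2 * rec.fs)
        np.testing.assert_allclose(ep.hbo[:, :, :b1].mean(axis=2), 0.0,
                                   atol=1e-12)
        np.testing.assert_allclose(ep.hbt, ep.hbo + ep.hbr, atol=1e-12)

    def test_missing_channel_named(self):
        rec = step_recording()
        with pytest.raises(KeyError, match="S7-D5"):
            fnirs.epoch_and_correct(rec, channels=("S1-D1", "S7-D5"))

    def test_edge_trial_dropped(self, caplog):
        rec = step_recording()
        rec.events.append(Event(58.0, 5.5, "move"))  # needs data to 68 s
        with caplog.at_level("WARNING", logger="neurobalance.fnirs"):
            ep = fnirs.epoch_and_correct(rec, channels=("S1-D1", "S1-D2"))
        assert ep.n_trials == 1
        assert ep.n_dropped == 1


class TestAverageCurve:
    def two_trial_epochs(self, a: float, b: float) -> fnirs.HemoEpochs:
        n = 40
        hbo = np.stack([np.full((2, n), a), np.full((2, n), b)], axis=1)
        hbo -= hbo[:, :, :10].mean(axis=2, keepdims=True)  # zero baseline
        return fnirs.HemoEpochs(hbo, -hbo / 3, hbo * 2 / 3, 10.0,
                                (-1.0, 3.0), (-1.0, 0.0), ["S1-D1", "S1-D2"])

    def test_identical_trials_equal_single_trial(self):
        ep = self.two_trial_epochs(1.0, 1.0)
        curves = fnirs.average_curve(ep)
        np.testing.assert_allclose(curves.hbo, ep.hbo[0, 0], atol=1e-12)

    def test_opposite_trials_cancel(self):
        n = 40
        trial = np.linspace(0, 1, n)
        hbo = np.stack([np.tile(trial, (2, 1)), np.tile(-trial, (2, 1))],
                       axis=1)
        ep = fnirs.HemoEpochs(hbo, -hbo / 3, hbo * 2 / 3, 10.0,
                              (-1.0, 3.0), (-1.0, 0.0), ["S1-D1", "S1-D2"])
        np.testing.assert_allclose(fnirs.average_curve(ep).hbo, 0.0,
                                   atol=1e-12)

    def test_noiseless_session_recovers_generative_response(self):
        """Averaged HBO matches the HRF (x) movement-boxcar to < 1% of peak.

        Long rests keep successive hemodynamic responses from overlapping,
        so each epoch sees one isolated response over a flat baseline.
        """
        timing = TrialTiming(rest_s=35.0)
        fs = 20.0
        rec = simulate_fnirs_session(timing, n_trials=5, fs=fs,
                                     amplitude_hbo=1.0,
                                     noise=NoiseSpec.quiet(), seed=0,
                                     lead_in_s=5.0)
        ep = fnirs.epoch_and_correct(rec, window=(-2.0, 10.0))
        curves = fnirs.average_curve(ep)
        # oracle: double-gamma HRF convolved with the 5.5 s boxcar
        t_k = np.arange(0, 32.0, 1.0 / fs)
        box = np.zeros(ep.hbo.shape[2])
        rel = curves.times
        box[(rel >= 0) & (rel < timing.movement_s)] = 1.0
        oracle = signal.fftconvolve(box, double_gamma_hrf(t_k))[: rel.size]
        oracle = oracle / oracle.max()  # peak normalised like the simulator
        peak = curves.hbo.max()
        # compare over the epoch window (oracle peak lies inside 0-10 s)
        assert np.max(np.abs(curves.hbo / peak - oracle / oracle.max())) < 0.02
        assert np.max(np.abs(curves.hbo - oracle)) < 0.01 * max(peak, 1.0)


class TestHboScalar:
    def triangle_curves(self) -> fnirs.AverageCurves:
        fs = 10.0
        times = np.linspace(-2.0, 10.0, 121)
        hbo = np.where(times < 0, 0.0,
                       np.where(times <= 5, 0.4 * times, 4 - 0.4 * times))
        return fnirs.AverageCurves(times, hbo, -hbo / 3, hbo * 2 / 3, fs)

    def test_triangle_peak_and_area(self):
        curves = self.triangle_curves()
        assert fnirs.hbo_scalar(curves, "peak") == pytest.approx(2.0)
        assert fnirs.hbo_scalar(curves, "area") == pytest.approx(10.0)

    def test_flat_curve_zero_features(self):
        c = self.triangle_curves()
        flat = fnirs.AverageCurves(c.times, np.zeros_like(c.hbo), c.hbr,
                                   c.hbt, c.fs)
        assert fnirs.hbo_scalar(flat, "peak") == 0.0
        assert fnirs.hbo_scalar(flat, "area") == 0.0

    def test_features_scale_linearly(self):
        c = self.triangle_curves()
        scaled = fnirs.AverageCurves(c.times, 3.5 * c.hbo, c.hbr, c.hbt, c.fs)
        assert fnirs.hbo_scalar(scaled, "peak") == pytest.approx(
            3.5 * fnirs.hbo_scalar(c, "peak"))
        assert fnirs.hbo_scalar(scaled, "area") == pytest.approx(
            3.5 * fnirs.hbo_scalar(c, "area"))

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            fnirs.hbo_scalar(self.triangle_curves(), "median")

    def test_signed_vs_absolute_area(self):
        c = self.triangle_curves()
        dipped = fnirs.AverageCurves(c.times, c.hbo - 1.0, c.hbr, c.hbt, c.fs)
        signed = fnirs.hbo_scalar(dipped, "area")
        absolute = fnirs.hbo_scalar(dipped, "area", absolute_area=True)
        assert absolute > signed


class TestGenerativeRecovery:
    def test_peak_proportional_to_amplitude(self):
        """Feature chain is 1-homogeneous in the simulated response amplitude."""
        amplitudes = np.array([0.5, 1.0, 1.5, 2.0, 2.5])
        peaks = []
        for amp in amplitudes:
            rec = simulate_fnirs_session(n_trials=8, amplitude_hbo=amp,
                                         noise=NoiseSpec.quiet(), seed=0)
            ep = fnirs.epoch_and_correct(rec)
            peaks.append(fnirs.hbo_scalar(fnirs.average_curve(ep), "peak"))
        r = np.corrcoef(amplitudes, peaks)[0, 1]
        assert r**2 > 0.999
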