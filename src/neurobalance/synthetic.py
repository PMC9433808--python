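"""Synthetic EEG, fNIRS and cohort generators with known ground truth.

Every generator is a pure function of its arguments including ``seed``, so
downstream stages can be tested against the generative parameters:

* :func:`simulate_eeg_trials` — 1/f background plus a band-limited
  oscillation whose amplitude drops by a known factor during dynamic
  dorsiflexion (the event-related desynchronization the ERD index measures).
* :func:`simulate_phase_coupled_pair` — two carriers whose per-sample phase
  difference is Gaussian with a chosen sd sigma; the phase synchronization
  index of such a pair is exp(-sigma^2 / 2), the resultant length of a
  wrapped Gaussian.
* :func:`simulate_fnirs_session` — canonical double-gamma hemodynamic
  response convolved with the movement boxcar, plus sinusoidal physiological
  noise (cardiac / respiratory / Mayer waves), drift and white noise.
* :func:`simulate_cohort` — feature tables drawn from the linear model
  BBS = b0 + b1*ERD + b2*HBO + b3*AGE + b4*HBO^2 + noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal, special
from scipy.ndimage import gaussian_filter1d

from .recordings import EEGRecording, Event, FNIRSRecording, TrialTiming

__all__ = [
    "NoiseSpec",
    "CohortSpec",
    "FNIRS_CHANNELS_22",
    "SENSORIMOTOR_CHANNELS",
    "simulate_eeg_trials",
    "simulate_phase_coupled_pair",
    "phase_jitter_process",
    "simulate_fnirs_session",
    "simulate_cohort",
    "double_gamma_hrf",
]

#: The 8 source-detector channels over the sensorimotor leg area whose
#: hemoglobin traces are averaged into the HBO feature.
SENSORIMOTOR_CHANNELS: tuple[str, ...] = (
    "S2-D4", "S2-D2", "S7-D2", "S7-D4", "S7-D7", "S7-D5", "S5-D7", "S5-D5",
)

#: A 22-channel montage containing the sensorimotor subset.
FNIRS_CHANNELS_22: tuple[str, ...] = SENSORIMOTOR_CHANNELS + (
    "S1-D1", "S1-D2", "S2-D1", "S3-D3", "S3-D4", "S4-D3", "S4-D5",
    "S5-D6", "S6-D6", "S6-D7", "S6-D8", "S7-D8", "S8-D5", "S8-D8",
)

EVENT_LABEL = "dorsiflexion"


def _pink_noise(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """Gaussian noise with 1/f power spectrum, unit variance."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    f[0] = f[1]  # avoid the DC singularity
    spec /= np.sqrt(f)
    x = np.fft.irfft(spec, n)
    return x / np.std(x)


def _narrowband_noise(
    rng: np.random.Generator, n: int, fs: float, band: tuple[float, float]
) -> np.ndarray:
    """Band-limited Gaussian oscillation, unit variance."""
    pad = int(2 * fs)
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n + 2 * pad))[pad:-pad]
    return x / np.std(x)


def _check_band(band: tuple[float, float], fs: float) -> None:
    lo, hi = band
    if not (0 < lo < hi):
        raise ValueError(f"band must satisfy 0 < low < high, got {band}")
    if hi >= fs / 2:
        raise ValueError(
            f"band high edge {hi} Hz must be below the Nyquist frequency "
            f"{fs / 2} Hz"
        )


def simulate_eeg_trials(
    timing: TrialTiming | None = None,
    n_trials: int = 50,
    fs: float = 1024.0,
    erd_depth: float = 0.5,
    erd_band: tuple[float, float] = (15.0, 23.0),
    seed: int = 0,
    channel_names: tuple[str, ...] = ("Cz",),
    background_rms_uv: float = 10.0,
    oscillation_rms_uv: float = 6.0,
    lead_in_s: float = 0.0,
) -> EEGRecording:
    """Simulate trials of ankle dorsiflexion EEG with injected beta ERD.

    Each channel is 1/f background noise plus an ongoing oscillation inside
    ``erd_band`` whose amplitude is multiplied by ``(1 - erd_depth)`` from
    movement onset to the end of the dynamic phase, then ramps linearly back
    to baseline over the static hold (recovered by the rest phase).

    Parameters
    ----------
    erd_depth : float in [0, 1]
        Fractional amplitude suppression of the oscillation during dynamic
        dorsiflexion. 0 means no event-related change.
    lead_in_s : float
        Quiet recording before the first trial starts.
    """
    timing = timing or TrialTiming()
    if not 0.0 <= erd_depth <= 1.0:
        raise ValueError(f"erd_depth must be within [0, 1], got {erd_depth}")
    _check_band(erd_band, fs)

    n = int(round((lead_in_s + n_trials * timing.total_s) * fs))
    t = np.arange(n) / fs
    onsets = timing.onsets(n_trials, lead_in_s)

    # amplitude envelope of the oscillation: 1 at rest, (1 - depth) during
    # dynamic dorsiflexion, linear recovery across the static hold
    envelope = np.ones(n)
    for onset in onsets:
        dyn0, dyn1 = onset, onset + timing.dynamic_s
        stat1 = dyn1 + timing.static_s
        mask_dyn = (t >= dyn0) & (t < dyn1)
        envelope[mask_dyn] = 1.0 - erd_depth
        mask_stat = (t >= dyn1) & (t < stat1)
        frac = (t[mask_stat] - dyn1) / timing.static_s
        envelope[mask_stat] = (1.0 - erd_depth) + erd_depth * frac

    rng = np.random.default_rng(seed)
    samples = np.empty((len(channel_names), n))
    for i in range(len(channel_names)):
        background = background_rms_uv * _pink_noise(rng, n, fs)
        osc = oscillation_rms_uv * _narrowband_noise(rng, n, fs, erd_band)
        samples[i] = background + envelope * osc

    events = [Event(float(o), timing.movement_s, EVENT_LABEL) for o in onsets]
    return EEGRecording(samples, fs, list(channel_names), events)


def phase_jitter_process(
    n_samples: int,
    phase_jitter_sd: float,
    fs: float,
    jitter_corr_s: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Smooth Gaussian process with exact marginal sd ``phase_jitter_sd``.

    Gaussian-kernel-smoothed white noise rescaled to the requested sd;
    the correlation time keeps the phase modulation slow enough for
    Hilbert-phase extraction while the marginal stays Gaussian, so the
    resultant length of the process is exp(-sd^2 / 2).
    """
    if phase_jitter_sd == 0:
        return np.zeros(n_samples)
    sigma_samp = max(jitter_corr_s * fs, 1.0)
    pad = int(10 * sigma_samp)
    raw = gaussian_filter1d(rng.standard_normal(n_samples + 2 * pad),
                            sigma_samp)
    delta = raw[pad:-pad]
    return delta / np.std(delta) * phase_jitter_sd


def simulate_phase_coupled_pair(
    n_samples: int,
    carrier_hz: float = 10.0,
    fs: float = 250.0,
    phase_jitter_sd: float = 0.5,
    seed: int = 0,
    jitter_corr_s: float = 0.1,
    channel_names: tuple[str, str] = ("C3", "C4"),
) -> EEGRecording:
    """Two sinusoidal channels with a controlled phase-difference spread.

    The per-sample phase difference between the channels is Gaussian with
    standard deviation ``phase_jitter_sd``, realised as a smooth Gaussian
    process (correlation time ``jitter_corr_s``) so that the instantaneous
    phase survives Hilbert-transform extraction. The population phase
    synchronization index of the pair is ``exp(-phase_jitter_sd**2 / 2)``,
    the resultant length of the wrapped Gaussian.
    """
    if n_samples < 16:
        raise ValueError(
            f"n_samples={n_samples} too small for a stable Hilbert phase "
            "(need >= 16)"
        )
    if phase_jitter_sd < 0:
        raise ValueError(f"phase_jitter_sd must be >= 0, got {phase_jitter_sd}")
    if carrier_hz >= fs / 2:
        raise ValueError(
            f"carrier {carrier_hz} Hz must be below the Nyquist frequency "
            f"{fs / 2} Hz"
        )

    rng = np.random.default_rng(seed)
    t = np.arange(n_samples) / fs
    delta = phase_jitter_process(n_samples, phase_jitter_sd, fs,
                                 jitter_corr_s, rng)
    common = 2 * np.pi * carrier_hz * t
    x = np.cos(common)
    y = np.cos(common - delta)
    return EEGRecording(np.vstack([x, y]), fs, list(channel_names), [])


def double_gamma_hrf(t: np.ndarray) -> np.ndarray:
    """Canonical double-gamma hemodynamic response function.

    Peak at ~6 s, undershoot at ~16 s, undershoot-to-peak ratio 1/6
    (the standard SPM/Glover parameterisation); unit peak amplitude.
    """
    t = np.asarray(t, dtype=float)
    h = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    peak = tp**5 * np.exp(-tp) / special.gamma(6)
    under = tp**15 * np.exp(-tp) / special.gamma(16)
    h[pos] = peak - under / 6.0
    return h / h.max() if h.max() > 0 else h


@dataclass(frozen=True)
class NoiseSpec:
    """Physiological noise model for fNIRS: three sinusoids + drift + white.

    Frequencies are the standard physiology: cardiac ~1.1 Hz, respiration
    ~0.25 Hz, Mayer waves ~0.1 Hz. Amplitudes are micromolar; drift is
    micromolar per second. Phases are randomised per channel.
    """

    cardiac_hz: float = 1.1
    resp_hz: float = 0.25
    mayer_hz: float = 0.1
    cardiac_amp: float = 0.10
    resp_amp: float = 0.10
    mayer_amp: float = 0.05
    drift_slope: float = 0.001
    white_sd: float = 0.05

    @classmethod
    def quiet(cls) -> "NoiseSpec":
        """All noise amplitudes zero (frequencies kept for validation)."""
        return cls(cardiac_amp=0.0, resp_amp=0.0, mayer_amp=0.0,
                   drift_slope=0.0, white_sd=0.0)


def simulate_fnirs_session(
    timing: TrialTiming | None = None,
    n_trials: int = 20,
    fs: float = 20.0,
    amplitude_hbo: float = 1.0,
    noise: NoiseSpec | None = None,
    seed: int = 0,
    channel_names: tuple[str, ...] = FNIRS_CHANNELS_22,
    active_channels: tuple[str, ...] = SENSORIMOTOR_CHANNELS,
    lead_in_s: float = 5.0,
) -> FNIRSRecording:
    """Simulate an fNIRS session of repeated ankle dorsiflexion.

    HBO on the active channels is the double-gamma HRF convolved with a
    boxcar spanning onset to onset + dynamic + static (the 5.5 s movement),
    scaled so its peak is ``amplitude_hbo``. HBR is the negative mirror at
    one third of the HBO amplitude — the conventional deoxygenation ratio —
    with its own independent noise. Non-active channels carry noise only.
    """
    timing = timing or TrialTiming()
    noise = NoiseSpec() if noise is None else noise
    if amplitude_hbo < 0:
        raise ValueError(f"amplitude_hbo must be >= 0, got {amplitude_hbo}")
    if fs <= 2 * noise.cardiac_hz:
        raise ValueError(
            f"fs={fs} Hz aliases the cardiac component: need fs > "
            f"2 x {noise.cardiac_hz} Hz"
        )
    missing = set(active_channels) - set(channel_names)
    if missing:
        raise ValueError(f"active channels not in montage: {sorted(missing)}")

    n = int(round((lead_in_s + n_trials * timing.total_s) * fs))
    t = np.arange(n) / fs
    onsets = timing.onsets(n_trials, lead_in_s)

    boxcar = np.zeros(n)
    for onset in onsets:
        boxcar[(t >= onset) & (t < onset + timing.movement_s)] = 1.0
    hrf = double_gamma_hrf(np.arange(0, 32.0, 1.0 / fs))
    response = signal.fftconvolve(boxcar, hrf)[:n]
    peak = response.max()
    if peak > 0:
        response = response / peak * amplitude_hbo

    rng = np.random.default_rng(seed)

    def channel_noise() -> np.ndarray:
        phases = rng.uniform(0, 2 * np.pi, size=3)
        out = (
            noise.cardiac_amp * np.sin(2 * np.pi * noise.cardiac_hz * t + phases[0])
            + noise.resp_amp * np.sin(2 * np.pi * noise.resp_hz * t + phases[1])
            + noise.mayer_amp * np.sin(2 * np.pi * noise.mayer_hz * t + phases[2])
            + noise.drift_slope * t
        )
        if noise.white_sd > 0:
            out = out + noise.white_sd * rng.standard_normal(n)
        return out

    active = set(active_channels)
    hbo = np.empty((len(channel_names), n))
    hbr = np.empty((len(channel_names), n))
    for i, name in enumerate(channel_names):
        resp = response if name in active else 0.0
        hbo[i] = resp + channel_noise()
        hbr[i] = -np.asarray(resp) / 3.0 + channel_noise()

    events = [Event(float(o), timing.movement_s, EVENT_LABEL) for o in onsets]
    return FNIRSRecording(hbo, hbr, fs, list(channel_names), events)


@dataclass(frozen=True)
class CohortSpec:
    """Generating model for a synthetic stroke cohort feature table.

    ``beta`` orders as (intercept, ERD, HBO, AGE, HBO^2) on the Berg Balance
    Scale; ``noise_sd`` is the residual sd in BBS points. Sampling ranges
    default to the spans seen in the eight-patient cohort this package
    models (ages 32-74 years, ERD indices -2..-0.4, HBO peaks 0.1-2.9).
    """

    n_subjects: int
    beta: tuple[float, float, float, float, float]
    noise_sd: float = 5.0
    age_range: tuple[float, float] = (30.0, 75.0)
    erd_range: tuple[float, float] = (-2.0, -0.3)
    hbo_range: tuple[float, float] = (0.1, 3.0)
    seed: int = 0
    clip_bbs: bool = False

    def __post_init__(self) -> None:
        if self.n_subjects < 3:
            raise ValueError(f"n_subjects must be >= 3, got {self.n_subjects}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if len(self.beta) != 5:
            raise ValueError("beta must have 5 entries "
                             "(intercept, ERD, HBO, AGE, HBO^2)")


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a subject feature table from the linear BBS model.

    Returns a DataFrame with columns subject_id, AGE, ERD, HBO, BBS where
    BBS = b0 + b1*ERD + b2*HBO + b3*AGE + b4*HBO^2 + N(0, noise_sd).
    BBS is clipped to the scale range [0, 56] only when ``clip_bbs`` is set,
    so parameter-recovery checks stay exact by default.
    """
    rng = np.random.default_rng(spec.seed)
    age = rng.uniform(*spec.age_range, size=spec.n_subjects)
    erd = rng.uniform(*spec.erd_range, size=spec.n_subjects)
    hbo = rng.uniform(*spec.hbo_range, size=spec.n_subjects)
    b0, b_erd, b_hbo, b_age, b_hbo2 = spec.beta
    bbs = (
        b0 + b_erd * erd + b_hbo * hbo + b_age * age + b_hbo2 * hbo**2
        + (rng.normal(0.0, spec.noise_sd, size=spec.n_subjects)
           if spec.noise_sd > 0 else 0.0)
    )
    if spec.clip_bbs:
        bbs = np.clip(bbs, 0.0, 56.0)
    return pd.DataFrame(
        {
            "subject_id": [f"S{i + 1}" for i in range(spec.n_subjects)],
            "AGE": age,
            "ERD": erd,
            "HBO": hbo,
            "BBS": bbs,
        }
    )
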