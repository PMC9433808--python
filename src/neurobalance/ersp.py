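"""Event-related spectral perturbation and the ERD index.

The pipeline is: band-pass + downsample the raw EEG (``preprocess``), cut
single-channel epochs around movement onset (``epoch``), estimate a
trial-averaged time-frequency power surface (``compute_ersp``), subtract the
per-frequency pre-movement baseline (``baseline_normalize``), and summarise
the beta-band desynchronization as the mean of the negative normalized power
bins in a fixed band x time rectangle (``erd_index``).

Conventions: t = 0 at movement onset; all sample windows are half-open;
the baseline-subtracted surface is additive (power units), not a dB ratio —
a dB mode exists behind a flag but is never the default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from fractions import Fraction

import numpy as np
from scipy import signal

from .recordings import EEGRecording

__all__ = [
    "Epochs",
    "ERSPGrid",
    "ERDIndex",
    "preprocess",
    "epoch",
    "compute_ersp",
    "baseline_normalize",
    "erd_index",
]

logger = logging.getLogger(__name__)


@dataclass
class Epochs:
    """Single-channel trial segments: ``data`` is trials x time, microvolts."""

    data: np.ndarray
    fs: float
    window: tuple[float, float]
    channel: str
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_times(self) -> int:
        return self.data.shape[1]

    @property
    def t0_index(self) -> int:
        """Sample index of movement onset within each epoch."""
        return int(round(-self.window[0] * self.fs))

    @property
    def times(self) -> np.ndarray:
        """Per-sample times in seconds relative to movement onset."""
        return self.window[0] + np.arange(self.n_times) / self.fs


@dataclass
class ERSPGrid:
    """Trial-averaged time-frequency power surface.

    ``power[i, j]`` is the mean over trials of the squared spectral
    magnitude at ``freqs[i]`` and ``times[j]`` (seconds from movement
    onset). After :func:`baseline_normalize`, ``power`` holds the
    baseline-subtracted surface and ``baseline_per_freq`` the subtracted
    per-frequency means.
    """

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    n_trials: int
    normalized: bool = False
    baseline_per_freq: np.ndarray | None = None
    baseline_window: tuple[float, float] | None = None
    n_baseline_bins: int | None = None

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.power.shape != (self.freqs.size, self.times.size):
            raise ValueError(
                f"power shape {self.power.shape} inconsistent with "
                f"{self.freqs.size} freqs x {self.times.size} times"
            )
        if not self.normalized and np.any(self.power < 0):
            raise ValueError("unnormalized power must be non-negative")


@dataclass(frozen=True)
class ERDIndex:
    """Mean of the strictly negative normalized-power bins in a rectangle.

    ``value`` <= 0 always; when no bin in the band x window rectangle is
    negative the value is 0 and ``empty_flag`` is set, keeping the feature
    defined (and auditable) for every subject.
    """

    value: float
    band: tuple[float, float]
    window: tuple[float, float]
    n_negative_bins: int
    empty_flag: bool

    def __post_init__(self) -> None:
        if self.value > 0:
            raise ValueError("ERD index must be <= 0")
        if (self.value == 0.0) != self.empty_flag:
            raise ValueError("value is 0 iff empty_flag is set")


def _bandpass_sos(band: tuple[float, float], fs: float, order: int = 4):
    lo, hi = band
    if not 0 < lo < hi:
        raise ValueError(f"band must satisfy 0 < low < high, got {band}")
    if hi >= fs / 2:
        raise ValueError(
            f"band high edge {hi} Hz is at or above the Nyquist frequency "
            f"{fs / 2} Hz"
        )
    return signal.butter(order, band, btype="bandpass", fs=fs, output="sos")


def preprocess(
    rec: EEGRecording,
    band: tuple[float, float] = (0.05, 35.0),
    fs_out: float = 256.0,
) -> EEGRecording:
    """Zero-phase band-pass then downsample to ``fs_out``.

    The 4th-order Butterworth filter is applied forward-backward
    (zero-phase) so ERD latencies are preserved. When the decimation ratio
    is an integer the band-pass itself is the anti-alias filter (its high
    edge must sit below the output Nyquist) and plain sample picking
    follows; otherwise polyphase resampling is used with a logged warning.
    Events are in seconds and carry over unchanged.
    """
    if fs_out > rec.fs:
        raise ValueError(f"fs_out={fs_out} exceeds recording fs={rec.fs}")
    if band[1] >= fs_out / 2:
        raise ValueError(
            f"band high edge {band[1]} Hz must be below the output Nyquist "
            f"{fs_out / 2} Hz"
        )
    sos = _bandpass_sos(band, rec.fs)
    filtered = signal.sosfiltfilt(sos, rec.samples, axis=1)

    ratio = rec.fs / fs_out
    if abs(ratio - round(ratio)) < 1e-9:
        out = filtered[:, :: int(round(ratio))]
    else:
        frac = Fraction(fs_out / rec.fs).limit_denominator(1000)
        logger.warning(
            "non-integer decimation ratio %.4f: polyphase resampling %d/%d",
            ratio, frac.numerator, frac.denominator,
        )
        out = signal.resample_poly(filtered, frac.numerator, frac.denominator,
                                   axis=1)
    return EEGRecording(out, fs_out, list(rec.channel_names), list(rec.events))


def epoch(
    rec: EEGRecording,
    channel: str = "Cz",
    window: tuple[float, float] = (-1.0, 5.0),
) -> Epochs:
    """Cut per-event slices of one channel, half-open in samples.

    Epoch k covers sample indices ``[round((onset_k + window[0]) * fs),
    start + n_win)`` where ``n_win = round((window[1] - window[0]) * fs)``.
    Rows are verbatim slices — no detrending or baseline handling here.
    Events too close to a recording edge are dropped with a logged count.
    """
    x = rec.channel(channel)
    n_win = int(round((window[1] - window[0]) * rec.fs))
    rows, dropped = [], 0
    for ev in rec.events:
        start = int(round((ev.onset_s + window[0]) * rec.fs))
        if start < 0 or start + n_win > x.size:
            dropped += 1
            continue
        rows.append(x[start : start + n_win])
    if dropped:
        logger.warning("dropped %d/%d events too close to a recording edge",
                       dropped, len(rec.events))
    if not rows:
        raise ValueError("no events fit inside the recording")
    return Epochs(np.vstack(rows), rec.fs, window, channel, n_dropped=dropped)


def _stft_grid(
    ep: Epochs, win_s: float, hop_divisor: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Trial-wise short-time Fourier power: returns (power, freqs, times).

    Hann-windowed frames fully inside the epoch, hop = window / divisor,
    no zero padding: power[k] = |rfft(frame * hann)|^2 per trial k.
    """
    nperseg = int(round(win_s * ep.fs))
    if nperseg < 2 or nperseg > ep.n_times:
        raise ValueError(
            f"window of {nperseg} samples does not fit epoch of "
            f"{ep.n_times} samples"
        )
    hop = max(1, nperseg // hop_divisor)
    win = signal.get_window("hann", nperseg, fftbins=True)
    starts = np.arange(0, ep.n_times - nperseg + 1, hop)
    freqs = np.fft.rfftfreq(nperseg, d=1.0 / ep.fs)
    frames = np.stack([ep.data[:, s : s + nperseg] for s in starts], axis=1)
    spec = np.fft.rfft(frames * win, axis=2)  # trials x frames x freqs
    power = np.abs(spec) ** 2
    times = ep.window[0] + (starts + nperseg / 2) / ep.fs
    return power.transpose(0, 2, 1), freqs, times  # trials x freqs x times


def _morlet_grid(
    ep: Epochs, freqs: np.ndarray, hop: int, n_cycles: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Morlet-wavelet power via mne, sampled every ``hop`` samples."""
    from mne.time_frequency import tfr_array_morlet

    data = ep.data[:, np.newaxis, :]  # trials x 1 channel x time
    power = tfr_array_morlet(
        data, sfreq=ep.fs, freqs=freqs, n_cycles=n_cycles, output="power",
        zero_mean=True,
    )[:, 0]  # trials x freqs x times
    times = ep.times
    return power[:, :, ::hop], freqs, times[::hop]


def compute_ersp(
    ep: Epochs,
    freqs: np.ndarray | None = None,
    method: str = "stft",
    win_s: float = 0.5,
    hop_divisor: int = 16,
    n_cycles: float = 7.0,
) -> ERSPGrid:
    """Trial-averaged spectral power: mean over trials of |F_k(f, t)|^2.

    ``method='stft'`` (default) uses Hann-windowed short-time Fourier frames
    of ``win_s`` seconds hopping by ``win_s / hop_divisor``; requested
    ``freqs`` are mapped to the nearest DFT bins (all bins when None).
    ``method='morlet'`` estimates power by complex Morlet wavelets at
    exactly the requested frequencies (required for this method).
    """
    if ep.n_trials < 1:
        raise ValueError("need at least one trial")
    nyq = ep.fs / 2
    if freqs is not None:
        freqs = np.asarray(freqs, dtype=float)
        if np.any(freqs > nyq):
            raise ValueError(
                f"requested frequencies exceed the Nyquist frequency {nyq} Hz"
            )

    if method == "stft":
        power, grid_freqs, times = _stft_grid(ep, win_s, hop_divisor)
        if freqs is not None:
            idx = np.unique([int(np.argmin(np.abs(grid_freqs - f)))
                             for f in freqs])
            power, grid_freqs = power[:, idx, :], grid_freqs[idx]
    elif method == "morlet":
        if freqs is None:
            raise ValueError("method='morlet' requires explicit freqs")
        nperseg = int(round(win_s * ep.fs))
        hop = max(1, nperseg // hop_divisor)
        power, grid_freqs, times = _morlet_grid(ep, freqs, hop, n_cycles)
    else:
        raise ValueError(f"unknown spectral method {method!r}")

    return ERSPGrid(
        power=power.mean(axis=0),
        freqs=grid_freqs,
        times=times,
        n_trials=ep.n_trials,
    )


def baseline_normalize(
    grid: ERSPGrid, baseline_window: tuple[float, float] = (-1.0, 0.0)
) -> ERSPGrid:
    """Subtract the per-frequency mean over the pre-movement baseline bins.

    Purely subtractive (power units): for every frequency f,
    ``out[f, t] = power[f, t] - mean over baseline bins of power[f, .]``,
    so the mean of the output over the baseline bins is identically zero.
    """
    if grid.normalized:
        raise ValueError("grid is already baseline-normalized")
    lo, hi = baseline_window
    mask = (grid.times >= lo) & (grid.times < hi)
    n_bins = int(mask.sum())
    if n_bins == 0:
        raise ValueError(
            f"baseline window {baseline_window} contains no time bins "
            f"(grid covers {grid.times[0]:.3f}..{grid.times[-1]:.3f} s)"
        )
    baseline = grid.power[:, mask].mean(axis=1)
    return replace(
        grid,
        power=grid.power - baseline[:, np.newaxis],
        normalized=True,
        baseline_per_freq=baseline,
        baseline_window=baseline_window,
        n_baseline_bins=n_bins,
    )


def erd_index(
    grid: ERSPGrid,
    band: tuple[float, float] = (15.0, 23.0),
    window: tuple[float, float] = (0.0, 1.0),
) -> ERDIndex:
    """Mean of the strictly negative normalized-power bins in band x window.

    Positive bins inside the rectangle are excluded from the mean, not
    zeroed. Band and time edges are inclusive. If the rectangle holds no
    negative bin the index is 0 with ``empty_flag`` set; an empty rectangle
    is an error (distinct from the no-negative-bins case).
    """
    if not grid.normalized:
        raise ValueError("grid must be baseline-normalized first")
    fmask = (grid.freqs >= band[0]) & (grid.freqs <= band[1])
    tmask = (grid.times >= window[0]) & (grid.times <= window[1])
    if not fmask.any() or not tmask.any():
        raise ValueError(
            f"band {band} Hz x window {window} s selects no bins on a grid "
            f"of {grid.freqs[0]:.1f}..{grid.freqs[-1]:.1f} Hz x "
            f"{grid.times[0]:.2f}..{grid.times[-1]:.2f} s"
        )
    rect = grid.power[np.ix_(fmask, tmask)]
    negatives = rect[rect < 0]
    if negatives.size == 0:
        return ERDIndex(0.0, band, window, 0, True)
    return ERDIndex(float(negatives.mean()), band, window,
                    int(negatives.size), False)
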