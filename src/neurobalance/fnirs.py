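"""Hemoglobin time-series features around ankle dorsiflexion.

HBO/HBR traces are band-pass filtered to 0.01-0.2 Hz (removing drift,
respiration harmonics and the cardiac pulse), segmented from 2 s before to
10 s after each movement onset, baseline-corrected to the 2 s pre-onset
mean, averaged over trials and over a fixed sensorimotor channel subset,
and summarised by either the peak or the signed area of the average HBO
curve over 0-10 s. The peak is the regression feature by default; the area
is available as an alternative mode.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .recordings import FNIRSRecording
from .synthetic import SENSORIMOTOR_CHANNELS

__all__ = [
    "HemoEpochs",
    "AverageCurves",
    "HBOFeature",
    "bandpass_hemo",
    "epoch_and_correct",
    "average_curve",
    "hbo_scalar",
    "hbo_feature",
]

logger = logging.getLogger(__name__)


@dataclass
class HemoEpochs:
    """Baseline-corrected per-channel, per-trial hemoglobin segments.

    Arrays are channels x trials x time (micromolar). Each trial/channel
    trace has had its mean over ``baseline_window`` subtracted; ``hbt`` is
    constructed as hbo + hbr *after* correction so the identity holds
    element-wise.
    """

    hbo: np.ndarray
    hbr: np.ndarray
    hbt: np.ndarray
    fs: float
    window: tuple[float, float]
    baseline_window: tuple[float, float]
    channels_used: list[str]
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if not (self.hbo.shape == self.hbr.shape == self.hbt.shape):
            raise ValueError("hbo, hbr, hbt must share one shape")
        if not np.allclose(self.hbt, self.hbo + self.hbr, atol=1e-12):
            raise ValueError("hbt must equal hbo + hbr element-wise")

    @property
    def n_trials(self) -> int:
        return self.hbo.shape[1]

    @property
    def times(self) -> np.ndarray:
        return self.window[0] + np.arange(self.hbo.shape[2]) / self.fs


@dataclass
class AverageCurves:
    """Trial- then channel-averaged hemoglobin time courses."""

    times: np.ndarray
    hbo: np.ndarray
    hbr: np.ndarray
    hbt: np.ndarray
    fs: float


@dataclass(frozen=True)
class HBOFeature:
    """Scalar summaries of the average HBO curve over the task window."""

    peak: float
    area: float
    window: tuple[float, float]


def bandpass_hemo(
    rec: FNIRSRecording,
    band: tuple[float, float] = (0.01, 0.2),
    order: int = 3,
) -> FNIRSRecording:
    """Zero-phase Butterworth band-pass of HBO and HBR independently.

    The default 0.01-0.2 Hz band removes slow drift and the ~1 Hz cardiac
    pulsation while passing the hemodynamic response. The low cutoff
    demands a long settle: recordings shorter than three filter time
    constants (tau = 1 / (2 pi f_low)) are rejected, and the zero-phase
    pass uses reflective padding of one time constant.
    """
    lo, hi = band
    if not 0 < lo < hi:
        raise ValueError(f"band must satisfy 0 < low < high, got {band}")
    if hi >= rec.fs / 2:
        raise ValueError(
            f"band high edge {hi} Hz must be below the Nyquist frequency "
            f"{rec.fs / 2} Hz"
        )
    tau_samples = rec.fs / (2 * np.pi * lo)
    if rec.n_samples < 3 * tau_samples:
        raise ValueError(
            f"recording of {rec.n_samples / rec.fs:.1f} s is shorter than 3 "
            f"filter time constants ({3 * tau_samples / rec.fs:.1f} s) for a "
            f"{lo} Hz low edge"
        )
    padlen = min(int(tau_samples), rec.n_samples - 1)
    logger.debug("bandpass_hemo: reflective padding of %d samples", padlen)
    sos = signal.butter(order, band, btype="bandpass", fs=rec.fs, output="sos")
    hbo = signal.sosfiltfilt(sos, rec.hbo, axis=1, padtype="even", padlen=padlen)
    hbr = signal.sosfiltfilt(sos, rec.hbr, axis=1, padtype="even", padlen=padlen)
    return FNIRSRecording(hbo, hbr, rec.fs, list(rec.channel_names),
                          list(rec.events))


def epoch_and_correct(
    rec: FNIRSRecording,
    channels: tuple[str, ...] = SENSORIMOTOR_CHANNELS,
    window: tuple[float, float] = (-2.0, 10.0),
    baseline: tuple[float, float] = (-2.0, 0.0),
) -> HemoEpochs:
    """Cut per-trial segments and subtract the pre-onset baseline mean.

    Every requested channel must exist — a missing one raises naming it
    (no silent subsetting). Trials whose window leaves the recording are
    dropped with a logged count. Per trial and channel, the mean over the
    baseline window is subtracted from HBO and HBR; HBT is then HBO + HBR.
    """
    missing = [c for c in channels if c not in rec.channel_names]
    if missing:
        raise KeyError(f"channels missing from recording: {missing}")
    if not (window[0] <= baseline[0] < baseline[1] <= window[1]):
        raise ValueError(
            f"baseline {baseline} must lie within the epoch window {window}"
        )
    idx = [rec.channel_index(c) for c in channels]
    n_win = int(round((window[1] - window[0]) * rec.fs))
    b0 = int(round((baseline[0] - window[0]) * rec.fs))
    b1 = int(round((baseline[1] - window[0]) * rec.fs))

    hbo_rows, hbr_rows, dropped = [], [], 0
    for ev in rec.events:
        start = int(round((ev.onset_s + window[0]) * rec.fs))
        if start < 0 or start + n_win > rec.n_samples:
            dropped += 1
            continue
        hbo_rows.append(rec.hbo[idx, start : start + n_win])
        hbr_rows.append(rec.hbr[idx, start : start + n_win])
    if dropped:
        logger.warning("dropped %d/%d trials too close to a recording edge",
                       dropped, len(rec.events))
    if not hbo_rows:
        raise ValueError("no trials fit inside the recording")

    # channels x trials x time
    hbo = np.stack(hbo_rows, axis=1)
    hbr = np.stack(hbr_rows, axis=1)
    hbo = hbo - hbo[:, :, b0:b1].mean(axis=2, keepdims=True)
    hbr = hbr - hbr[:, :, b0:b1].mean(axis=2, keepdims=True)
    return HemoEpochs(
        hbo=hbo, hbr=hbr, hbt=hbo + hbr, fs=rec.fs, window=window,
        baseline_window=baseline, channels_used=list(channels),
        n_dropped=dropped,
    )


def average_curve(ep: HemoEpochs) -> AverageCurves:
    """Mean over trials then over channels, per hemoglobin species.

    With equal trial counts per channel (the only case a single recording
    produces) the averaging order is immaterial; it is fixed as
    trials-then-channels for definiteness.
    """
    if ep.n_trials < 1:
        raise ValueError("need at least one trial")
    return AverageCurves(
        times=ep.times,
        hbo=ep.hbo.mean(axis=1).mean(axis=0),
        hbr=ep.hbr.mean(axis=1).mean(axis=0),
        hbt=ep.hbt.mean(axis=1).mean(axis=0),
        fs=ep.fs,
    )


def hbo_scalar(
    curves: AverageCurves,
    mode: str = "peak",
    window: tuple[float, float] = (0.0, 10.0),
    absolute_area: bool = False,
) -> float:
    """Scalar HBO feature from the average curve over the task window.

    ``mode='peak'``: maximum of the curve on the window. ``mode='area'``:
    trapezoidal integral over the window in concentration x seconds —
    signed by default (negative lobes subtract); set ``absolute_area`` to
    integrate |curve| instead.
    """
    mask = (curves.times >= window[0]) & (curves.times <= window[1])
    if not mask.any():
        raise ValueError(
            f"window {window} s outside curve support "
            f"{curves.times[0]:.2f}..{curves.times[-1]:.2f} s"
        )
    seg = curves.hbo[mask]
    t = curves.times[mask]
    if mode == "peak":
        return float(seg.max())
    if mode == "area":
        y = np.abs(seg) if absolute_area else seg
        return float(np.trapezoid(y, t))
    raise ValueError(f"unknown mode {mode!r} (expected 'peak' or 'area')")


def hbo_feature(
    ep: HemoEpochs, window: tuple[float, float] = (0.0, 10.0)
) -> HBOFeature:
    """Convenience: both scalar summaries of the averaged HBO curve."""
    curves = average_curve(ep)
    return HBOFeature(
        peak=hbo_scalar(curves, "peak", window),
        area=hbo_scalar(curves, "area", window),
        window=window,
    )
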