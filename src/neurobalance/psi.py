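"""Phase synchronization index (PSI) between EEG channel pairs.

The signal is band-passed to the band of interest, the instantaneous phase
is taken from the analytic signal (Hilbert transform), and the PSI of a
channel pair is the resultant length of the per-sample phase differences

    PSI = sqrt(<cos phi_xy(t)>^2 + <sin phi_xy(t)>^2),

a number in [0, 1]: 1 for perfectly locked phases, 0 for phases spread
uniformly. The inter-hemispheric summary averages the PSI of homologous
left/right sensorimotor pairs (C3-C4, CP3-CP4, FC3-FC4 by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

from .recordings import EEGRecording, normalize_1020_label

__all__ = [
    "PhaseSeries",
    "PSIResult",
    "ALPHA_BAND",
    "DEFAULT_HOMOLOGOUS_PAIRS",
    "instantaneous_phase",
    "psi",
    "interhemispheric_psi",
    "group_compare",
]

#: Alpha band used for the inter-hemispheric comparison (Hz).
ALPHA_BAND: tuple[float, float] = (8.0, 13.0)

#: Motor-relevant homologous sensor pairs for the inter-hemispheric summary.
DEFAULT_HOMOLOGOUS_PAIRS: tuple[tuple[str, str], ...] = (
    ("C3", "C4"), ("CP3", "CP4"), ("FC3", "FC4"),
)


@dataclass
class PhaseSeries:
    """Per-channel instantaneous phase, radians in (-pi, pi].

    ``trim`` samples at each edge are contaminated by filter settling and
    Hilbert edge effects and are excluded from every downstream average.
    """

    phase: np.ndarray
    fs: float
    band: tuple[float, float]
    channel_names: list[str]
    trim: int

    def __post_init__(self) -> None:
        self.phase = np.atleast_2d(np.asarray(self.phase, dtype=float))
        if np.any(self.phase <= -np.pi) or np.any(self.phase > np.pi):
            raise ValueError("phases must lie in (-pi, pi]")
        if 2 * self.trim >= self.phase.shape[1]:
            raise ValueError(
                f"trim of {self.trim} samples per edge leaves no interior in "
                f"{self.phase.shape[1]} samples"
            )

    def channel_index(self, name: str) -> int:
        name = normalize_1020_label(name)
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"channel {name!r} not in phase series "
                f"(have {self.channel_names})"
            ) from None


@dataclass(frozen=True)
class PSIResult:
    """Per-pair phase synchronization values in [0, 1]."""

    pairs: tuple[tuple[str, str], ...]
    values: tuple[float, ...]
    band: tuple[float, float]
    window: tuple[float, float] | None

    def __post_init__(self) -> None:
        for v in self.values:
            if not 0.0 <= v <= 1.0 + 1e-12:
                raise ValueError(f"PSI {v} outside [0, 1]")

    @property
    def mean(self) -> float:
        """Subject-level summary: mean PSI over the pairs."""
        return float(np.mean(self.values))


def instantaneous_phase(
    rec: EEGRecording, band: tuple[float, float], filter_order: int = 4
) -> PhaseSeries:
    """Band-pass (zero-phase Butterworth) then analytic-signal phase.

    The recorded ``trim`` is one filter settling length, three periods of
    the band's low edge. Channels with (numerically) zero signal have no
    defined phase and are rejected.
    """
    lo, hi = band
    if not 0 < lo < hi:
        raise ValueError(f"band must satisfy 0 < low < high, got {band}")
    if hi >= rec.fs / 2:
        raise ValueError(
            f"band high edge {hi} Hz must be below the Nyquist frequency "
            f"{rec.fs / 2} Hz"
        )
    scale = np.abs(rec.samples).max()
    rms = np.sqrt(np.mean(rec.samples**2, axis=1))
    dead = rms <= 1e-12 * max(scale, 1.0)
    if dead.any():
        names = [rec.channel_names[i] for i in np.flatnonzero(dead)]
        raise ValueError(
            f"channels {names} are (near-)zero: instantaneous phase undefined"
        )
    sos = signal.butter(filter_order, band, btype="bandpass", fs=rec.fs,
                        output="sos")
    filtered = signal.sosfiltfilt(sos, rec.samples, axis=1)
    phase = np.angle(signal.hilbert(filtered, axis=1))
    trim = int(round(3 * rec.fs / lo))
    trim = min(trim, (rec.n_samples - 1) // 2)
    return PhaseSeries(phase, rec.fs, band, list(rec.channel_names), trim)


def _resultant_length(dphi: np.ndarray) -> float:
    return float(np.hypot(np.mean(np.cos(dphi)), np.mean(np.sin(dphi))))


def _window_slice(ph: PhaseSeries, window: tuple[float, float] | None) -> slice:
    n = ph.phase.shape[1]
    lo, hi = ph.trim, n - ph.trim
    if window is not None:
        lo = max(lo, int(round(window[0] * ph.fs)))
        hi = min(hi, int(round(window[1] * ph.fs)))
    if hi <= lo:
        raise ValueError(
            f"window {window} is empty after trimming {ph.trim} samples "
            "per edge"
        )
    return slice(lo, hi)


def psi(
    ph: PhaseSeries,
    pair: tuple[str, str],
    window: tuple[float, float] | None = None,
) -> PSIResult:
    """PSI of one channel pair over a time window (seconds from start).

    The per-sample phase difference phi_x - phi_y is averaged as a unit
    phasor; the PSI is the phasor's length. ``window=None`` uses the whole
    trimmed interior.
    """
    ia, ib = ph.channel_index(pair[0]), ph.channel_index(pair[1])
    sl = _window_slice(ph, window)
    dphi = ph.phase[ia, sl] - ph.phase[ib, sl]
    return PSIResult(
        pairs=(tuple(pair),),
        values=(_resultant_length(dphi),),
        band=ph.band,
        window=window,
    )


_LEFT_ODD = frozenset("13579")
_RIGHT_EVEN = frozenset("24680")


def _hemisphere(label: str) -> str:
    """'left', 'right' or 'midline' from the 10/20 label's trailing digit."""
    tail = label.rstrip()[-1]
    if tail in _LEFT_ODD:
        return "left"
    if tail in _RIGHT_EVEN:
        return "right"
    return "midline"


def interhemispheric_psi(
    rec: EEGRecording,
    band: tuple[float, float] = ALPHA_BAND,
    homologous_pairs: tuple[tuple[str, str], ...] = DEFAULT_HOMOLOGOUS_PAIRS,
    window: tuple[float, float] | None = None,
) -> PSIResult:
    """PSI per homologous left/right pair; ``.mean`` is the subject summary.

    Each pair must contain one left- and one right-hemisphere sensor (odd /
    even trailing digit in the 10/20 convention); midline or same-side
    pairs are rejected.
    """
    for a, b in homologous_pairs:
        ha, hb = _hemisphere(normalize_1020_label(a)), _hemisphere(
            normalize_1020_label(b))
        if {ha, hb} != {"left", "right"}:
            raise ValueError(
                f"pair ({a}, {b}) is not inter-hemispheric "
                f"({ha} vs {hb})"
            )
    ph = instantaneous_phase(rec, band)
    values = []
    for pair in homologous_pairs:
        values.append(psi(ph, pair, window).values[0])
    return PSIResult(
        pairs=tuple(tuple(p) for p in homologous_pairs),
        values=tuple(values),
        band=band,
        window=window,
    )


def group_compare(
    values_a: np.ndarray,
    values_b: np.ndarray,
    test: str = "welch",
) -> tuple[float, float]:
    """Two-sided comparison of per-subject scalars between two groups.

    ``test='welch'`` (default) is the unequal-variance t-test;
    ``test='mannwhitney'`` the exact-when-small rank test. Returns
    (statistic, p_value).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 subjects")
    if test == "welch":
        if np.var(a) == 0 and np.var(b) == 0:
            raise ValueError(
                "both groups have zero variance: the t statistic is "
                "undefined; use test='mannwhitney' instead"
            )
        res = stats.ttest_ind(a, b, equal_var=False)
    elif test == "mannwhitney":
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
    else:
        raise ValueError(f"unknown test {test!r}")
    return float(res.statistic), float(res.pvalue)
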