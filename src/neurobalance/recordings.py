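"""Core containers: trial clock, EEG and fNIRS recordings, event tables.

Events are stored in seconds from the start of the recording (0-based time
origin), as ``(onset_s, duration_s, label)`` triples, and survive resampling
unchanged because they live on the wall-clock axis rather than the sample axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "TrialTiming",
    "Event",
    "EEGRecording",
    "FNIRSRecording",
    "normalize_1020_label",
]


@dataclass(frozen=True)
class Event:
    onset_s: float
    duration_s: float
    label: str


@dataclass(frozen=True)
class TrialTiming:
    """Within-trial clock for the ankle-dorsiflexion paradigm.

    A trial is preparation -> dynamic dorsiflexion -> static hold -> rest.
    Movement onset (t = 0 for all epoch windows) is the end of the
    preparation phase. Defaults give the 11.5 s trial used throughout.
    """

    prep_s: float = 1.0
    dynamic_s: float = 2.5
    static_s: float = 3.0
    rest_s: float = 5.0

    def __post_init__(self) -> None:
        for name in ("prep_s", "dynamic_s", "static_s", "rest_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")

    @property
    def total_s(self) -> float:
        return self.prep_s + self.dynamic_s + self.static_s + self.rest_s

    @property
    def movement_s(self) -> float:
        """Duration of active movement (dynamic + static)."""
        return self.dynamic_s + self.static_s

    def onsets(self, n_trials: int, lead_in_s: float = 0.0) -> np.ndarray:
        """Movement-onset times for ``n_trials`` back-to-back trials."""
        k = np.arange(n_trials)
        return lead_in_s + self.prep_s + k * self.total_s


def normalize_1020_label(label: str) -> str:
    """Canonical 10/20 capitalisation: letters upper-case, midline 'z' lower.

    'cz' -> 'Cz', 'FC3' -> 'FC3', 'cpZ' -> 'CPz'.
    """
    up = label.strip().upper()
    return up[:-1] + "z" if up.endswith("Z") else up


def _validate_events(events: Sequence[Event], n_samples: int, fs: float) -> None:
    onsets = [e.onset_s for e in events]
    if any(b <= a for a, b in zip(onsets, onsets[1:])):
        raise ValueError("event onsets must be strictly increasing")
    if events and events[-1].onset_s > n_samples / fs:
        raise ValueError(
            f"last event onset {events[-1].onset_s:.3f} s exceeds recording "
            f"length {n_samples / fs:.3f} s"
        )


@dataclass
class EEGRecording:
    """Multi-channel EEG: ``samples`` is channels x time in microvolts."""

    samples: np.ndarray
    fs: float
    channel_names: list[str]
    events: list[Event] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ValueError(f"fs must be > 0, got {self.fs}")
        if len(self.channel_names) != self.samples.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.samples.shape[0]} rows"
            )
        self.channel_names = [normalize_1020_label(c) for c in self.channel_names]
        _validate_events(self.events, self.samples.shape[1], self.fs)

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel_index(self, name: str) -> int:
        name = normalize_1020_label(name)
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"channel {name!r} not in recording (have {self.channel_names})"
            ) from None

    def channel(self, name: str) -> np.ndarray:
        return self.samples[self.channel_index(name)]

    def copy_with(self, **kw) -> "EEGRecording":
        return replace(self, **kw)


@dataclass
class FNIRSRecording:
    """fNIRS hemoglobin concentration changes, channels x time, micromolar.

    ``hbo`` and ``hbr`` share one channel axis; total hemoglobin is always
    the sum ``hbt = hbo + hbr`` and is therefore a derived property, never
    stored, so the identity cannot drift.
    """

    hbo: np.ndarray
    hbr: np.ndarray
    fs: float
    channel_names: list[str]
    events: list[Event] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.hbo = np.atleast_2d(np.asarray(self.hbo, dtype=float))
        self.hbr = np.atleast_2d(np.asarray(self.hbr, dtype=float))
        if self.hbo.shape != self.hbr.shape:
            raise ValueError(
                f"hbo shape {self.hbo.shape} != hbr shape {self.hbr.shape}"
            )
        if self.fs <= 0:
            raise ValueError(f"fs must be > 0, got {self.fs}")
        if len(self.channel_names) != self.hbo.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.hbo.shape[0]} rows"
            )
        _validate_events(self.events, self.hbo.shape[1], self.fs)

    @property
    def hbt(self) -> np.ndarray:
        return self.hbo + self.hbr

    @property
    def n_samples(self) -> int:
        return self.hbo.shape[1]

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"channel {name!r} not in recording (have {self.channel_names})"
            ) from None
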