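"""Pipeline configuration: every stage parameter in one serializable record.

Defaults are the analysis conditions used throughout this package: 0.05-35 Hz
EEG band downsampled to 256 Hz, epochs -1..5 s around onset with a -1..0 s
baseline, ERD rectangle 15-23 Hz x 0-1 s, alpha-band (8-13 Hz) PSI over the
motor homologue pairs, 0.01-0.2 Hz hemoglobin band with the eight
sensorimotor channels and a -2..10 s epoch, peak HBO feature, and
leave-one-out cross-validation.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


def _tuplize(value):
    if isinstance(value, (list, tuple)):
        return tuple(_tuplize(v) for v in value)
    return value


@dataclass(frozen=True)
class PipelineConfig:
    # EEG preprocessing / ERD
    eeg_band: tuple[float, float] = (0.05, 35.0)
    eeg_fs_out: float = 256.0
    eeg_channel: str = "Cz"
    epoch_window: tuple[float, float] = (-1.0, 5.0)
    baseline_window: tuple[float, float] = (-1.0, 0.0)
    ersp_method: str = "stft"
    ersp_win_s: float = 0.5
    erd_band: tuple[float, float] = (15.0, 23.0)
    erd_window: tuple[float, float] = (0.0, 1.0)
    # PSI
    psi_band: tuple[float, float] = (8.0, 13.0)
    psi_pairs: tuple[tuple[str, str], ...] = (
        ("C3", "C4"), ("CP3", "CP4"), ("FC3", "FC4"),
    )
    psi_window: tuple[float, float] | None = (0.0, 5.0)
    # fNIRS
    fnirs_band: tuple[float, float] = (0.01, 0.2)
    fnirs_channels: tuple[str, ...] = (
        "S2-D4", "S2-D2", "S7-D2", "S7-D4", "S7-D7", "S7-D5", "S5-D7", "S5-D5",
    )
    fnirs_window: tuple[float, float] = (-2.0, 10.0)
    fnirs_baseline: tuple[float, float] = (-2.0, 0.0)
    hbo_mode: str = "peak"
    hbo_window: tuple[float, float] = (0.0, 10.0)
    # regression
    cv_scheme: str = "leave-one-out"
    # run control
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, list):
                object.__setattr__(self, f.name, _tuplize(v))
        if self.hbo_mode not in ("peak", "area"):
            raise ValueError(f"hbo_mode must be 'peak' or 'area', got "
                             f"{self.hbo_mode!r}")
        if self.cv_scheme != "leave-one-out":
            raise ValueError(f"unknown cv_scheme {self.cv_scheme!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**{k: _tuplize(v) for k, v in d.items()})

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "PipelineConfig":
        text = (Path(source).read_text()
                if isinstance(source, Path) or "\n" not in str(source)
                and Path(source).exists()
                else str(source))
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError("config YAML must map keys to values")
        return cls.from_dict(data)
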