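"""Readers and writers for recordings, events and feature tables.

On disk, an EEG or fNIRS recording is either

* a plain-text bundle — a CSV sample matrix (time rows x channel columns),
  a JSON sidecar with the sampling rate and channel names, and an events
  TSV with columns ``onset`` / ``duration`` / ``trial_type`` (seconds,
  0-based time origin at recording start) — exact round trips; or
* a standard binary format: EDF for EEG (read via :mod:`mne`), SNIRF for
  fNIRS (HDF5 via :mod:`h5py`, hemoglobin data-type labels mapped to
  hbo/hbr).

Feature tables travel as CSV with the fixed schema
``subject_id,AGE,ERD,HBO,BBS``.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .recordings import EEGRecording, Event, FNIRSRecording
from .regression import validate_feature_table

__all__ = [
    "read_events_tsv",
    "write_events_tsv",
    "read_eeg",
    "write_eeg_csv",
    "read_fnirs",
    "write_fnirs_csv",
    "write_fnirs_snirf",
    "read_cohort_csv",
    "write_cohort_csv",
]

_EVENT_COLS = ["onset", "duration", "trial_type"]


# -- events -----------------------------------------------------------------

def write_events_tsv(events: list[Event], path: str | Path) -> None:
    df = pd.DataFrame(
        [(e.onset_s, e.duration_s, e.label) for e in events],
        columns=_EVENT_COLS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_events_tsv(path: str | Path) -> list[Event]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _EVENT_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"events TSV {path} missing columns {missing}")
    onsets = df["onset"].to_numpy(dtype=float)
    if np.any(np.diff(onsets) <= 0):
        raise ValueError(f"events TSV {path}: onsets must be strictly increasing")
    return [
        Event(float(r.onset), float(r.duration), str(r.trial_type))
        for r in df.itertuples()
    ]


# -- EEG --------------------------------------------------------------------

def _sidecar_paths(base: Path) -> tuple[Path, Path]:
    stem = base.with_suffix("")
    return stem.with_suffix(".json"), Path(f"{stem}_events.tsv")


def write_eeg_csv(rec: EEGRecording, path: str | Path) -> None:
    """CSV matrix (time x channels) + JSON sidecar + events TSV."""
    path = Path(path)
    meta_path, events_path = _sidecar_paths(path)
    pd.DataFrame(rec.samples.T, columns=rec.channel_names).to_csv(
        path, index=False
    )
    meta_path.write_text(json.dumps(
        {"fs": rec.fs, "channel_names": rec.channel_names}, indent=2))
    write_events_tsv(rec.events, events_path)


def _read_eeg_csv(path: Path) -> EEGRecording:
    meta_path, events_path = _sidecar_paths(path)
    if not meta_path.exists():
        raise FileNotFoundError(f"CSV recording {path} needs sidecar {meta_path}")
    meta = json.loads(meta_path.read_text())
    df = pd.read_csv(path)
    names = meta["channel_names"]
    if len(names) != df.shape[1]:
        raise ValueError(
            f"{path}: {df.shape[1]} CSV columns but sidecar declares "
            f"{len(names)} channels"
        )
    events = read_events_tsv(events_path) if events_path.exists() else []
    return EEGRecording(df.to_numpy(dtype=float).T, float(meta["fs"]),
                        list(names), events)


def _read_eeg_edf(path: Path) -> EEGRecording:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    _, events_path = _sidecar_paths(path)
    events = read_events_tsv(events_path) if events_path.exists() else []
    return EEGRecording(
        raw.get_data() * 1e6,  # volts -> microvolts
        float(raw.info["sfreq"]),
        list(raw.ch_names),
        events,
    )


def read_eeg(path: str | Path, format: str | None = None) -> EEGRecording:
    """Read an EEG recording; format from the extension when not given."""
    path = Path(path)
    fmt = format or ("edf" if path.suffix.lower() == ".edf" else "csv")
    if fmt == "edf":
        return _read_eeg_edf(path)
    if fmt == "csv":
        return _read_eeg_csv(path)
    raise ValueError(f"unknown EEG format {fmt!r} (expected 'edf' or 'csv')")


# -- fNIRS ------------------------------------------------------------------

def write_fnirs_csv(rec: FNIRSRecording, base: str | Path) -> None:
    """Paired CSVs ``<base>_hbo.csv`` / ``<base>_hbr.csv`` + sidecars."""
    base = Path(base).with_suffix("")
    for species, arr in (("hbo", rec.hbo), ("hbr", rec.hbr)):
        pd.DataFrame(arr.T, columns=rec.channel_names).to_csv(
            Path(f"{base}_{species}.csv"), index=False
        )
    Path(f"{base}.json").write_text(json.dumps(
        {"fs": rec.fs, "channel_names": rec.channel_names}, indent=2))
    write_events_tsv(rec.events, Path(f"{base}_events.tsv"))


def _read_fnirs_csv(base: Path) -> FNIRSRecording:
    base = base.with_suffix("")
    hbo_path, hbr_path = Path(f"{base}_hbo.csv"), Path(f"{base}_hbr.csv")
    if not hbo_path.exists():
        raise FileNotFoundError(hbo_path)
    if not hbr_path.exists():
        raise FileNotFoundError(
            f"{hbr_path} missing: both hbo and hbr series are required "
            "(total hemoglobin is their sum)"
        )
    meta = json.loads(Path(f"{base}.json").read_text())
    hbo = pd.read_csv(hbo_path).to_numpy(dtype=float).T
    hbr = pd.read_csv(hbr_path).to_numpy(dtype=float).T
    events_path = Path(f"{base}_events.tsv")
    events = read_events_tsv(events_path) if events_path.exists() else []
    return FNIRSRecording(hbo, hbr, float(meta["fs"]),
                          list(meta["channel_names"]), events)


def write_fnirs_snirf(rec: FNIRSRecording, path: str | Path) -> None:
    """Minimal SNIRF: one data block, HbO then HbR measurement lists."""
    path = Path(path)
    n_ch, n_t = rec.hbo.shape
    t = np.arange(n_t) / rec.fs
    series = np.hstack([rec.hbo.T, rec.hbr.T])  # time x (hbo..., hbr...)
    str_dt = h5py.string_dtype("utf-8")
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0", dtype=str_dt)
        nirs = f.create_group("nirs")
        data = nirs.create_group("data1")
        data.create_dataset("dataTimeSeries", data=series)
        data.create_dataset("time", data=t)
        for j, label in enumerate(["HbO"] * n_ch + ["HbR"] * n_ch):
            ml = data.create_group(f"measurementList{j + 1}")
            src, det = rec.channel_names[j % n_ch].split("-")
            ml.create_dataset("sourceIndex", data=int(src[1:]))
            ml.create_dataset("detectorIndex", data=int(det[1:]))
            ml.create_dataset("dataType", data=99999)
            ml.create_dataset("dataTypeLabel", data=label, dtype=str_dt)
        if rec.events:
            stim = nirs.create_group("stim1")
            stim.create_dataset("name", data=rec.events[0].label, dtype=str_dt)
            stim.create_dataset(
                "data",
                data=np.array([(e.onset_s, e.duration_s, 1.0)
                               for e in rec.events]),
            )


def _read_fnirs_snirf(path: Path) -> FNIRSRecording:
    with h5py.File(path, "r") as f:
        data = f["nirs"]["data1"]
        series = np.asarray(data["dataTimeSeries"])
        t = np.asarray(data["time"])
        fs = 1.0 / float(np.median(np.diff(t)))
        hbo_cols, hbr_cols, names = [], [], {}
        mls = sorted(
            (k for k in data.keys() if k.startswith("measurementList")),
            key=lambda k: int(k[len("measurementList"):]),
        )
        for j, key in enumerate(mls):
            ml = data[key]
            label = ml["dataTypeLabel"][()]
            label = label.decode() if isinstance(label, bytes) else str(label)
            name = (f"S{int(ml['sourceIndex'][()])}-"
                    f"D{int(ml['detectorIndex'][()])}")
            if label.lower() == "hbo":
                hbo_cols.append(j)
                names[len(hbo_cols) - 1] = name
            elif label.lower() == "hbr":
                hbr_cols.append(j)
        if not hbo_cols or not hbr_cols:
            raise ValueError(
                f"{path}: SNIRF file must contain both HbO and HbR "
                "measurement lists"
            )
        if len(hbo_cols) != len(hbr_cols):
            raise ValueError(
                f"{path}: {len(hbo_cols)} HbO vs {len(hbr_cols)} HbR channels"
            )
        events = []
        for key in sorted(k for k in f["nirs"].keys() if k.startswith("stim")):
            stim = f["nirs"][key]
            label = stim["name"][()]
            label = label.decode() if isinstance(label, bytes) else str(label)
            for onset, duration, _ in np.atleast_2d(np.asarray(stim["data"])):
                events.append(Event(float(onset), float(duration), label))
        events.sort(key=lambda e: e.onset_s)
        return FNIRSRecording(
            series[:, hbo_cols].T,
            series[:, hbr_cols].T,
            fs,
            [names[i] for i in range(len(hbo_cols))],
            events,
        )


def read_fnirs(path: str | Path, format: str | None = None) -> FNIRSRecording:
    """Read an fNIRS recording; format from the extension when not given."""
    path = Path(path)
    fmt = format or ("snirf" if path.suffix.lower() == ".snirf" else "csv")
    if fmt == "snirf":
        return _read_fnirs_snirf(path)
    if fmt == "csv":
        return _read_fnirs_csv(path)
    raise ValueError(f"unknown fNIRS format {fmt!r} (expected 'snirf' or 'csv')")


# -- feature tables ---------------------------------------------------------

def write_cohort_csv(table: pd.DataFrame, path: str | Path) -> None:
    cols = ["subject_id", "AGE", "ERD", "HBO", "BBS"]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"cohort table missing columns {missing}")
    table[cols].to_csv(path, index=False)


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    validate_feature_table(table, check_range=True)
    return table
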