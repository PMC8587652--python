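"""File I/O: EDF recordings, CSV annotations/datasets, JSON configs.

EDF (European Data Format) is the standard container for polysomnographic
EEG.  Reading goes through :mod:`mne`; writing uses a minimal self-
contained 16-bit EDF writer (single channel, physical dimension uV) that
round-trips through the mne reader.  Event annotations travel as plain
CSV (``onset_s,duration_s,label``), segment datasets as CSV with one row
per segment (features/samples then label), and TFR grids as long-format
CSV (``n,k,v,value``).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import Event, EventList, Signal
from .synth import SegmentDataset, SynthConfig
from .tfr import TFRGrid


# ---------------------------------------------------------------------------
# EDF


def _edf_field(text: str, width: int) -> bytes:
    s = str(text)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(path: str | Path, signal: Signal, label: str = "EEG") -> None:
    """Write a single-channel 16-bit EDF file (physical dimension uV).

    The record duration is one second, so the sampling rate must be a
    positive integer; the recording is zero-padded to a whole number of
    records.
    """
    fs = signal.fs
    if abs(fs - round(fs)) > 1e-9 or fs <= 0:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    x = np.real(np.asarray(signal.samples, dtype=float))
    n_records = int(np.ceil(x.size / fs))
    x = np.pad(x, (0, n_records * fs - x.size))
    phys_max = float(np.max(np.abs(x))) or 1.0
    dig_min, dig_max = -32768, 32767
    scale = dig_max / phys_max
    digital = np.clip(np.round(x * scale), dig_min, dig_max).astype("<i2")

    header = b"".join(
        [
            _edf_field("0", 8),  # version
            _edf_field("X X X X", 80),  # patient id (anonymous)
            _edf_field("Startdate X X X X", 80),  # recording id
            _edf_field("01.01.00", 8),
            _edf_field("00.00.00", 8),
            _edf_field(str(256 + 256), 8),  # header bytes: 256 + ns*256
            _edf_field("", 44),
            _edf_field(str(n_records), 8),
            _edf_field("1", 8),  # record duration (s)
            _edf_field("1", 4),  # ns
            # per-signal fields
            _edf_field(label, 16),
            _edf_field("", 80),  # transducer
            _edf_field("uV", 8),
            _edf_field(f"{-phys_max:.6g}"[:8], 8),
            _edf_field(f"{phys_max:.6g}"[:8], 8),
            _edf_field(str(dig_min), 8),
            _edf_field(str(dig_max), 8),
            _edf_field("", 80),  # prefiltering
            _edf_field(str(fs), 8),
            _edf_field("", 32),
        ]
    )
    with open(path, "wb") as f:
        f.write(header)
        digital.tofile(f)


def read_edf(path: str | Path) -> Signal:
    """Read the first channel of an EDF file (microvolts)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data()[0] * 1e6  # mne returns volts
    return Signal(data, fs=float(raw.info["sfreq"]))


# ---------------------------------------------------------------------------
# events / configs / datasets


def write_events_csv(path: str | Path, events: EventList) -> None:
    pd.DataFrame(
        [
            {"onset_s": e.onset_s, "duration_s": e.duration_s, "label": e.label}
            for e in events
        ],
        columns=["onset_s", "duration_s", "label"],
    ).to_csv(path, index=False)


def read_events_csv(path: str | Path) -> EventList:
    df = pd.read_csv(path)
    return EventList(
        [
            Event(float(r.onset_s), float(r.duration_s), str(r.label))
            for r in df.itertuples()
        ]
    )


def write_config_json(path: str | Path, cfg: SynthConfig) -> None:
    Path(path).write_text(json.dumps(dataclasses.asdict(cfg), indent=2))


def read_config_json(path: str | Path) -> SynthConfig:
    d = json.loads(Path(path).read_text())
    for k, v in d.items():
        if isinstance(v, list):
            d[k] = tuple(v)
    return SynthConfig(**d)


def write_dataset_csv(path: str | Path, ds: SegmentDataset) -> None:
    """One row per segment: x0..x{n-1}, label."""
    df = pd.DataFrame(np.real(ds.X))
    df.columns = [f"x{i}" for i in range(ds.X.shape[1])]
    df["label"] = ds.y
    df.to_csv(path, index=False)


def read_dataset_csv(path: str | Path) -> SegmentDataset:
    df = pd.read_csv(path)
    y = df.pop("label").to_numpy()
    return SegmentDataset(df.to_numpy(), y, None)


def write_tfr_csv(path: str | Path, grid: TFRGrid) -> None:
    """Long-format export: time index n, bin k, normalized frequency v, value."""
    n_idx, k_idx = np.meshgrid(
        np.arange(grid.time_axis.size), np.arange(grid.n_freq), indexing="ij"
    )
    vals = grid.values
    df = pd.DataFrame(
        {
            "n": np.asarray(grid.time_axis)[n_idx.ravel()],
            "k": k_idx.ravel(),
            "v": grid.freq_axis[k_idx.ravel()],
            "value": np.real(vals).ravel(),
        }
    )
    if np.iscomplexobj(vals):
        df["value_imag"] = vals.imag.ravel()
    df.to_csv(path, index=False)
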