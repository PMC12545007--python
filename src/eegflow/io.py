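"""On-disk formats: HDF5 window stores, HDF5 recording sets, and a minimal
EDF writer for exporting synthetic recordings.

The window store is the exchange format between preprocessing and every
trainable model: an ``N x electrodes x samples`` array of 2-s windows plus
labels, per-window recording ids, the train/eval split, and the sampling
rate.  EDF reading goes through :mod:`mne`; the writer here produces plain
16-bit EDF with 1-s data records, enough to round-trip synthetic data through
the same path as clinical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np

WINDOW_STORE_SCHEMA = 1


@dataclass
class WindowStore:
    """A set of fixed-length EEG windows with labels and provenance."""

    windows: np.ndarray  # (N, electrodes, samples), input units (uV)
    labels: np.ndarray  # (N,) int, 0 = healthy, 1 = pathological
    recording_ids: np.ndarray  # (N,) int
    split: np.ndarray  # (N,) int, 0 = train, 1 = eval
    sampling_rate_hz: float
    electrode_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        n = len(self.windows)
        for name in ("labels", "recording_ids", "split"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match number of windows")
        if not np.all(np.isfinite(self.windows)):
            raise ValueError("window store contains non-finite samples")

    def __len__(self) -> int:
        return len(self.windows)

    def subset(self, mask: np.ndarray) -> "WindowStore":
        return WindowStore(
            self.windows[mask],
            self.labels[mask],
            self.recording_ids[mask],
            self.split[mask],
            self.sampling_rate_hz,
            self.electrode_names,
        )

    def train_eval(self) -> tuple["WindowStore", "WindowStore"]:
        return self.subset(self.split == 0), self.subset(self.split == 1)

    def manifest(self) -> dict:
        return {
            "schema": WINDOW_STORE_SCHEMA,
            "n_windows": int(len(self)),
            "n_electrodes": int(self.windows.shape[1]),
            "window_samples": int(self.windows.shape[2]),
            "sampling_rate_hz": float(self.sampling_rate_hz),
            "electrode_names": list(self.electrode_names),
            "n_train": int(np.sum(self.split == 0)),
            "n_eval": int(np.sum(self.split == 1)),
            "class_counts": {
                "healthy": int(np.sum(self.labels == 0)),
                "pathological": int(np.sum(self.labels == 1)),
            },
        }

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.attrs["schema"] = WINDOW_STORE_SCHEMA
            f.attrs["sampling_rate_hz"] = float(self.sampling_rate_hz)
            f.attrs["electrode_names"] = json.dumps(list(self.electrode_names))
            f.create_dataset("windows", data=self.windows)
            f.create_dataset("labels", data=self.labels.astype(np.int64))
            f.create_dataset("recording_ids", data=self.recording_ids.astype(np.int64))
            f.create_dataset("split", data=self.split.astype(np.int64))

    @classmethod
    def load(cls, path) -> "WindowStore":
        with h5py.File(path, "r") as f:
            if int(f.attrs["schema"]) != WINDOW_STORE_SCHEMA:
                raise ValueError(f"unsupported window store schema {f.attrs['schema']}")
            return cls(
                windows=f["windows"][()],
                labels=f["labels"][()],
                recording_ids=f["recording_ids"][()],
                split=f["split"][()],
                sampling_rate_hz=float(f.attrs["sampling_rate_hz"]),
                electrode_names=json.loads(f.attrs["electrode_names"]),
            )


def save_recordings_h5(recordings, path) -> None:
    """Persist a list of Recording objects (equal shapes not required)."""
    with h5py.File(path, "w") as f:
        for i, r in enumerate(recordings):
            g = f.create_group(f"recording_{i:05d}")
            g.create_dataset("signals", data=r.signals)
            g.attrs["sampling_rate_hz"] = float(r.sampling_rate_hz)
            g.attrs["electrode_names"] = json.dumps(list(r.electrode_names))
            g.attrs["label"] = int(r.label)
            g.attrs["split"] = str(r.split)
            g.attrs["recording_id"] = str(r.recording_id)


def load_recordings_h5(path) -> list:
    from .preprocessing import Recording

    out = []
    with h5py.File(path, "r") as f:
        for key in sorted(f.keys()):
            g = f[key]
            out.append(
                Recording(
                    signals=g["signals"][()],
                    sampling_rate_hz=float(g.attrs["sampling_rate_hz"]),
                    electrode_names=json.loads(g.attrs["electrode_names"]),
                    label=int(g.attrs["label"]),
                    split=str(g.attrs["split"]),
                    recording_id=str(g.attrs["recording_id"]),
                )
            )
    return out


def _edf_field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(path, signals: np.ndarray, sampling_rate_hz: float, channel_names) -> None:
    """Write a minimal 16-bit EDF file with 1-second data records.

    Channel labels follow the clinical ``EEG <name>-REF`` convention so the
    reading path exercises the same alias resolution as real files.  Signals
    are in microvolts; values are linearly quantized into the int16 range.
    """
    signals = np.asarray(signals, dtype=np.float64)
    n_sig, n_samp = signals.shape
    fs = int(round(sampling_rate_hz))
    if abs(fs - sampling_rate_hz) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    n_records = n_samp // fs
    if n_records * fs != n_samp:
        signals = signals[:, : n_records * fs]
    phys_max = max(1.0, float(np.max(np.abs(signals))) * 1.01)
    dig_min, dig_max = -32768, 32767

    header = b""
    header += _edf_field("0", 8)
    header += _edf_field("X X X X", 80)
    header += _edf_field("Startdate 01-JAN-2000 X X X", 80)
    header += _edf_field("01.01.00", 8)
    header += _edf_field("00.00.00", 8)
    header += _edf_field(256 * (1 + n_sig), 8)
    header += _edf_field("", 44)
    header += _edf_field(n_records, 8)
    header += _edf_field("1", 8)
    header += _edf_field(n_sig, 4)
    for name in channel_names:
        header += _edf_field(f"EEG {name}-REF", 16)
    header += b"".join(_edf_field("", 80) for _ in range(n_sig))
    header += b"".join(_edf_field("uV", 8) for _ in range(n_sig))
    header += b"".join(_edf_field(f"{-phys_max:.6g}"[:8], 8) for _ in range(n_sig))
    header += b"".join(_edf_field(f"{phys_max:.6g}"[:8], 8) for _ in range(n_sig))
    header += b"".join(_edf_field(dig_min, 8) for _ in range(n_sig))
    header += b"".join(_edf_field(dig_max, 8) for _ in range(n_sig))
    header += b"".join(_edf_field("", 80) for _ in range(n_sig))
    header += b"".join(_edf_field(fs, 8) for _ in range(n_sig))
    header += b"".join(_edf_field("", 32) for _ in range(n_sig))

    scale = (dig_max - dig_min) / (2 * phys_max)
    digital = np.clip(np.round(signals * scale), dig_min, dig_max).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header)
        for rec in range(n_records):
            block = digital[:, rec * fs : (rec + 1) * fs]
            fh.write(block.tobytes())
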