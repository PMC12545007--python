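"""Recording-level preprocessing: the clinical-corpus reduction pipeline
(crop, resample to 64 Hz, 2-s windows) and the sub-delta lowpass.

The reduction follows the recipe used for desk-scale pathology decoding on
TUAB-style recordings: drop the first minute (artifact-prone), keep the next
two minutes, downsample to 64 Hz with polyphase anti-aliasing, and cut
non-overlapping 2-s windows.  Electrodes are reordered into a fixed canonical
21-channel 10-20 montage; clinical label variants such as ``EEG FP1-REF`` are
resolved through an alias table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy.signal import resample_poly

from .io import WindowStore

logger = logging.getLogger(__name__)

#: Canonical 21-electrode order (10-20 nomenclature, old-style temporal names).
ELECTRODES_21 = [
    "FP1", "FP2", "F7", "F3", "FZ", "F4", "F8", "A1", "T3", "C3", "CZ",
    "C4", "T4", "A2", "T5", "P3", "PZ", "P4", "T6", "O1", "O2",
]

#: Modern 10-10 names occasionally used for the same positions.
_NAME_ALIASES = {"T7": "T3", "T8": "T4", "P7": "T5", "P8": "T6"}


@dataclass
class Recording:
    """One multichannel EEG recording with its pathology label."""

    signals: np.ndarray  # (electrodes, samples), microvolts
    sampling_rate_hz: float
    electrode_names: list[str]
    label: int  # 0 = non-pathological/healthy, 1 = pathological
    split: str = "train"
    recording_id: str = ""

    @property
    def duration_s(self) -> float:
        return self.signals.shape[1] / self.sampling_rate_hz


def canonical_name(raw: str) -> str:
    """Resolve a clinical channel label ('EEG FP1-REF', 'T7', ...) to the canonical name."""
    name = raw.strip().upper()
    if name.startswith("EEG "):
        name = name[4:]
    for suffix in ("-REF", "-LE", "-AR"):
        if name.endswith(suffix):
            name = name[: -len(suffix)]
    return _NAME_ALIASES.get(name, name)


def canonical_electrode_indices(names) -> list[int]:
    """Indices picking the canonical 21 electrodes, in order, out of `names`.

    Raises if any canonical electrode is missing, listing the absent names.
    """
    resolved = {canonical_name(n): i for i, n in enumerate(names)}
    missing = [e for e in ELECTRODES_21 if e not in resolved]
    if missing:
        raise ValueError(f"recording is missing required electrodes: {missing}")
    return [resolved[e] for e in ELECTRODES_21]


def read_edf(path, label: int = 0, split: str = "train") -> Recording:
    """Read an EDF file into a Recording (signals in microvolts)."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    signals = raw.get_data() * 1e6  # mne uses volts internally
    return Recording(
        signals=signals,
        sampling_rate_hz=float(raw.info["sfreq"]),
        electrode_names=list(raw.ch_names),
        label=label,
        split=split,
        recording_id=str(path),
    )


class RecordingTooShort(ValueError):
    pass


def reduce_recording(
    r: Recording,
    target_rate_hz: float = 64.0,
    skip_s: float = 60.0,
    keep_s: float = 120.0,
) -> Recording:
    """Crop to [skip_s, skip_s + keep_s), downsample, reorder electrodes.

    The output has exactly ``keep_s * target_rate_hz`` samples (7,680 at the
    defaults) in the canonical electrode order.
    """
    if r.duration_s < skip_s + keep_s:
        raise RecordingTooShort(
            f"recording {r.recording_id!r} is {r.duration_s:.1f} s, "
            f"needs at least {skip_s + keep_s:.0f} s"
        )
    order = canonical_electrode_indices(r.electrode_names)
    fs = r.sampling_rate_hz
    a = int(round(skip_s * fs))
    b = a + int(round(keep_s * fs))
    cropped = r.signals[order, a:b]
    if fs != target_rate_hz:
        frac = Fraction(target_rate_hz / fs).limit_denominator(10000)
        resampled = resample_poly(cropped, frac.numerator, frac.denominator, axis=1)
    else:
        resampled = cropped
    n_expected = int(round(keep_s * target_rate_hz))
    if resampled.shape[1] < n_expected:
        resampled = np.pad(resampled, ((0, 0), (0, n_expected - resampled.shape[1])))
    resampled = resampled[:, :n_expected]
    return Recording(
        signals=resampled,
        sampling_rate_hz=target_rate_hz,
        electrode_names=list(ELECTRODES_21),
        label=r.label,
        split=r.split,
        recording_id=r.recording_id,
    )


def window_recording(r: Recording, window_s: float = 2.0, overlap_s: float = 0.0) -> np.ndarray:
    """Cut a recording into fixed-length windows: (n_windows, electrodes, samples).

    Non-overlapping by default; window k covers samples [k*S, (k+1)*S).
    """
    S = int(round(window_s * r.sampling_rate_hz))
    hop = S - int(round(overlap_s * r.sampling_rate_hz))
    if hop <= 0:
        raise ValueError("overlap must be smaller than the window length")
    n = (r.signals.shape[1] - S) // hop + 1
    if n <= 0:
        return np.empty((0, r.signals.shape[0], S))
    return np.stack([r.signals[:, k * hop : k * hop + S] for k in range(n)])


def lowpass_below(signal: np.ndarray, cutoff_hz: float = 0.5, sampling_rate_hz: float = 64.0) -> np.ndarray:
    """Remove every Fourier component strictly above `cutoff_hz` (last axis).

    Implemented by zeroing DFT bins, so it is idempotent and exactly preserves
    retained components, including DC.
    """
    signal = np.asarray(signal, dtype=np.float64)
    n = signal.shape[-1]
    spec = np.fft.rfft(signal, axis=-1)
    freqs = np.fft.rfftfreq(n, d=1.0 / sampling_rate_hz)
    spec[..., freqs > cutoff_hz + 1e-12] = 0.0
    return np.fft.irfft(spec, n=n, axis=-1)


def build_window_store(
    recordings: list[Recording],
    reduce: bool = True,
    window_s: float = 2.0,
    overlap_s: float = 0.0,
    target_rate_hz: float = 64.0,
) -> WindowStore:
    """Run the reduction pipeline over recordings and collect all windows.

    Too-short recordings are skipped with a logged reason.  With
    ``reduce=False`` (e.g. synthetic data already at the target rate in
    canonical order), recordings are windowed as-is.
    """
    all_windows, labels, rec_ids, split = [], [], [], []
    for i, r in enumerate(recordings):
        if reduce:
            try:
                r = reduce_recording(r, target_rate_hz=target_rate_hz)
            except RecordingTooShort as e:
                logger.warning("skipping recording: %s", e)
                continue
        w = window_recording(r, window_s=window_s, overlap_s=overlap_s)
        all_windows.append(w)
        labels.extend([r.label] * len(w))
        rec_ids.extend([i] * len(w))
        split.extend([0 if r.split == "train" else 1] * len(w))
    if not all_windows:
        raise ValueError("no usable recordings")
    fs = target_rate_hz if reduce else recordings[0].sampling_rate_hz
    return WindowStore(
        windows=np.concatenate(all_windows),
        labels=np.asarray(labels, dtype=np.int64),
        recording_ids=np.asarray(rec_ids, dtype=np.int64),
        split=np.asarray(split, dtype=np.int64),
        sampling_rate_hz=fs,
        electrode_names=list(recordings[0].electrode_names),
    )
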