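"""Spectral validation analyses: relative log-bandpower scalp maps and
class-wise sub-delta Fourier amplitude maps.

Bandpower maps answer "where on the scalp, and in which band, does the
pathological class carry more power than the healthy class?".  Power spectra
are computed from 10-s windows with 5-s overlap, Hamming-tapered, the median
power per frequency bin is taken across all windows of a class (pooled over
recordings), bins are averaged within standard bands, and the map shows
log(pathological / healthy) per electrode and band.

Sub-delta amplitude maps show the class-wise mean |DFT| of the 2-s training
windows at the 0-Hz and 0.5-Hz bins — the features where a frontal,
healthy-dominant difference shows up.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import get_window

from .preprocessing import ELECTRODES_21, Recording

#: Standard band definitions (Hz); the top band is truncated at Nyquist for 64-Hz data.
BANDS = [
    ("delta", 0.0, 4.0),
    ("theta", 4.0, 8.0),
    ("alpha", 8.0, 14.0),
    ("low_beta", 14.0, 20.0),
    ("high_beta", 20.0, 30.0),
    ("low_gamma", 30.0, 50.0),
]


@dataclass
class ScalpMap:
    """One value per canonical electrode, labeled with what it measures."""

    electrodes: list[str]
    values: np.ndarray
    label: str
    units: str

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.electrodes, name=self.label)


def windowed_power(
    signals: np.ndarray,
    sampling_rate_hz: float,
    window_s: float = 10.0,
    hop_s: float = 5.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Hamming-tapered power per sliding window: (n_windows, electrodes, n_bins)."""
    S = int(round(window_s * sampling_rate_hz))
    hop = int(round(hop_s * sampling_rate_hz))
    if signals.shape[-1] < S:
        raise ValueError(f"signal shorter than the {window_s}-s analysis window")
    segs = sliding_window_view(signals, S, axis=-1)[..., ::hop, :]  # (E, n_win, S)
    taper = get_window("hamming", S)
    spec = np.fft.rfft(segs * taper, axis=-1)
    power = np.abs(spec) ** 2
    freqs = np.fft.rfftfreq(S, d=1.0 / sampling_rate_hz)
    return np.moveaxis(power, -2, 0), freqs  # (n_win, E, n_bins)


def _median_band_power(recordings: list[Recording], bands) -> np.ndarray:
    fs = recordings[0].sampling_rate_hz
    pools = []
    for r in recordings:
        p, freqs = windowed_power(r.signals, fs)
        pools.append(p)
    power = np.concatenate(pools, axis=0)  # pooled windows across recordings
    med = np.median(power, axis=0)  # (E, n_bins)
    out = np.empty((med.shape[0], len(bands)))
    nyquist = fs / 2.0
    for j, (_, lo, hi) in enumerate(bands):
        sel = (freqs >= lo) & (freqs < min(hi, nyquist) + 1e-12)
        out[:, j] = med[:, sel].mean(axis=1)
    return out


def bandpower_maps(
    healthy: list[Recording],
    pathological: list[Recording],
    bands=BANDS,
) -> list[ScalpMap]:
    """Per-band scalp maps of log(median pathological power / median healthy power)."""
    if not healthy or not pathological:
        raise ValueError("both classes need at least one recording")
    ph = _median_band_power(healthy, bands)
    pp = _median_band_power(pathological, bands)
    electrodes = list(healthy[0].electrode_names) or list(ELECTRODES_21)
    # log(pp) - log(ph) rather than log(pp/ph): exactly antisymmetric under class swap
    return [
        ScalpMap(electrodes, np.log(pp[:, j]) - np.log(ph[:, j]), name,
                 "log power ratio (pathological/healthy)")
        for j, (name, _, _) in enumerate(bands)
    ]


def bandpower_frame(maps: list[ScalpMap]) -> pd.DataFrame:
    return pd.DataFrame({m.label: m.to_series() for m in maps})


def subdelta_amplitude_maps(
    windows: np.ndarray,
    labels: np.ndarray,
    sampling_rate_hz: float = 64.0,
) -> list[ScalpMap]:
    """Class-wise mean |DFT| per electrode at the 0-Hz and 0.5-Hz bins of 2-s windows."""
    windows = np.asarray(windows, dtype=np.float64)
    labels = np.asarray(labels)
    spec = np.fft.rfft(windows, axis=-1)
    freqs = np.fft.rfftfreq(windows.shape[-1], d=1.0 / sampling_rate_hz)
    maps = []
    for c, cname in enumerate(("healthy", "pathological")):
        sel = labels == c
        if not np.any(sel):
            raise ValueError(f"no windows for class {cname}")
        amp = np.abs(spec[sel])
        for b, bname in ((0, "0.0 Hz"), (1, f"{freqs[1]:.2g} Hz")):
            maps.append(
                ScalpMap(
                    list(ELECTRODES_21)[: windows.shape[1]],
                    amp[:, :, b].mean(axis=0),
                    f"{cname} @ {bname}",
                    "mean |DFT| amplitude",
                )
            )
    return maps
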