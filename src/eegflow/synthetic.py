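"""Synthetic EEG with planted, parameterized class differences.

The generator emulates the qualitative structure of clinical pathology
decoding data: a 1/f ("pink") background at every electrode plus a small set
of localized sources whose amplitude depends on the class label.  The default
configuration plants the three effects reported for pathological-vs-healthy
EEG:

* 10-Hz (alpha) activity at O1/O2, stronger in the healthy class;
* 2-Hz (delta, "temporal slowing") activity at T3/T4, stronger in the
  pathological class;
* a 0.3-Hz frontal drift at FP1/FP2, stronger in the healthy class
  (the sub-delta, healthy-dominant feature).

Oscillatory sources are amplitude-modulated sinusoids with a random phase per
recording, so no trivially learnable phase locking exists across recordings.
Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io import WindowStore
from .preprocessing import ELECTRODES_21, Recording, build_window_store


def _topography(electrodes: list[str]) -> np.ndarray:
    topo = np.zeros(len(ELECTRODES_21))
    for e in electrodes:
        topo[ELECTRODES_21.index(e)] = 1.0
    return topo


@dataclass
class SourceSpec:
    """One planted source: where (topography), what (frequency, waveform kind),
    and how strongly per class (amplitudes in uV, healthy then pathological)."""

    topography: np.ndarray  # (21,)
    freq_hz: float
    amplitude_healthy: float
    amplitude_pathological: float
    kind: str = "narrowband"  # sinusoid | narrowband | drift

    def amplitude(self, label: int) -> float:
        return self.amplitude_pathological if label == 1 else self.amplitude_healthy


def default_sources() -> list[SourceSpec]:
    return [
        SourceSpec(_topography(["O1", "O2"]), 10.0, 12.0, 4.0, "narrowband"),
        SourceSpec(_topography(["T3", "T4"]), 2.0, 4.0, 12.0, "narrowband"),
        SourceSpec(_topography(["FP1", "FP2"]), 0.3, 12.0, 4.0, "drift"),
    ]


@dataclass
class GeneratorConfig:
    n_recordings_per_class: int = 200
    duration_s: float = 60.0
    sampling_rate_hz: float = 64.0
    seed: int = 0
    background_exponent: float = 1.0  # power ~ 1/f^beta
    background_rms: float = 10.0  # uV
    train_fraction: float = 0.75
    sources: list[SourceSpec] = field(default_factory=default_sources)

    def with_amplitude_scale(self, factor: float) -> "GeneratorConfig":
        """Scale every planted class *difference* by `factor`, keeping the mean level."""
        scaled = []
        for s in self.sources:
            mean = 0.5 * (s.amplitude_healthy + s.amplitude_pathological)
            half = 0.5 * (s.amplitude_healthy - s.amplitude_pathological) * factor
            scaled.append(
                replace(
                    s,
                    amplitude_healthy=max(mean + half, 0.0),
                    amplitude_pathological=max(mean - half, 0.0),
                )
            )
        return replace(self, sources=scaled)


def _pink_background(rng: np.random.Generator, n_channels: int, n_samples: int,
                     exponent: float, rms: float, fs: float) -> np.ndarray:
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    shaping = np.zeros_like(freqs)
    shaping[1:] = freqs[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * shaping, n=n_samples, axis=1)
    std = x.std(axis=1, keepdims=True)
    std[std == 0] = 1.0
    return x / std * rms


def _envelope(rng: np.random.Generator, n_samples: int, fs: float, cutoff_hz: float = 1.0) -> np.ndarray:
    """Slowly varying positive envelope with mean ~1."""
    noise = rng.standard_normal(n_samples)
    spec = np.fft.rfft(noise)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    spec[freqs > cutoff_hz] = 0.0
    slow = np.fft.irfft(spec, n=n_samples)
    std = slow.std()
    if std > 0:
        slow = slow / std
    return np.clip(1.0 + 0.5 * slow, 0.1, None)


def _source_signal(rng: np.random.Generator, spec: SourceSpec, n_samples: int, fs: float) -> np.ndarray:
    t = np.arange(n_samples) / fs
    phase = rng.uniform(0, 2 * np.pi)
    carrier = np.sin(2 * np.pi * spec.freq_hz * t + phase)
    if spec.kind == "sinusoid":
        return carrier
    if spec.kind == "drift":
        # slow wandering component: sinusoid at the drift frequency, random phase
        return carrier
    if spec.kind == "narrowband":
        return _envelope(rng, n_samples, fs) * carrier
    raise ValueError(f"unknown source kind {spec.kind!r}")


def generate(config: GeneratorConfig) -> list[Recording]:
    """Generate labeled recordings: sum of planted sources plus 1/f background."""
    fs = config.sampling_rate_hz
    n_samples = int(round(config.duration_s * fs))
    n_channels = len(ELECTRODES_21)
    for s in config.sources:
        if len(s.topography) != n_channels:
            raise ValueError(
                f"topography length {len(s.topography)} != {n_channels} electrodes"
            )
        if s.amplitude_healthy < 0 or s.amplitude_pathological < 0:
            raise ValueError("source amplitudes must be non-negative")
    rng = np.random.default_rng(config.seed)
    n_train = int(round(config.train_fraction * config.n_recordings_per_class))
    recordings = []
    for label in (0, 1):
        for i in range(config.n_recordings_per_class):
            x = _pink_background(
                rng, n_channels, n_samples, config.background_exponent,
                config.background_rms, fs,
            )
            for s in config.sources:
                amp = s.amplitude(label)
                if amp > 0:
                    x += amp * np.outer(s.topography, _source_signal(rng, s, n_samples, fs))
            recordings.append(
                Recording(
                    signals=x,
                    sampling_rate_hz=fs,
                    electrode_names=list(ELECTRODES_21),
                    label=label,
                    split="train" if i < n_train else "eval",
                    recording_id=f"synthetic-{'HP'[label]}{i:04d}",
                )
            )
    return recordings


def generate_windows(config: GeneratorConfig, window_s: float = 2.0) -> WindowStore:
    """Generate recordings and cut them directly into a window store."""
    return build_window_store(generate(config), reduce=False, window_s=window_s)


# ---------------------------------------------------------------------------
# planted sub-delta feature clusters for the Fourier-mixture classifier
# ---------------------------------------------------------------------------


def planted_subdelta_clusters(
    n_windows: int,
    seed: int = 0,
    n_components: int = 8,
    window_samples: int = 128,
    separation: float = 400.0,
    within_std: float = 20.0,
):
    """Windows whose sub-delta Fourier features form well-separated clusters.

    Each of `n_components` clusters has a known 63-dim mean (unnormalized DFT
    convention: Re of bin 0 and Re/Im of bin 1 per electrode) and a pure class
    assignment, alternating healthy/pathological.  Windows are synthesized by
    inverse DFT so feature extraction recovers the planted values exactly.

    Returns (windows, labels, truth) where truth carries the component means,
    class weights (one-hot), and component assignment per window.
    """
    n_electrodes = len(ELECTRODES_21)
    d = 3 * n_electrodes
    rng = np.random.default_rng(seed)
    comp_means = rng.standard_normal((n_components, d)) * separation
    comp_class = np.arange(n_components) % 2  # alternating pure classes
    assignment = rng.integers(0, n_components, size=n_windows)
    feats = comp_means[assignment] + within_std * rng.standard_normal((n_windows, d))
    labels = comp_class[assignment]

    spec = np.zeros((n_windows, n_electrodes, window_samples // 2 + 1), dtype=complex)
    f = feats.reshape(n_windows, n_electrodes, 3)
    spec[:, :, 0] = f[:, :, 0]
    spec[:, :, 1] = f[:, :, 1] + 1j * f[:, :, 2]
    windows = np.fft.irfft(spec, n=window_samples, axis=2)
    truth = {
        "component_means": comp_means,
        "class_weights": np.eye(2)[comp_class],  # (K, 2) one-hot
        "assignment": assignment,
    }
    return windows, labels.astype(np.int64), truth


def single_source_windows(
    n_windows: int,
    seed: int = 0,
    window_samples: int = 128,
    sampling_rate_hz: float = 64.0,
    freq_hz: float = 10.0,
    snr: float = 2.0,
):
    """Windows generated as x = a s(t) + noise with a known mixing topography.

    The source s is an amplitude-modulated sinusoid; its presence/absence
    defines the two classes.  Used for filter-to-pattern (Haufe) recovery:
    the ground-truth activation pattern is proportional to `a`.
    """
    rng = np.random.default_rng(seed)
    n_electrodes = len(ELECTRODES_21)
    a = rng.standard_normal(n_electrodes)
    a /= np.linalg.norm(a)
    labels = rng.integers(0, 2, size=n_windows)
    t = np.arange(window_samples) / sampling_rate_hz
    noise = rng.standard_normal((n_windows, n_electrodes, window_samples))
    windows = noise.copy()
    for i in range(n_windows):
        if labels[i] == 1:
            phase = rng.uniform(0, 2 * np.pi)
            env = _envelope(rng, window_samples, sampling_rate_hz)
            s = snr * env * np.sin(2 * np.pi * freq_hz * t + phase)
            windows[i] += np.outer(a, s)
    return windows, labels.astype(np.int64), a
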