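"""Prototype visualizations for the invertible generative classifier.

Two complementary procedures:

* **Class prototypes** — invert each class's latent Gaussian mean through the
  network: x_c = f^{-1}(mu_c).  The result is the most likely input under
  that class's latent prior, a whole-montage "prototypical example".

* **Per-electrode prototypes** — optimize a single-electrode signal x* so
  that windows carrying x* at electrode e_k are (a) likely under the target
  class and (b) classified as the target class, *marginalizing* over the
  signals at all other electrodes.  The marginal is approximated by Monte
  Carlo: background windows are drawn from the training data and electrode
  e_k is replaced by x*,

      p(x*_{ek} | c) ~= (1/n) sum_l p(x_l | c ; x_l,ek = x*_{ek}),

  computed as a logsumexp.  For the classification term the per-sample log
  densities are divided by the classifier's learned temperature before the
  logsumexp, which prevents a few background samples from dominating the
  pooled class score; the generative term is left unscaled.

Background samples are pooled across both classes.  The reported
``mean_posterior`` is the average softmax probability of the target class
over a large held-out background set (10,240 samples by default), so an
electrode the network never uses stays near 0.5.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .autodiff import Tensor, concatenate, logsumexp, parameter
from .invnet import CLASS_NAMES, EEGInvNet
from .optim import AdamW


@dataclass
class ClassPrototype:
    signal: np.ndarray  # (electrodes, samples), input units
    class_id: int
    source: str = "prior_mean_inversion"


@dataclass
class ElectrodePrototype:
    electrode_index: int
    signal: np.ndarray  # (samples,), input units
    class_id: int
    mean_posterior: float
    objective_history: list[float] = field(default_factory=list)

    def __post_init__(self):
        if not 0.0 <= self.mean_posterior <= 1.0:
            raise ValueError("mean_posterior must be a probability")


@dataclass
class BackgroundSampleSet:
    """Training windows used to marginalize over non-optimized electrodes."""

    samples: np.ndarray  # (n, electrodes, samples), input units

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if len(self.samples) < 1:
            raise ValueError("background sample set must be nonempty")

    @property
    def n(self) -> int:
        return len(self.samples)


def class_prototype(model: EEGInvNet, c: int) -> ClassPrototype:
    """Invert the class's latent Gaussian mean back to an input-space signal."""
    z = model.class_means.data[c]
    x_scaled = model.net_inverse(z)
    signal = x_scaled * model.channel_scale[:, None]
    return ClassPrototype(signal=signal, class_id=c)


def _patched_log_probs(model: EEGInvNet, x_star: np.ndarray, ek: int,
                       bg: BackgroundSampleSet, batch_size: int = 512) -> np.ndarray:
    """(n, 2) log p of background windows with electrode ek replaced by x_star."""
    out = np.empty((bg.n, 2))
    for i in range(0, bg.n, batch_size):
        chunk = bg.samples[i : i + batch_size].copy()
        chunk[:, ek, :] = x_star
        out[i : i + batch_size] = model.log_prob_all(chunk)
    return out


def marginal_log_prob(model: EEGInvNet, x_star: np.ndarray, ek: int, c: int,
                      bg: BackgroundSampleSet) -> float:
    """Monte-Carlo marginal log-likelihood of the single-electrode signal."""
    lp = _patched_log_probs(model, x_star, ek, bg)[:, c]
    m = lp.max()
    return float(m + np.log(np.mean(np.exp(lp - m))))


def classification_score(model: EEGInvNet, x_star: np.ndarray, ek: int,
                         bg: BackgroundSampleSet, c: int, t: float | None = None) -> float:
    """Temperature-pooled log posterior of class c for the patched windows."""
    if t is None:
        t = model.temperature
    if t <= 0:
        raise ValueError("temperature must be positive")
    lp = _patched_log_probs(model, x_star, ek, bg) / t  # (n, 2)
    pooled = np.logaddexp.reduce(lp, axis=0)  # logsumexp over samples, per class
    return float(pooled[c] - np.logaddexp.reduce(pooled))


def _objective_t(model: EEGInvNet, x_star_scaled: Tensor, ek: int,
                 bg_scaled: np.ndarray, c: int, t: float, alpha: float) -> Tensor:
    """Differentiable prototype objective on scaled windows (to be maximized)."""
    B = len(bg_scaled)
    bgT = Tensor(bg_scaled)
    xs = x_star_scaled.reshape(1, 1, -1).broadcast_to((B, 1, bg_scaled.shape[2]))
    patched = concatenate([bgT[:, :ek, :], xs, bgT[:, ek + 1 :, :]], axis=1)
    lp = model._log_prob_all_t(patched)  # (B, 2)
    pooled = logsumexp(lp * (1.0 / t), axis=0)  # (2,)
    clf = pooled[c] - logsumexp(pooled, axis=0)
    marg = logsumexp(lp[:, c], axis=0) - np.log(B)
    return clf + alpha * marg


def optimize_electrode_prototype(
    model: EEGInvNet,
    ek: int,
    c: int,
    bg_source: np.ndarray,
    steps: int = 500,
    batch_size: int = 64,
    lr: float = 0.01,
    seed: int = 0,
    eval_n: int = 10240,
    fixed_background: bool = False,
) -> ElectrodePrototype:
    """Gradient-ascent per-electrode prototype with Monte-Carlo marginalization.

    `bg_source` is an array of training windows in input units (pooled across
    classes).  Each step draws a fresh background mini-batch unless
    `fixed_background` is set.  The optimized signal starts at zero and is
    reported in input units together with the mean posterior over a held-out
    evaluation background set of `eval_n` samples.
    """
    bg_source = np.asarray(bg_source, dtype=np.float64)
    if len(bg_source) == 0:
        raise ValueError("background source must be nonempty")
    cfg = model.config
    rng = np.random.default_rng(seed)
    scaled_source = bg_source / model.channel_scale[:, None]
    x_star = parameter(np.zeros(cfg.window_samples))
    opt = AdamW([x_star], lr=lr, weight_decay=0.0)
    t = model.temperature
    alpha = model.alpha
    fixed_idx = rng.integers(0, len(bg_source), size=batch_size)
    history: list[float] = []
    for step in range(steps):
        idx = fixed_idx if fixed_background else rng.integers(0, len(bg_source), size=batch_size)
        obj = _objective_t(model, x_star, ek, scaled_source[idx], c, t, alpha)
        if not np.isfinite(obj.data):
            raise RuntimeError(f"prototype objective diverged at step {step}")
        history.append(float(obj.data))
        loss = -obj
        opt.zero_grad()
        loss.backward()
        opt.step()
    signal = x_star.data * model.channel_scale[ek]

    eval_idx = np.random.default_rng(seed + 1).integers(0, len(bg_source), size=eval_n)
    posts = []
    for i in range(0, eval_n, 512):
        chunk = bg_source[eval_idx[i : i + 512]].copy()
        chunk[:, ek, :] = signal
        posts.append(model.classify(chunk)[:, c])
    mean_post = float(np.concatenate(posts).mean())
    return ElectrodePrototype(
        electrode_index=ek,
        signal=signal,
        class_id=c,
        mean_posterior=mean_post,
        objective_history=history,
    )


def export_prototype_csv(proto, sampling_rate_hz: float, csv_path, json_path=None,
                         electrode_names: list[str] | None = None, settings: dict | None = None) -> None:
    """Write a prototype as CSV (time in seconds, amplitude in input units)
    with a JSON sidecar carrying the evaluation statistic and settings."""
    if isinstance(proto, ClassPrototype):
        n = proto.signal.shape[1]
        data = {"time_s": np.arange(n) / sampling_rate_hz}
        names = electrode_names or [f"ch{i}" for i in range(proto.signal.shape[0])]
        for i, name in enumerate(names):
            data[name] = proto.signal[i]
        sidecar = {"kind": "class_prototype", "class": CLASS_NAMES[proto.class_id],
                   "source": proto.source}
    else:
        n = len(proto.signal)
        data = {"time_s": np.arange(n) / sampling_rate_hz, "amplitude": proto.signal}
        sidecar = {
            "kind": "electrode_prototype",
            "class": CLASS_NAMES[proto.class_id],
            "electrode_index": int(proto.electrode_index),
            "mean_posterior": proto.mean_posterior,
        }
    if settings:
        sidecar["settings"] = settings
    pd.DataFrame(data).to_csv(csv_path, index=False)
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump(sidecar, fh, indent=2)
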