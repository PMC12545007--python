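"""Gaussian-mixture classifier on per-electrode sub-delta Fourier features.

For a 2-s window at 64 Hz, the DFT's bin 0 is the DC component and bin 1 sits
at 0.5 Hz.  Three features are kept per electrode — Re(bin 0), Re(bin 1),
Im(bin 1) — giving 63 features for the 21-electrode montage (unnormalized
forward DFT convention, so features are reproducible bit for bit).

The classifier is a single shared 8-component diagonal-covariance Gaussian
mixture; each component k carries a learnable class weight v_{k,c}
(a softmax over the two classes) in addition to its mixture weight pi_k.
The class-conditional density is

    p(x | c) = sum_k w_{k,c} N(x; mu_k, diag(sigma_k^2)),
    w_{k,c}  = pi_k v_{k,c} / sum_j pi_j v_{j,c},

so both the overall mixture weights and each class-conditional weight vector
normalize to one.  A component that belongs purely to one class converges to
v near (1, 0) or (0, 1).

Training is by gradient descent on the same combined
classification-plus-generative loss used by the invertible network, with
alpha = 1/63 and a learned softmax temperature.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .autodiff import Tensor, logsumexp, parameter
from .optim import AdamW, cosine_restart_lr
from .preprocessing import ELECTRODES_21

_VAR_FLOOR = 1e-6


def extract_features(x: np.ndarray, sampling_rate_hz: float = 64.0) -> np.ndarray:
    """Sub-delta Fourier features of 2-s windows: per electrode Re(bin 0),
    Re(bin 1), Im(bin 1), concatenated electrode-major."""
    x = np.asarray(x, dtype=np.float64)
    single = x.ndim == 2
    if single:
        x = x[None]
    n = x.shape[-1]
    required = int(round(2.0 * sampling_rate_hz))
    if n != required:
        raise ValueError(
            f"window must span 2 s ({required} samples at {sampling_rate_hz} Hz), got {n}"
        )
    spec = np.fft.rfft(x, axis=-1)
    feats = np.stack([spec[..., 0].real, spec[..., 1].real, spec[..., 1].imag], axis=-1)
    feats = feats.reshape(x.shape[0], -1)
    return feats[0] if single else feats


@dataclass
class GMMHistory:
    loss: list[float] = field(default_factory=list)
    accuracy: list[float] = field(default_factory=list)


class FourierGMM:
    """Shared Gaussian mixture with per-component class weights."""

    def __init__(self, n_features: int = 63, n_components: int = 8, seed: int = 0):
        self.n_features = n_features
        self.n_components = n_components
        rng = np.random.default_rng(seed)
        self.means = parameter(rng.standard_normal((n_components, n_features)))
        self.log_vars = parameter(np.zeros((n_components, n_features)))
        self.mix_logits = parameter(np.zeros(n_components))
        self.class_logits = parameter(np.zeros((n_components, 2)))
        self.log_t = parameter(np.log(n_features))

    def parameters(self) -> list[Tensor]:
        return [self.means, self.log_vars, self.mix_logits, self.class_logits, self.log_t]

    # -- derived quantities (numpy) -------------------------------------------
    @property
    def mixture_weights(self) -> np.ndarray:
        m = self.mix_logits.data
        e = np.exp(m - m.max())
        return e / e.sum()

    @property
    def class_weights(self) -> np.ndarray:
        """(K, 2): per-component class weights v_{k,c} (softmax over classes)."""
        cl = self.class_logits.data
        e = np.exp(cl - cl.max(axis=1, keepdims=True))
        return e / e.sum(axis=1, keepdims=True)

    def class_component_weights(self) -> np.ndarray:
        """(K, 2): w_{k,c} proportional to pi_k v_{k,c}, normalized over k."""
        w = self.mixture_weights[:, None] * self.class_weights
        return w / w.sum(axis=0, keepdims=True)

    # -- densities ---------------------------------------------------------------
    def _log_w_t(self) -> Tensor:
        """(K, 2) log w_{k,c} as a differentiable tensor."""
        log_pi = self.mix_logits - logsumexp(self.mix_logits, axis=0, keepdims=True)
        log_v = self.class_logits - logsumexp(self.class_logits, axis=1, keepdims=True)
        joint = log_pi.reshape(-1, 1) + log_v
        return joint - logsumexp(joint, axis=0, keepdims=True)

    def _log_comp_t(self, x: Tensor) -> Tensor:
        """(B, K) log N(x; mu_k, sigma_k^2)."""
        B = x.shape[0]
        var = self.log_vars.exp() + _VAR_FLOOR  # (K, D)
        diff = x.reshape(B, 1, self.n_features) - self.means
        sq = (diff * diff / var).sum(axis=2)  # (B, K)
        log_norm = var.log().sum(axis=1) + self.n_features * np.log(2 * np.pi)  # (K,)
        return (sq + log_norm) * (-0.5)

    def _log_prob_all_t(self, x: Tensor) -> Tensor:
        """(B, 2) class-conditional mixture log densities."""
        log_comp = self._log_comp_t(x)  # (B, K)
        log_w = self._log_w_t()  # (K, 2)
        B = x.shape[0]
        stacked = log_comp.reshape(B, self.n_components, 1) + log_w
        return logsumexp(stacked, axis=1)

    def log_prob_all(self, features: np.ndarray) -> np.ndarray:
        features = np.atleast_2d(np.asarray(features, dtype=np.float64))
        return self._log_prob_all_t(Tensor(features)).data

    def gmm_class_log_prob(self, features: np.ndarray, c: int) -> float | np.ndarray:
        lp = self.log_prob_all(features)[:, c]
        return float(lp[0]) if lp.shape[0] == 1 and np.asarray(features).ndim == 1 else lp

    def classify(self, features: np.ndarray) -> np.ndarray:
        """Bayes posterior over classes (uniform class priors)."""
        lp = self.log_prob_all(features)
        lp = lp - lp.max(axis=1, keepdims=True)
        p = np.exp(lp)
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, features: np.ndarray) -> np.ndarray:
        return np.argmax(self.log_prob_all(features), axis=1)

    def score(self, features: np.ndarray, labels: np.ndarray) -> float:
        return float(np.mean(self.predict(features) == np.asarray(labels)))

    def responsibilities(self, features: np.ndarray) -> np.ndarray:
        """(B, K) posterior over components under the marginal mixture."""
        x = Tensor(np.atleast_2d(np.asarray(features, dtype=np.float64)))
        log_comp = self._log_comp_t(x).data
        log_pi = np.log(self.mixture_weights)
        joint = log_comp + log_pi
        joint -= joint.max(axis=1, keepdims=True)
        r = np.exp(joint)
        return r / r.sum(axis=1, keepdims=True)

    # -- init / maintenance --------------------------------------------------------
    def initialize_from_data(self, features: np.ndarray, rng: np.random.Generator) -> None:
        """Seed component means with k-means++-style spreading (far-apart data
        points are preferred), variances with the data variance."""
        n = len(features)
        centers = [features[rng.integers(n)]]
        d2 = np.sum((features - centers[0]) ** 2, axis=1)
        for _ in range(1, self.n_components):
            probs = d2 / d2.sum() if d2.sum() > 0 else np.full(n, 1.0 / n)
            centers.append(features[rng.choice(n, p=probs)])
            d2 = np.minimum(d2, np.sum((features - centers[-1]) ** 2, axis=1))
        self.means.data = np.asarray(centers, dtype=np.float64)
        var = features.var(axis=0) + 1e-3
        self.log_vars.data = np.tile(np.log(var), (self.n_components, 1))

    def _reinit_collapsed(self, features: np.ndarray, rng: np.random.Generator) -> None:
        collapsed = np.exp(self.log_vars.data).min(axis=1) < 1e-8
        if np.any(collapsed):
            warnings.warn(
                f"re-initializing {int(collapsed.sum())} collapsed mixture component(s)"
            )
            idx = rng.choice(len(features), size=int(collapsed.sum()), replace=False)
            self.means.data[collapsed] = features[idx]
            self.log_vars.data[collapsed] = np.log(features.var(axis=0) + 1e-3)

    def save(self, path) -> None:
        np.savez(path, means=self.means.data, log_vars=self.log_vars.data,
                 mix_logits=self.mix_logits.data, class_logits=self.class_logits.data,
                 log_t=self.log_t.data)

    @classmethod
    def load(cls, path) -> "FourierGMM":
        with np.load(path) as d:
            model = cls(n_features=d["means"].shape[1], n_components=d["means"].shape[0])
            for name in ("means", "log_vars", "mix_logits", "class_logits", "log_t"):
                getattr(model, name).data = np.array(d[name])
        return model


def train_fourier_gmm(
    dataset: tuple[np.ndarray, np.ndarray],
    seed: int = 0,
    n_components: int = 8,
    epochs: int = 30,
    lr: float = 0.05,
    batch_size: int = 512,
    restart_period: int = 25,
    verbose: bool = False,
) -> tuple[FourierGMM, GMMHistory]:
    """Fit the mixture classifier on (features, labels) by gradient descent on
    the combined classification + generative loss (alpha = 1/n_features)."""
    features, labels = np.asarray(dataset[0], dtype=np.float64), np.asarray(dataset[1])
    rng = np.random.default_rng(seed)
    model = FourierGMM(n_features=features.shape[1], n_components=n_components, seed=seed)
    model.initialize_from_data(features, rng)
    # standardize internally for conditioning; fold back via affine-invariant params
    mu0, sd0 = features.mean(axis=0), features.std(axis=0) + 1e-12
    feats = (features - mu0) / sd0
    model.means.data = (model.means.data - mu0) / sd0
    model.log_vars.data = model.log_vars.data - 2 * np.log(sd0)
    alpha = 1.0 / features.shape[1]
    opt = AdamW(model.parameters(), lr=lr, weight_decay=0.0)
    history = GMMHistory()
    n = len(feats)
    for epoch in range(epochs):
        opt.lr = cosine_restart_lr(lr, epoch, period=restart_period)
        perm = rng.permutation(n)
        total, correct = 0.0, 0
        for start in range(0, n, batch_size):
            sel = perm[start : start + batch_size]
            xb = Tensor(feats[sel])
            lp = model._log_prob_all_t(xb)
            idx = (np.arange(len(sel)), labels[sel])
            t_inv = (-model.log_t).exp()
            logits = lp * t_inv
            clf = logsumexp(logits, axis=1) - logits[idx]
            gen = lp[idx] * (-alpha)
            loss = (clf + gen).mean()
            if not np.isfinite(loss.data):
                raise RuntimeError(f"NaN/inf mixture loss at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            total += float(loss.data) * len(sel)
            correct += int(np.sum(np.argmax(lp.data, axis=1) == labels[sel]))
        model._reinit_collapsed(feats, rng)
        history.loss.append(total / n)
        history.accuracy.append(correct / n)
        if verbose:  # pragma: no cover
            print(f"epoch {epoch:3d}  loss {history.loss[-1]:.4f}  acc {history.accuracy[-1]:.3f}")
    # de-standardize so the model operates on raw features
    model.means.data = model.means.data * sd0 + mu0
    model.log_vars.data = model.log_vars.data + 2 * np.log(sd0)
    return model, history


def visualize_components(
    model: FourierGMM, electrode_names: list[str] | None = None
) -> tuple[pd.DataFrame, dict]:
    """Per-component scalp-value tables for the three feature parts, ordered by
    pathological class weight (most pathological first)."""
    names = electrode_names or list(ELECTRODES_21)
    e = len(names)
    if model.n_features != 3 * e:
        raise ValueError(f"model has {model.n_features} features, expected {3 * e}")
    v = model.class_weights
    order = np.argsort(-v[:, 1], kind="stable")
    rows = []
    for rank, k in enumerate(order):
        m = model.means.data[k].reshape(e, 3)
        for i, name in enumerate(names):
            rows.append({
                "rank": rank,
                "component": int(k),
                "pathological_weight": v[k, 1],
                "healthy_weight": v[k, 0],
                "electrode": name,
                "bin0_real": m[i, 0],
                "bin1_real": m[i, 1],
                "bin1_imag": m[i, 2],
            })
    frame = pd.DataFrame(rows)
    metadata = {
        "ordering": "descending pathological class weight",
        "order": [int(k) for k in order],
        "scaling_note": "colormaps are scaled separately for each frequency bin",
        "per_bin_max_abs": {
            "bin0_real": float(np.abs(model.means.data.reshape(-1, e, 3)[:, :, 0]).max()),
            "bin1_real": float(np.abs(model.means.data.reshape(-1, e, 3)[:, :, 1]).max()),
            "bin1_imag": float(np.abs(model.means.data.reshape(-1, e, 3)[:, :, 2]).max()),
        },
    }
    return frame, metadata


def export_components_csv(model: FourierGMM, csv_path, json_path=None,
                          electrode_names: list[str] | None = None) -> None:
    frame, metadata = visualize_components(model, electrode_names)
    frame.to_csv(csv_path, index=False)
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump(metadata, fh, indent=2)
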