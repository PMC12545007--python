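"""EEG-InvNet: a multi-stage invertible network trained as a class-conditional
generative classifier for binary EEG pathology decoding.

The network is a stack of stages operating at progressively lower temporal
resolution.  Each stage starts with a Haar squeeze (C x T -> 2C x T/2) and is
followed by blocks of activation normalization, invertible linear channel
mixing, and additive coupling.  Because every layer is bijective and
dimension-preserving, the model assigns exact densities through the change of
variables

    log p(x | c) = log N(z; mu_c, diag(sigma_c^2)) + log |det df/dx|,  z = f(x)

with one diagonal-Gaussian latent prior per class.  Classification follows
Bayes' rule with uniform class priors; during training the class
log-likelihoods are divided by a learned temperature t before the softmax,
and the total loss is

    L(x, c) = -log softmax(log p(x|c') / t)[c] - alpha * log p(x | c)

with alpha fixed to the inverse of the input dimensionality.

Inputs are scaled per channel by the training-set median absolute deviation,
and a small amount of Gaussian noise is added during likelihood training to
keep densities finite on quantized signals.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .autodiff import Tensor, logsumexp, parameter
from .invertible import ActNorm, AdditiveCoupling, HaarSqueeze, InvLinear
from .optim import AdamW, cosine_restart_lr

CLASS_NAMES = ("healthy", "pathological")
CHECKPOINT_SCHEMA = 1


@dataclass
class EEGInvNetConfig:
    n_electrodes: int = 21
    window_samples: int = 128
    n_stages: int = 3
    blocks_per_stage: int = 4
    kernel_size: int = 3
    hidden_multiplier: int = 2
    sampling_rate_hz: float = 64.0

    def __post_init__(self):
        if self.window_samples % (2**self.n_stages) != 0:
            raise ValueError(
                f"window_samples={self.window_samples} must be divisible by "
                f"2^n_stages={2**self.n_stages}"
            )

    @property
    def dim(self) -> int:
        return self.n_electrodes * self.window_samples

    @property
    def alpha(self) -> float:
        """Generative-loss weight: inverse of the input dimensionality."""
        return 1.0 / self.dim

    @property
    def stage_shapes(self) -> list[tuple[int, int]]:
        shapes = []
        c, t = self.n_electrodes, self.window_samples
        for _ in range(self.n_stages):
            c, t = 2 * c, t // 2
            shapes.append((c, t))
        return shapes


@dataclass
class LatentState:
    z: np.ndarray
    logdet: float


@dataclass
class TrainingHistory:
    loss: list[float] = field(default_factory=list)
    accuracy: list[float] = field(default_factory=list)
    temperature: list[float] = field(default_factory=list)
    learning_rate: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)


def _as_batch(x: np.ndarray, config: EEGInvNetConfig) -> tuple[np.ndarray, bool]:
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 2:
        x = x[None]
        single = True
    elif x.ndim == 3:
        single = False
    else:
        raise ValueError(f"expected (electrodes, time) or batched windows, got shape {x.shape}")
    if x.shape[1] != config.n_electrodes or x.shape[2] != config.window_samples:
        raise ValueError(
            f"window shape {x.shape[1:]} does not match configured "
            f"{config.n_electrodes} x {config.window_samples}"
        )
    return x, single


class EEGInvNet:
    """Invertible generative classifier over 2-class EEG windows."""

    def __init__(self, config: EEGInvNetConfig | None = None, seed: int = 0):
        self.config = config or EEGInvNetConfig()
        rng = np.random.default_rng(seed)
        cfg = self.config
        self.layers: list = []
        self.layer_names: list[str] = []
        c = cfg.n_electrodes
        swap = False
        for s in range(cfg.n_stages):
            self.layers.append(HaarSqueeze())
            self.layer_names.append(f"stage{s}.squeeze")
            c *= 2
            for b in range(cfg.blocks_per_stage):
                self.layers.append(ActNorm(c))
                self.layer_names.append(f"stage{s}.block{b}.actnorm")
                self.layers.append(InvLinear(c, rng))
                self.layer_names.append(f"stage{s}.block{b}.invlinear")
                half = c // 2
                self.layers.append(
                    AdditiveCoupling(
                        c,
                        swap=swap,
                        kernel_size=cfg.kernel_size,
                        hidden_channels=cfg.hidden_multiplier * half,
                        rng=rng,
                    )
                )
                self.layer_names.append(f"stage{s}.block{b}.coupling")
                swap = not swap
        d = cfg.dim
        # per-class diagonal Gaussian priors, learnable; temperature learned in log space
        self.class_means = parameter(np.zeros((2, d)))
        self.class_log_stds = parameter(np.zeros((2, d)))
        self.log_t = parameter(np.log(d))
        # per-channel divisor applied to raw inputs; set from training data
        self.channel_scale = np.ones(cfg.n_electrodes)

    # -- parameter plumbing -------------------------------------------------
    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for layer in self.layers:
            params.extend(layer.parameters())
        params.extend([self.class_means, self.class_log_stds, self.log_t])
        return params

    @property
    def temperature(self) -> float:
        return float(np.exp(self.log_t.data))

    @property
    def alpha(self) -> float:
        return self.config.alpha

    # -- core bijection ------------------------------------------------------
    def _forward_t(self, x: Tensor, check: bool = False) -> tuple[Tensor, Tensor]:
        h = x
        logdet: Tensor = Tensor(0.0)
        for layer, name in zip(self.layers, self.layer_names):
            h, ld = layer.forward(h)
            logdet = logdet + ld
            if check and not np.all(np.isfinite(h.data)):
                raise FloatingPointError(f"non-finite activations after layer {name}")
        B = h.shape[0]
        return h.reshape(B, self.config.dim), logdet

    def net_forward(self, x: np.ndarray) -> LatentState:
        """Map scaled input window(s) to the latent vector plus accumulated log|det J|."""
        xb, single = _as_batch(x, self.config)
        z, logdet = self._forward_t(Tensor(xb))
        z = z.data
        return LatentState(z[0] if single else z, float(logdet.data))

    def net_inverse(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=np.float64)
        single = z.ndim == 1
        if single:
            z = z[None]
        if z.shape[1] != self.config.dim:
            raise ValueError(f"latent dimension {z.shape[1]} != {self.config.dim}")
        cf, tf = self.config.stage_shapes[-1]
        h = z.reshape(z.shape[0], cf, tf)
        for layer in reversed(self.layers):
            h = layer.inverse(h)
        return h[0] if single else h

    # -- densities and classification -----------------------------------------
    def _log_prob_all_t(self, x: Tensor, check: bool = False) -> Tensor:
        """(B, 2) class-conditional log densities for scaled inputs."""
        z, logdet = self._forward_t(x, check=check)
        B = z.shape[0]
        d = self.config.dim
        zb = z.reshape(B, 1, d)
        std_inv = (-self.class_log_stds).exp()  # (2, d)
        normalized = (zb - self.class_means) * std_inv
        sq = (normalized * normalized).sum(axis=2)  # (B, 2)
        log_norm = self.class_log_stds.sum(axis=1) + 0.5 * d * np.log(2 * np.pi)  # (2,)
        return sq * (-0.5) - log_norm + logdet

    def _scale(self, x: np.ndarray) -> np.ndarray:
        return x / self.channel_scale[:, None]

    def log_prob_all(self, x: np.ndarray) -> np.ndarray:
        """Class-conditional log densities log p(x | c) for raw input windows."""
        xb, single = _as_batch(x, self.config)
        lp = self._log_prob_all_t(Tensor(self._scale(xb))).data
        # scaling x -> x/s is itself a change of variables with constant log|det|
        lp = lp - np.sum(np.log(self.channel_scale)) * self.config.window_samples
        return lp[0] if single else lp

    def log_prob(self, x: np.ndarray, c: int) -> float | np.ndarray:
        lp = self.log_prob_all(x)
        return lp[..., c]

    def classify(self, x: np.ndarray) -> np.ndarray:
        """Posterior class probabilities: softmax over log p(x|c) / t."""
        lp = self.log_prob_all(x) / self.temperature
        lp = lp - lp.max(axis=-1, keepdims=True)
        p = np.exp(lp)
        return p / p.sum(axis=-1, keepdims=True)

    def predict(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        xb, _ = _as_batch(x, self.config)
        out = np.empty(len(xb), dtype=np.int64)
        for i in range(0, len(xb), batch_size):
            out[i : i + batch_size] = np.argmax(self.log_prob_all(xb[i : i + batch_size]), axis=1)
        return out

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        xb, _ = _as_batch(x, self.config)
        out = np.empty((len(xb), 2))
        for i in range(0, len(xb), batch_size):
            out[i : i + batch_size] = self.classify(xb[i : i + batch_size])
        return out

    def score(self, x: np.ndarray, labels: np.ndarray, batch_size: int = 256) -> float:
        return float(np.mean(self.predict(x, batch_size) == np.asarray(labels)))

    # -- loss ------------------------------------------------------------------
    def training_loss_t(self, x_scaled: np.ndarray, labels: np.ndarray) -> tuple[Tensor, np.ndarray]:
        """Mean combined loss over a scaled batch; also returns hard predictions."""
        lp = self._log_prob_all_t(Tensor(x_scaled))
        if not np.all(np.isfinite(lp.data)):
            # rerun with per-layer checks to name the offending layer
            self._log_prob_all_t(Tensor(x_scaled), check=True)
            raise FloatingPointError("non-finite class log-probabilities")
        B = x_scaled.shape[0]
        idx = (np.arange(B), np.asarray(labels))
        t_inv = (-self.log_t).exp()
        logits = lp * t_inv
        clf = logsumexp(logits, axis=1) - logits[idx]
        gen = lp[idx] * (-self.alpha)
        loss = (clf + gen).mean()
        preds = np.argmax(lp.data, axis=1)
        return loss, preds

    def training_loss(self, x: np.ndarray, c_true) -> float:
        """Combined loss -log softmax(log p(x|c')/t)[c] - alpha log p(x|c) on raw windows."""
        xb, single = _as_batch(x, self.config)
        labels = np.atleast_1d(np.asarray(c_true))
        loss, _ = self.training_loss_t(self._scale(xb), labels)
        return float(loss.data)

    # -- training ---------------------------------------------------------------
    def initialize_actnorms(self, x_scaled: np.ndarray) -> None:
        """Data-dependent initialization: propagate a batch and set each ActNorm so
        its outputs have zero mean / unit variance per channel."""
        h = np.asarray(x_scaled, dtype=np.float64)
        for layer in self.layers:
            if isinstance(layer, ActNorm) and not layer.initialized:
                layer.initialize_from(h)
            h, _ = layer.forward(Tensor(h))
            h = h.data

    def fit_channel_scale(self, windows: np.ndarray) -> None:
        med = np.median(windows, axis=(0, 2), keepdims=True)
        mad = np.median(np.abs(windows - med), axis=(0, 2))
        mad = np.where(mad > 0, mad, 1.0)
        self.channel_scale = mad

    def check_invertible_weights(self) -> None:
        for layer in self.layers:
            if isinstance(layer, InvLinear):
                layer.check_nonsingular()

    def train(
        self,
        dataset,
        epochs: int = 50,
        seed: int = 0,
        lr: float = 1e-3,
        weight_decay: float = 1e-5,
        batch_size: int = 64,
        restart_period: int = 25,
        noise_std: float = 1e-3,
        validation=None,
        verbose: bool = False,
    ) -> TrainingHistory:
        """Fit the generative classifier with AdamW and cosine warm restarts.

        `dataset` is (windows, labels) with windows (N, electrodes, samples) in
        input units and integer labels in {0: healthy, 1: pathological}.
        Deterministic for a fixed seed.
        """
        windows, labels = dataset[0], dataset[1]
        windows = np.asarray(windows, dtype=np.float64)
        labels = np.asarray(labels, dtype=np.int64)
        if len(windows) != len(labels):
            raise ValueError("windows and labels lengths differ")
        rng = np.random.default_rng(seed)
        self.fit_channel_scale(windows)
        scaled = self._scale(windows)
        first = scaled[: min(batch_size * 4, len(scaled))]
        self.initialize_actnorms(first)
        opt = AdamW(self.parameters(), lr=lr, weight_decay=weight_decay)
        history = TrainingHistory()
        n = len(scaled)
        for epoch in range(epochs):
            opt.lr = cosine_restart_lr(lr, epoch, period=restart_period)
            perm = rng.permutation(n)
            total, correct, count = 0.0, 0, 0
            for start in range(0, n, batch_size):
                sel = perm[start : start + batch_size]
                xb = scaled[sel] + noise_std * rng.standard_normal((len(sel),) + scaled.shape[1:])
                loss, preds = self.training_loss_t(xb, labels[sel])
                if not np.isfinite(loss.data):
                    raise RuntimeError(f"NaN/inf loss at epoch {epoch}, batch start {start}")
                opt.zero_grad()
                loss.backward()
                opt.step()
                total += float(loss.data) * len(sel)
                correct += int(np.sum(preds == labels[sel]))
                count += len(sel)
            self.check_invertible_weights()
            history.loss.append(total / count)
            history.accuracy.append(correct / count)
            history.temperature.append(self.temperature)
            history.learning_rate.append(opt.lr)
            if validation is not None:
                history.val_accuracy.append(self.score(validation[0], validation[1]))
            if verbose:  # pragma: no cover
                msg = (
                    f"epoch {epoch:3d}  loss {history.loss[-1]:.4f}  "
                    f"acc {history.accuracy[-1]:.3f}  t {self.temperature:.1f}"
                )
                if validation is not None:
                    msg += f"  val_acc {history.val_accuracy[-1]:.3f}"
                print(msg)
        return history

    # -- checkpointing ------------------------------------------------------------
    def named_parameters(self) -> dict[str, Tensor]:
        named: dict[str, Tensor] = {}
        for layer, name in zip(self.layers, self.layer_names):
            for i, p in enumerate(layer.parameters()):
                named[f"{name}.p{i}"] = p
        named["class_means"] = self.class_means
        named["class_log_stds"] = self.class_log_stds
        named["log_t"] = self.log_t
        return named

    def save(self, path) -> None:
        arrays = {k: v.data for k, v in self.named_parameters().items()}
        arrays["channel_scale"] = self.channel_scale
        meta = {"schema": CHECKPOINT_SCHEMA, "config": asdict(self.config)}
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "EEGInvNet":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            if meta["schema"] != CHECKPOINT_SCHEMA:
                raise ValueError(f"unsupported checkpoint schema {meta['schema']}")
            model = cls(EEGInvNetConfig(**meta["config"]))
            named = model.named_parameters()
            for k, p in named.items():
                p.data = np.array(data[k], dtype=np.float64)
            model.channel_scale = np.array(data["channel_scale"], dtype=np.float64)
        for layer in model.layers:
            if isinstance(layer, ActNorm):
                layer.initialized = True
        return model
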