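"""EEG-CosNet: a fully visualizable compact discriminative network.

The whole prediction function is three interpretable steps:

1. spatial filtering        h1 = Ws^T x
2. feature construction     h2_i(tau) = | cos_sim(h1_i[tau : tau+L], f_i) |
                            h3_i = mean over tau                    (in [0,1])
3. linear classification    p(pathological) = sigmoid(Wc^T h3 + b)

Each of the 64 spatiotemporal filters pairs one spatial filter (a scalp
topography once transformed to a pattern) with one temporal filter of 64
samples (one second at 64 Hz).  The absolute cosine similarity makes the
output invariant to the joint sign of a spatial+temporal filter pair and
bounds every feature to [0, 1]; windows where the filtered segment has zero
norm contribute similarity 0 (no class evidence).

The network is trained by distillation: binary cross-entropy against the
class probabilities predicted by a trained EEG-InvNet (soft targets), with
the same AdamW + cosine-warm-restart schedule.  After training, filters are
turned into interpretable *patterns*: spatial filters are multiplied by the
electrode covariance (per filter, no whitening across filters), and
classifier weights by the mean feature activation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, moving_abs_cosine, parameter
from .optim import AdamW, cosine_restart_lr


@dataclass
class PatternSet:
    spatial_patterns: np.ndarray  # (electrodes, n_filters)
    classifier_patterns: np.ndarray  # (n_filters,)
    electrode_covariance: np.ndarray  # (electrodes, electrodes)


@dataclass
class FilterRanking:
    order: np.ndarray  # all filters, descending classifier pattern (most pathological first)
    top_pathological: np.ndarray
    top_healthy: np.ndarray


class EEGCosNet:
    """Spatial filters -> absolute moving cosine similarity -> mean -> sigmoid."""

    def __init__(
        self,
        n_electrodes: int = 21,
        n_filters: int = 64,
        filter_length: int = 64,
        seed: int = 0,
    ):
        self.n_electrodes = n_electrodes
        self.n_filters = n_filters
        self.filter_length = filter_length
        rng = np.random.default_rng(seed)
        self.Ws = parameter(rng.standard_normal((n_electrodes, n_filters)) / np.sqrt(n_electrodes))
        self.f = parameter(rng.standard_normal((n_filters, filter_length)))
        self.Wc = parameter(np.zeros((n_filters, 1)))
        self.bias = parameter(0.0)

    def parameters(self) -> list[Tensor]:
        return [self.Ws, self.f, self.Wc, self.bias]

    def _check_filters(self) -> None:
        norms = np.linalg.norm(self.f.data, axis=1)
        if np.any(norms == 0):
            raise ValueError("temporal filters must have nonzero norm")

    def _forward_t(self, x: Tensor) -> tuple[Tensor, Tensor, Tensor]:
        """logits (B,), features h3 (B, F) for a batch tensor (B, E, T)."""
        if x.shape[-1] < self.filter_length:
            raise ValueError(
                f"window length {x.shape[-1]} < filter length {self.filter_length}"
            )
        h1 = self.Ws.transpose((1, 0)) @ x  # (F, E) @ (B, E, T) -> (B, F, T)
        h2 = moving_abs_cosine(h1, self.f)  # (B, F, T-L+1)
        h3 = h2.mean(axis=2)  # (B, F)
        logits = (h3 @ self.Wc).reshape(x.shape[0]) + self.bias
        return logits, h3, h2

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(p_pathological, h3) for raw windows (numpy in, numpy out)."""
        x = np.asarray(x, dtype=np.float64)
        single = x.ndim == 2
        if single:
            x = x[None]
        self._check_filters()
        logits, h3, _ = self._forward_t(Tensor(x))
        p = 1.0 / (1.0 + np.exp(-logits.data))
        return (p[0], h3.data[0]) if single else (p, h3.data)

    def predict(self, x: np.ndarray) -> np.ndarray:
        p, _ = self.forward(x)
        return (np.atleast_1d(p) > 0.5).astype(np.int64)

    def features(self, x: np.ndarray, batch_size: int = 512) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        out = np.empty((len(x), self.n_filters))
        for i in range(0, len(x), batch_size):
            _, out[i : i + batch_size] = self.forward(x[i : i + batch_size])
        return out

    def predict_proba(self, x: np.ndarray, batch_size: int = 512) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        out = np.empty(len(x))
        for i in range(0, len(x), batch_size):
            p, _ = self.forward(x[i : i + batch_size])
            out[i : i + batch_size] = p
        return out

    # -- persistence ---------------------------------------------------------
    def save(self, path) -> None:
        np.savez(
            path,
            Ws=self.Ws.data,
            f=self.f.data,
            Wc=self.Wc.data,
            bias=self.bias.data,
        )

    @classmethod
    def load(cls, path) -> "EEGCosNet":
        with np.load(path) as d:
            model = cls(
                n_electrodes=d["Ws"].shape[0],
                n_filters=d["Ws"].shape[1],
                filter_length=d["f"].shape[1],
            )
            model.Ws.data = np.array(d["Ws"])
            model.f.data = np.array(d["f"])
            model.Wc.data = np.array(d["Wc"])
            model.bias.data = np.array(d["bias"])
        return model


def cosnet_forward(x: np.ndarray, model: EEGCosNet) -> tuple[np.ndarray, np.ndarray]:
    """Functional form of the three-step computation: (p_pathological, h3)."""
    return model.forward(x)


def distill(
    student: EEGCosNet,
    windows: np.ndarray,
    teacher_probs: np.ndarray,
    epochs: int = 25,
    seed: int = 0,
    lr: float = 1e-3,
    weight_decay: float = 1e-5,
    batch_size: int = 64,
    restart_period: int = 25,
    verbose: bool = False,
) -> dict:
    """Train the student on the teacher's pathological-class probabilities.

    Minimizes binary cross-entropy between the student's sigmoid output and
    the soft targets.  Logs per-epoch loss and the fraction of matching hard
    labels (agreement).  Deterministic per seed.
    """
    windows = np.asarray(windows, dtype=np.float64)
    teacher_probs = np.asarray(teacher_probs, dtype=np.float64)
    if len(windows) != len(teacher_probs):
        raise ValueError(
            f"{len(windows)} windows but {len(teacher_probs)} teacher probabilities"
        )
    if np.any(teacher_probs <= 0) or np.any(teacher_probs >= 1):
        teacher_probs = np.clip(teacher_probs, 1e-7, 1 - 1e-7)
    rng = np.random.default_rng(seed)
    opt = AdamW(student.parameters(), lr=lr, weight_decay=weight_decay)
    history = {"loss": [], "agreement": [], "learning_rate": []}
    n = len(windows)
    hard_teacher = (teacher_probs > 0.5).astype(np.int64)
    for epoch in range(epochs):
        opt.lr = cosine_restart_lr(lr, epoch, period=restart_period)
        perm = rng.permutation(n)
        total, agree = 0.0, 0
        for start in range(0, n, batch_size):
            sel = perm[start : start + batch_size]
            xb = Tensor(windows[sel])
            q = teacher_probs[sel]
            logits, _, _ = student._forward_t(xb)
            # BCE on soft targets, stable in the logits
            loss = (Tensor(q) * (-logits).softplus() + Tensor(1.0 - q) * logits.softplus()).mean()
            if not np.isfinite(loss.data):
                raise RuntimeError(f"NaN/inf distillation loss at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            total += float(loss.data) * len(sel)
            agree += int(np.sum((logits.data > 0) == (hard_teacher[sel] == 1)))
        history["loss"].append(total / n)
        history["agreement"].append(agree / n)
        history["learning_rate"].append(opt.lr)
        if verbose:  # pragma: no cover
            print(f"epoch {epoch:3d}  loss {history['loss'][-1]:.4f}  "
                  f"agreement {history['agreement'][-1]:.3f}")
    return history


def agreement(student: EEGCosNet, windows: np.ndarray, teacher_hard: np.ndarray) -> float:
    """Fraction of windows where student and teacher hard labels match."""
    preds = (student.predict_proba(windows) > 0.5).astype(np.int64)
    return float(np.mean(preds == np.asarray(teacher_hard)))


def to_patterns(model: EEGCosNet, windows: np.ndarray, shrinkage: float = 0.0) -> PatternSet:
    """Transform discriminative filters into generative patterns.

    The electrode covariance is estimated over all time points of all
    training windows; each spatial filter is multiplied by it independently
    (no whitening across filters, since each spatial filter pairs with its
    own temporal filter).  Classifier weights are multiplied elementwise by
    the mean absolute-cosine feature over the dataset.
    """
    windows = np.asarray(windows, dtype=np.float64)
    n, e, t = windows.shape
    if n * t <= e:
        raise ValueError(f"need more than {e} total time points to estimate the covariance")
    flat = windows.transpose(1, 0, 2).reshape(e, n * t)
    flat = flat - flat.mean(axis=1, keepdims=True)
    cov = flat @ flat.T / (flat.shape[1] - 1)
    if shrinkage > 0:
        cov = (1 - shrinkage) * cov + shrinkage * (np.trace(cov) / e) * np.eye(e)
    spatial = cov @ model.Ws.data  # per-filter, columnwise
    mean_h3 = model.features(windows).mean(axis=0)
    classifier = model.Wc.data[:, 0] * mean_h3
    return PatternSet(spatial, classifier, cov)


def rank_filters(patterns: PatternSet, k: int = 16) -> FilterRanking:
    """Order filters by transformed classifier weight (descending = most
    pathological-associated first); ties break by filter index."""
    cp = patterns.classifier_patterns
    order = np.argsort(-cp, kind="stable")
    ascending = np.argsort(cp, kind="stable")
    k = min(k, len(cp))
    return FilterRanking(order=order, top_pathological=order[:k], top_healthy=ascending[:k])
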