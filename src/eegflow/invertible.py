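"""Invertible layer primitives: activation normalization, invertible linear
channel mixing, additive coupling, and the Haar squeeze.

Every layer offers an exact inverse and an analytic log-Jacobian-determinant.
Feature maps are arrays of shape ``(batch, channels, time)``; the functional
wrappers at the bottom also accept a single unbatched ``(channels, time)``
map, which is how they appear in formulas.  The product channels x time is
preserved by every transformation, which is what makes the change-of-variables
density exact.

Conventions fixed here (they matter for reproducibility, not for the math):

* coupling splits channels into halves; which half is transformed alternates
  from block to block (``swap`` flag) so that all channels get updated;
* the Haar squeeze puts the pairwise means in the first half of the output
  channels and the (a - b) differences in the second half.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, as_tensor, concatenate, conv1d_same, logabsdet, parameter

_SINGULAR_TOL = 1e-12


def _check_channels(x_channels: int, expected: int, layer: str) -> None:
    if x_channels != expected:
        raise ValueError(f"{layer}: expected {expected} channels, got {x_channels}")


class ActNorm:
    """Per-channel affine transform y = exp(log_scale) * x + shift.

    Initialized at the identity; :meth:`initialize_from` performs the usual
    data-dependent initialization (post-layer activations get zero mean and
    unit variance per channel on the provided batch).
    """

    def __init__(self, n_channels: int):
        self.n_channels = n_channels
        self.log_scale = parameter(np.zeros(n_channels))
        self.shift = parameter(np.zeros(n_channels))
        self.initialized = False

    def parameters(self) -> list[Tensor]:
        return [self.log_scale, self.shift]

    def initialize_from(self, x: np.ndarray, eps: float = 1e-8) -> None:
        mean = x.mean(axis=(0, 2))
        std = x.std(axis=(0, 2)) + eps
        self.log_scale.data = -np.log(std)
        self.shift.data = -mean / std
        self.initialized = True

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor]:
        _check_channels(x.shape[-2], self.n_channels, "ActNorm")
        C = self.n_channels
        scale = self.log_scale.exp().reshape(1, C, 1)
        y = x * scale + self.shift.reshape(1, C, 1)
        logdet = self.log_scale.sum() * float(x.shape[-1])
        return y, logdet

    def inverse(self, y: np.ndarray) -> np.ndarray:
        _check_channels(y.shape[-2], self.n_channels, "ActNorm")
        scale = np.exp(self.log_scale.data)[:, None]
        return (y - self.shift.data[:, None]) / scale


class InvLinear:
    """Channel mixing by an invertible square matrix, shared across time points."""

    def __init__(self, n_channels: int, rng: np.random.Generator | None = None):
        self.n_channels = n_channels
        if rng is None:
            w = np.eye(n_channels)
        else:
            a = rng.standard_normal((n_channels, n_channels))
            q, r = np.linalg.qr(a)
            q *= np.sign(np.diag(r))  # unique orthogonal factor
            w = q
        self.weight = parameter(w)
        self.check_nonsingular()

    def parameters(self) -> list[Tensor]:
        return [self.weight]

    def check_nonsingular(self) -> None:
        det = np.linalg.det(self.weight.data)
        if abs(det) < _SINGULAR_TOL:
            raise np.linalg.LinAlgError(
                f"InvLinear weight is numerically singular (|det| = {abs(det):.3e})"
            )

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor]:
        _check_channels(x.shape[-2], self.n_channels, "InvLinear")
        self.check_nonsingular()
        y = as_tensor(self.weight) @ x
        logdet = logabsdet(self.weight) * float(x.shape[-1])
        return y, logdet

    def inverse(self, y: np.ndarray) -> np.ndarray:
        _check_channels(y.shape[-2], self.n_channels, "InvLinear")
        self.check_nonsingular()
        return np.linalg.solve(self.weight.data, y)


class CouplingSubnet:
    """Two same-padded 1-D convolutions with an ELU in between.

    Maps the pass-through half (``in_channels``) to an additive update for the
    transformed half (``out_channels``).  The final convolution is
    zero-initialized so a fresh coupling layer is the identity.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        hidden_channels: int | None = None,
        kernel_size: int = 3,
        rng: np.random.Generator | None = None,
    ):
        if hidden_channels is None:
            hidden_channels = 2 * in_channels
        self.kernel_size = kernel_size
        fan_in = in_channels * kernel_size
        if rng is None:
            w1 = np.zeros((hidden_channels, in_channels, kernel_size))
        else:
            w1 = rng.standard_normal((hidden_channels, in_channels, kernel_size)) / np.sqrt(fan_in)
        self.w1 = parameter(w1)
        self.b1 = parameter(np.zeros(hidden_channels))
        self.w2 = parameter(np.zeros((out_channels, hidden_channels, kernel_size)))
        self.b2 = parameter(np.zeros(out_channels))

    def parameters(self) -> list[Tensor]:
        return [self.w1, self.b1, self.w2, self.b2]

    def __call__(self, x: Tensor) -> Tensor:
        h = conv1d_same(x, self.w1, self.b1).elu()
        return conv1d_same(h, self.w2, self.b2)


class AdditiveCoupling:
    """Additive coupling: one half of the channels is shifted by a function of
    the other half; the Jacobian is unit-triangular so log|det| = 0.

    With ``swap=False`` the first half is transformed; with ``swap=True`` the
    second half is.
    """

    def __init__(
        self,
        n_channels: int,
        swap: bool = False,
        kernel_size: int = 3,
        hidden_channels: int | None = None,
        rng: np.random.Generator | None = None,
    ):
        if n_channels % 2 != 0:
            raise ValueError(f"AdditiveCoupling needs an even channel count, got {n_channels}")
        self.n_channels = n_channels
        self.swap = swap
        half = n_channels // 2
        self.subnet = CouplingSubnet(half, half, hidden_channels, kernel_size, rng)

    def parameters(self) -> list[Tensor]:
        return self.subnet.parameters()

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor]:
        _check_channels(x.shape[-2], self.n_channels, "AdditiveCoupling")
        half = self.n_channels // 2
        a, b = x[:, :half, :], x[:, half:, :]
        if self.swap:
            out = concatenate([a, b + self.subnet(a)], axis=1)
        else:
            out = concatenate([a + self.subnet(b), b], axis=1)
        return out, Tensor(0.0)

    def inverse(self, y: np.ndarray) -> np.ndarray:
        _check_channels(y.shape[-2], self.n_channels, "AdditiveCoupling")
        half = self.n_channels // 2
        a, b = y[:, :half, :], y[:, half:, :]
        if self.swap:
            update = self.subnet(Tensor(a)).data
            return np.concatenate([a, b - update], axis=1)
        update = self.subnet(Tensor(b)).data
        return np.concatenate([a - update, b], axis=1)


class HaarSqueeze:
    """One stage of a Haar transform along time, folded into channels.

    Forward maps (C, T) to (2C, T/2): channels [0, C) hold the pairwise means
    (a + b)/2 and channels [C, 2C) the differences a - b.  The per-pair matrix
    [[1/2, 1/2], [1, -1]] has |det| = 1, so log|det| = 0.
    """

    @staticmethod
    def parameters() -> list[Tensor]:
        return []

    @staticmethod
    def forward(x: Tensor) -> tuple[Tensor, Tensor]:
        T = x.shape[-1]
        if T % 2 != 0:
            raise ValueError(f"HaarSqueeze needs an even number of time points, got {T}")
        a = x[:, :, 0::2]
        b = x[:, :, 1::2]
        means = (a + b) * 0.5
        diffs = a - b
        return concatenate([means, diffs], axis=1), Tensor(0.0)

    @staticmethod
    def inverse(y: np.ndarray) -> np.ndarray:
        C2 = y.shape[-2]
        if C2 % 2 != 0:
            raise ValueError(f"HaarSqueeze inverse needs an even channel count, got {C2}")
        C = C2 // 2
        means, diffs = y[:, :C, :], y[:, C:, :]
        a = means + diffs / 2.0
        b = means - diffs / 2.0
        out = np.empty((y.shape[0], C, 2 * y.shape[-1]), dtype=y.dtype)
        out[:, :, 0::2] = a
        out[:, :, 1::2] = b
        return out


# ---------------------------------------------------------------------------
# functional wrappers: operate on a single (channels, time) feature map or a
# batch, in either direction, returning (result, logdet)
# ---------------------------------------------------------------------------


def _batched(x: np.ndarray) -> tuple[np.ndarray, bool]:
    x = np.asarray(x, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise ValueError("feature map contains non-finite entries")
    if x.ndim == 2:
        return x[None], True
    if x.ndim == 3:
        return x, False
    raise ValueError(f"expected (channels, time) or (batch, channels, time), got shape {x.shape}")


def _apply(layer, x, direction: str) -> tuple[np.ndarray, float]:
    xb, squeeze = _batched(x)
    if direction == "forward":
        y, logdet = layer.forward(Tensor(xb))
        y, ld = y.data, float(logdet.data)
    elif direction == "inverse":
        y = layer.inverse(xb)
        _, logdet = layer.forward(Tensor(y))
        ld = -float(logdet.data)
    else:
        raise ValueError(f"direction must be 'forward' or 'inverse', got {direction!r}")
    return (y[0] if squeeze else y), ld


def actnorm_apply(x, p: ActNorm, direction: str = "forward"):
    return _apply(p, x, direction)


def invlinear_apply(x, p: InvLinear, direction: str = "forward"):
    return _apply(p, x, direction)


def additive_coupling_apply(x, net: AdditiveCoupling, direction: str = "forward"):
    return _apply(net, x, direction)


def haar_squeeze(x, direction: str = "forward"):
    xb, squeeze = _batched(x)
    if direction == "forward":
        y, _ = HaarSqueeze.forward(Tensor(xb))
        y = y.data
    elif direction == "inverse":
        y = HaarSqueeze.inverse(xb)
    else:
        raise ValueError(f"direction must be 'forward' or 'inverse', got {direction!r}")
    return (y[0] if squeeze else y), 0.0
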