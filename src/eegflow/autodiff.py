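"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small engine covering exactly the operations the EEG models in
this package need: broadcasting arithmetic, matmul, pointwise nonlinearities,
reductions, basic indexing, 1-D same-padded convolution, a moving
absolute-cosine-similarity primitive, and ``log|det|`` of a square matrix.
Gradients of every primitive are verified against central finite differences
in the test suite.

Tensors wrap ``float64`` arrays.  A node records its parents and a closure
that scatters the output gradient back to them; ``Tensor.backward`` runs a
topological sweep.  Operations on tensors none of whose parents require
gradients skip closure creation entirely, so inference-mode code pays almost
nothing for going through the same code path as training.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "parameter",
    "as_tensor",
    "concatenate",
    "logsumexp",
    "conv1d_same",
    "moving_abs_cosine",
    "logabsdet",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, (g, s) in enumerate(zip(grad.shape, shape)) if s == 1 and g != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: tuple["Tensor", ...] = (),
        backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    # -- introspection -----------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- graph construction ------------------------------------------------
    @staticmethod
    def _make(data, parents: tuple["Tensor", ...], backward: Callable) -> "Tensor":
        if any(p.requires_grad for p in parents):
            return Tensor(data, requires_grad=True, parents=parents, backward=backward)
        return Tensor(data)

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that does not require grad")
        if grad is None:
            if self.data.size != 1:
                raise RuntimeError("backward() without an explicit gradient requires a scalar")
            grad = np.ones_like(self.data)
        # iterative topological order
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                # free intermediate gradients; leaves keep theirs
                if node._parents:
                    node.grad = None

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out_data = self.data + other.data

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        return Tensor._make(out_data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            self._accumulate(-g)

        return Tensor._make(-self.data, (self,), bwd)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out_data = self.data * other.data

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        return Tensor._make(out_data, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out_data = self.data / other.data

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(-g * self.data / other.data**2, other.shape))

        return Tensor._make(out_data, (self, other), bwd)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")
        out_data = self.data**exponent

        def bwd(g):
            self._accumulate(g * exponent * self.data ** (exponent - 1))

        return Tensor._make(out_data, (self,), bwd)

    def __matmul__(self, other):
        other = as_tensor(other)
        a, b = self.data, other.data
        out_data = a @ b

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g @ np.swapaxes(b, -1, -2), self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(np.swapaxes(a, -1, -2) @ g, other.shape))

        return Tensor._make(out_data, (self, other), bwd)

    # -- pointwise nonlinearities -------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def bwd(g):
            self._accumulate(g * out_data)

        return Tensor._make(out_data, (self,), bwd)

    def log(self):
        def bwd(g):
            self._accumulate(g / self.data)

        return Tensor._make(np.log(self.data), (self,), bwd)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def bwd(g):
            self._accumulate(g * 0.5 / out_data)

        return Tensor._make(out_data, (self,), bwd)

    def abs(self):
        def bwd(g):
            self._accumulate(g * np.sign(self.data))

        return Tensor._make(np.abs(self.data), (self,), bwd)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))

        def bwd(g):
            self._accumulate(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), bwd)

    def softplus(self):
        """log(1 + exp(x)), numerically stable for large |x|."""
        out_data = np.logaddexp(0.0, self.data)

        def bwd(g):
            self._accumulate(g / (1.0 + np.exp(-self.data)))

        return Tensor._make(out_data, (self,), bwd)

    def elu(self):
        """Exponential linear unit: x for x > 0, exp(x) - 1 otherwise."""
        neg = np.exp(np.minimum(self.data, 0.0)) - 1.0
        out_data = np.where(self.data > 0, self.data, neg)

        def bwd(g):
            self._accumulate(g * np.where(self.data > 0, 1.0, neg + 1.0))

        return Tensor._make(out_data, (self,), bwd)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            gg = g
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accumulate(np.broadcast_to(gg, self.shape).copy())

        return Tensor._make(out_data, (self,), bwd)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- shape manipulation ---------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.shape

        def bwd(g):
            self._accumulate(g.reshape(orig))

        return Tensor._make(self.data.reshape(shape), (self,), bwd)

    def transpose(self, axes: Sequence[int]):
        inv = np.argsort(axes)

        def bwd(g):
            self._accumulate(g.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), bwd)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def bwd(g):
            full = np.zeros_like(self.data)
            full[idx] += g
            self._accumulate(full)

        return Tensor._make(out_data, (self,), bwd)

    def broadcast_to(self, shape):
        def bwd(g):
            self._accumulate(_unbroadcast(g, self.shape))

        return Tensor._make(np.broadcast_to(self.data, shape).copy(), (self,), bwd)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def parameter(data) -> Tensor:
    return Tensor(np.array(data, dtype=np.float64), requires_grad=True)


def concatenate(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accumulate(piece)

    return Tensor._make(out_data, tuple(tensors), bwd)


def logsumexp(x: Tensor, axis: int, keepdims: bool = False) -> Tensor:
    x = as_tensor(x)
    m = x.data.max(axis=axis, keepdims=True)
    shifted = np.exp(x.data - m)
    total = shifted.sum(axis=axis, keepdims=True)
    out_data = m + np.log(total)
    softmax = shifted / total
    if not keepdims:
        out_data = np.squeeze(out_data, axis=axis)

    def bwd(g):
        gg = g if keepdims else np.expand_dims(g, axis)
        x._accumulate(gg * softmax)

    return Tensor._make(out_data, (x,), bwd)


def conv1d_same(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Same-padded 1-D convolution (cross-correlation) over the last axis.

    x: (batch, in_channels, T); w: (out_channels, in_channels, K) with K odd;
    b: (out_channels,) or None.  Output: (batch, out_channels, T).
    """
    x, w = as_tensor(x), as_tensor(w)
    K = w.shape[-1]
    if K % 2 != 1:
        raise ValueError(f"kernel size must be odd, got {K}")
    p = (K - 1) // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p)))
    win = sliding_window_view(xp, K, axis=2)  # (B, Cin, T, K)
    out_data = np.einsum("bitk,oik->bot", win, w.data, optimize=True)
    parents: list[Tensor] = [x, w]
    if b is not None:
        b = as_tensor(b)
        out_data = out_data + b.data[:, None]
        parents.append(b)

    def bwd(g):
        if w.requires_grad:
            w._accumulate(np.einsum("bot,bitk->oik", g, win, optimize=True))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2)))
        if x.requires_grad:
            gp = np.pad(g, ((0, 0), (0, 0), (p, p)))
            gwin = sliding_window_view(gp, K, axis=2)  # (B, Cout, T, K)
            wflip = w.data[:, :, ::-1]
            x._accumulate(np.einsum("botk,oik->bit", gwin, wflip, optimize=True))

    return Tensor._make(out_data, tuple(parents), bwd)


def _rolling_sum(x: np.ndarray, L: int) -> np.ndarray:
    """Sum over each length-L window along the last axis (valid positions)."""
    c = np.cumsum(x, axis=-1)
    out = c[..., L - 1 :].copy()
    out[..., 1:] -= c[..., : -L]
    return out


def moving_abs_cosine(h: Tensor, f: Tensor, eps: float = 1e-30) -> Tensor:
    """|cosine similarity| between every length-L window of h and the filters f.

    h: (batch, n_filters, T); f: (n_filters, L).  Each filter slides over its
    own channel with stride 1, valid positions only.  Output:
    (batch, n_filters, T - L + 1) in [0, 1].  Segments (or filters) with zero
    norm yield similarity 0 and propagate zero gradient.

    The sliding dot products (and their gradients) are computed with batched
    FFT correlations, which is what keeps the 64-filter network fast on long
    windows; the FFT length is padded past T + Tv to avoid circular aliasing.
    """
    h, f = as_tensor(h), as_tensor(f)
    L = f.shape[-1]
    T = h.shape[-1]
    Tv = T - L + 1
    if T < L:
        raise ValueError(f"window length {T} shorter than filter length {L}")
    nfft = 1 << int(T + Tv - 1).bit_length()
    H = np.fft.rfft(h.data, nfft, axis=2)  # (B, F, nfft/2+1)
    F_rev = np.fft.rfft(f.data[:, ::-1], nfft, axis=1)
    # (h conv f_rev)[t + L - 1] = sum_l h[t + l] f[l]
    dots = np.fft.irfft(H * F_rev, nfft, axis=2)[:, :, L - 1 : L - 1 + Tv]
    energy = _rolling_sum(h.data**2, L)
    nw = np.sqrt(np.maximum(energy, 0.0))
    nf = np.sqrt((f.data**2).sum(axis=1))  # (F,)
    denom = nw * nf[None, :, None]
    valid = denom > eps
    safe = np.where(valid, denom, 1.0)
    cs = np.clip(np.where(valid, dots / safe, 0.0), -1.0, 1.0)
    out_data = np.abs(cs)

    def bwd(g):
        g2 = g * np.sign(cs)  # d|cs|/dcs
        a = np.where(valid, g2 / safe, 0.0)  # (B, F, Tv)
        A = np.fft.rfft(a, nfft, axis=2)
        if h.requires_grad:
            # term 1: sum_t a[t] f[s - t]  (convolution of a with f)
            F_ = np.fft.rfft(f.data, nfft, axis=1)
            gh = np.fft.irfft(A * F_, nfft, axis=2)[:, :, :T]
            # term 2: -h[s] * sum over windows t covering s of g2 cs / nw^2
            safe_nw2 = np.where(nw > eps, energy, 1.0)
            bcoef = np.where(valid, g2 * cs / safe_nw2, 0.0)
            pad = np.zeros(h.shape[:2] + (T,))
            pad[:, :, :Tv] = bcoef
            c = np.cumsum(pad, axis=2)
            s = np.arange(T)
            hi = np.minimum(s, Tv - 1)
            lo = np.maximum(0, s - L + 1)
            box = c[:, :, hi] - np.where(lo > 0, c[:, :, lo - 1], 0.0)
            gh -= h.data * box
            h._accumulate(gh)
        if f.requires_grad:
            # sum_{b,t} a[b,f,t] h[b,f,t+l]: cross-correlation via conj FFT
            corr = np.fft.irfft(np.conj(A) * H, nfft, axis=2)[:, :, :L]
            gf = corr.sum(axis=0)
            nf2 = np.where(nf > eps, nf**2, 1.0)
            gf -= ((g2 * cs).sum(axis=(0, 2)) / nf2)[:, None] * f.data
            f._accumulate(gf)

    return Tensor._make(out_data, (h, f), bwd)


def logabsdet(w: Tensor) -> Tensor:
    """log|det W| of a square matrix, with gradient inv(W)^T."""
    w = as_tensor(w)
    sign, ld = np.linalg.slogdet(w.data)
    if sign == 0:
        raise np.linalg.LinAlgError("singular matrix in logabsdet")
    w_inv_t = None

    def bwd(g):
        nonlocal w_inv_t
        if w_inv_t is None:
            w_inv_t = np.linalg.inv(w.data).T
        w._accumulate(g * w_inv_t)

    return Tensor._make(ld, (w,), bwd)
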