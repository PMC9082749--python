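"""Minimal reverse-mode automatic differentiation over numpy arrays.

Provides a :class:`Tensor` wrapper with a dynamic tape, the elementwise /
linear-algebra primitives needed by the decoder networks, and fused ops with
hand-written adjoints where a primitive composition would be slow (2-D valid
convolution, non-overlapping max-pooling, full LSTM sequence recurrence) or
impossible (gradient reversal).

Every fused adjoint is cross-checked against central finite differences in the
test-suite; do not modify a backward rule without re-running those checks.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.special import expit


def _tune_allocator() -> None:
    """Keep large malloc blocks on the heap for reuse.

    Training allocates and frees tens-of-MB activation buffers every batch;
    with glibc defaults those go through mmap/munmap and every reuse
    re-faults the pages, which dominates wall time on some kernels.  Raising
    the mmap/trim thresholds makes the arenas persistent.  No-op off glibc.
    """
    import ctypes

    try:
        libc = ctypes.CDLL("libc.so.6")
        libc.mallopt(-3, 1 << 30)  # M_MMAP_THRESHOLD
        libc.mallopt(-4, 1 << 30)  # M_TRIM_THRESHOLD
    except (OSError, AttributeError):  # pragma: no cover - non-glibc platforms
        pass


_tune_allocator()

__all__ = [
    "Tensor",
    "concat",
    "conv2d",
    "grad_reverse",
    "lstm_sequence",
    "maxpool2d",
    "sigmoid",
    "relu",
    "tanh",
    "log_softmax",
    "Adam",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading broadcast axes
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum axes that were 1 in the original shape
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with a gradient slot and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: tuple["Tensor", ...] = (),
        backward: Callable[[np.ndarray], None] | None = None,
    ):
        arr = np.asarray(data)
        if arr.dtype != np.float32:  # keep float32 (fast path); promote the rest
            arr = arr.astype(np.float64) if arr.dtype != np.float64 else arr
        self.data = arr
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # ------------------------------------------------------------------ basics
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
        else:
            self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    # --------------------------------------------------------------- autograd
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an explicit gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; graphs here can be 10k+ nodes deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accum(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -------------------------------------------------------------- operators
    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g * self.data / other.data**2, other.shape))

        out._backward = bwd
        return out

    def __pow__(self, p: float):
        out = Tensor(self.data**p, parents=(self,))
        out._backward = lambda g: self._accum(g * p * self.data ** (p - 1))
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g @ np.swapaxes(other.data, -1, -2), self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(np.swapaxes(self.data, -1, -2) @ g, other.shape))

        out._backward = bwd
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], parents=(self,))

        def bwd(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        out._backward = bwd
        return out

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bwd(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape).copy())

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), parents=(self,))
        out._backward = lambda g: self._accum(g.reshape(self.shape))
        return out

    def transpose(self, *axes):
        out = Tensor(self.data.transpose(axes), parents=(self,))
        inv = np.argsort(axes)
        out._backward = lambda g: self._accum(g.transpose(inv))
        return out

    # ------------------------------------------------------------ nonlinearity
    def exp(self):
        out = Tensor(np.exp(self.data), parents=(self,))
        out._backward = lambda g: self._accum(g * out.data)
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))
        out._backward = lambda g: self._accum(g / self.data)
        return out


def sigmoid(x: Tensor) -> Tensor:
    s = expit(x.data)
    out = Tensor(s, parents=(x,))
    out._backward = lambda g: x._accum(g * s * (1.0 - s))
    return out


def tanh(x: Tensor) -> Tensor:
    t = np.tanh(x.data)
    out = Tensor(t, parents=(x,))
    out._backward = lambda g: x._accum(g * (1.0 - t * t))
    return out


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out = Tensor(x.data * mask, parents=(x,))
    out._backward = lambda g: x._accum(g * mask)
    return out


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable log-softmax along ``axis``."""
    m = x.data.max(axis=axis, keepdims=True)
    z = x.data - m
    lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
    out = Tensor(z - lse, parents=(x,))
    sm = np.exp(out.data)

    def bwd(g):
        x._accum(g - sm * g.sum(axis=axis, keepdims=True))

    out._backward = bwd
    return out


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), parents=tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accum(piece)

    out._backward = bwd
    return out


def grad_reverse(x: Tensor, lam: float) -> Tensor:
    """Identity forward; backward multiplies the gradient by ``-lam``."""
    out = Tensor(x.data, parents=(x,))
    out._backward = lambda g: x._accum(-lam * g)
    return out


# --------------------------------------------------------------------- conv2d
def conv2d(x: Tensor, w: Tensor, b: Tensor, stride: tuple[int, int] = (1, 1)) -> Tensor:
    """Valid (no-padding) 2-D convolution via an im2col GEMM.

    x: (B, H, W, Cin); w: (kH, kW, Cin, Cout); b: (Cout,).
    Output (B, H', W', Cout) with H' = (H - kH)//sH + 1.
    """
    B, H, W, Cin = x.shape
    kH, kW, _, Cout = w.shape
    sH, sW = stride
    if kH > H or kW > W:
        raise ValueError(f"kernel ({kH}x{kW}) larger than input ({H}x{W})")
    Ho = (H - kH) // sH + 1
    Wo = (W - kW) // sW + 1
    # K-major im2col: cols[k(i,j,cin), m(b,ho,wo)] so each kernel tap is a
    # contiguous block in both the gather here and the col2im scatter below
    M = B * Ho * Wo
    cols = np.empty((kH, kW, Cin, B, Ho, Wo), dtype=x.data.dtype)
    for i in range(kH):
        for j in range(kW):
            patch = x.data[:, i : i + Ho * sH : sH, j : j + Wo * sW : sW, :]
            cols[i, j] = patch.transpose(3, 0, 1, 2)
    cols2d = cols.reshape(kH * kW * Cin, M)
    w2d = w.data.reshape(kH * kW * Cin, Cout)  # rows ordered (kH, kW, Cin)
    out_data = (cols2d.T @ w2d + b.data).reshape(B, Ho, Wo, Cout)
    out = Tensor(out_data, parents=(x, w, b))

    def bwd(g):
        g2d = g.reshape(M, Cout)
        if b.requires_grad:
            b._accum(g2d.sum(axis=0))
        if w.requires_grad:
            w._accum((cols2d @ g2d).reshape(w.shape))
        if x.requires_grad:
            gcols = (w2d @ g2d.T).reshape(kH, kW, Cin, B, Ho, Wo)
            gx = np.zeros_like(x.data)
            for i in range(kH):
                for j in range(kW):
                    gx[:, i : i + Ho * sH : sH, j : j + Wo * sW : sW, :] += \
                        gcols[i, j].transpose(1, 2, 3, 0)
            x._accum(gx)

    out._backward = bwd
    return out


def batchnorm_train(
    x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5
) -> tuple[Tensor, np.ndarray, np.ndarray]:
    """Fused batch normalization over all axes but the last (training mode),
    with a closed-form backward.  Returns (normalized tensor, batch mean,
    batch variance); the stats feed running-average updates."""
    axes = tuple(range(x.ndim - 1))
    m = float(np.prod([x.shape[a] for a in axes]))
    mu = x.data.mean(axis=axes)
    xc = x.data - mu
    var = np.mean(xc * xc, axis=axes)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out = Tensor(xhat * gamma.data + beta.data, parents=(x, gamma, beta))

    def bwd(g):
        if beta.requires_grad:
            beta._accum(g.sum(axis=axes))
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=axes))
        if x.requires_grad:
            gxhat = g * gamma.data
            t1 = gxhat.sum(axis=axes)
            t2 = (gxhat * xhat).sum(axis=axes)
            x._accum(inv * (gxhat - (t1 + xhat * t2) / m))

    out._backward = bwd
    return out, mu, var


def maxpool2d(x: Tensor, pool: tuple[int, int]) -> Tensor:
    """Non-overlapping max-pool with window == stride; trailing rows/cols
    that do not fill a window are truncated (floor semantics)."""
    B, H, W, C = x.shape
    pH, pW = pool
    Ho, Wo = H // pH, W // pW
    crop = x.data[:, : Ho * pH, : Wo * pW, :]
    windows = crop.reshape(B, Ho, pH, Wo, pW, C)
    flat = windows.transpose(0, 1, 3, 5, 2, 4).reshape(B, Ho, Wo, C, pH * pW)
    arg = flat.argmax(axis=-1)
    out = Tensor(np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0], parents=(x,))

    def bwd(g):
        gflat = np.zeros_like(flat)
        np.put_along_axis(gflat, arg[..., None], g[..., None], axis=-1)
        gwin = gflat.reshape(B, Ho, Wo, C, pH, pW).transpose(0, 1, 4, 2, 5, 3)
        gx = np.zeros_like(x.data)
        gx[:, : Ho * pH, : Wo * pW, :] = gwin.reshape(B, Ho * pH, Wo * pW, C)
        x._accum(gx)

    out._backward = bwd
    return out


# ------------------------------------------------------------- fused LSTM BPTT
def lstm_sequence(
    x: Tensor, w: Tensor, u: Tensor, b: Tensor, return_mean: bool = False
) -> Tensor:
    """Run a full LSTM recurrence over a batch of sequences.

    x: (B, T, I); w: (I, 4H) input weights; u: (H, 4H) recurrent weights;
    b: (4H,) biases.  Gate blocks are ordered [input, forget, output, cell].
    Returns the final hidden state (B, H), or the mean over all steps when
    ``return_mean`` is set.  Backward is hand-written truncated-free BPTT.
    """
    B, T, I = x.shape
    H = u.shape[0]
    xd, wd, ud, bd = x.data, w.data, u.data, b.data
    dt = xd.dtype
    pre_x = xd.reshape(B * T, I) @ wd
    pre_x = pre_x.reshape(B, T, 4 * H) + bd
    h = np.zeros((B, H), dtype=dt)
    c = np.zeros((B, H), dtype=dt)
    gates_i = np.empty((T, B, H), dtype=dt)
    gates_f = np.empty((T, B, H), dtype=dt)
    gates_o = np.empty((T, B, H), dtype=dt)
    gates_g = np.empty((T, B, H), dtype=dt)
    cells = np.empty((T, B, H), dtype=dt)
    tanh_c = np.empty((T, B, H), dtype=dt)
    hs = np.empty((T, B, H), dtype=dt)
    for t in range(T):
        z = pre_x[:, t, :] + h @ ud
        i_g = expit(z[:, :H])
        f_g = expit(z[:, H : 2 * H])
        o_g = expit(z[:, 2 * H : 3 * H])
        g_g = np.tanh(z[:, 3 * H :])
        c = f_g * c + i_g * g_g
        tc = np.tanh(c)
        h = o_g * tc
        gates_i[t], gates_f[t], gates_o[t], gates_g[t] = i_g, f_g, o_g, g_g
        cells[t], tanh_c[t], hs[t] = c, tc, h
    out_data = hs.mean(axis=0) if return_mean else hs[-1]
    out = Tensor(out_data, parents=(x, w, u, b))

    def bwd(g):
        dh_extra = np.broadcast_to(g / T, (T, B, H)).copy() if return_mean else None
        dh = g.copy() if not return_mean else np.zeros((B, H), dtype=dt)
        dc = np.zeros((B, H), dtype=dt)
        dz_all = np.empty((T, B, 4 * H), dtype=dt)
        for t in range(T - 1, -1, -1):
            if return_mean:
                dh = dh + dh_extra[t]
            i_g, f_g, o_g, g_g = gates_i[t], gates_f[t], gates_o[t], gates_g[t]
            tc = tanh_c[t]
            do = dh * tc
            dc = dc + dh * o_g * (1.0 - tc * tc)
            c_prev = cells[t - 1] if t > 0 else np.zeros((B, H))
            df = dc * c_prev
            di = dc * g_g
            dg = dc * i_g
            dz = np.concatenate(
                [
                    di * i_g * (1.0 - i_g),
                    df * f_g * (1.0 - f_g),
                    do * o_g * (1.0 - o_g),
                    dg * (1.0 - g_g * g_g),
                ],
                axis=1,
            )
            dz_all[t] = dz
            dh = dz @ ud.T
            dc = dc * f_g
        if b.requires_grad:
            b._accum(dz_all.sum(axis=(0, 1)))
        if w.requires_grad:
            w._accum(np.einsum("bti,tbh->ih", xd, dz_all))
        if u.requires_grad:
            h_prev = np.concatenate([np.zeros((1, B, H)), hs[:-1]], axis=0)
            u._accum(np.einsum("tbh,tbk->hk", h_prev, dz_all))
        if x.requires_grad:
            x._accum(np.einsum("tbk,ik->bti", dz_all, wd))

    out._backward = bwd
    return out


# ------------------------------------------------------------------- optimizer
class Adam:
    """Adam optimizer over a list of Tensors (deterministic, no weight decay)."""

    def __init__(self, params: Iterable[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
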