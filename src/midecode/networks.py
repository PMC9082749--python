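"""Trainable sub-networks of the decoder.

Four parameter groups compose the full model:

* the **feature mapper** — a Bi-LSTM over the raw 500 x 3 sequence in
  parallel with a CNN over the 90 x 90 time-frequency image, concatenated;
* the **fusion encoder** — the encoder stack of a two-stage stacked sparse
  autoencoder compressing the two branch features into a compact code;
* the **task head** — 4-class softmax classifier;
* the **domain head** — session/subject discriminator.

Each building block also exposes a plain-numpy reference path
(:func:`lstm_step`, :func:`bilstm_forward`, :func:`conv_forward`,
:func:`cnn_forward`, :func:`ssae_forward`) with the exact gate/layer
equations, used for inference and as the cross-check target of the fused
autodiff ops.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import (
    Adam,  # noqa: F401  (re-exported for callers)
    Tensor,
    batchnorm_train,
    concat,
    conv2d,
    grad_reverse,
    lstm_sequence,
    maxpool2d,
    relu,
    sigmoid,
    tanh,
)
from .autodiff import log_softmax as _log_softmax

GATE_ORDER = ("i", "f", "o", "c")
N_CLASSES = 4

__all__ = [
    "LSTMGateParams",
    "lstm_step",
    "LSTMCell",
    "BiLSTM",
    "bilstm_forward",
    "BatchNorm",
    "ConvLayer",
    "conv_forward",
    "Dense",
    "CNN",
    "cnn_forward",
    "parameter_count",
    "SSAE",
    "ssae_forward",
    "FusionModel",
    "softmax",
    "task_predict",
    "classification_loss",
    "domain_loss",
]


def _uniform(rng: np.random.Generator, *shape: int, scale: float = 0.05,
             dtype=np.float64) -> Tensor:
    return Tensor(rng.uniform(-scale, scale, size=shape).astype(dtype), requires_grad=True)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    from scipy.special import expit

    return expit(z)


# ---------------------------------------------------------------------- LSTM
@dataclass
class LSTMGateParams:
    """Per-gate weight matrices W (input), U (recurrent) and biases b, in
    gate order (input, forget, output, cell-candidate)."""

    W: dict[str, np.ndarray]
    U: dict[str, np.ndarray]
    b: dict[str, np.ndarray]

    def __post_init__(self):
        for g in GATE_ORDER:
            if g not in self.W or g not in self.U or g not in self.b:
                raise ValueError(f"missing gate {g!r}")
        h = self.U["i"].shape[0]
        i = self.W["i"].shape[1]
        for g in GATE_ORDER:
            if self.W[g].shape != (h, i) or self.U[g].shape != (h, h) or self.b[g].shape != (h,):
                raise ValueError(f"inconsistent dimensions for gate {g!r}")
        self.hidden_size = h
        self.input_size = i


def lstm_step(
    x_t: np.ndarray, state: tuple[np.ndarray, np.ndarray], p: LSTMGateParams
) -> tuple[np.ndarray, np.ndarray]:
    """One LSTM recurrence step.

        i_t = σ(W_i x_t + U_i h_{t-1} + b_i)
        f_t = σ(W_f x_t + U_f h_{t-1} + b_f)
        o_t = σ(W_o x_t + U_o h_{t-1} + b_o)
        c_t = f_t ⊙ c_{t-1} + i_t ⊙ tanh(W_c x_t + U_c h_{t-1} + b_c)
        h_t = o_t ⊙ tanh(c_t)
    """
    h_prev, c_prev = state
    x_t = np.asarray(x_t, dtype=np.float64)
    if x_t.shape[-1] != p.input_size or h_prev.shape[-1] != p.hidden_size:
        raise ValueError(
            f"dimension mismatch: x {x_t.shape} vs input_size {p.input_size}, "
            f"h {h_prev.shape} vs hidden_size {p.hidden_size}"
        )
    i_t = _sigmoid(x_t @ p.W["i"].T + h_prev @ p.U["i"].T + p.b["i"])
    f_t = _sigmoid(x_t @ p.W["f"].T + h_prev @ p.U["f"].T + p.b["f"])
    o_t = _sigmoid(x_t @ p.W["o"].T + h_prev @ p.U["o"].T + p.b["o"])
    g_t = np.tanh(x_t @ p.W["c"].T + h_prev @ p.U["c"].T + p.b["c"])
    c_t = f_t * c_prev + i_t * g_t
    h_t = o_t * np.tanh(c_t)
    return h_t, c_t


class LSTMCell:
    """Trainable LSTM cell with stacked gate matrices (columns ordered
    [i | f | o | c])."""

    def __init__(self, input_size: int, hidden_size: int, rng: np.random.Generator,
                 dtype=np.float64):
        self.input_size = input_size
        self.hidden_size = hidden_size
        self.w = _uniform(rng, input_size, 4 * hidden_size, dtype=dtype)
        self.u = _uniform(rng, hidden_size, 4 * hidden_size, dtype=dtype)
        self.b = _uniform(rng, 4 * hidden_size, dtype=dtype)

    def parameters(self) -> list[Tensor]:
        return [self.w, self.u, self.b]

    def gate_params(self) -> LSTMGateParams:
        h = self.hidden_size
        W, U, b = {}, {}, {}
        for k, g in enumerate(GATE_ORDER):
            sl = slice(k * h, (k + 1) * h)
            W[g] = self.w.data[:, sl].T.copy()
            U[g] = self.u.data[:, sl].T.copy()
            b[g] = self.b.data[sl].copy()
        return LSTMGateParams(W=W, U=U, b=b)


class BiLSTM:
    """Bidirectional LSTM over (B, T, 3) sequences.

    The forward cell consumes the sequence in time order, the backward cell
    in reverse; their final (or mean) hidden states are merged either by
    concatenation (output 2*hidden) or a Hadamard product (output hidden).
    """

    def __init__(
        self,
        input_size: int = 3,
        hidden_size: int = 64,
        merge_mode: str = "concat",
        reduce: str = "last",
        rng: np.random.Generator | None = None,
        dtype=np.float64,
    ):
        if merge_mode not in ("concat", "hadamard"):
            raise ValueError(f"unknown merge_mode {merge_mode!r}")
        if reduce not in ("last", "mean"):
            raise ValueError(f"unknown reduce {reduce!r}")
        rng = rng or np.random.default_rng(0)
        self.hidden_size = hidden_size
        self.merge_mode = merge_mode
        self.reduce = reduce
        self.forward_cell = LSTMCell(input_size, hidden_size, rng, dtype)
        self.backward_cell = LSTMCell(input_size, hidden_size, rng, dtype)

    @property
    def out_dim(self) -> int:
        return 2 * self.hidden_size if self.merge_mode == "concat" else self.hidden_size

    def parameters(self) -> list[Tensor]:
        return self.forward_cell.parameters() + self.backward_cell.parameters()

    def forward(self, x: Tensor) -> Tensor:
        if x.ndim != 3:
            raise ValueError("BiLSTM expects (batch, time, features)")
        if x.shape[1] < 1:
            raise ValueError("empty sequence")
        mean = self.reduce == "mean"
        hf = lstm_sequence(x, self.forward_cell.w, self.forward_cell.u,
                           self.forward_cell.b, return_mean=mean)
        x_rev = Tensor(x.data[:, ::-1, :].copy(), requires_grad=False) \
            if not x.requires_grad else x[:, ::-1, :]
        hb = lstm_sequence(x_rev, self.backward_cell.w, self.backward_cell.u,
                           self.backward_cell.b, return_mean=mean)
        if self.merge_mode == "concat":
            return concat([hf, hb], axis=1)
        return hf * hb


def bilstm_forward(seq: np.ndarray, p: BiLSTM) -> np.ndarray:
    """Reference Bi-LSTM over one (T, input_size) sequence using the
    per-gate :func:`lstm_step` recurrence (no autodiff)."""
    seq = np.asarray(seq, dtype=np.float64)
    if seq.ndim != 2:
        raise ValueError("expected a (T, features) sequence")
    if seq.shape[0] < 1:
        raise ValueError("empty sequence")
    out = []
    for cell, s in ((p.forward_cell, seq), (p.backward_cell, seq[::-1])):
        gp = cell.gate_params()
        h = np.zeros(cell.hidden_size)
        c = np.zeros(cell.hidden_size)
        hist = []
        for t in range(s.shape[0]):
            h, c = lstm_step(s[t], (h, c), gp)
            hist.append(h)
        out.append(np.mean(hist, axis=0) if p.reduce == "mean" else h)
    hf, hb = out
    return np.concatenate([hf, hb]) if p.merge_mode == "concat" else hf * hb


# ----------------------------------------------------------------------- CNN
class BatchNorm:
    """Per-channel batch normalization over (B, H, W, C) activations."""

    def __init__(self, n_channels: int, momentum: float = 0.1, eps: float = 1e-5,
                 dtype=np.float64):
        self.gamma = Tensor(np.ones(n_channels, dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros(n_channels, dtype=dtype), requires_grad=True)
        self.running_mean = np.zeros(n_channels, dtype=dtype)
        self.running_var = np.ones(n_channels, dtype=dtype)
        self.momentum = momentum
        self.eps = eps

    def parameters(self) -> list[Tensor]:
        return [self.gamma, self.beta]

    def forward(self, x: Tensor, training: bool) -> Tensor:
        if training:
            out, mu, var = batchnorm_train(x, self.gamma, self.beta, self.eps)
            self.running_mean += self.momentum * (mu - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
            return out
        xhat = (x - self.running_mean) * ((self.running_var + self.eps) ** -0.5)
        return xhat * self.gamma + self.beta


class ConvLayer:
    """Valid 2-D convolution -> batch-norm -> ReLU."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: tuple[int, int],
        stride: tuple[int, int] = (1, 1),
        batch_norm: bool = True,
        rng: np.random.Generator | None = None,
        dtype=np.float64,
    ):
        rng = rng or np.random.default_rng(0)
        self.kernel = kernel
        self.stride = stride
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.w = _uniform(rng, kernel[0], kernel[1], in_channels, out_channels, dtype=dtype)
        self.b = _uniform(rng, out_channels, dtype=dtype)
        self.bn = BatchNorm(out_channels, dtype=dtype) if batch_norm else None

    def parameters(self) -> list[Tensor]:
        ps = [self.w, self.b]
        if self.bn is not None:
            ps += self.bn.parameters()
        return ps

    def out_shape(self, h: int, w: int) -> tuple[int, int, int]:
        kh, kw = self.kernel
        sh, sw = self.stride
        if kh > h or kw > w:
            raise ValueError(f"kernel {self.kernel} larger than input ({h}, {w})")
        return ((h - kh) // sh + 1, (w - kw) // sw + 1, self.out_channels)

    def forward(self, x: Tensor, training: bool) -> Tensor:
        y = conv2d(x, self.w, self.b, self.stride)
        if self.bn is not None:
            y = self.bn.forward(y, training)
        return relu(y)


def conv_forward(img: np.ndarray, layer: ConvLayer) -> np.ndarray:
    """Reference single-image convolution pass (inference-mode BN).

    img: (H, W, Cin) -> (H', W', Cout)."""
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 3 or img.shape[2] != layer.in_channels:
        raise ValueError(f"expected (H, W, {layer.in_channels}) input, got {img.shape}")
    x = Tensor(img[None])
    return layer.forward(x, training=False).data[0]


class Dense:
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator | None = None,
                 dtype=np.float64):
        rng = rng or np.random.default_rng(0)
        self.in_dim, self.out_dim = in_dim, out_dim
        self.w = _uniform(rng, in_dim, out_dim, dtype=dtype)
        self.b = _uniform(rng, out_dim, dtype=dtype)

    def parameters(self) -> list[Tensor]:
        return [self.w, self.b]

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[-1] != self.in_dim:
            raise ValueError(f"dense layer expects {self.in_dim} features, got {x.shape[-1]}")
        return x @ self.w + self.b


#: expected shape chain for the default 90x90 input
CNN_SHAPE_CHAIN = {
    "input": (90, 90, 1),
    "C1": (84, 84, 25),
    "P1": (42, 28, 25),
    "C2": (38, 24, 50),
    "P2": (19, 6, 50),
    "F1": 5700,
    "F2": 60,
}


class CNN:
    """Spectral-image branch: C1(25@7x7) -> P1(2x3) -> C2(50@5x5) -> P2(2x4)
    -> flatten(5700) -> dense(60).

    The layer chain is validated against :data:`CNN_SHAPE_CHAIN` at
    construction; a configuration that breaks it raises immediately.
    """

    def __init__(
        self,
        input_shape: tuple[int, int] = (90, 90),
        rng: np.random.Generator | None = None,
        batch_norm: bool = True,
        validate_chain: bool = True,
        dtype=np.float64,
    ):
        rng = rng or np.random.default_rng(0)
        self.input_shape = input_shape
        self.dtype = dtype
        self.c1 = ConvLayer(1, 25, (7, 7), (1, 1), batch_norm, rng, dtype)
        self.p1 = (2, 3)
        self.c2 = ConvLayer(25, 50, (5, 5), (1, 1), batch_norm, rng, dtype)
        self.p2 = (2, 4)
        h, w = input_shape
        chain: dict[str, tuple | int] = {"input": (h, w, 1)}
        h, w, c = self.c1.out_shape(h, w)
        chain["C1"] = (h, w, c)
        h, w = h // self.p1[0], w // self.p1[1]
        chain["P1"] = (h, w, c)
        h, w, c = self.c2.out_shape(h, w)
        chain["C2"] = (h, w, c)
        h, w = h // self.p2[0], w // self.p2[1]
        chain["P2"] = (h, w, c)
        flat = h * w * c
        chain["F1"] = flat
        chain["F2"] = 60
        self.shape_chain = chain
        if validate_chain and input_shape == (90, 90) and chain != CNN_SHAPE_CHAIN:
            raise ValueError(f"CNN layer chain {chain} violates the required {CNN_SHAPE_CHAIN}")
        self.f2 = Dense(flat, 60, rng, dtype)

    @property
    def out_dim(self) -> int:
        return 60

    def parameters(self) -> list[Tensor]:
        return self.c1.parameters() + self.c2.parameters() + self.f2.parameters()

    def forward(self, img: Tensor, training: bool = False) -> Tensor:
        if img.ndim == 3:  # (B, H, W) -> add channel axis
            img = img.reshape(img.shape[0], img.shape[1], img.shape[2], 1)
        if img.shape[1:3] != tuple(self.input_shape):
            raise ValueError(f"expected {self.input_shape} image, got {img.shape[1:3]}")
        x = self.c1.forward(img, training)
        x = maxpool2d(x, self.p1)
        x = self.c2.forward(x, training)
        x = maxpool2d(x, self.p2)
        x = x.reshape(x.shape[0], -1)
        return self.f2.forward(x)

    def parameter_counts(self) -> dict[str, int]:
        counts = {
            "C1": parameter_count(self.c1),
            "C2": parameter_count(self.c2),
            "F2": parameter_count(self.f2),
        }
        bn = 0
        for layer in (self.c1, self.c2):
            if layer.bn is not None:
                bn += layer.bn.gamma.data.size + layer.bn.beta.data.size
        counts["BN"] = bn
        return counts


def cnn_forward(img: np.ndarray, p: CNN) -> np.ndarray:
    """Reference single-image CNN pass (inference mode): (90, 90) -> (60,)."""
    img = np.asarray(img, dtype=np.float64)
    if img.shape != tuple(p.input_shape):
        raise ValueError(f"expected {p.input_shape} image, got {img.shape}")
    return p.forward(Tensor(img[None]), training=False).data[0]


def parameter_count(layer: ConvLayer | Dense) -> int:
    """Weights + biases of one layer; batch-norm parameters are reported
    separately (see ``CNN.parameter_counts``)."""
    if isinstance(layer, ConvLayer):
        kh, kw = layer.kernel
        return kh * kw * layer.in_channels * layer.out_channels + layer.out_channels
    if isinstance(layer, Dense):
        return layer.in_dim * layer.out_dim + layer.out_dim
    raise TypeError(f"cannot count parameters of {type(layer).__name__}")


# ---------------------------------------------------------------------- SSAE
class SSAE:
    """Two-stage stacked sparse autoencoder.

    Each stage is a sigmoid encoder/decoder pair H = σ(W_en x + b_en),
    x' = σ(W_de H + b_de); the encoder stack is the fusion map of the full model.
    Sparsity is a KL(ρ ‖ ρ̂) penalty on mean encoder activations.
    """

    def __init__(
        self,
        input_dim: int,
        hidden_dims: tuple[int, ...] = (64, 37),
        sparsity_target: float = 0.05,
        sparsity_weight: float = 0.1,
        rng: np.random.Generator | None = None,
        dtype=np.float64,
    ):
        rng = rng or np.random.default_rng(0)
        self.input_dim = input_dim
        self.hidden_dims = tuple(hidden_dims)
        self.sparsity_target = sparsity_target
        self.sparsity_weight = sparsity_weight
        dims = (input_dim,) + self.hidden_dims
        self.encoders = [Dense(dims[k], dims[k + 1], rng, dtype)
                         for k in range(len(self.hidden_dims))]
        self.decoders = [Dense(dims[k + 1], dims[k], rng, dtype)
                         for k in range(len(self.hidden_dims))]

    @property
    def code_dim(self) -> int:
        return self.hidden_dims[-1]

    def parameters(self) -> list[Tensor]:
        ps: list[Tensor] = []
        for e in self.encoders:
            ps += e.parameters()
        for d in self.decoders:
            ps += d.parameters()
        return ps

    def encoder_parameters(self) -> list[Tensor]:
        ps: list[Tensor] = []
        for e in self.encoders:
            ps += e.parameters()
        return ps

    def encode(self, x: Tensor) -> Tensor:
        for enc in self.encoders:
            x = sigmoid(enc.forward(x))
        return x

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor]:
        code = self.encode(x)
        y = code
        for dec in reversed(self.decoders):
            y = sigmoid(dec.forward(y))
        return code, y

    def reconstruction_loss(self, x: Tensor) -> Tensor:
        code, recon = self.forward(x)
        err = recon - x
        mse = (err * err).mean()
        if self.sparsity_weight > 0:
            rho = self.sparsity_target
            rho_hat = code.mean(axis=0)
            # KL(ρ ‖ ρ̂) summed over code units, clamp-free (sigmoid keeps ρ̂ in (0,1))
            kl = (rho * np.log(rho)) - rho * rho_hat.log() \
                + ((1 - rho) * np.log(1 - rho)) - (1 - rho) * (1.0 - rho_hat).log()
            mse = mse + self.sparsity_weight * kl.sum()
        return mse


def ssae_forward(x: np.ndarray, p: SSAE) -> tuple[np.ndarray, np.ndarray]:
    """Reference stacked-autoencoder pass: returns (code, reconstruction)."""
    x = np.asarray(x, dtype=np.float64)
    squeeze = x.ndim == 1
    xt = Tensor(x[None] if squeeze else x)
    if xt.shape[-1] != p.input_dim:
        raise ValueError(f"expected {p.input_dim}-dim input, got {xt.shape[-1]}")
    code, recon = p.forward(xt)
    if squeeze:
        return code.data[0], recon.data[0]
    return code.data, recon.data


# ------------------------------------------------------------------ the model
class FusionModel:
    """Full decoder: (Bi-LSTM ‖ CNN) feature mapper -> SSAE fusion encoder
    -> task / domain heads."""

    def __init__(
        self,
        n_domains: int = 2,
        hidden_size: int = 64,
        ssae_dims: tuple[int, ...] = (64, 37),
        merge_mode: str = "concat",
        seed: int = 0,
        batch_norm: bool = True,
        input_scale: float = 1.0,
        dtype=np.float32,
    ):
        rng = np.random.default_rng(seed)
        self.dtype = np.dtype(dtype).type
        self.bilstm = BiLSTM(3, hidden_size, merge_mode=merge_mode, rng=rng, dtype=dtype)
        self.cnn = CNN(rng=rng, batch_norm=batch_norm, dtype=dtype)
        self.feature_dim = self.bilstm.out_dim + self.cnn.out_dim
        self.ssae = SSAE(self.feature_dim, ssae_dims, rng=rng, dtype=dtype)
        self.task_head = Dense(self.ssae.code_dim, N_CLASSES, rng, dtype)
        self.domain_head = Dense(self.ssae.code_dim, n_domains, rng, dtype)
        self.n_domains = n_domains
        self.input_scale = input_scale  # divides raw sequences before the Bi-LSTM

    # parameter groups -----------------------------------------------------
    def mapper_parameters(self) -> list[Tensor]:
        return self.bilstm.parameters() + self.cnn.parameters()

    def fusion_parameters(self) -> list[Tensor]:
        return self.ssae.encoder_parameters()

    def task_head_parameters(self) -> list[Tensor]:
        return self.task_head.parameters()

    def domain_head_parameters(self) -> list[Tensor]:
        return self.domain_head.parameters()

    def parameters(self) -> list[Tensor]:
        return (self.mapper_parameters() + self.fusion_parameters()
                + self.task_head_parameters() + self.domain_head_parameters())

    # forward passes -------------------------------------------------------
    def features(self, seqs: Tensor, imgs: Tensor, training: bool = False) -> Tensor:
        """Feature mapper: raw (B, T, 3) sequences + (B, 90, 90) images -> fused features."""
        if self.input_scale != 1.0:
            seqs = Tensor(seqs.data / self.input_scale) if not seqs.requires_grad \
                else seqs * (1.0 / self.input_scale)
        ft = self.bilstm.forward(seqs)
        fc = self.cnn.forward(imgs, training)
        return concat([ft, fc], axis=1)

    def encode(self, seqs: Tensor, imgs: Tensor, training: bool = False) -> Tensor:
        """Fusion code: encoder stack over the mapped features."""
        return self.ssae.encode(self.features(seqs, imgs, training))

    def task_logits(self, code: Tensor) -> Tensor:
        return self.task_head.forward(code)

    def domain_logits(self, code: Tensor, reverse_lambda: float | None = None) -> Tensor:
        if reverse_lambda is not None:
            code = grad_reverse(code, reverse_lambda)
        return self.domain_head.forward(code)


def softmax(a: np.ndarray) -> np.ndarray:
    """Shift-invariant softmax along the last axis."""
    a = np.asarray(a, dtype=np.float64)
    z = a - a.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def task_predict(model: FusionModel, trials: np.ndarray, images: np.ndarray) -> np.ndarray:
    """Class probabilities for (n, 3, 500) trials and their (n, 90, 90)
    images (inference mode)."""
    trials = np.asarray(trials, dtype=np.float64)
    images = np.asarray(images, dtype=np.float64)
    if trials.ndim != 3 or trials.shape[1] != 3:
        raise ValueError(f"feature-mapper stage: expected (n, 3, T) trials, got {trials.shape}")
    if images.ndim != 3:
        raise ValueError(f"feature-mapper stage: expected (n, H, W) images, got {images.shape}")
    seqs = Tensor(trials.transpose(0, 2, 1).astype(model.dtype))
    code = model.encode(seqs, Tensor(images.astype(model.dtype)), training=False)
    return softmax(model.task_logits(code).data)


def classification_loss(probs: np.ndarray, labels: np.ndarray | int) -> float:
    """Mean negative log-probability of the correct label (ε-clamped)."""
    probs = np.atleast_2d(np.asarray(probs, dtype=np.float64))
    labels = np.atleast_1d(np.asarray(labels, dtype=np.int64))
    p = probs[np.arange(len(labels)), labels]
    return float(np.mean(-np.log(np.clip(p, 1e-12, None))))


def domain_loss(domain_probs: np.ndarray | float, d: np.ndarray | int) -> float:
    """Domain-discrimination loss.

    Binary form (scalar probability p of domain 1 and d ∈ {0, 1}):
        L = d log(1/p) + (1 - d) log(1/(1 - p)).
    For a probability vector over >2 domains: categorical cross-entropy.
    """
    p = np.asarray(domain_probs, dtype=np.float64)
    if p.ndim == 0 or (p.ndim == 1 and np.isscalar(d)) and p.size == 1:
        p = float(p)
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"invalid probability {p}")
        d = int(d)
        eps = 1e-12
        return float(d * -np.log(max(p, eps)) + (1 - d) * -np.log(max(1.0 - p, eps)))
    probs = np.atleast_2d(p)
    if np.any(probs < 0) or np.any(np.abs(probs.sum(axis=-1) - 1.0) > 1e-6):
        raise ValueError("invalid probability distribution(s)")
    labels = np.atleast_1d(np.asarray(d, dtype=np.int64))
    sel = probs[np.arange(len(labels)), labels]
    return float(np.mean(-np.log(np.clip(sel, 1e-12, None))))


def nll_from_logits(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Differentiable mean cross-entropy from raw logits (training path;
    numerically equals classification_loss(softmax(logits), labels))."""
    logp = _log_softmax(logits, axis=-1)
    n = logits.shape[0]
    picked = logp[np.arange(n), np.asarray(labels, dtype=np.int64)]
    return -picked.mean()
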