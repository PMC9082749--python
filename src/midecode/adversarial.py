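"""Domain-adversarial objective and min-max training.

The total cost is

    E = (1/n) Σ_src L_y  −  λ [ (1/n) Σ_src L_d + (1/n') Σ_tgt L_d ]

minimized over the feature-mapper/task-head parameters and maximized over
the domain-discriminating direction.  The saddle point is realized with a
gradient-reversal layer between the fusion encoder and the domain head:
the domain head descends its own cross-entropy at full
strength while the reversed gradient (scaled by -λ) reaches the encoder.
λ is ramped linearly from 0 over the first third of training.

With λ = 0 the loop reduces exactly — bit-for-bit under a fixed seed — to
plain classifier training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Adam, Tensor, log_softmax
from .networks import FusionModel, nll_from_logits
from .preprocess import TrialSet

__all__ = [
    "ObjectiveConfig",
    "TrainState",
    "regularizer_theta",
    "total_cost",
    "pretrain_ssae",
    "train_minmax",
    "train_classifier",
    "calibrate",
    "domain_accuracy",
    "task_accuracy",
]


@dataclass
class ObjectiveConfig:
    """Hyper-parameters of the min-max objective and its optimizer."""

    lam: float = 1.0  # adversarial weight λ
    epochs: int = 100
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0
    lambda_ramp_frac: float = 1.0 / 3.0  # λ ramps 0 -> lam over this fraction of epochs
    hidden_size: int = 64
    ssae_dims: tuple[int, ...] = (64, 37)
    pretrain_epochs: int = 30  # SSAE pretraining steps (full-batch)
    batch_norm: bool = True
    task_only: bool = False  # plain classifier: domain head never evaluated
    n: int | None = None  # source-domain sample count (derived if None)
    n_prime: int | None = None

    def __post_init__(self):
        if self.lam < 0:
            raise ValueError("λ must be non-negative")

    @property
    def N(self) -> int | None:
        if self.n is None or self.n_prime is None:
            return None
        return self.n + self.n_prime

    def lam_at(self, epoch: int) -> float:
        ramp = max(1, int(round(self.epochs * self.lambda_ramp_frac)))
        return self.lam * min(1.0, (epoch + 1) / ramp)


@dataclass
class TrainState:
    model: FusionModel
    epoch: int = 0
    history: dict[str, list[float]] = field(
        default_factory=lambda: {
            "task_loss": [], "domain_loss": [], "task_acc": [], "domain_acc": []
        }
    )
    config: ObjectiveConfig | None = None

    def record(self, **kv: float) -> None:
        for k, v in kv.items():
            self.history[k].append(float(v))


# -------------------------------------------------------------- cost formulas
def regularizer_theta(domain_losses: np.ndarray, cfg: ObjectiveConfig) -> float:
    """θ = −(1/n) Σ_{i≤n} L_d,i − (1/n') Σ_{i>n} L_d,i over the concatenated
    per-sample losses [source part | further part]."""
    losses = np.asarray(domain_losses, dtype=np.float64)
    n, n_prime = cfg.n, cfg.n_prime
    if n is None or n_prime is None:
        raise ValueError("cfg.n and cfg.n_prime must be set")
    if n <= 0 or n_prime <= 0:
        raise ValueError("both partitions must be non-empty")
    if len(losses) != n + n_prime:
        raise ValueError(f"expected {n + n_prime} losses, got {len(losses)}")
    return float(-(losses[:n].mean()) - losses[n:].mean())


def total_cost(
    task_losses: np.ndarray, domain_losses: np.ndarray, cfg: ObjectiveConfig
) -> float:
    """E = mean task loss + λ·θ (θ as above); reduces to the plain classifier
    cost at λ = 0."""
    if cfg.lam < 0:
        raise ValueError("λ must be non-negative")
    task = np.asarray(task_losses, dtype=np.float64)
    return float(task.mean() + cfg.lam * regularizer_theta(domain_losses, cfg))


# ------------------------------------------------------------ SSAE pretraining
def pretrain_ssae(features: np.ndarray, ssae, epochs: int, lr: float = 1e-3):
    """Greedy stage-wise then joint reconstruction training (full-batch Adam).

    Returns the same (mutated) SSAE instance.  ``epochs`` applies per stage
    and again to the joint fine-tune; 0 epochs leaves parameters untouched.
    """
    from .autodiff import sigmoid as t_sigmoid

    features = np.asarray(features, dtype=np.float64)
    if features.ndim != 2 or features.shape[0] == 0:
        raise ValueError("feature set must be a non-empty (n, d) array")
    if epochs == 0:
        return ssae
    x_stage = features
    for enc, dec in zip(ssae.encoders, ssae.decoders):
        params = enc.parameters() + dec.parameters()
        opt = Adam(params, lr=lr)
        xt = Tensor(x_stage)
        for _ in range(epochs):
            opt.zero_grad()
            code = t_sigmoid(enc.forward(xt))
            recon = t_sigmoid(dec.forward(code))
            err = recon - xt
            loss = (err * err).mean()
            if ssae.sparsity_weight > 0:
                rho = ssae.sparsity_target
                rho_hat = code.mean(axis=0)
                kl = (rho * np.log(rho)) - rho * rho_hat.log() \
                    + ((1 - rho) * np.log(1 - rho)) - (1 - rho) * (1.0 - rho_hat).log()
                loss = loss + ssae.sparsity_weight * kl.sum()
            loss.backward()
            opt.step()
        # next stage trains on this stage's codes
        code = t_sigmoid(enc.forward(Tensor(x_stage)))
        x_stage = code.data
    # joint fine-tune of the full stack
    opt = Adam(ssae.parameters(), lr=lr)
    xt = Tensor(features)
    for _ in range(epochs):
        opt.zero_grad()
        loss = ssae.reconstruction_loss(xt)
        loss.backward()
        opt.step()
    return ssae


def ssae_mse(ssae, features: np.ndarray) -> float:
    _, recon = ssae.forward(Tensor(np.asarray(features, dtype=np.float64)))
    return float(np.mean((recon.data - features) ** 2))


# ------------------------------------------------------------------- training
def _prepare(trials: TrialSet, images: np.ndarray):
    seqs = trials.trials.transpose(0, 2, 1)  # (n, T, 3)
    scale = float(seqs.std())
    return seqs, np.asarray(images, dtype=np.float64), (scale if scale > 0 else 1.0)


def _domain_weights(dom: np.ndarray, n_domains: int) -> np.ndarray:
    """Per-sample weights realizing the sum of per-domain averages."""
    w = np.zeros(len(dom))
    for k in range(n_domains):
        mask = dom == k
        if mask.any():
            w[mask] = 1.0 / mask.sum()
    return w


def train_minmax(
    trials: TrialSet,
    images: np.ndarray,
    cfg: ObjectiveConfig,
    model: FusionModel | None = None,
) -> TrainState:
    """Min-max training of the full decoder on matched (trial, image) pairs.

    Descends the task loss over all parameters while the gradient-reversal
    layer feeds ``-λ ∂L_d`` back into the encoder; the domain head itself
    descends its cross-entropy unscaled.  Deterministic under ``cfg.seed``.
    """
    dom_values = np.unique(trials.domain_ids)
    if not cfg.task_only and len(dom_values) < 2:
        raise ValueError("adversarial training needs at least 2 distinct domain_ids")
    dom = np.searchsorted(dom_values, trials.domain_ids)
    n_domains = max(len(dom_values), 2)
    seqs, images, scale = _prepare(trials, images)
    labels = trials.labels
    n = len(trials)
    fresh_model = model is None
    if fresh_model:
        model = FusionModel(
            n_domains=n_domains,
            hidden_size=cfg.hidden_size,
            ssae_dims=cfg.ssae_dims,
            seed=cfg.seed,
            batch_norm=cfg.batch_norm,
            input_scale=scale,
        )
    seqs = seqs.astype(model.dtype)
    images = images.astype(model.dtype)
    if fresh_model and cfg.pretrain_epochs > 0:
        feats = _batched_features(model, seqs, images, cfg.batch_size)
        pretrain_ssae(feats, model.ssae, cfg.pretrain_epochs, lr=cfg.learning_rate)
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed)
    state = TrainState(model=model, config=cfg)
    for ep in range(cfg.epochs):
        lam_t = cfg.lam_at(ep)
        order = rng.permutation(n)
        ep_task, ep_dom, hit_task, hit_dom, seen = 0.0, 0.0, 0, 0, 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            sb = Tensor(seqs[idx])
            ib = Tensor(images[idx])
            yb = labels[idx]
            db = dom[idx]
            opt.zero_grad()
            code = model.encode(sb, ib, training=True)
            tl = model.task_logits(code)
            loss = nll_from_logits(tl, yb)
            task_loss_val = float(loss.data)
            if not cfg.task_only:
                dl = model.domain_logits(code, reverse_lambda=lam_t)
                logp = log_softmax(dl, axis=-1)
                picked = logp[np.arange(len(db)), db]
                w = _domain_weights(db, n_domains).astype(code.data.dtype)
                dterm = -(picked * w).sum()
                loss = loss + dterm
                ep_dom += float(dterm.data) * len(idx)
                hit_dom += int((dl.data.argmax(axis=1) == db).sum())
            loss.backward()
            opt.step()
            ep_task += task_loss_val * len(idx)
            hit_task += int((tl.data.argmax(axis=1) == yb).sum())
            seen += len(idx)
        state.epoch = ep + 1
        state.record(
            task_loss=ep_task / seen,
            domain_loss=ep_dom / seen if not cfg.task_only else float("nan"),
            task_acc=hit_task / seen,
            domain_acc=hit_dom / seen if not cfg.task_only else float("nan"),
        )
    return state


def _batched_features(model, seqs, images, batch_size) -> np.ndarray:
    out = []
    for start in range(0, len(seqs), batch_size):
        f = model.features(Tensor(seqs[start : start + batch_size]),
                           Tensor(images[start : start + batch_size]), training=False)
        out.append(f.data)
    return np.concatenate(out)


def train_classifier(trials: TrialSet, images: np.ndarray, cfg: ObjectiveConfig,
                     model: FusionModel | None = None) -> TrainState:
    """Plain (non-adversarial) classifier training: the same loop with the
    domain head never evaluated."""
    from dataclasses import replace

    return train_minmax(trials, images, replace(cfg, task_only=True, lam=0.0), model=model)


def calibrate(
    pretrained: FusionModel | None,
    target: TrialSet,
    images: np.ndarray,
    fraction: float,
    epochs: int,
    cfg: ObjectiveConfig | None = None,
) -> TrainState:
    """Fine-tune on a class-stratified ``fraction`` of the target trials with
    task loss only.  ``pretrained=None`` trains from scratch under the same
    budget (the no-pretraining comparison arm)."""
    if not 0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    cfg = cfg or ObjectiveConfig()
    from dataclasses import replace

    cfg = replace(cfg, task_only=True, lam=0.0, epochs=epochs)
    rng = np.random.default_rng(cfg.seed)
    if fraction < 1.0:
        keep: list[int] = []
        for k in np.unique(target.labels):
            idx = np.flatnonzero(target.labels == k)
            take = max(1, int(round(fraction * len(idx))))
            keep.extend(rng.choice(idx, size=take, replace=False))
        sel = np.sort(np.asarray(keep))
    else:
        sel = np.arange(len(target))
    sub = target.subset(sel)
    sub_images = np.asarray(images)[sel]
    if epochs == 0:
        state = TrainState(model=pretrained, config=cfg)
        return state
    if pretrained is not None:
        # fine-tune all parameters; SSAE pretraining already happened upstream
        return train_minmax(sub, sub_images, replace(cfg, pretrain_epochs=0),
                            model=pretrained)
    return train_minmax(sub, sub_images, cfg)


# ------------------------------------------------------------------- metrics
def task_accuracy(model: FusionModel, trials: TrialSet, images: np.ndarray,
                  batch_size: int = 64) -> float:
    seqs = trials.trials.transpose(0, 2, 1).astype(model.dtype)
    images = np.asarray(images).astype(model.dtype)
    hits = 0
    for start in range(0, len(trials), batch_size):
        code = model.encode(Tensor(seqs[start : start + batch_size]),
                            Tensor(images[start : start + batch_size]))
        pred = model.task_logits(code).data.argmax(axis=1)
        hits += int((pred == trials.labels[start : start + batch_size]).sum())
    return hits / len(trials)


def domain_accuracy(model: FusionModel, trials: TrialSet, images: np.ndarray,
                    batch_size: int = 64) -> float:
    dom_values = np.unique(trials.domain_ids)
    dom = np.searchsorted(dom_values, trials.domain_ids)
    seqs = trials.trials.transpose(0, 2, 1).astype(model.dtype)
    images = np.asarray(images).astype(model.dtype)
    hits = 0
    for start in range(0, len(trials), batch_size):
        code = model.encode(Tensor(seqs[start : start + batch_size]),
                            Tensor(images[start : start + batch_size]))
        pred = model.domain_logits(code).data.argmax(axis=1)
        hits += int((pred == dom[start : start + batch_size]).sum())
    return hits / len(trials)
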