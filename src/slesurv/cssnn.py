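"""Cost-sensitive semi-supervised neural survival-outcome classifier.

The classifier is a small feed-forward network (117 -> 64 -> 64 -> 2,
softmax head) trained with a *dynamic weighted delayed mean-squared-error*
loss designed for imbalanced, partly censored clinical cohorts:

    Loss = dyn_weight_MSE(y1, out_x1) + alpha(t) * dyn_weight_MSE(y2, out_x2)

where (y1, out_x1) are the true-label batch and (y2, out_x2) the
pseudo-label batch.  ``dyn_weight_MSE`` is a per-sample class-weighted MSE
whose weights are recomputed once per batch:

    weight_i = zero_weight if y_i = 0 else one_weight,
    zero_weight = Np / N,   one_weight = Nn / N,

with Np the number of death (label 1) samples, Nn the number of survival
(label 0) samples and N the batch size — so the rare death class carries
the larger penalty.  ``alpha(t)`` ramps the pseudo-label term in linearly
between epochs T1 and T2, reaching alpha_f, so unreliable early
pseudo-labels do not dominate training.

Training follows four steps: (i) supervised training on a 1:1
under-sampled labeled set; (ii) pseudo-labeling of the censored records by
argmax of the predicted class probabilities; (iii) cost-sensitive
retraining on labeled + pseudo-labeled data with the combined loss;
(iv) final prediction on the held-out test set.

The network is implemented directly on numpy: the architecture is tiny,
training is CPU-bound matrix algebra, and a self-contained implementation
keeps every run bit-reproducible from a single integer seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "LossConfig",
    "NetConfig",
    "BatchWeights",
    "PseudoLabelSet",
    "TrainedModel",
    "class_weights",
    "batch_mse",
    "dyn_weight_mse",
    "delay_coefficient",
    "combined_loss",
    "train_initial",
    "pseudo_label",
    "train_cost_sensitive",
]


@dataclass(frozen=True)
class LossConfig:
    """Pseudo-label delay-ramp parameters: alpha(t)=0 for t<T1, linear up
    to alpha_f on [T1, T2], then constant."""

    alpha_f: float = 3.0
    t1: int = 100
    t2: int = 600

    def __post_init__(self) -> None:
        if self.t1 >= self.t2:
            raise ValueError("need T1 < T2")
        if self.alpha_f < 0:
            raise ValueError("alpha_f must be nonnegative")


@dataclass(frozen=True)
class NetConfig:
    input_dim: int = 117
    hidden: tuple[int, ...] = (64, 64)
    output_dim: int = 2
    learning_rate: float = 0.002
    batch_size: int = 32
    epochs: int = 800
    seed: int = 0

    def __post_init__(self) -> None:
        if self.input_dim <= 0 or self.output_dim <= 0 or any(h <= 0 for h in self.hidden):
            raise ValueError("all layer widths must be positive")
        if self.batch_size < 2:
            raise ValueError("batch_size must be at least 2")


@dataclass(frozen=True)
class BatchWeights:
    zero_weight: float
    one_weight: float
    n_death: int
    n_survival: int
    n: int


@dataclass
class PseudoLabelSet:
    """Argmax labels assigned to censored records by a trained model."""

    record_ids: np.ndarray
    labels: np.ndarray
    source: str = "pseudo"
    model_id: str = ""

    @property
    def n_death(self) -> int:
        return int(np.sum(self.labels == 1))

    @property
    def n_survival(self) -> int:
        return int(np.sum(self.labels == 0))


# ---------------------------------------------------------------------------
# Loss pieces
# ---------------------------------------------------------------------------


def class_weights(batch_labels: np.ndarray) -> BatchWeights:
    """Per-batch class weights: zero_weight = Np/N, one_weight = Nn/N.

    Survivors (label 0) are weighted by the death fraction of the batch and
    deaths (label 1) by the survival fraction, so the minority class gets
    the larger weight.  Degenerate single-class batches yield a (0, 1) or
    (1, 0) pair exactly as the definition dictates; no epsilon floor.
    """
    y = np.asarray(batch_labels, dtype=int)
    if y.size == 0:
        raise ValueError("batch must be nonempty")
    n = y.size
    np_ = int(np.sum(y == 1))
    nn = n - np_
    return BatchWeights(
        zero_weight=np_ / n, one_weight=nn / n, n_death=np_, n_survival=nn, n=n
    )


def per_sample_weights(batch_labels: np.ndarray) -> np.ndarray:
    """weight_i = (1 - y_i) * zero_weight + y_i * one_weight."""
    w = class_weights(batch_labels)
    y = np.asarray(batch_labels, dtype=float)
    return (1.0 - y) * w.zero_weight + y * w.one_weight


def batch_mse(targets: np.ndarray, outputs: np.ndarray) -> float:
    """MSE = (1 / (2 * batchsize)) * sum_i sum_k (y_ik - out_ik)^2."""
    t = np.asarray(targets, dtype=float)
    o = np.asarray(outputs, dtype=float)
    if t.shape != o.shape:
        raise ValueError(f"shape mismatch: {t.shape} vs {o.shape}")
    return float(np.sum((t - o) ** 2) / (2 * t.shape[0]))


def dyn_weight_mse(targets: np.ndarray, outputs: np.ndarray, weights: np.ndarray) -> float:
    """Per-sample weighted MSE: (1 / (2 * batchsize)) * sum_i w_i * sum_k (y_ik - out_ik)^2.

    The weight enters inside the sample sum — a scalar multiplier would
    defeat the per-sample class-weight construction.
    """
    t = np.asarray(targets, dtype=float)
    o = np.asarray(outputs, dtype=float)
    w = np.asarray(weights, dtype=float)
    if t.shape != o.shape or w.shape[0] != t.shape[0]:
        raise ValueError("targets, outputs and weights must agree in length")
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    return float(np.sum(w * np.sum((t - o) ** 2, axis=1)) / (2 * t.shape[0]))


def delay_coefficient(t: int, cfg: LossConfig) -> float:
    """alpha(t): 0 before T1, linear ramp to alpha_f on [T1, T2], then flat."""
    if t < 0:
        raise ValueError("epoch index must be nonnegative")
    if t < cfg.t1:
        return 0.0
    if t <= cfg.t2:
        return cfg.alpha_f * (t - cfg.t1) / (cfg.t2 - cfg.t1)
    return cfg.alpha_f


def combined_loss(
    true_targets: np.ndarray,
    true_outputs: np.ndarray,
    true_labels: np.ndarray,
    pseudo_targets: np.ndarray | None,
    pseudo_outputs: np.ndarray | None,
    pseudo_labels: np.ndarray | None,
    t: int,
    cfg: LossConfig,
) -> float:
    """Loss = dyn_weight_MSE(true batch) + alpha(t) * dyn_weight_MSE(pseudo batch).

    Each term uses class weights computed on its own batch.  An empty
    pseudo batch reduces the loss to the supervised term.
    """
    loss = dyn_weight_mse(true_targets, true_outputs, per_sample_weights(true_labels))
    if pseudo_targets is not None and len(pseudo_targets) > 0:
        a = delay_coefficient(t, cfg)
        if a > 0.0:
            loss += a * dyn_weight_mse(
                pseudo_targets, pseudo_outputs, per_sample_weights(pseudo_labels)
            )
    return loss


def one_hot_targets(labels: np.ndarray) -> np.ndarray:
    """(1,0) for survival, (0,1) for death."""
    y = np.asarray(labels, dtype=int)
    out = np.zeros((y.size, 2))
    out[np.arange(y.size), y] = 1.0
    return out


# ---------------------------------------------------------------------------
# Network
# ---------------------------------------------------------------------------


class _MLP:
    """Feed-forward net with ReLU hidden layers and a softmax head,
    trained by plain SGD on the weighted-MSE loss."""

    def __init__(self, cfg: NetConfig, rng: np.random.Generator):
        dims = (cfg.input_dim, *cfg.hidden, cfg.output_dim)
        self.cfg = cfg
        self.W = [
            rng.normal(0.0, np.sqrt(2.0 / dims[i]), size=(dims[i], dims[i + 1]))
            for i in range(len(dims) - 1)
        ]
        self.b = [np.zeros(dims[i + 1]) for i in range(len(dims) - 1)]

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        acts = [x]
        h = x
        for i in range(len(self.W) - 1):
            h = np.maximum(h @ self.W[i] + self.b[i], 0.0)
            acts.append(h)
        z = h @ self.W[-1] + self.b[-1]
        z = z - z.max(axis=1, keepdims=True)
        e = np.exp(z)
        p = e / e.sum(axis=1, keepdims=True)
        acts.append(p)
        return p, acts

    def grad(
        self, acts: list[np.ndarray], targets: np.ndarray, weights: np.ndarray, scale: float
    ) -> tuple[list[np.ndarray], list[np.ndarray]]:
        """Gradients of scale * dyn_weight_MSE w.r.t. parameters."""
        p = acts[-1]
        n = targets.shape[0]
        # dL/dp_ik = scale * w_i * (p - y) / n ; then through softmax
        g = scale * weights[:, None] * (p - targets) / n
        dz = p * (g - np.sum(g * p, axis=1, keepdims=True))
        dW = [np.zeros_like(w) for w in self.W]
        db = [np.zeros_like(b) for b in self.b]
        delta = dz
        for i in range(len(self.W) - 1, -1, -1):
            dW[i] = acts[i].T @ delta
            db[i] = delta.sum(axis=0)
            if i > 0:
                delta = (delta @ self.W[i].T) * (acts[i] > 0.0)
        return dW, db

    def apply(self, dW: list[np.ndarray], db: list[np.ndarray]) -> None:
        lr = self.cfg.learning_rate
        for i in range(len(self.W)):
            self.W[i] -= lr * dW[i]
            self.b[i] -= lr * db[i]


@dataclass
class TrainedModel:
    """A trained classifier plus its config and per-epoch loss history."""

    net: _MLP
    cfg: NetConfig
    history: list[dict] = field(default_factory=list)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """(n, 2) rows of (P(survive), P(death)); each row sums to 1."""
        x = np.asarray(x, dtype=float)
        if x.ndim == 1:
            x = x[None, :]
        if x.shape[1] != self.cfg.input_dim:
            raise ValueError(
                f"feature dimension {x.shape[1]} != model input {self.cfg.input_dim}"
            )
        p, _ = self.net.forward(x)
        return p

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Argmax class labels; exact 0.5/0.5 ties go to survival (0)."""
        p = self.predict_proba(x)
        return (p[:, 1] > p[:, 0]).astype(int)

    def save(self, path: str | Path) -> None:
        payload = {
            "cfg": {
                "input_dim": self.cfg.input_dim,
                "hidden": list(self.cfg.hidden),
                "output_dim": self.cfg.output_dim,
                "learning_rate": self.cfg.learning_rate,
                "batch_size": self.cfg.batch_size,
                "epochs": self.cfg.epochs,
                "seed": self.cfg.seed,
            },
            "W": [w.tolist() for w in self.net.W],
            "b": [b.tolist() for b in self.net.b],
            "history": self.history,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        d = json.loads(Path(path).read_text())
        cfg = NetConfig(
            input_dim=d["cfg"]["input_dim"],
            hidden=tuple(d["cfg"]["hidden"]),
            output_dim=d["cfg"]["output_dim"],
            learning_rate=d["cfg"]["learning_rate"],
            batch_size=d["cfg"]["batch_size"],
            epochs=d["cfg"]["epochs"],
            seed=d["cfg"]["seed"],
        )
        net = _MLP(cfg, np.random.default_rng(0))
        net.W = [np.array(w) for w in d["W"]]
        net.b = [np.array(b) for b in d["b"]]
        return cls(net=net, cfg=cfg, history=d["history"])


# ---------------------------------------------------------------------------
# Training steps
# ---------------------------------------------------------------------------


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start : start + batch_size]


def train_initial(
    features: np.ndarray, labels: np.ndarray, cfg: NetConfig | None = None
) -> TrainedModel:
    """Step (i): supervised training on the balanced labeled set.

    Uses the per-batch class-weighted MSE only (no pseudo term).  The input
    is expected to be under-sampled to ~1:1; single-class input is an
    error.
    """
    cfg = cfg or NetConfig()
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    rng = np.random.default_rng(cfg.seed)
    net = _MLP(cfg, rng)
    targets = one_hot_targets(y)
    history = []
    for epoch in range(1, cfg.epochs + 1):
        total, count = 0.0, 0
        for idx in _batches(len(y), cfg.batch_size, rng):
            w = per_sample_weights(y[idx])
            p, acts = net.forward(x[idx])
            dW, db = net.grad(acts, targets[idx], w, scale=1.0)
            net.apply(dW, db)
            total += dyn_weight_mse(targets[idx], p, w)
            count += 1
        history.append({"epoch": epoch, "loss": total / count})
    return TrainedModel(net=net, cfg=cfg, history=history)


def pseudo_label(
    model: TrainedModel, censored_features: np.ndarray, record_ids: np.ndarray | None = None
) -> PseudoLabelSet:
    """Step (ii): label every censored record by predicted-class argmax."""
    x = np.asarray(censored_features, dtype=float)
    labels = model.predict(x)
    if record_ids is None:
        record_ids = np.arange(len(labels))
    return PseudoLabelSet(record_ids=np.asarray(record_ids), labels=labels)


def train_cost_sensitive(
    labeled_features: np.ndarray,
    labeled_labels: np.ndarray,
    pseudo_features: np.ndarray,
    pseudo_set: PseudoLabelSet,
    cfg: NetConfig | None = None,
    loss_cfg: LossConfig | None = None,
    rebalance: bool = True,
) -> TrainedModel:
    """Step (iii): cost-sensitive retraining with the combined loss.

    Each epoch pairs one true-label batch with one pseudo-label batch; the
    pseudo gradient is scaled by alpha(epoch).  The labeled portion is
    re-under-sampled to 1:1 (same policy as step (i)) unless
    ``rebalance=False``.  The per-epoch history records the supervised and
    pseudo loss terms separately.
    """
    from .data_model import undersample_majority

    cfg = cfg or NetConfig()
    loss_cfg = loss_cfg or LossConfig()
    xl = np.asarray(labeled_features, dtype=float)
    yl = np.asarray(labeled_labels, dtype=int)
    xp = np.asarray(pseudo_features, dtype=float)
    yp = np.asarray(pseudo_set.labels, dtype=int)
    if len(xp) != len(yp):
        raise ValueError("pseudo features/labels length mismatch")

    rng = np.random.default_rng(cfg.seed)
    if rebalance:
        keep = undersample_majority(yl, seed=int(rng.integers(2**31)))
        xl, yl = xl[keep], yl[keep]
    if len(np.unique(yl)) < 2:
        raise ValueError("labeled data must contain both classes")

    net = _MLP(cfg, rng)
    tl = one_hot_targets(yl)
    tp = one_hot_targets(yp)
    nt, np_ = len(yl), len(yp)
    bs = cfg.batch_size
    history = []
    for epoch in range(1, cfg.epochs + 1):
        a = delay_coefficient(epoch, loss_cfg)
        true_batches = list(_batches(nt, bs, rng))
        pseudo_batches = list(_batches(np_, bs, rng)) if np_ else []
        n_steps = max(len(true_batches), len(pseudo_batches))
        sup_total, pseudo_total = 0.0, 0.0
        for s in range(n_steps):
            ti = true_batches[s % len(true_batches)]
            w_t = per_sample_weights(yl[ti])
            p_t, acts_t = net.forward(xl[ti])
            dW, db = net.grad(acts_t, tl[ti], w_t, scale=1.0)
            sup_total += dyn_weight_mse(tl[ti], p_t, w_t)
            if pseudo_batches and a > 0.0:
                pi = pseudo_batches[s % len(pseudo_batches)]
                w_p = per_sample_weights(yp[pi])
                p_p, acts_p = net.forward(xp[pi])
                dW2, db2 = net.grad(acts_p, tp[pi], w_p, scale=a)
                for i in range(len(dW)):
                    dW[i] += dW2[i]
                    db[i] += db2[i]
                pseudo_total += a * dyn_weight_mse(tp[pi], p_p, w_p)
            net.apply(dW, db)
        history.append(
            {
                "epoch": epoch,
                "alpha": a,
                "supervised_loss": sup_total / n_steps,
                "pseudo_loss": pseudo_total / n_steps,
                "loss": (sup_total + pseudo_total) / n_steps,
            }
        )
    return TrainedModel(net=net, cfg=cfg, history=history)
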