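"""Sparse-coding classifier head: unrolled ISTA layer + linear softmax.

High-dimensional scattering vectors overfit small expression corpora, so the
network head first re-encodes each (standardized) feature vector as a sparse
code over a learnable dictionary D via T unrolled iterations of the
iterative soft-thresholding algorithm (ISTA),

    z_{t+1} = soft(z_t + eta * D^T (x - D z_t), eta * lambda),   z_0 = 0,
    soft(v, a) = sign(v) * max(|v| - a, 0),

i.e. exact proximal-gradient steps on the lasso objective
0.5 ||x - D z||^2 + lambda ||z||_1 (the threshold is the step size times the
penalty, so the unrolled layer converges to that objective's minimizer),

with step size eta = 1 / sigma_max(D)^2 (recomputed each update by warm-
started power iteration) and a learnable threshold lambda. The code feeds a
fully-connected softmax layer trained with cross-entropy under mini-batch
momentum SGD (or Adam). Gradients through the unrolled iterations are exact
reverse-mode derivations; eta is treated as a constant of the forward pass.

Everything is plain numpy; training is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TrainConfig",
    "SparseLayerConfig",
    "SparseNet",
    "sparse_layer_forward",
    "lasso_objective",
    "soft_threshold",
    "nn_train",
]


@dataclass
class TrainConfig:
    optimizer: str = "momentum_sgd"  # or "adam"
    learning_rate: float = 0.001
    batch_size: int = 32
    weight_decay: float = 0.001
    epochs: int = 60
    momentum: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size < 1 or self.epochs < 0:
            raise ValueError("invalid training configuration")
        if self.optimizer not in ("momentum_sgd", "adam"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


@dataclass
class SparseLayerConfig:
    dictionary_size: int = 64
    iterations: int = 3
    threshold: float = 0.1  # initial lambda; learnable

    def __post_init__(self) -> None:
        if self.dictionary_size < 1 or self.iterations < 1 or self.threshold < 0:
            raise ValueError("invalid sparse layer configuration")


def soft_threshold(v: np.ndarray, lam: float) -> np.ndarray:
    return np.sign(v) * np.maximum(np.abs(v) - lam, 0.0)


def spectral_norm_sq(D: np.ndarray, u: np.ndarray | None = None, iters: int = 10):
    """Largest squared singular value of D by power iteration on D^T D.

    Returns (sigma_max^2, u) where u is the right singular vector estimate,
    reusable as a warm start.
    """
    m = D.shape[1]
    if u is None:
        u = np.full(m, 1.0 / np.sqrt(m))
    for _ in range(iters):
        w = D.T @ (D @ u)
        n = np.linalg.norm(w)
        if n == 0:
            return 0.0, u
        u = w / n
    return float(u @ (D.T @ (D @ u))), u


def sparse_layer_forward(
    x: np.ndarray,
    dictionary: np.ndarray,
    lam: float,
    iterations: int,
    step: float | None = None,
    return_trace: bool = False,
):
    """Unrolled ISTA encoding of ``x`` (vector or batch of rows).

    ``step=None`` uses 1/sigma_max(D)^2. With ``return_trace`` the list of
    iterates [z_0 ... z_T] is returned alongside the final code.
    """
    D = np.asarray(dictionary, dtype=float)
    single = np.asarray(x).ndim == 1
    X = np.atleast_2d(np.asarray(x, dtype=float))
    if step is None:
        s2, _ = spectral_norm_sq(D, iters=50)
        step = 1.0 / s2
    Z = np.zeros((X.shape[0], D.shape[1]))
    trace = [Z.copy()]
    for _ in range(iterations):
        R = X - Z @ D.T
        V = Z + step * (R @ D)
        Z = soft_threshold(V, step * lam)
        if return_trace:
            trace.append(Z.copy())
    Z_out = Z[0] if single else Z
    if return_trace:
        return Z_out, [t[0] if single else t for t in trace]
    return Z_out


def lasso_objective(x: np.ndarray, D: np.ndarray, z: np.ndarray, lam: float) -> float:
    r = x - D @ z
    return float(0.5 * r @ r + lam * np.abs(z).sum())


class SparseNet:
    """Unrolled-ISTA encoder + linear softmax classifier."""

    def __init__(self, n_features: int, n_classes: int, cfg: SparseLayerConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        m = cfg.dictionary_size
        D = rng.standard_normal((n_features, m))
        D /= np.linalg.norm(D, axis=0, keepdims=True)
        self.D = D
        self.lam = float(cfg.threshold)
        self.T = cfg.iterations
        self.W = 0.01 * rng.standard_normal((m, n_classes))
        self.b = np.zeros(n_classes)
        self._power_u: np.ndarray | None = None
        self.n_classes = n_classes

    # ---- forward / backward -------------------------------------------------

    def _step_size(self, refine: int = 3) -> float:
        iters = 30 if self._power_u is None else refine
        s2, self._power_u = spectral_norm_sq(self.D, self._power_u, iters=iters)
        return 1.0 / s2

    def encode(self, X: np.ndarray, keep_cache: bool = False):
        eta = self._step_size()
        Z = np.zeros((X.shape[0], self.D.shape[1]))
        cache = []
        for _ in range(self.T):
            R = X - Z @ self.D.T
            V = Z + eta * (R @ self.D)
            if keep_cache:
                cache.append((Z, R, V))
            Z = soft_threshold(V, eta * self.lam)
        return (Z, eta, cache) if keep_cache else Z

    def logits(self, X: np.ndarray) -> np.ndarray:
        return self.encode(X) @ self.W + self.b

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.argmax(self.logits(X), axis=1)

    def loss_and_grads(self, X: np.ndarray, y: np.ndarray):
        """Cross-entropy loss and exact gradients w.r.t. D, lambda, W, b."""
        B = X.shape[0]
        Z, eta, cache = self.encode(X, keep_cache=True)
        logits = Z @ self.W + self.b
        logits -= logits.max(axis=1, keepdims=True)
        expl = np.exp(logits)
        P = expl / expl.sum(axis=1, keepdims=True)
        loss = -np.mean(np.log(P[np.arange(B), y] + 1e-300))
        dlogits = P.copy()
        dlogits[np.arange(B), y] -= 1.0
        dlogits /= B
        gW = Z.T @ dlogits
        gb = dlogits.sum(axis=0)
        dZ = dlogits @ self.W.T
        gD = np.zeros_like(self.D)
        glam = 0.0
        # reverse through the unrolled iterations
        for Z_prev, R, V in reversed(cache):
            mask = (np.abs(V) > eta * self.lam).astype(float)
            dV = dZ * mask
            glam += -eta * np.sum(np.sign(V) * dV)
            dZ_prev = dV.copy()
            dR = eta * (dV @ self.D.T)
            gD += eta * (R.T @ dV)
            dZ_prev += -(dR @ self.D)
            gD += -(dR.T @ Z_prev)
            dZ = dZ_prev
        return loss, {"D": gD, "lam": glam, "W": gW, "b": gb}

    # ---- parameter access for the optimizer --------------------------------

    def get_params(self) -> dict:
        return {"D": self.D, "lam": self.lam, "W": self.W, "b": self.b}

    def set_params(self, params: dict) -> None:
        self.D = params["D"]
        self.lam = max(0.0, float(params["lam"]))
        self.W = params["W"]
        self.b = params["b"]
        self._power_u = None

    def copy_params(self) -> dict:
        return {"D": self.D.copy(), "lam": self.lam, "W": self.W.copy(), "b": self.b.copy()}


def _make_optimizer(cfg: TrainConfig):
    if cfg.optimizer == "momentum_sgd":
        state: dict = {}

        def update(name, value, grad):
            v = state.get(name, 0.0)
            v = cfg.momentum * v - cfg.learning_rate * grad
            state[name] = v
            return value + v

    else:  # adam
        state = {"t": 0}
        b1, b2, eps = 0.9, 0.999, 1e-8

        def update(name, value, grad):
            m = state.get(("m", name), 0.0)
            v = state.get(("v", name), 0.0)
            m = b1 * m + (1 - b1) * grad
            v = b2 * v + (1 - b2) * np.square(grad)
            state[("m", name)] = m
            state[("v", name)] = v
            t = state["t"]
            mhat = m / (1 - b1**t)
            vhat = v / (1 - b2**t)
            return value - cfg.learning_rate * mhat / (np.sqrt(vhat) + eps)

    def step(params: dict, grads: dict, decay_names=("D", "W")):
        if cfg.optimizer == "adam":
            state["t"] += 1
        out = {}
        for name, value in params.items():
            g = grads[name]
            if name in decay_names and cfg.weight_decay > 0:
                g = g + cfg.weight_decay * value
            out[name] = update(name, value, g)
        return out

    return step


@dataclass
class TrainHistory:
    loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_val_accuracy: float = float("nan")


def nn_train(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    n_classes: int,
    cfg: TrainConfig | None = None,
    sparse_cfg: SparseLayerConfig | None = None,
) -> tuple[SparseNet, TrainHistory]:
    """Train the sparse-coding head; the returned model carries the
    parameters of the epoch with the best validation accuracy, with lower
    validation cross-entropy as the tie-break (validation accuracy
    saturates quickly on small separable splits, and among saturated
    epochs the lower-loss one has better margins).

    Raises on divergence (NaN loss), naming the epoch.
    """
    cfg = cfg or TrainConfig()
    sparse_cfg = sparse_cfg or SparseLayerConfig()
    y_train = np.asarray(y_train, dtype=int)
    y_val = np.asarray(y_val, dtype=int)
    model = SparseNet(X_train.shape[1], n_classes, sparse_cfg, seed=cfg.seed)
    opt = _make_optimizer(cfg)
    rng = np.random.default_rng(cfg.seed + 1)
    hist = TrainHistory()
    best = model.copy_params()
    best_acc = -1.0
    best_vloss = np.inf
    if cfg.epochs == 0:
        hist.best_epoch = -1
        hist.best_val_accuracy = float(np.mean(model.predict(X_val) == y_val)) if len(y_val) else float("nan")
        return model, hist
    n = len(X_train)
    for epoch in range(cfg.epochs):
        perm = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, cfg.batch_size):
            idx = perm[start : start + cfg.batch_size]
            loss, grads = model.loss_and_grads(X_train[idx], y_train[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(f"training diverged (non-finite loss) at epoch {epoch}")
            model.set_params(opt(model.get_params(), grads))
            epoch_loss += loss
            n_batches += 1
        train_acc = float(np.mean(model.predict(X_train) == y_train))
        if len(y_val):
            val_acc = float(np.mean(model.predict(X_val) == y_val))
            val_loss, _ = model.loss_and_grads(X_val, y_val)
        else:
            val_acc, val_loss = train_acc, epoch_loss / max(n_batches, 1)
        hist.loss.append(epoch_loss / max(n_batches, 1))
        hist.train_accuracy.append(train_acc)
        hist.val_accuracy.append(val_acc)
        hist.val_loss.append(float(val_loss))
        if val_acc > best_acc or (val_acc == best_acc and val_loss < best_vloss):
            best_acc = val_acc
            best_vloss = val_loss
            best = model.copy_params()
            hist.best_epoch = epoch
    model.set_params(best)
    hist.best_val_accuracy = best_acc
    return model, hist
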