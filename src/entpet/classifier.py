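"""Shared-encoder, permutation-structured 5-class network.

Each of a sample's four candidate rows passes through an identical
fully-connected ReLU encoder (widths 512, 256); the four latent vectors are
concatenated and fused by one further hidden layer (width 128) feeding a
5-way softmax head (classes 0-3: index of the true candidate row; class 4:
false LOR).  Training uses Adam, class-weighted focal loss, a
reduce-on-plateau learning-rate schedule, early stopping on validation
loss, and best-checkpoint restoration.  The implementation is plain NumPy
in float32, single-device and fully deterministic under its seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "ModelSpec",
    "TrainSpec",
    "FoldSplit",
    "SharedEncoderModel",
    "build_model",
    "focal_loss",
    "make_folds",
    "train_fold",
    "predict",
    "class_weights_from_labels",
]

N_CLASSES = 5
N_ROWS = 4


@dataclass(frozen=True)
class ModelSpec:
    encoder_widths: tuple[int, ...] = (512, 256)
    fusion_widths: tuple[int, ...] = (128,)
    n_classes: int = N_CLASSES


@dataclass(frozen=True)
class TrainSpec:
    batch_size: int = 128
    learning_rate: float = 1e-3
    max_epochs: int = 200
    early_stopping_patience: int = 10
    scheduler_factor: float = 0.5
    scheduler_patience: int = 3
    min_learning_rate: float = 1e-6
    focal_gamma: float = 2.0
    seed: int = 0


@dataclass(frozen=True)
class FoldSplit:
    fold: int
    train_idx: np.ndarray
    val_idx: np.ndarray


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

class SharedEncoderModel:
    """Weights and forward pass; float32 throughout."""

    def __init__(self, spec: ModelSpec, n_features: int, rng_seed: int = 0):
        self.spec = spec
        self.n_features = n_features
        rng = np.random.default_rng(rng_seed)
        self.params: dict[str, np.ndarray] = {}
        dims_enc = [n_features, *spec.encoder_widths]
        for i in range(len(dims_enc) - 1):
            self._init_layer(rng, f"enc{i}", dims_enc[i], dims_enc[i + 1])
        fused_in = spec.encoder_widths[-1] * N_ROWS
        dims_fus = [fused_in, *spec.fusion_widths, spec.n_classes]
        for i in range(len(dims_fus) - 1):
            self._init_layer(rng, f"fus{i}", dims_fus[i], dims_fus[i + 1])

    def _init_layer(self, rng, name, d_in, d_out):
        w = rng.standard_normal((d_in, d_out)) * np.sqrt(2.0 / d_in)
        self.params[f"{name}_W"] = w.astype(np.float32)
        self.params[f"{name}_b"] = np.zeros(d_out, dtype=np.float32)

    @property
    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    def encode_rows(self, rows: np.ndarray) -> np.ndarray:
        """Apply the shared encoder to (m, n_features) rows."""
        h = rows.astype(np.float32)
        for i in range(len(self.spec.encoder_widths)):
            h = np.maximum(h @ self.params[f"enc{i}_W"] + self.params[f"enc{i}_b"], 0.0)
        return h

    def forward(self, X: np.ndarray, cache: bool = False):
        """Softmax probabilities for (n, 4, d) inputs."""
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 3 or X.shape[1] != N_ROWS or X.shape[2] != self.n_features:
            raise ValueError(
                f"expected input of shape (n, {N_ROWS}, {self.n_features}), got {X.shape}")
        n = X.shape[0]
        acts = [X.reshape(n * N_ROWS, self.n_features)]
        h = acts[0]
        for i in range(len(self.spec.encoder_widths)):
            h = np.maximum(h @ self.params[f"enc{i}_W"] + self.params[f"enc{i}_b"], 0.0)
            acts.append(h)
        fused = h.reshape(n, -1)
        facts = [fused]
        h = fused
        n_fus = len(self.spec.fusion_widths) + 1
        for i in range(n_fus):
            z = h @ self.params[f"fus{i}_W"] + self.params[f"fus{i}_b"]
            h = z if i == n_fus - 1 else np.maximum(z, 0.0)
            facts.append(h)
        logits = facts[-1]
        logits = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        probs = e / e.sum(axis=1, keepdims=True)
        if cache:
            return probs, (acts, facts)
        return probs

    def copy_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def load_params(self, params: dict[str, np.ndarray]) -> None:
        self.params = {k: v.copy() for k, v in params.items()}

    def save(self, path) -> None:
        np.savez(path, **self.params,
                 _n_features=self.n_features,
                 _encoder=np.array(self.spec.encoder_widths),
                 _fusion=np.array(self.spec.fusion_widths),
                 _n_classes=self.spec.n_classes)

    @classmethod
    def load(cls, path) -> "SharedEncoderModel":
        with np.load(path) as z:
            spec = ModelSpec(encoder_widths=tuple(int(x) for x in z["_encoder"]),
                             fusion_widths=tuple(int(x) for x in z["_fusion"]),
                             n_classes=int(z["_n_classes"]))
            model = cls(spec, int(z["_n_features"]))
            model.params = {k: z[k] for k in z.files if not k.startswith("_")}
        return model


def build_model(spec: ModelSpec, n_features_per_row: int,
                rng_seed: int = 0) -> SharedEncoderModel:
    if n_features_per_row < 1:
        raise ValueError("n_features_per_row must be >= 1")
    return SharedEncoderModel(spec, n_features_per_row, rng_seed)


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

_EPS = 1e-12


def focal_loss(probabilities, labels, class_weights=None, gamma: float = 2.0):
    """Mean class-weighted focal loss: -alpha_y (1 - p_y)^gamma log p_y."""
    p = np.asarray(probabilities, dtype=float)
    if p.ndim == 1:
        p = p[None, :]
    y = np.atleast_1d(np.asarray(labels, dtype=int))
    py = np.clip(p[np.arange(len(y)), y], _EPS, 1.0)
    alpha = np.ones(p.shape[1]) if class_weights is None else np.asarray(class_weights, dtype=float)
    loss = -alpha[y] * (1.0 - py) ** gamma * np.log(py)
    return float(loss.mean())


def _focal_grad_logits(probs, y, alpha, gamma):
    """d(mean focal loss)/d(logits) for softmax probabilities."""
    n = probs.shape[0]
    py = np.clip(probs[np.arange(n), y], _EPS, 1.0)
    one_minus = 1.0 - py
    # dL/dp_y
    dldp = alpha[y] * (gamma * one_minus ** (gamma - 1.0) * np.log(py)
                       - one_minus ** gamma / py)
    # dp_y/dz_j = p_y (delta_jy - p_j)
    grad = probs * (-py * dldp)[:, None]
    grad[np.arange(n), y] += py * dldp
    return (grad / n).astype(np.float32)


def class_weights_from_labels(labels, n_classes: int = N_CLASSES) -> np.ndarray:
    """Inverse-frequency class weights, normalized to mean 1."""
    counts = np.bincount(np.asarray(labels, dtype=int), minlength=n_classes).astype(float)
    counts[counts == 0] = 1.0
    w = 1.0 / counts
    return w / w.mean()


# ---------------------------------------------------------------------------
# folds
# ---------------------------------------------------------------------------

def make_folds(labels, k: int = 5, rng_seed: int = 0) -> list[FoldSplit]:
    """Stratified k-fold splits, deterministic under the seed."""
    y = np.asarray(labels, dtype=int)
    if y.size < k:
        raise ValueError("dataset smaller than the number of folds")
    counts = np.bincount(y)
    if np.any((counts > 0) & (counts < k)):
        import warnings

        warnings.warn("a class has fewer members than folds; stratification degraded",
                      stacklevel=2)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=rng_seed)
    return [FoldSplit(fold=i, train_idx=tr, val_idx=va)
            for i, (tr, va) in enumerate(skf.split(np.zeros_like(y), y))]


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    learning_rate: list[float] = field(default_factory=list)
    best_epoch: int = -1
    stopped_epoch: int = -1


class _Adam:
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr = lr
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] -= (self.lr * (self.m[k] / b1t)
                          / (np.sqrt(self.v[k] / b2t) + self.eps)).astype(np.float32)


def _backward(model: SharedEncoderModel, X, y, alpha, gamma):
    """Forward + gradients of the mean focal loss w.r.t. all parameters."""
    probs, (acts, facts) = model.forward(X, cache=True)
    n = X.shape[0]
    grads: dict[str, np.ndarray] = {}
    g = _focal_grad_logits(probs, y, alpha, gamma)

    n_fus = len(model.spec.fusion_widths) + 1
    for i in range(n_fus - 1, -1, -1):
        a_in = facts[i]
        grads[f"fus{i}_W"] = a_in.T @ g
        grads[f"fus{i}_b"] = g.sum(axis=0)
        if i > 0:
            g = (g @ model.params[f"fus{i}_W"].T) * (facts[i] > 0)
        else:
            g = g @ model.params[f"fus{i}_W"].T
    g = g.reshape(n * N_ROWS, -1) * (acts[-1] > 0)
    n_enc = len(model.spec.encoder_widths)
    for i in range(n_enc - 1, -1, -1):
        grads[f"enc{i}_W"] = acts[i].T @ g
        grads[f"enc{i}_b"] = g.sum(axis=0)
        if i > 0:
            g = (g @ model.params[f"enc{i}_W"].T) * (acts[i] > 0)
    loss = focal_loss(probs, y, alpha, gamma)
    return loss, grads


def train_fold(model: SharedEncoderModel, X_train, y_train, X_val, y_val,
               train_spec: TrainSpec | None = None, class_weights=None):
    """Train one fold; returns ``(model_at_best_checkpoint, history)``.

    Inputs must already be scaled with a scaler fit on the training fold
    only.  Validation loss drives both the reduce-on-plateau schedule and
    early stopping; the returned model carries the best-validation
    checkpoint weights.
    """
    spec = train_spec or TrainSpec()
    rng = np.random.default_rng(spec.seed)
    X_train = np.asarray(X_train, dtype=np.float32)
    X_val = np.asarray(X_val, dtype=np.float32)
    y_train = np.asarray(y_train, dtype=int)
    y_val = np.asarray(y_val, dtype=int)
    alpha = (np.ones(model.spec.n_classes) if class_weights is None
             else np.asarray(class_weights, dtype=float))

    opt = _Adam(model.params, spec.learning_rate)
    hist = TrainHistory()
    best_val = np.inf
    best_params = model.copy_params()
    since_best = 0
    since_sched = 0

    for epoch in range(spec.max_epochs):
        order = rng.permutation(len(X_train))
        ep_loss = 0.0
        for start in range(0, len(order), spec.batch_size):
            idx = order[start:start + spec.batch_size]
            loss, grads = _backward(model, X_train[idx], y_train[idx],
                                    alpha, spec.focal_gamma)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}")
            opt.step(model.params, grads)
            ep_loss += loss * len(idx)
        ep_loss /= len(order)

        val_probs = predict(model, X_val)
        val_loss = focal_loss(val_probs, y_val, alpha, spec.focal_gamma)
        hist.train_loss.append(ep_loss)
        hist.val_loss.append(val_loss)
        hist.learning_rate.append(opt.lr)

        if val_loss < best_val - 1e-9:
            best_val = val_loss
            best_params = model.copy_params()
            hist.best_epoch = epoch
            since_best = 0
            since_sched = 0
        else:
            since_best += 1
            since_sched += 1
            if since_sched > spec.scheduler_patience:
                opt.lr = max(opt.lr * spec.scheduler_factor, spec.min_learning_rate)
                since_sched = 0
            if since_best >= spec.early_stopping_patience:
                hist.stopped_epoch = epoch
                break
    else:
        hist.stopped_epoch = spec.max_epochs - 1

    model.load_params(best_params)
    return model, hist


def predict(model: SharedEncoderModel, X, batch_size: int = 4096) -> np.ndarray:
    """Class probabilities for (n, 4, d) scaled inputs."""
    X = np.asarray(X, dtype=np.float32)
    if X.ndim == 2:
        X = X[None, :, :]
    out = np.empty((X.shape[0], model.spec.n_classes), dtype=np.float32)
    for s in range(0, X.shape[0], batch_size):
        out[s:s + batch_size] = model.forward(X[s:s + batch_size])
    return out
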