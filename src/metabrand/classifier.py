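"""LSTM sequence classifier over per-slice feature sequences.

The network consumes the ordered 80 x 2048 feature sequence of a scan
and emits two class probabilities (control, aMCI):

    LSTM (final hidden state, dropout 0.5)
      -> Dense (sigmoid, 512 units)
      -> Dropout (0.5)
      -> Dense (softmax, 2 units)

The recurrence accumulates information across slices, exploiting the
anatomical dependence between neighboring slices.  aMCI is the positive
class throughout (sensitivity = true-positive rate on aMCI); prediction
ties break toward aMCI, matching the screening use case.

The implementation is plain NumPy: seeded Glorot initialization,
truncated-nothing backpropagation through all 80 timesteps, inverted
dropout, the Adam optimizer, and optional early stopping on validation
loss.  With a fixed seed and a fixed BLAS, training is reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .cohort import BinnedMetadata, Scheme, VARIABLE_ORDER, category_orders
from .features import FEATURE_DIM, SEQUENCE_LENGTH, FeatureSequence

__all__ = [
    "ClassifierConfig",
    "LstmClassifier",
    "TrainingHistory",
    "build_classifier",
    "encode_clinical",
    "clinical_embedding",
    "wide_deep_fuse",
    "fit",
    "predict_proba",
    "predict_label",
    "CLINICAL_DIM",
]

CLINICAL_DIM = 15  # one-hot blocks of sizes 4 + 2 + 3 + 4 + 2
_GRAD_CLIP_NORM = 5.0


@dataclass(frozen=True)
class ClassifierConfig:
    """Architecture and training settings.

    Architecture defaults follow the published layer stack; the training
    loop settings (optimizer steps, epochs, batch size) are explicit
    here because they are tunable.
    """

    recurrent_units: int = 2048
    recurrent_dropout_rate: float = 0.5
    dense_units: int = 512
    dense_activation: str = "sigmoid"
    post_dense_dropout: float = 0.5
    output_units: int = 2
    output_activation: str = "softmax"
    input_dim: int = FEATURE_DIM
    timesteps: int = SEQUENCE_LENGTH
    epochs: int = 50
    batch_size: int = 8
    learning_rate: float = 1e-4
    early_stopping_patience: int = 10
    #: sd of Gaussian jitter added to (standardized) training inputs;
    #: regularizes against memorizing low-margin coordinates
    input_noise_sd: float = 0.0
    #: fraction of final epochs whose parameters are averaged into the
    #: returned model (stochastic weight averaging; 0 disables).
    #: Stabilizes the epoch-to-epoch oscillation of small-batch training.
    average_tail: float = 0.0
    #: scale each standardized feature by its between-participant
    #: reliability, Var(participant means) / total variance (computed on
    #: the training set, unsupervised).  Emphasizes participant-stable
    #: coordinates over per-slice noise for participant-level labels.
    reliability_weighting: bool = False
    #: L1 shrinkage applied to the input weight matrix after each Adam
    #: step (proximal soft-threshold).  Encourages the recurrent layer
    #: to read few input coordinates, discouraging memorization through
    #: idiosyncratic feature combinations.
    l1_input: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("recurrent_units", "dense_units", "output_units",
                     "input_dim", "timesteps", "epochs", "batch_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("recurrent_dropout_rate", "post_dense_dropout"):
            if not 0.0 <= getattr(self, name) < 1.0:
                raise ValueError(f"{name} must be in [0, 1)")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))


def _softmax(x: np.ndarray) -> np.ndarray:
    z = x - x.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


@dataclass
class TrainingHistory:
    epoch: list[int] = field(default_factory=list)
    loss: list[float] = field(default_factory=list)
    acc: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)

    def to_csv(self, path: str | Path) -> Path:
        import csv

        path = Path(path)
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["epoch", "loss", "acc", "val_loss", "val_acc"])
            for i, ep in enumerate(self.epoch):
                w.writerow([
                    ep, self.loss[i], self.acc[i],
                    self.val_loss[i] if self.val_loss else "",
                    self.val_acc[i] if self.val_acc else "",
                ])
        return path


class LstmClassifier:
    """The 4-layer recurrent classifier, parameters in NumPy arrays."""

    #: label encoding: index 0 = Control, index 1 = aMCI (positive class)
    CLASSES = ("Control", "aMCI")

    def __init__(self, config: ClassifierConfig):
        self.config = config
        H, D = config.recurrent_units, config.input_dim
        rng = np.random.default_rng(config.seed)
        # gate order along the 4H axis: input, forget, cell, output
        self.Wx = _glorot(rng, D, H, (D, 4 * H))
        self.Wh = _glorot(rng, H, H, (H, 4 * H))
        self.b = np.zeros(4 * H, dtype=np.float32)
        self.b[H:2 * H] = 1.0  # forget-gate bias
        self.W1 = _glorot(rng, H, config.dense_units, (H, config.dense_units))
        self.b1 = np.zeros(config.dense_units, dtype=np.float32)
        self.W2 = _glorot(rng, config.dense_units, config.output_units,
                          (config.dense_units, config.output_units))
        self.b2 = np.zeros(config.output_units, dtype=np.float32)
        # per-feature standardization, learned from the training set
        self.norm_mean = np.zeros(config.input_dim, dtype=np.float32)
        self.norm_std = np.ones(config.input_dim, dtype=np.float32)
        self.history = TrainingHistory()
        self.trained = False

    # -- parameter plumbing -------------------------------------------------
    _PARAM_NAMES = ("Wx", "Wh", "b", "W1", "b1", "W2", "b2")

    def parameters(self) -> dict[str, np.ndarray]:
        return {name: getattr(self, name) for name in self._PARAM_NAMES}

    # -- forward ------------------------------------------------------------
    def _recur(self, X: np.ndarray, keep_cache: bool = False):
        """Run the LSTM over X (N, T, D); return final hidden state."""
        N, T, D = X.shape
        H = self.config.recurrent_units
        pre = X.reshape(N * T, D) @ self.Wx
        pre = pre.reshape(N, T, 4 * H)
        h = np.zeros((N, H), dtype=np.float32)
        c = np.zeros((N, H), dtype=np.float32)
        cache = [] if keep_cache else None
        for t in range(T):
            g = pre[:, t] + h @ self.Wh + self.b
            i = _sigmoid(g[:, :H])
            f = _sigmoid(g[:, H:2 * H])
            cc = np.tanh(g[:, 2 * H:3 * H])
            o = _sigmoid(g[:, 3 * H:])
            c_prev = c
            c = f * c_prev + i * cc
            tc = np.tanh(c)
            h_prev = h
            h = o * tc
            if keep_cache:
                cache.append((i, f, cc, o, c_prev, tc, h_prev))
        return h, cache

    def _head(self, h: np.ndarray, mask1=None, mask2=None):
        """Dense-sigmoid -> dropout -> dense-softmax on hidden state h."""
        if mask1 is not None:
            h = h * mask1
        a1 = _sigmoid(h @ self.W1 + self.b1)
        a1d = a1 * mask2 if mask2 is not None else a1
        logits = a1d @ self.W2 + self.b2
        return _softmax(logits), a1, a1d, h

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        return (X - self.norm_mean) / self.norm_std

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Class probabilities, shape (N, 2): columns (Control, aMCI)."""
        X = self._standardize(_as_batch(X, self.config))
        h, _ = self._recur(X)
        probs, *_ = self._head(h)
        return probs

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predicted labels; ties go to aMCI (the positive class)."""
        probs = self.predict_proba(X)
        idx = (probs[:, 1] >= probs[:, 0]).astype(int)
        return np.array([self.CLASSES[i] for i in idx])

    # -- training -----------------------------------------------------------
    def _loss_grads(self, X, y_onehot, rng):
        """Cross-entropy loss and gradients for one minibatch."""
        cfg = self.config
        N, T, _ = X.shape
        H = cfg.recurrent_units
        h_final, cache = self._recur(X, keep_cache=True)

        keep1 = 1.0 - cfg.recurrent_dropout_rate
        keep2 = 1.0 - cfg.post_dense_dropout
        mask1 = (rng.random((N, H)) < keep1).astype(np.float32) / keep1 if keep1 < 1 else None
        mask2 = (
            (rng.random((N, cfg.dense_units)) < keep2).astype(np.float32) / keep2
            if keep2 < 1 else None
        )
        probs, a1, a1d, h_drop = self._head(h_final, mask1, mask2)

        eps = 1e-12
        loss = float(-(y_onehot * np.log(probs + eps)).sum() / N)

        dlogits = (probs - y_onehot) / N                       # (N, 2)
        gW2 = a1d.T @ dlogits
        gb2 = dlogits.sum(axis=0)
        da1 = dlogits @ self.W2.T
        if mask2 is not None:
            da1 = da1 * mask2
        dz1 = da1 * a1 * (1.0 - a1)
        gW1 = h_drop.T @ dz1
        gb1 = dz1.sum(axis=0)
        dh = dz1 @ self.W1.T
        if mask1 is not None:
            dh = dh * mask1

        # backprop through time
        gWx = np.zeros_like(self.Wx)
        gWh = np.zeros_like(self.Wh)
        gb = np.zeros_like(self.b)
        dc = np.zeros((N, H), dtype=np.float32)
        dpre = np.empty((N, T, 4 * H), dtype=np.float32)
        for t in range(T - 1, -1, -1):
            i, f, cc, o, c_prev, tc, h_prev = cache[t]
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc * tc)
            di = dc * cc
            df = dc * c_prev
            dcc = dc * i
            dg = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dcc * (1.0 - cc * cc),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            dpre[:, t] = dg
            gWh += h_prev.T @ dg
            gb += dg.sum(axis=0)
            dh = dg @ self.Wh.T
            dc = dc * f
        gWx = X.reshape(N * T, -1).T @ dpre.reshape(N * T, 4 * H)

        grads = {"Wx": gWx, "Wh": gWh, "b": gb, "W1": gW1, "b1": gb1,
                 "W2": gW2, "b2": gb2}
        norm = np.sqrt(sum(float((g * g).sum()) for g in grads.values()))
        if norm > _GRAD_CLIP_NORM:
            scale = _GRAD_CLIP_NORM / norm
            grads = {k: g * scale for k, g in grads.items()}
        return loss, grads

    def evaluate(self, X, y_index) -> tuple[float, float]:
        """Mean cross-entropy and accuracy on (X, integer labels)."""
        probs = self.predict_proba(X)
        eps = 1e-12
        loss = float(-np.log(probs[np.arange(len(y_index)), y_index] + eps).mean())
        acc = float(((probs[:, 1] >= probs[:, 0]).astype(int) == y_index).mean())
        return loss, acc

    # -- persistence --------------------------------------------------------
    def save(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "config.json").write_text(json.dumps(asdict(self.config)))
        np.savez(
            directory / "parameters.npz",
            norm_mean=self.norm_mean, norm_std=self.norm_std,
            **self.parameters(),
        )
        self.history.to_csv(directory / "history.csv")
        return directory

    @classmethod
    def load(cls, directory: str | Path) -> "LstmClassifier":
        directory = Path(directory)
        config = ClassifierConfig(**json.loads((directory / "config.json").read_text()))
        model = cls(config)
        with np.load(directory / "parameters.npz") as data:
            for name in cls._PARAM_NAMES + ("norm_mean", "norm_std"):
                setattr(model, name, data[name].astype(np.float32))
        model.trained = True
        return model


def build_classifier(config: ClassifierConfig | None = None) -> LstmClassifier:
    """An untrained, seed-initialized classifier."""
    return LstmClassifier(config or ClassifierConfig())


def _as_batch(X, config: ClassifierConfig) -> np.ndarray:
    if isinstance(X, FeatureSequence):
        X = X.matrix
    X = np.asarray(X, dtype=np.float32)
    if X.ndim == 2:
        X = X[None]
    if X.ndim != 3 or X.shape[1] != config.timesteps or X.shape[2] != config.input_dim:
        raise ValueError(
            f"expected sequences of shape ({config.timesteps}, {config.input_dim}), "
            f"got {X.shape}"
        )
    return X


def _encode_labels(labels) -> np.ndarray:
    out = []
    for lab in labels:
        if lab in ("aMCI", 1):
            out.append(1)
        elif lab in ("Control", 0):
            out.append(0)
        else:
            raise ValueError(f"unknown class label {lab!r}")
    return np.array(out, dtype=int)


def fit(
    classifier: LstmClassifier,
    sequences,
    labels,
    validation: tuple | None = None,
) -> LstmClassifier:
    """Train by seeded mini-batch Adam on cross-entropy.

    ``sequences`` is an (N, 80, 2048) array (or list of
    :class:`FeatureSequence`); ``labels`` the matching class labels.
    Both classes must be present with at least two examples each.  When
    ``validation=(X_val, y_val)`` is given, training stops early once
    validation loss has not improved for ``early_stopping_patience``
    epochs and the best-validation-loss parameters are restored.
    """
    cfg = classifier.config
    if isinstance(sequences, (list, tuple)):
        sequences = np.stack(
            [s.matrix if isinstance(s, FeatureSequence) else np.asarray(s)
             for s in sequences]
        )
    X = _as_batch(sequences, cfg)
    y = _encode_labels(labels)
    if len(X) != len(y):
        raise ValueError(f"{len(X)} sequences but {len(y)} labels")
    if len(X) == 0:
        raise ValueError("empty training set")
    counts = np.bincount(y, minlength=2)
    if (counts < 2).any():
        raise ValueError(
            f"need >= 2 examples per class, got Control={counts[0]}, aMCI={counts[1]}"
        )
    y_onehot = np.eye(2, dtype=np.float32)[y]

    # per-feature standardization over the training set (stored on the
    # model and re-applied at prediction time)
    mean = X.mean(axis=(0, 1))
    std = X.std(axis=(0, 1))
    std[std < 1e-6] = 1.0
    if cfg.reliability_weighting:
        participant_means = X.mean(axis=1)              # (N, D)
        between = participant_means.var(axis=0)
        within = X.var(axis=1).mean(axis=0)
        weight = between / (between + within + 1e-12)
        std = std / np.maximum(weight, 1e-3)
    classifier.norm_mean = mean.astype(np.float32)
    classifier.norm_std = std.astype(np.float32)
    Xs = classifier._standardize(X)

    val = None
    if validation is not None:
        Xv = _as_batch(validation[0], cfg)
        yv = _encode_labels(validation[1])
        val = (Xv, yv)

    rng = np.random.default_rng(cfg.seed + 1)
    adam_m = {k: np.zeros_like(v) for k, v in classifier.parameters().items()}
    adam_v = {k: np.zeros_like(v) for k, v in classifier.parameters().items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0

    best_val, best_params, patience_left = np.inf, None, cfg.early_stopping_patience
    swa_start = (
        cfg.epochs - max(1, int(round(cfg.average_tail * cfg.epochs))) + 1
        if cfg.average_tail > 0 else None
    )
    swa_sum: dict[str, np.ndarray] | None = None
    swa_count = 0
    hist = classifier.history
    n = len(X)
    for epoch in range(1, cfg.epochs + 1):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            batch = Xs[idx]
            if cfg.input_noise_sd > 0:
                batch = batch + cfg.input_noise_sd * rng.standard_normal(
                    batch.shape
                ).astype(np.float32)
            loss, grads = classifier._loss_grads(batch, y_onehot[idx], rng)
            step += 1
            lr_t = cfg.learning_rate * np.sqrt(1 - beta2 ** step) / (1 - beta1 ** step)
            for k, g in grads.items():
                adam_m[k] = beta1 * adam_m[k] + (1 - beta1) * g
                adam_v[k] = beta2 * adam_v[k] + (1 - beta2) * g * g
                param = getattr(classifier, k)
                param -= (lr_t * adam_m[k] / (np.sqrt(adam_v[k]) + eps)).astype(np.float32)
            if cfg.l1_input > 0:
                thresh = np.float32(lr_t * cfg.l1_input)
                Wx = classifier.Wx
                classifier.Wx = (
                    np.sign(Wx) * np.maximum(np.abs(Wx) - thresh, 0.0)
                ).astype(np.float32)
        if swa_start is not None and epoch >= swa_start:
            params = classifier.parameters()
            if swa_sum is None:
                swa_sum = {k: v.astype(np.float64).copy() for k, v in params.items()}
            else:
                for k, v in params.items():
                    swa_sum[k] += v
            swa_count += 1
        train_loss, train_acc = classifier.evaluate(X, y)
        hist.epoch.append(epoch)
        hist.loss.append(train_loss)
        hist.acc.append(train_acc)
        if val is not None:
            val_loss, val_acc = classifier.evaluate(*val)
            hist.val_loss.append(val_loss)
            hist.val_acc.append(val_acc)
            if val_loss < best_val - 1e-6:
                best_val = val_loss
                best_params = {k: v.copy() for k, v in classifier.parameters().items()}
                patience_left = cfg.early_stopping_patience
            else:
                patience_left -= 1
                if patience_left <= 0:
                    break
    if best_params is not None:
        for k, v in best_params.items():
            setattr(classifier, k, v)
    elif swa_sum is not None and swa_count > 0:
        for k, v in swa_sum.items():
            setattr(classifier, k, (v / swa_count).astype(np.float32))
    classifier.trained = True
    return classifier


def predict_proba(model: LstmClassifier, seq) -> np.ndarray:
    """(p_control, p_aMCI) for one sequence, or (N, 2) for a batch."""
    single = isinstance(seq, FeatureSequence) or np.asarray(
        seq, dtype=np.float32
    ).ndim == 2
    probs = model.predict_proba(seq)
    return probs[0] if single else probs


def predict_label(model: LstmClassifier, seq) -> str | np.ndarray:
    labels = model.predict(seq)
    single = isinstance(seq, FeatureSequence) or np.asarray(
        seq, dtype=np.float32
    ).ndim == 2
    return labels[0] if single else labels


# -- clinical covariate vector and wide-and-deep fusion ----------------------

def encode_clinical(
    meta: BinnedMetadata, scheme: Scheme | str = Scheme.HNR
) -> np.ndarray:
    """One-hot encode the five binned covariates (length 15).

    Blocks follow the fixed variable order (age, gender, education,
    marital status, APOE-ε4) with sizes 4, 2, 3, 4, 2; exactly one entry
    per block is 1.
    """
    orders = category_orders(scheme)
    values = meta.as_dict()
    vec = np.zeros(CLINICAL_DIM, dtype=np.float32)
    offset = 0
    for var in VARIABLE_ORDER:
        cats = orders[var]
        try:
            vec[offset + cats.index(values[var])] = 1.0
        except ValueError:
            raise ValueError(
                f"{var} value {values[var]!r} not among categories {cats}"
            ) from None
        offset += len(cats)
    return vec


def clinical_embedding(
    clinical: np.ndarray, projection_seed: int = 0
) -> np.ndarray:
    """Map the 15-dim clinical vector to 2048 dims by a seeded linear map.

    The projection matrix is a fixed function of ``projection_seed``;
    rows are scaled so the embedding has roughly unit variance when
    exactly five entries of the input are 1.
    """
    clinical = np.asarray(clinical, dtype=np.float32).ravel()
    if clinical.shape != (CLINICAL_DIM,):
        raise ValueError(f"clinical vector must have length {CLINICAL_DIM}")
    rng = np.random.default_rng(projection_seed)
    W = rng.standard_normal((CLINICAL_DIM, FEATURE_DIM)).astype(np.float32)
    return (clinical @ W) / np.float32(np.sqrt(5.0))


def wide_deep_fuse(
    seq: FeatureSequence | np.ndarray,
    clinical: np.ndarray,
    projection_seed: int = 0,
    embedding: np.ndarray | None = None,
) -> FeatureSequence:
    """Multiplicative fusion of visual features with clinical covariates.

    The clinical one-hot vector is embedded into the 2048-dim feature
    space by a fixed seeded linear map and each timestep's feature row
    is multiplied elementwise by that embedding (a dot-product-style
    cross of the wide and deep inputs).  Passing ``embedding`` directly
    bypasses the projection (e.g. an all-ones embedding is the identity).
    """
    matrix = seq.matrix if isinstance(seq, FeatureSequence) else np.asarray(seq, np.float32)
    pid = seq.participant_id if isinstance(seq, FeatureSequence) else ""
    if matrix.shape != (SEQUENCE_LENGTH, FEATURE_DIM):
        raise ValueError(
            f"sequence must be ({SEQUENCE_LENGTH}, {FEATURE_DIM}), got {matrix.shape}"
        )
    if embedding is None:
        embedding = clinical_embedding(clinical, projection_seed)
    embedding = np.asarray(embedding, dtype=np.float32).ravel()
    if embedding.shape != (FEATURE_DIM,):
        raise ValueError(f"embedding must have length {FEATURE_DIM}")
    return FeatureSequence(
        matrix=matrix * embedding[None, :],
        participant_id=pid,
        input_mode="widedeep",
    )
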