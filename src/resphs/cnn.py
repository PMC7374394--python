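"""Parameterized 1D CNN classifier and the recognition-rate objective.

The network mirrors the architecture family being searched over: a stack of
``cld`` convolutional blocks — each a valid (no-padding, stride-1)
convolution with ``kc^d`` kernels of size ``1 x ks^d`` followed by ReLU and
width-2 max-pooling — then a flatten and two ReLU dense layers of widths
``dlnc^1`` and ``dlnc^2``, and a softmax output over the five pattern
classes.  Max-pooling is skipped automatically in a block whose feature
length is too short to pool.

Everything (forward pass, backpropagation, minibatch stochastic gradient
descent) is implemented directly on numpy arrays, which keeps the package
dependency-light and fully deterministic under a seeded generator.  Training
stops at the epoch budget or as soon as the mean training loss drops below a
configurable satisfaction threshold.

The module's product is :func:`make_objective`: a closure that maps a
hyperparameter vector to a validation recognition rate in percent, the
objective the search engine maximizes.  Architectures that cannot be built
for the input length, or whose training diverges, score 0 so the optimizer
simply discards them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .space import HPVector
from .signals import RespirationDataset

__all__ = [
    "ShapeError",
    "TrainingConfig",
    "EvaluationResult",
    "Conv1DNet",
    "build_model",
    "train_model",
    "evaluate_model",
    "make_objective",
]

logger = logging.getLogger(__name__)

N_CLASSES = 5


class ShapeError(ValueError):
    """A layer's feature map would collapse below one sample."""


@dataclass(frozen=True)
class TrainingConfig:
    """Training settings for one architecture evaluation.

    ``loss_threshold`` is the loss-satisfaction criterion: training stops
    early once the epoch-mean cross-entropy falls below it.  ``normalize``
    z-scores each piece before training; it defaults off because signal
    amplitude is itself class-discriminative (apnea is defined by a >90 %
    amplitude reduction), so per-piece standardization discards signal.
    """

    learning_rate: float = 0.1
    epochs: int = 25
    batch_size: int = 30
    loss_threshold: float = 1e-3
    pool_width: int = 2
    normalize: bool = False

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass(frozen=True)
class EvaluationResult:
    """Recognition rate (percent) and the 5x5 confusion matrix (rows =
    true class, columns = predicted class)."""

    rate: float
    confusion: np.ndarray


@dataclass
class TrainResult:
    loss_curve: np.ndarray
    diverged: bool = False


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


class Conv1DNet:
    """A concrete network for one hyperparameter vector.

    The layer plan (and hence the parameter count) is a pure function of the
    hyperparameters, input length and class count; weights exist only after
    :meth:`initialize`.
    """

    def __init__(
        self,
        hp: HPVector,
        input_length: int,
        n_classes: int = N_CLASSES,
        pool_width: int = 2,
    ):
        if input_length < 1:
            raise ShapeError("input_length must be >= 1")
        self.hp = hp
        self.input_length = int(input_length)
        self.n_classes = int(n_classes)
        self.pool_width = int(pool_width)
        # Per-block plan: (kernel_size, kernel_count, in_channels, pooled)
        self.blocks: list[tuple[int, int, int, bool]] = []
        length = self.input_length
        channels = 1
        for d, (ks, kc) in enumerate(zip(hp.ks, hp.kc), start=1):
            out_len = length - ks + 1
            if out_len < 1:
                raise ShapeError(
                    f"conv block {d}: kernel size {ks} exceeds feature length {length}"
                )
            pooled = self.pool_width > 1 and out_len >= self.pool_width
            self.blocks.append((ks, kc, channels, pooled))
            length = out_len // self.pool_width if pooled else out_len
            channels = kc
        self.flat_dim = channels * length
        self.dense_dims = [self.flat_dim, hp.dlnc[0], hp.dlnc[1], self.n_classes]
        self.params: Optional[dict[str, np.ndarray]] = None

    @property
    def n_parameters(self) -> int:
        n = 0
        for ks, kc, cin, _ in self.blocks:
            n += kc * cin * ks + kc
        for din, dout in zip(self.dense_dims[:-1], self.dense_dims[1:]):
            n += din * dout + dout
        return n

    def initialize(self, rng: np.random.Generator) -> None:
        """He-initialize all weights; biases start at zero."""
        params: dict[str, np.ndarray] = {}
        for i, (ks, kc, cin, _) in enumerate(self.blocks):
            fan_in = cin * ks
            params[f"Wc{i}"] = rng.normal(0.0, np.sqrt(2.0 / fan_in), (kc, cin, ks))
            params[f"bc{i}"] = np.zeros(kc)
        for i, (din, dout) in enumerate(zip(self.dense_dims[:-1], self.dense_dims[1:])):
            params[f"Wd{i}"] = rng.normal(0.0, np.sqrt(2.0 / din), (din, dout))
            params[f"bd{i}"] = np.zeros(dout)
        self.params = params

    # -- forward / backward -------------------------------------------------

    def _forward(self, X: np.ndarray, store: bool):
        """Return logits for ``X`` of shape (n, length); optionally keep the
        intermediates needed for backpropagation."""
        assert self.params is not None, "initialize() first"
        cache: list[dict] = []
        a = X[:, None, :]  # (n, channels=1, length)
        for i, (ks, kc, cin, pooled) in enumerate(self.blocks):
            W, b = self.params[f"Wc{i}"], self.params[f"bc{i}"]
            windows = sliding_window_view(a, ks, axis=2)  # (n, cin, L_out, ks)
            z = np.einsum("kcs,ncls->nkl", W, windows, optimize=True) + b[None, :, None]
            h = _relu(z)
            if pooled:
                L = h.shape[2] - h.shape[2] % self.pool_width
                hp_ = h[:, :, :L].reshape(h.shape[0], kc, L // self.pool_width, self.pool_width)
                arg = np.argmax(hp_, axis=3)
                out = np.take_along_axis(hp_, arg[..., None], axis=3)[..., 0]
            else:
                out, arg = h, None
            if store:
                cache.append({"a_in": a, "windows": windows, "z": z, "h": h, "arg": arg})
            a = out
        flat = a.reshape(a.shape[0], -1)
        acts = [flat]
        for i in range(3):
            W, b = self.params[f"Wd{i}"], self.params[f"bd{i}"]
            z = acts[-1] @ W + b
            acts.append(_relu(z) if i < 2 else z)
        if store:
            return acts[-1], cache, acts, a.shape
        return acts[-1]

    def logits(self, X: np.ndarray) -> np.ndarray:
        return self._forward(X, store=False)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.argmax(self.logits(X), axis=1)

    def _backward(self, dlogits, cache, acts, conv_out_shape) -> dict[str, np.ndarray]:
        grads: dict[str, np.ndarray] = {}
        g = dlogits
        for i in (2, 1, 0):
            a_in = acts[i]
            grads[f"Wd{i}"] = a_in.T @ g
            grads[f"bd{i}"] = g.sum(axis=0)
            g = g @ self.params[f"Wd{i}"].T
            if i > 0:
                g = g * (acts[i] > 0)
        g = g.reshape(conv_out_shape)
        for i in range(len(self.blocks) - 1, -1, -1):
            ks, kc, cin, pooled = self.blocks[i]
            c = cache[i]
            h = c["h"]
            if pooled:
                L = h.shape[2] - h.shape[2] % self.pool_width
                dh = np.zeros_like(h)
                dh_blocks = dh[:, :, :L].reshape(h.shape[0], kc, L // self.pool_width, self.pool_width)
                np.put_along_axis(dh_blocks, c["arg"][..., None], g[..., None], axis=3)
                dh[:, :, :L] = dh_blocks.reshape(h.shape[0], kc, L)
            else:
                dh = g
            dz = dh * (c["z"] > 0)
            grads[f"Wc{i}"] = np.einsum("nkl,ncls->kcs", dz, c["windows"], optimize=True)
            grads[f"bc{i}"] = dz.sum(axis=(0, 2))
            if i > 0:
                W = self.params[f"Wc{i}"]
                a_in = c["a_in"]
                da = np.zeros_like(a_in)
                L_out = dz.shape[2]
                for s in range(ks):
                    da[:, :, s : s + L_out] += np.einsum(
                        "nkl,kc->ncl", dz, W[:, :, s], optimize=True
                    )
                g = da
        return grads

    def train_step(self, X: np.ndarray, y: np.ndarray, lr: float) -> float:
        """One SGD step on a minibatch; returns the mean cross-entropy."""
        logits, cache, acts, shape = self._forward(X, store=True)
        z = logits - logits.max(axis=1, keepdims=True)
        log_probs = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
        n = len(y)
        loss = -log_probs[np.arange(n), y].mean()
        probs = np.exp(log_probs)
        dlogits = probs
        dlogits[np.arange(n), y] -= 1.0
        dlogits /= n
        grads = self._backward(dlogits, cache, acts, shape)
        for key, g in grads.items():
            self.params[key] -= lr * g
        return float(loss)


def build_model(
    hp: HPVector, input_length: int, n_classes: int = N_CLASSES, pool_width: int = 2
) -> Conv1DNet:
    """Construct the (uninitialized) network for a hyperparameter vector.

    Raises :class:`ShapeError`, naming the offending layer, if a convolution
    would shrink the feature map below one sample.
    """
    return Conv1DNet(hp, input_length, n_classes=n_classes, pool_width=pool_width)


def _normalize(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def train_model(
    model: Conv1DNet,
    X: np.ndarray,
    y: np.ndarray,
    config: TrainingConfig,
    rng: np.random.Generator,
) -> TrainResult:
    """Train with minibatch SGD until the epoch budget or the loss threshold.

    Returns the per-epoch mean training-loss curve.  A non-finite loss marks
    the run diverged and stops training immediately.
    """
    if len(X) == 0:
        raise ValueError("training split is empty")
    if config.normalize:
        X = _normalize(X)
    if model.params is None:
        model.initialize(rng)
    losses: list[float] = []
    n = len(X)
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            loss = model.train_step(X[idx], y[idx], config.learning_rate)
            if not np.isfinite(loss):
                logger.warning("training diverged (non-finite loss)")
                losses.append(loss)
                return TrainResult(loss_curve=np.array(losses), diverged=True)
            epoch_losses.append(loss)
        losses.append(float(np.mean(epoch_losses)))
        if losses[-1] < config.loss_threshold:
            break
    return TrainResult(loss_curve=np.array(losses))


def evaluate_model(
    model: Conv1DNet, X: np.ndarray, y: np.ndarray, normalize: bool = True
) -> EvaluationResult:
    """Recognition rate and confusion matrix on a held-out split.

    The rate is ``100 x correct / total`` and equals the confusion-matrix
    trace over its total by construction.
    """
    if len(X) == 0:
        raise ValueError("evaluation split is empty")
    y = np.asarray(y)
    if np.any((y < 0) | (y >= model.n_classes)):
        raise ValueError(f"labels outside the {model.n_classes} known classes")
    if normalize:
        X = _normalize(X)
    pred = model.predict(X)
    confusion = np.zeros((model.n_classes, model.n_classes), dtype=int)
    np.add.at(confusion, (y, pred), 1)
    rate = 100.0 * np.trace(confusion) / confusion.sum()
    return EvaluationResult(rate=float(rate), confusion=confusion)


def make_objective(
    dataset: RespirationDataset,
    config: TrainingConfig,
    rng: np.random.Generator,
    *,
    resplit_per_call: bool = False,
    val_fraction: float = 0.2,
) -> Callable[[HPVector], float]:
    """Build the recognition-rate objective from a split dataset.

    Each call builds the architecture, trains it on the training split and
    returns the validation recognition rate in percent.  With
    ``resplit_per_call`` the learning pool (train + validation) is
    re-partitioned at the given fraction on every call, emulating a fresh
    random split per evaluation; the test set never moves.  Build or
    training failures return 0.0 with a logged warning, keeping the
    objective total over the valid space.
    """
    if dataset.splits is None:
        raise ValueError("dataset has no split assignment; call split_dataset first")
    input_length = dataset.pieces[0].samples.shape[0]
    pool = np.concatenate([dataset.splits.train, dataset.splits.val])

    def current_split() -> tuple[np.ndarray, np.ndarray]:
        if not resplit_per_call:
            return dataset.splits.train, dataset.splits.val
        n_val = max(1, round(len(pool) * val_fraction))
        perm = rng.permutation(len(pool))
        return pool[perm[n_val:]], pool[perm[:n_val]]

    def objective(hp: HPVector) -> float:
        train_idx, val_idx = current_split()
        try:
            model = build_model(hp, input_length, pool_width=config.pool_width)
            result = train_model(
                model, dataset.signals(train_idx), dataset.labels(train_idx), config, rng
            )
            if result.diverged:
                logger.warning("objective: training diverged for %s; scoring 0", hp.as_tuple())
                return 0.0
            ev = evaluate_model(
                model, dataset.signals(val_idx), dataset.labels(val_idx),
                normalize=config.normalize,
            )
        except ShapeError as err:
            logger.warning("objective: unbuildable architecture %s (%s); scoring 0",
                           hp.as_tuple(), err)
            return 0.0
        return ev.rate

    return objective
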