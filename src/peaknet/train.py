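"""Minibatch training with RMSprop updates and early stopping.

The optimizer follows the classic RMSprop recipe: a per-parameter
exponential moving average of squared gradients normalizes each step.
Training monitors validation loss; when it fails to improve for
``patience`` consecutive epochs (default 12) the loop stops and the
parameters from the best-validation epoch are restored.

``TrainConfig.monitor`` selects the early-stopping criterion: held-out
accuracy ("auc", the default — stop when the validation mean AUC ceases
to increase) or validation loss ("loss").  With binary cross entropy a
model can keep improving its ranking while its calibration on held-out
data degrades, so the loss criterion can stop long before accuracy
peaks; accuracy is what the training procedure is meant to maximize.

Transfer learning for a new single-target data set is supported by
seeding a fresh network with a pretrained model's weights (all stages
below the final layer copied verbatim, final layer re-initialized) and
making exactly one pass through the new data at half the learning rate;
additional passes overfit small single-target tasks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .metrics import auc
from .nn import ArchitectureSpec, Network

logger = logging.getLogger(__name__)


class TrainingDivergedError(RuntimeError):
    pass


@dataclass
class TrainConfig:
    batch_size: int = 128
    learning_rate: float = 0.002
    rmsprop_decay: float = 0.98
    rmsprop_epsilon: float = 1e-8
    patience: int = 12
    max_epochs: int = 100
    monitor: str = "auc"
    seed: int = 0

    def __post_init__(self):
        if self.monitor not in ("auc", "loss"):
            raise ValueError("monitor must be 'auc' or 'loss'")
        if min(self.batch_size, self.patience, self.max_epochs) < 1:
            raise ValueError("batch_size, patience and max_epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0 < self.rmsprop_decay < 1:
            raise ValueError("rmsprop_decay must lie in (0, 1)")
        if self.patience > self.max_epochs:
            raise ValueError("patience cannot exceed max_epochs")


@dataclass
class TrainHistory:
    train_loss: list = field(default_factory=list)
    valid_loss: list = field(default_factory=list)
    valid_auc: list = field(default_factory=list)
    best_epoch: int = -1

    @property
    def n_epochs(self):
        return len(self.train_loss)


class RMSprop:
    """cache <- decay*cache + (1-decay)*g^2;  p <- p - lr*g/(sqrt(cache)+eps)."""

    def __init__(self, params, learning_rate, decay=0.98, epsilon=1e-8):
        self.params = params
        self.lr = learning_rate
        self.decay = decay
        self.eps = epsilon
        self.caches = [np.zeros_like(p, dtype=np.float64) for p in params]

    def step(self, grads):
        for p, g, c in zip(self.params, grads, self.caches):
            c *= self.decay
            c += (1.0 - self.decay) * np.square(g, dtype=np.float64)
            p -= (self.lr * g / (np.sqrt(c) + self.eps)).astype(p.dtype)


def _epoch_pass(network, optimizer, X, Y, order, batch_size):
    """One shuffled pass; returns mean per-sequence loss and update count."""
    total, n_updates = 0.0, 0
    for lo in range(0, len(order), batch_size):
        idx = order[lo : lo + batch_size]
        loss, grads = network.loss_and_grads(X[idx], Y[idx])
        if not np.isfinite(loss):
            raise TrainingDivergedError(
                "non-finite training loss; try a smaller learning rate"
            )
        optimizer.step(grads)
        total += loss * len(idx)
        n_updates += 1
    return total / len(order), n_updates


def _mean_valid_auc(network, X, Y, idx):
    preds = network.predict(X[idx])
    labels = np.asarray(Y)[idx]
    vals = []
    for t in range(labels.shape[1]):
        col = labels[:, t]
        if 0 < col.sum() < len(col):
            vals.append(auc(col, preds[:, t]))
    return float(np.mean(vals)) if vals else np.nan


def train(network, X, Y, train_idx, valid_idx, config=None, verbose=False):
    """Fit ``network`` in place; returns the :class:`TrainHistory`.

    Validation loss is evaluated after every epoch in eval mode; the
    parameters (and batch-norm running moments) of the best epoch are
    checkpointed and restored before returning.
    """
    config = config or TrainConfig()
    train_idx = np.asarray(train_idx)
    valid_idx = np.asarray(valid_idx)
    if np.intersect1d(train_idx, valid_idx).size:
        raise ValueError("train and validation sets must be disjoint")

    rng = np.random.default_rng(config.seed)
    optimizer = RMSprop(
        network.parameters(),
        config.learning_rate,
        decay=config.rmsprop_decay,
        epsilon=config.rmsprop_epsilon,
    )
    history = TrainHistory()
    best_crit, best_state, stale = np.inf, None, 0
    for epoch in range(config.max_epochs):
        order = rng.permutation(train_idx)
        tloss, _ = _epoch_pass(network, optimizer, X, Y, order, config.batch_size)
        vloss = network.eval_loss(X[valid_idx], np.asarray(Y)[valid_idx])
        vauc = _mean_valid_auc(network, X, Y, valid_idx)
        history.train_loss.append(tloss)
        history.valid_loss.append(vloss)
        history.valid_auc.append(vauc)
        if verbose:
            logger.info(
                "epoch %d: train loss %.4f, valid loss %.4f, valid AUC %.4f",
                epoch, tloss, vloss, vauc,
            )
        crit = vloss if config.monitor == "loss" else -vauc
        if crit < best_crit:
            best_crit, best_state, stale = crit, network.get_state(), 0
            history.best_epoch = epoch
        else:
            stale += 1
            if stale >= config.patience:
                break
    if best_state is not None:
        network.set_state(best_state)
    return history


def transfer_seed(pretrained: Network, new_n_targets: int, seed: int = 0) -> Network:
    """Seed a model for ``new_n_targets`` from a pretrained multi-task model.

    Every stage below the final layer is copied verbatim (weights, batch
    norm scale/shift and running moments); the final linear layer is
    re-initialized for the new target count.
    """
    old_spec = pretrained.spec
    spec = ArchitectureSpec(
        n_targets=new_n_targets,
        input_length=old_spec.input_length,
        conv_layers=old_spec.conv_layers,
        fc_layers=old_spec.fc_layers,
        dropout_rates=old_spec.dropout_rates,
    )
    new = Network(spec, seed=seed, dtype=pretrained.dtype)
    state = pretrained.get_state()
    final_prefix = f"layer{len(new.layers) - 1:03d}/"
    keep = {k: v for k, v in state.items() if not k.startswith(final_prefix)}
    partial = new.get_state()
    partial.update(keep)
    new.set_state(partial)
    return new


def finetune_single_pass(network, X, Y, train_idx, config=None):
    """Exactly one epoch of RMSprop updates at half the learning rate.

    Returns the number of parameter updates performed,
    ``ceil(n_train / batch_size)``; zero-length data leaves the model
    untouched.
    """
    config = config or TrainConfig()
    train_idx = np.asarray(train_idx)
    if train_idx.size == 0:
        return 0
    optimizer = RMSprop(
        network.parameters(),
        config.learning_rate / 2.0,
        decay=config.rmsprop_decay,
        epsilon=config.rmsprop_epsilon,
    )
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(train_idx)
    _, n_updates = _epoch_pass(network, optimizer, X, Y, order, config.batch_size)
    return n_updates
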