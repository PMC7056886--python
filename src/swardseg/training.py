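"""Training loop and the partial categorical cross-entropy loss.

The loss averages -log p(true class) over labelled pixels only; pixels
carrying the IGNORE label (sample edges, other pastoral species, unlabelled
regions of partial images) contribute nothing, and their logits provably do
not affect the value or gradients.

A documented monitoring caveat: with edge-heavy synthetic data the test
loss routinely starts rising after a few tens of epochs while accuracy and
mIoU keep improving, because class-boundary pixels dominate the loss.  The
trainer therefore checkpoints on test mIoU, never on loss.
"""
from __future__ import annotations

import copy
import csv
import logging
import sys
from dataclasses import dataclass, field

import numpy as np

from . import evaluation, nn
from .lcnet import LCNet, preprocess
from .sig import Dataset
from .types import IGNORE, N_CLASSES

log = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    """Optimisation settings; the defaults are the full-scale protocol
    (400 epochs, batch 24, Adam at 5e-5).  Desk-scale runs override
    ``epochs``/``batch_size``/``learning_rate`` and may cap ``max_steps``.
    """

    epochs: int = 400
    batch_size: int = 24
    learning_rate: float = 5e-5
    optimiser: str = "adam"
    seed: int = 0
    max_steps: int | None = None
    eval_every: int = 1
    checkpoint_best: bool = True

    def validate(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.optimiser.lower() != "adam":
            raise ValueError(f"unsupported optimiser {self.optimiser!r}")


class EmptyBatchError(ValueError):
    """Raised when a batch contains no labelled (non-IGNORE) pixels."""


def partial_xent(
    logits: np.ndarray, labels: np.ndarray, return_grad: bool = False
) -> float | tuple[float, np.ndarray]:
    """Mean -log softmax probability of the true class over non-IGNORE pixels.

    ``logits``: (..., H, W, C) float; ``labels``: (..., H, W) ints in
    {0..C-1} plus IGNORE.  With ``return_grad`` the gradient with respect
    to the logits is returned too (exactly zero at IGNORE pixels).
    """
    labels = np.asarray(labels)
    if logits.shape[:-1] != labels.shape:
        raise ValueError("logits and labels spatial shapes disagree")
    c = logits.shape[-1]
    valid = labels != IGNORE
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise EmptyBatchError("batch has no labelled (non-IGNORE) pixels")
    if np.any((labels[valid] < 0) | (labels[valid] >= c)):
        raise ValueError("labels outside class range")

    lv = logits[valid]                       # (n_valid, C) — IGNORE logits never read
    z = lv - lv.max(axis=-1, keepdims=True)
    logsumexp = np.log(np.exp(z).sum(axis=-1))
    true = labels[valid]
    loss = float(np.mean(logsumexp - z[np.arange(n_valid), true]))
    if not return_grad:
        return loss
    p = np.exp(z)
    p /= p.sum(axis=-1, keepdims=True)
    p[np.arange(n_valid), true] -= 1.0
    grad = np.zeros_like(logits, dtype=nn.FLOAT)
    grad[valid] = p / n_valid
    return loss, grad


def initialise(network: LCNet, config: TrainConfig) -> LCNet:
    """Re-initialise all weights (Xavier) from the config seed.

    A pretrained backbone, when configured and available on disk, would be
    loaded here in place of the encoder's random weights; by default every
    layer is randomly initialised so no download is ever required.
    """
    fresh = LCNet(copy.deepcopy(network.config), seed=config.seed)
    network.load_state(fresh.state())
    return network


@dataclass
class History:
    epochs: list[int] = field(default_factory=list)
    loss_train: list[float] = field(default_factory=list)
    loss_test: list[float] = field(default_factory=list)
    macc_test: list[float] = field(default_factory=list)
    miou_test: list[float] = field(default_factory=list)

    def to_csv(self, path: str) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["epoch", "loss_train", "loss_test", "mAcc", "mIoU"])
            for row in zip(self.epochs, self.loss_train, self.loss_test,
                           self.macc_test, self.miou_test):
                w.writerow(row)


def _stack(dataset: Dataset) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([preprocess(im) for im in dataset.images])
    y = np.stack(dataset.labels).astype(np.int64)
    return x, y


def evaluate_dataset(network: LCNet, x: np.ndarray, y: np.ndarray,
                     batch_size: int, n_classes: int = N_CLASSES) -> tuple[float, float, float]:
    """(loss, mAcc, mIoU) of a network over a stacked dataset."""
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    losses, weights = [], []
    for i in range(0, len(x), batch_size):
        xb, yb = x[i : i + batch_size], y[i : i + batch_size]
        logits = network.forward_batch(xb, train=False)
        try:
            losses.append(partial_xent(logits, yb))
            weights.append(int(np.sum(yb != IGNORE)))
        except EmptyBatchError:
            pass
        pred = logits.argmax(axis=-1)
        cm += evaluation.confusion(pred, yb, n_classes=n_classes)
    loss = float(np.average(losses, weights=weights)) if losses else float("nan")
    rep = evaluation.metrics(cm, weighting="frequency")
    return loss, rep.mAcc, rep.mIoU


def train(
    network: LCNet,
    dataset: Dataset,
    config: TrainConfig,
    test_dataset: Dataset | None = None,
) -> tuple[LCNet, History]:
    """Run the optimisation loop; returns the network and its history.

    Batches with zero labelled pixels are skipped with a log message.  When
    a test dataset is given, the parameters achieving the best test mIoU
    are restored at the end (checkpoint-on-mIoU; see module docstring).
    """
    config.validate()
    if len(dataset) == 0:
        raise ValueError("empty training dataset")
    rng = np.random.default_rng(config.seed)
    x, y = _stack(dataset)
    xt = yt = None
    if test_dataset is not None and len(test_dataset) > 0:
        xt, yt = _stack(test_dataset)

    opt = nn.Adam(network.params(), lr=config.learning_rate)
    history = History()
    best_miou, best_state = -1.0, None
    step = 0
    done = False
    for epoch in range(config.epochs):
        order = rng.permutation(len(x))
        epoch_losses, epoch_weights = [], []
        for i in range(0, len(order), config.batch_size):
            idx = order[i : i + config.batch_size]
            logits = network.forward_batch(x[idx], train=True)
            try:
                loss, grad = partial_xent(logits, y[idx], return_grad=True)
            except EmptyBatchError:
                log.warning("skipping batch with no labelled pixels")
                continue
            opt.zero_grad()
            network.backward(grad)
            opt.step()
            epoch_losses.append(loss)
            epoch_weights.append(int(np.sum(y[idx] != IGNORE)))
            step += 1
            if config.max_steps is not None and step >= config.max_steps:
                done = True
                break
        train_loss = float(np.average(epoch_losses, weights=epoch_weights)) if epoch_losses else float("nan")
        if (epoch % config.eval_every == 0) or done or epoch == config.epochs - 1:
            if xt is not None:
                test_loss, macc, miou = evaluate_dataset(network, xt, yt, config.batch_size)
            else:
                test_loss, macc, miou = float("nan"), float("nan"), float("nan")
            history.epochs.append(epoch)
            history.loss_train.append(train_loss)
            history.loss_test.append(test_loss)
            history.macc_test.append(macc)
            history.miou_test.append(miou)
            log.info("epoch %d: loss %.4f test-loss %.4f mAcc %.4f mIoU %.4f",
                     epoch, train_loss, test_loss, macc, miou)
            if config.checkpoint_best and xt is not None and miou > best_miou:
                best_miou, best_state = miou, network.state()
        if done:
            break
    if best_state is not None:
        network.load_state(best_state)
    return network, history


def _configure_logging(logfile: str | None = None) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if logfile:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(level=logging.INFO, handlers=handlers, force=True)
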