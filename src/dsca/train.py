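"""Training loop with weighted BCE, Adam and best-checkpoint retention.

The dural sac covers well under 1% of an axial slice, so an unweighted
per-pixel cross-entropy is dominated by background.  Training therefore
uses a class-weighted binary cross-entropy with positive/negative weights
20.0 : 1.0, optimized with Adam.  After every epoch the validation loss is
evaluated and the parameter state with the lowest validation loss seen so
far is retained; reported accuracies come from that retained state.

Cross-validation repeats this once per fold of a patient-grouped
``FoldPlan`` and appends the arithmetic-mean row over folds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import _autograd as ag
from .io_prep import FoldPlan
from .nets import NetSpec, NetworkGraph, build_network, save_checkpoint

__all__ = [
    "TrainConfig",
    "FoldResult",
    "CrossValResult",
    "weighted_bce",
    "train_fold",
    "run_cross_validation",
    "pixel_accuracy",
]

logger = logging.getLogger(__name__)

_EPS = 1e-7  # probability clamp before the log


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 8
    epochs: int = 20
    w_pos: float = 20.0
    w_neg: float = 1.0
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.w_pos <= 0 or self.w_neg <= 0:
            raise ValueError("class weights must be positive")


@dataclass
class FoldResult:
    fold_index: int
    best_checkpoint: str | None
    training_accuracy: float
    validation_accuracy: float
    train_loss_trace: list[float] = field(default_factory=list)
    val_loss_trace: list[float] = field(default_factory=list)
    best_epoch: int = 0
    best_val_loss: float = float("inf")
    network: NetworkGraph | None = field(default=None, repr=False)


def weighted_bce(y: np.ndarray, p: np.ndarray,
                 w_pos: float = 20.0, w_neg: float = 1.0) -> float:
    """Mean class-weighted binary cross-entropy on probabilities.

    ``-mean(w_pos * y * log p + w_neg * (1-y) * log(1-p))`` with ``p``
    clamped to [1e-7, 1 - 1e-7] before the logarithm.
    """
    y = np.asarray(y, dtype=np.float64)
    p = np.asarray(p, dtype=np.float64)
    if y.shape != p.shape:
        raise ValueError("y and p must have identical shapes")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("y must be binary")
    p = np.clip(p, _EPS, 1.0 - _EPS)
    return float(-np.mean(w_pos * y * np.log(p) + w_neg * (1.0 - y) * np.log1p(-p)))


def pixel_accuracy(net: NetworkGraph, images: np.ndarray, masks: np.ndarray,
                   threshold: float = 0.5, batch_size: int = 8) -> float:
    """Fraction of pixels whose thresholded prediction matches the mask."""
    correct = 0
    total = 0
    for i in range(0, len(images), batch_size):
        p = net.predict_proba(images[i:i + batch_size])
        pred = p >= threshold
        correct += int(np.sum(pred == (masks[i:i + batch_size] > 0.5)))
        total += p.size
    return correct / total


def _stack(records):
    """Accept (SliceRecord, mask) pairs, (image, mask) pairs or two arrays."""
    images, masks = [], []
    for rec, mask in records:
        images.append(np.asarray(getattr(rec, "image", rec), dtype=np.float32))
        masks.append(np.asarray(mask, dtype=np.float32))
    return np.stack(images), np.stack(masks)


def _eval_loss(net: NetworkGraph, images, masks, config: TrainConfig) -> float:
    """Weighted-BCE validation loss, averaged over pixels of all slices."""
    total = 0.0
    n_pix = 0
    for i in range(0, len(images), config.batch_size):
        logits = net.forward_logits(images[i:i + config.batch_size])
        loss = ag.weighted_bce_with_logits(logits, masks[i:i + config.batch_size, :, :, None],
                                           config.w_pos, config.w_neg)
        total += float(loss.data) * logits.data.size
        n_pix += logits.data.size
    return total / n_pix


def train_fold(net_spec: NetSpec, train_records, val_records,
               config: TrainConfig, checkpoint_path=None,
               fold_index: int = 0) -> FoldResult:
    """Train one network on one train/validation split.

    Runs ``config.epochs`` epochs of seeded, shuffled mini-batches; after
    each epoch the validation loss is evaluated and the best parameter
    state retained.  Raises ``RuntimeError`` (with the epoch index) if the
    loss becomes non-finite.
    """
    x_tr, y_tr = _stack(train_records)
    x_va, y_va = _stack(val_records)
    if len(x_tr) == 0 or len(x_va) == 0:
        raise ValueError("empty training or validation shard")

    net = build_network(net_spec)
    opt = ag.Adam(net.parameters(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)

    best_state = None
    best_val = float("inf")
    best_epoch = 0
    train_trace: list[float] = []
    val_trace: list[float] = []

    for epoch in range(config.epochs):
        order = rng.permutation(len(x_tr))
        epoch_loss = 0.0
        n_batches = 0
        for i in range(0, len(order), config.batch_size):
            idx = order[i:i + config.batch_size]
            opt.zero_grad()
            logits = net.forward_logits(x_tr[idx])
            loss = ag.weighted_bce_with_logits(logits, y_tr[idx][:, :, :, None],
                                               config.w_pos, config.w_neg)
            if not np.isfinite(loss.data):
                raise RuntimeError(f"non-finite training loss at epoch {epoch}")
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data)
            n_batches += 1
        train_trace.append(epoch_loss / n_batches)

        val_loss = _eval_loss(net, x_va, y_va, config)
        if not np.isfinite(val_loss):
            raise RuntimeError(f"non-finite validation loss at epoch {epoch}")
        val_trace.append(val_loss)
        if val_loss < best_val:
            best_val = val_loss
            best_epoch = epoch
            best_state = [p.data.copy() for p in net.parameters()]
        logger.info("fold %d epoch %d: train loss %.5f, val loss %.5f",
                    fold_index, epoch, train_trace[-1], val_loss)

    for p, state in zip(net.parameters(), best_state):
        p.data = state

    ckpt = None
    if checkpoint_path is not None:
        ckpt = str(checkpoint_path)
        Path(ckpt).parent.mkdir(parents=True, exist_ok=True)
        save_checkpoint(net, ckpt)

    return FoldResult(
        fold_index=fold_index,
        best_checkpoint=ckpt,
        training_accuracy=pixel_accuracy(net, x_tr, y_tr, batch_size=config.batch_size),
        validation_accuracy=pixel_accuracy(net, x_va, y_va, batch_size=config.batch_size),
        train_loss_trace=train_trace,
        val_loss_trace=val_trace,
        best_epoch=best_epoch,
        best_val_loss=best_val,
        network=net,
    )


@dataclass
class CrossValResult:
    folds: list[FoldResult]
    table: pd.DataFrame   # per-fold accuracies plus an "Average" row

    @property
    def mean_training_accuracy(self) -> float:
        return float(np.mean([f.training_accuracy for f in self.folds]))

    @property
    def mean_validation_accuracy(self) -> float:
        return float(np.mean([f.validation_accuracy for f in self.folds]))


def fold_average(values) -> float:
    """Arithmetic mean over fold-level values (the table's Average row)."""
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        raise ValueError("no fold values to average")
    return float(values.mean())


def run_cross_validation(net_spec: NetSpec, records, fold_plan: FoldPlan,
                         config: TrainConfig, checkpoint_dir=None) -> CrossValResult:
    """Train once per fold of a patient-grouped plan and tabulate accuracies.

    ``records`` is a sequence of (SliceRecord, mask) pairs; each repetition
    trains on the patients outside the fold and validates (and selects the
    checkpoint) on the held-out fold.  The returned table carries one row
    per fold and an "Average" row of arithmetic means.
    """
    records = list(records)
    by_patient: dict[str, list] = {}
    for rec, mask in records:
        by_patient.setdefault(str(rec.patient_id), []).append((rec, mask))
    missing = set(by_patient) - set(fold_plan.assignment)
    if missing:
        raise ValueError(f"patients missing from fold plan: {sorted(missing)[:5]}")

    results: list[FoldResult] = []
    for fold in range(fold_plan.k):
        train_pat, val_pat = fold_plan.split(fold)
        train_recs = [pair for p in train_pat for pair in by_patient.get(p, [])]
        val_recs = [pair for p in val_pat for pair in by_patient.get(p, [])]
        ckpt = (Path(checkpoint_dir) / f"{net_spec.variant}_fold{fold}.npz"
                if checkpoint_dir is not None else None)
        try:
            fold_spec = NetSpec(variant=net_spec.variant, depth=net_spec.depth,
                                base_filters=net_spec.base_filters,
                                alpha=net_spec.alpha, seed=net_spec.seed + fold)
            results.append(train_fold(fold_spec, train_recs, val_recs, config,
                                      checkpoint_path=ckpt, fold_index=fold))
        except (RuntimeError, ValueError) as exc:
            raise RuntimeError(f"fold {fold} failed: {exc}") from exc

    rows = [{"fold": f.fold_index + 1,
             "training_accuracy": f.training_accuracy,
             "validation_accuracy": f.validation_accuracy} for f in results]
    rows.append({"fold": "Average",
                 "training_accuracy": fold_average(r["training_accuracy"] for r in rows),
                 "validation_accuracy": fold_average(r["validation_accuracy"] for r in rows)})
    return CrossValResult(folds=results, table=pd.DataFrame(rows))
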