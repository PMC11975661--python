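"""End-to-end desk-scale benchmark: phantoms -> training -> agreement.

This wires the full measurement chain together at a size a single CPU can
handle: 300 training and 60 held-out phantom slices at 96x96 pixels,
encoder depth 3 with 8 base filters, 8 epochs of weighted-BCE training
(weights 20:1) at batch size 8.  The held-out patients never contribute a
training batch; they double as the checkpoint-selection set, matching the
cross-validation protocol where the held-out fold is evaluated per epoch.

The benchmark reports, per architecture: pooled pixel metrics (accuracy,
precision, recall, F1), the per-slice area MAE, the Pearson correlation of
predicted vs true DSCA, and the Bland-Altman summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .agreement import (AgreementReport, MetricsReport, bland_altman,
                        classification_metrics, mae, pool_confusion)
from .io_prep import normalize_image, SliceRecord
from .nets import NetSpec, predict_mask, VARIANTS
from .phantom import PhantomConfig, generate_samples
from .quant import quantify_pair
from .train import TrainConfig, train_fold

__all__ = ["BenchmarkSettings", "VariantOutcome", "make_benchmark_data",
           "evaluate_network", "run_benchmark"]


@dataclass(frozen=True)
class BenchmarkSettings:
    """Problem sizes for the desk-scale benchmark."""

    train_slices: int = 300
    eval_slices: int = 60
    image_size: int = 96
    depth: int = 3
    base_filters: int = 16 // 2  # 8: desk-scale profile
    epochs: int = 8
    batch_size: int = 8
    w_pos: float = 20.0
    w_neg: float = 1.0


@dataclass
class VariantOutcome:
    """Everything measured for one trained architecture."""

    variant: str
    metrics: MetricsReport
    agreement: AgreementReport
    mae_mm2: float
    area_records: list = field(repr=False)
    fold_result: object = field(default=None, repr=False)
    network: object = field(default=None, repr=False)


def make_benchmark_data(seed: int, settings: BenchmarkSettings = BenchmarkSettings()):
    """Generate patient-grouped train and held-out phantom shards.

    Patients are generated in order; the first patients fill the training
    shard (truncated at ``train_slices``), subsequent patients fill the
    held-out shard, so no patient straddles the boundary.
    """
    lo, hi = 3, 8
    mean_slices = (lo + hi) / 2
    need = settings.train_slices + settings.eval_slices
    config = PhantomConfig(
        image_size=settings.image_size,
        n_patients=int(np.ceil(need / mean_slices * 1.5)) + 4,
        slices_per_patient=(lo, hi),
        seed=int(seed) & 0x7FFFFFFF,
    )
    train, heldout = [], []
    train_patients = set()
    for sample in generate_samples(config):
        record = SliceRecord(image=normalize_image(sample.image),
                             patient_id=sample.patient_id,
                             slice_id=sample.slice_id,
                             pixel_spacing_mm=sample.pixel_spacing_mm)
        pair = (record, sample.mask)
        if len(train) < settings.train_slices:
            train.append(pair)
            train_patients.add(sample.patient_id)
        elif sample.patient_id in train_patients:
            continue  # drop leftover slices of a train patient: no leakage
        elif len(heldout) < settings.eval_slices:
            heldout.append(pair)
        else:
            break
    if len(train) < settings.train_slices or len(heldout) < settings.eval_slices:
        raise RuntimeError("phantom cohort too small for requested shard sizes")
    return train, heldout


def evaluate_network(net, records, threshold: float = 0.5) -> VariantOutcome:
    """Predict, quantify and score one network on (SliceRecord, mask) pairs."""
    preds, truths, areas = [], [], []
    for record, mask in records:
        pred = predict_mask(net, record.image, threshold=threshold)
        preds.append(pred)
        truths.append(mask)
        areas.append(quantify_pair(pred, mask, record.pixel_spacing_mm,
                                   slice_id=record.slice_id,
                                   patient_id=record.patient_id))
    metrics = classification_metrics(pool_confusion(preds, truths))
    metrics.mae_mm2 = mae(areas)
    return VariantOutcome(
        variant=net.variant,
        metrics=metrics,
        agreement=bland_altman(areas),
        mae_mm2=metrics.mae_mm2,
        area_records=areas,
        network=net,
    )


def run_benchmark(seed: int, variants=VARIANTS,
                  settings: BenchmarkSettings = BenchmarkSettings(),
                  checkpoint_dir=None) -> dict[str, VariantOutcome]:
    """Train and evaluate each requested variant; returns per-variant outcomes."""
    seed = int(seed) & 0x7FFFFFFF
    train, heldout = make_benchmark_data(seed, settings)
    config = TrainConfig(batch_size=settings.batch_size, epochs=settings.epochs,
                         w_pos=settings.w_pos, w_neg=settings.w_neg,
                         seed=seed + 101)
    outcomes: dict[str, VariantOutcome] = {}
    for k, variant in enumerate(variants):
        spec = NetSpec(variant=variant, depth=settings.depth,
                       base_filters=settings.base_filters, seed=seed + 7 * (k + 1))
        ckpt = None
        if checkpoint_dir is not None:
            from pathlib import Path
            ckpt = Path(checkpoint_dir) / f"{variant}.npz"
        fold = train_fold(spec, train, heldout, config, checkpoint_path=ckpt)
        outcome = evaluate_network(fold.network, heldout)
        outcome.fold_result = fold
        outcomes[variant] = outcome
    return outcomes
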