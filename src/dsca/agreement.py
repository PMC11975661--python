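"""Evaluation statistics: pixel metrics, area MAE, Pearson, Bland-Altman.

Pixel-wise classification metrics are pooled over all evaluated slices
into one confusion table (a single precision/recall per model, as is usual
when one model is summarized by one row).  Area agreement between
predicted and ground-truth DSCA is summarized by the mean absolute error,
the Pearson product-moment correlation, and a Bland-Altman analysis with
differences taken as predicted - actual, so a positive mean difference
reads as overestimation.  Limits of agreement are mean +/- 1.96 sample
standard deviations (n-1 denominator).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .quant import AreaRecord

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "AgreementReport",
    "pool_confusion",
    "classification_metrics",
    "mae",
    "pearson",
    "bland_altman",
    "render_reports",
]

logger = logging.getLogger(__name__)

Z_LOA = 1.96  # normal quantile defining the limits of agreement


@dataclass
class ConfusionCounts:
    """Pixel-wise confusion counts pooled over an evaluation set."""

    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.tn + other.tn, self.fn + other.fn)


@dataclass
class MetricsReport:
    """Classification metrics plus (optionally) the area MAE."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    mae_mm2: float = float("nan")


@dataclass
class AgreementReport:
    """Bland-Altman summary plus the Pearson correlation of the area pairs."""

    mean_diff_mm2: float
    sd_diff_mm2: float
    loa_low: float
    loa_high: float
    pearson_r: float
    n: int
    means: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)
    diffs: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)


def pool_confusion(pred_masks, truth_masks) -> ConfusionCounts:
    """Pool pixel-wise TP/FP/TN/FN over aligned binary mask collections."""
    counts = ConfusionCounts()
    pred_masks, truth_masks = list(pred_masks), list(truth_masks)
    if len(pred_masks) != len(truth_masks):
        raise ValueError("prediction and truth collections differ in length")
    for pred, truth in zip(pred_masks, truth_masks):
        pred = np.asarray(pred).astype(bool)
        truth = np.asarray(truth).astype(bool)
        if pred.shape != truth.shape:
            raise ValueError(f"mask shape mismatch: {pred.shape} vs {truth.shape}")
        counts.tp += int(np.sum(pred & truth))
        counts.fp += int(np.sum(pred & ~truth))
        counts.tn += int(np.sum(~pred & ~truth))
        counts.fn += int(np.sum(~pred & truth))
    return counts


def _safe_div(num: float, den: float, name: str) -> float:
    if den == 0:
        logger.warning("%s undefined (zero denominator); reporting 0.0", name)
        return 0.0
    return num / den


def classification_metrics(c: ConfusionCounts) -> MetricsReport:
    """Accuracy, precision, recall and F1 from pooled confusion counts.

    F1 is the harmonic mean of precision and recall.  Ratios with a zero
    denominator are reported as 0.0 (and logged).
    """
    if c.total == 0:
        raise ValueError("confusion counts are all zero")
    precision = _safe_div(c.tp, c.tp + c.fp, "precision")
    recall = _safe_div(c.tp, c.tp + c.fn, "recall")
    f1 = _safe_div(2 * precision * recall, precision + recall, "f1")
    return MetricsReport(
        accuracy=(c.tp + c.tn) / c.total,
        precision=precision,
        recall=recall,
        f1=f1,
    )


def _areas(records) -> tuple[np.ndarray, np.ndarray]:
    true = np.array([r.area_true_mm2 for r in records], dtype=float)
    pred = np.array([r.area_pred_mm2 for r in records], dtype=float)
    return true, pred


def mae(records) -> float:
    """Mean absolute error (mm²) between predicted and true areas."""
    if len(records) == 0:
        raise ValueError("mae requires at least one record")
    true, pred = _areas(records)
    return float(np.mean(np.abs(pred - true)))


def pearson(records) -> float:
    """Sample Pearson correlation between predicted and true areas.

    Returns NaN (with a warning) when either series is constant, where the
    coefficient is undefined.
    """
    if len(records) < 3:
        raise ValueError("pearson requires at least 3 records")
    true, pred = _areas(records)
    if np.ptp(true) == 0 or np.ptp(pred) == 0:
        warnings.warn("Pearson r undefined for a constant series; returning NaN",
                      stacklevel=2)
        return float("nan")
    return float(stats.pearsonr(pred, true).statistic)


def bland_altman(records) -> AgreementReport:
    """Bland-Altman agreement between predicted and actual DSCA.

    Differences are predicted - actual; limits of agreement are the mean
    difference +/- 1.96 sample standard deviations.
    """
    if len(records) < 2:
        raise ValueError("bland_altman requires at least 2 records")
    true, pred = _areas(records)
    diffs = pred - true
    means = (pred + true) / 2.0
    d_mean = float(np.mean(diffs))
    s_d = float(np.std(diffs, ddof=1))
    r = pearson(records) if len(records) >= 3 and np.ptp(true) > 0 and np.ptp(pred) > 0 \
        else float("nan")
    return AgreementReport(
        mean_diff_mm2=d_mean,
        sd_diff_mm2=s_d,
        loa_low=d_mean - Z_LOA * s_d,
        loa_high=d_mean + Z_LOA * s_d,
        pearson_r=r,
        n=len(records),
        means=means,
        diffs=diffs,
    )


# ---------------------------------------------------------------------------
# report rendering


def render_reports(metrics_rows, agreement: AgreementReport, area_records,
                   out_dir, examples=None) -> dict[str, Path]:
    """Write the evaluation artifacts for one run.

    ``metrics_rows`` is a list of dicts with keys model, dataset and the
    MetricsReport fields; ``examples`` (optional) is a list of
    ``(image, truth_mask, pred_mask, AreaRecord)`` tuples rendered as
    image / ground-truth / prediction triptychs with the two areas in the
    panel titles.

    Returns a mapping of artifact name to written path.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import pandas as pd

    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create report directory {out}: {exc}") from exc

    written: dict[str, Path] = {}

    cols = ["model", "dataset", "accuracy", "precision", "recall", "f1", "mae_mm2"]
    mdf = pd.DataFrame(list(metrics_rows))[cols]
    written["metrics_csv"] = out / "metrics.csv"
    mdf.to_csv(written["metrics_csv"], index=False)

    written["agreement_json"] = out / "agreement.json"
    written["agreement_json"].write_text(json.dumps({
        "mean_diff_mm2": agreement.mean_diff_mm2,
        "sd_diff_mm2": agreement.sd_diff_mm2,
        "loa_low": agreement.loa_low,
        "loa_high": agreement.loa_high,
        "pearson_r": agreement.pearson_r,
        "n": agreement.n,
    }, indent=2))

    true, pred = _areas(area_records)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(true, pred, s=12, alpha=0.7)
    lim = [0, max(true.max(), pred.max()) * 1.05] if len(true) else [0, 1]
    ax.plot(lim, lim, "k--", lw=0.8)
    ax.set_xlabel("actual DSCA (mm$^2$)")
    ax.set_ylabel("predicted DSCA (mm$^2$)")
    ax.set_title(f"Pearson r = {agreement.pearson_r:.4f} (n = {agreement.n})")
    fig.tight_layout()
    written["scatter_png"] = out / "scatter.png"
    fig.savefig(written["scatter_png"], dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(agreement.means, agreement.diffs, s=12, alpha=0.7)
    ax.axhline(agreement.mean_diff_mm2, color="red", ls="--",
               label=f"mean {agreement.mean_diff_mm2:.4f}")
    for v in (agreement.loa_low, agreement.loa_high):
        ax.axhline(v, color="blue", ls="--")
    ax.set_xlabel("mean of predicted and actual DSCA (mm$^2$)")
    ax.set_ylabel("predicted $-$ actual (mm$^2$)")
    ax.set_title(f"limits of agreement [{agreement.loa_low:.4f}, {agreement.loa_high:.4f}]")
    ax.legend()
    fig.tight_layout()
    written["bland_altman_png"] = out / "bland_altman.png"
    fig.savefig(written["bland_altman_png"], dpi=120)
    plt.close(fig)

    for i, (image, truth_mask, pred_mask, rec) in enumerate(examples or []):
        fig, axes = plt.subplots(1, 3, figsize=(9, 3))
        axes[0].imshow(image, cmap="gray")
        axes[0].set_title("input slice")
        axes[1].imshow(truth_mask, cmap="gray")
        axes[1].set_title(f"ground truth: {rec.area_true_mm2:.4f} mm$^2$")
        axes[2].imshow(pred_mask, cmap="gray")
        axes[2].set_title(f"prediction: {rec.area_pred_mm2:.4f} mm$^2$")
        for ax in axes:
            ax.axis("off")
        fig.tight_layout()
        p = out / f"triptych_{i:02d}.png"
        written[f"triptych_{i:02d}"] = p
        fig.savefig(p, dpi=120)
        plt.close(fig)

    return written
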