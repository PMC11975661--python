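"""Cross-sectional area from a binary mask and the pixel spacing.

The DSCA of a slice is the foreground pixel count times the pixel's
physical area: ``area = n_fg * spacing**2`` for isotropic spacing, or
``n_fg * row_mm * col_mm`` when row/column spacings differ.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AreaRecord", "calculate_area", "quantify_pair"]


@dataclass
class AreaRecord:
    """Paired predicted / ground-truth DSCA for one slice."""

    slice_id: str
    patient_id: str
    area_true_mm2: float
    area_pred_mm2: float
    pixel_spacing_mm: float


def _check_binary(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    if not np.isin(mask, (0, 1)).all():
        raise ValueError("mask must be strictly binary (values in {0, 1})")
    return mask


def calculate_area(mask: np.ndarray, pixel_size_mm) -> float:
    """Area in mm² of a binary mask's foreground.

    ``pixel_size_mm`` is either a positive scalar (isotropic in-plane
    spacing) or a ``(row_mm, col_mm)`` pair for anisotropic grids.
    """
    mask = _check_binary(mask)
    if np.ndim(pixel_size_mm) == 0:
        row = col = float(pixel_size_mm)
    else:
        row, col = (float(v) for v in pixel_size_mm)
    if row <= 0 or col <= 0:
        raise ValueError("pixel size must be positive")
    return float(np.sum(mask)) * row * col


def quantify_pair(pred: np.ndarray, truth: np.ndarray, spacing,
                  slice_id: str = "", patient_id: str = "") -> AreaRecord:
    """Quantify predicted and ground-truth DSCA for one aligned slice pair."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"mask shape mismatch: {pred.shape} vs {truth.shape}")
    scalar = float(spacing) if np.ndim(spacing) == 0 else float(np.sqrt(spacing[0] * spacing[1]))
    return AreaRecord(
        slice_id=slice_id,
        patient_id=patient_id,
        area_true_mm2=calculate_area(truth, spacing),
        area_pred_mm2=calculate_area(pred, spacing),
        pixel_spacing_mm=scalar,
    )
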