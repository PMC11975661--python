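"""Slice/mask ingestion, normalization, binarization and fold planning.

Raw 8-bit slices are normalized to [0, 1] by dividing by 255.0; ground-
truth mask exports are binarized at the 150/255 threshold; off-resolution
inputs are resampled to the 320x320 working grid with the pixel spacing
rescaled accordingly.  Cross-validation folds are built at *patient* level
so that no subject's slices straddle a train/validation boundary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from skimage.transform import resize

__all__ = [
    "SliceRecord",
    "FoldPlan",
    "normalize_image",
    "binarize_mask",
    "resample_to_working_resolution",
    "make_folds",
    "load_manifest",
    "read_image_file",
    "load_slice",
]

#: A binary mask grid is a float array with values in {0.0, 1.0} aligned to
#: its slice; the alias documents intent in signatures.
MaskGrid = np.ndarray

WORKING_RESOLUTION = 320
BINARIZE_THRESHOLD = 150


@dataclass
class SliceRecord:
    """One normalized slice plus its provenance and pixel spacing."""

    image: np.ndarray           # (H, W) float32 in [0, 1]
    patient_id: str
    slice_id: str
    pixel_spacing_mm: float


def normalize_image(raw: np.ndarray) -> np.ndarray:
    """Scale 8-bit intensities into [0, 1] by dividing by 255.0."""
    raw = np.asarray(raw, dtype=np.float32)
    if raw.min() < 0 or raw.max() > 255:
        raise ValueError("raw intensities must lie in [0, 255]")
    return raw / np.float32(255.0)


def binarize_mask(raw_mask: np.ndarray, threshold: float = BINARIZE_THRESHOLD,
                  mode: str = "ge") -> MaskGrid:
    """Turn an exported 8-bit mask into a strict {0.0, 1.0} grid.

    ``mode='ge'`` (default) marks foreground where intensity >= threshold,
    which tolerates anti-aliased mask exports; ``mode='eq'`` keeps the
    literal equality reading.  Idempotent on grids already in {0, 255} or
    already binary when thresholded again after x255 scaling.
    """
    raw_mask = np.asarray(raw_mask, dtype=np.float32)
    if mode == "ge":
        out = raw_mask >= threshold
    elif mode == "eq":
        out = raw_mask == threshold
    else:
        raise ValueError("mode must be 'ge' or 'eq'")
    return out.astype(np.float32)


def resample_to_working_resolution(image: np.ndarray, pixel_spacing_mm: float,
                                   target: int = WORKING_RESOLUTION,
                                   is_mask: bool = False):
    """Resample a square slice to ``target`` x ``target`` pixels.

    Returns ``(image, new_spacing)`` with the spacing rescaled by
    ``input_size / target`` so physical extent is preserved.  Images use
    bilinear interpolation; masks use nearest-neighbor so they stay binary.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("expected a 2-D slice")
    size = image.shape[0]
    if image.shape != (size, size):
        raise ValueError("expected a square slice")
    if size == target:
        return image, pixel_spacing_mm
    order = 0 if is_mask else 1
    out = resize(image.astype(np.float32), (target, target), order=order,
                 mode="edge", anti_aliasing=False, preserve_range=True)
    return out.astype(np.float32), pixel_spacing_mm * (size / target)


@dataclass
class FoldPlan:
    """Patient-level k-fold assignment, reproducible from its seed."""

    k: int
    assignment: dict[str, int]   # patient_id -> fold index
    seed: int

    def patients_in_fold(self, fold: int) -> list[str]:
        return sorted(p for p, f in self.assignment.items() if f == fold)

    def split(self, fold: int) -> tuple[list[str], list[str]]:
        """(training patients, held-out patients) for one repetition."""
        held = set(self.patients_in_fold(fold))
        train = sorted(p for p in self.assignment if p not in held)
        return train, sorted(held)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(
            {"k": self.k, "seed": self.seed, "assignment": self.assignment},
            indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "FoldPlan":
        d = json.loads(Path(path).read_text())
        return cls(k=d["k"], assignment=d["assignment"], seed=d["seed"])


def make_folds(patient_ids, k: int = 5, seed: int = 0) -> FoldPlan:
    """Shuffle patients with ``seed`` and deal them round-robin into k folds.

    Fold sizes differ by at most one patient; folds partition the patient
    set, so no subject can appear on both sides of a split.
    """
    patients = sorted(set(map(str, patient_ids)))
    if len(patients) < k:
        raise ValueError(f"need at least k={k} distinct patients, got {len(patients)}")
    rng = np.random.default_rng(seed)
    order = [patients[i] for i in rng.permutation(len(patients))]
    assignment = {p: i % k for i, p in enumerate(order)}
    return FoldPlan(k=k, assignment=assignment, seed=seed)


# ---------------------------------------------------------------------------
# file readers


def read_image_file(path) -> tuple[np.ndarray, float | None]:
    """Read a grayscale slice from PNG or DICOM.

    Returns ``(array, spacing_mm_or_None)``; DICOM spacing comes from the
    PixelSpacing attribute, PNG files carry no spacing metadata.
    """
    path = Path(path)
    if path.suffix.lower() in (".dcm", ".dicom"):
        import pydicom
        ds = pydicom.dcmread(str(path))
        spacing = float(ds.PixelSpacing[0]) if "PixelSpacing" in ds else None
        return ds.pixel_array.astype(np.float32), spacing
    arr = np.asarray(Image.open(path), dtype=np.float32)
    return arr, None


def load_manifest(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    return pd.read_csv(path)


def load_slice(row, root, target: int | None = None,
               bit_depth: int = 8) -> tuple[SliceRecord, MaskGrid]:
    """Load one manifest row into a normalized SliceRecord and binary mask.

    ``row`` is a manifest record (mapping with patient_id, slice_id,
    image_path, mask_path, spacing_mm).  Intensities above 8 bits are
    rescaled into the 8-bit range before the /255 normalization.
    """
    root = Path(root)
    image, dcm_spacing = read_image_file(root / row["image_path"])
    spacing = float(dcm_spacing if dcm_spacing is not None else row["spacing_mm"])
    if bit_depth > 8:
        image = image / (2 ** (bit_depth - 8))
    raw_mask, _ = read_image_file(root / row["mask_path"])
    if image.shape != raw_mask.shape:
        raise ValueError(f"slice/mask shape mismatch for {row['slice_id']}")
    if target is not None:
        image, spacing = resample_to_working_resolution(image, spacing, target)
        raw_mask, _ = resample_to_working_resolution(raw_mask, spacing, target, is_mask=True)
    record = SliceRecord(image=normalize_image(image),
                         patient_id=str(row["patient_id"]),
                         slice_id=str(row["slice_id"]),
                         pixel_spacing_mm=spacing)
    return record, binarize_mask(raw_mask)
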