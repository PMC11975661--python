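"""Synthetic axial T1-like lumbar-slice phantoms with known sac geometry.

Real studies of dural-sac cross-sectional area (DSCA) start from expert
masks drawn on axial T1-weighted MRI.  This module replaces that input with
a fully synthetic stand-in whose ground truth is *analytic*: each slice
contains a single smooth, star-convex "dural sac" whose boundary is a
radial-Fourier curve

    r(theta) = r0 * (1 + sum_k a_k cos(k theta) + b_k sin(k theta)),

rasterized by pixel-center inclusion.  The sac is hypointense (CSF is dark
on T1), surrounded by a bright epidural-fat ring inside mid-intensity
background tissue.  Because the boundary polygon's shoelace area is known
exactly, every downstream stage — binarization, segmentation, pixel-count
area quantification, agreement statistics — can be validated against an
independent geometric oracle.

Everything is deterministic given ``(seed, patient_id, slice_index)``.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "PhantomConfig",
    "PhantomSample",
    "generate_phantom",
    "generate_samples",
    "generate_dataset",
    "analytic_polygon_area",
]

_N_VERTICES = 1024  # boundary polygon resolution

#: Default mean intensities (8-bit units) per tissue region; T1-like
#: contrast: CSF-filled sac dark, epidural fat bright, soft tissue mid.
DEFAULT_INTENSITIES = {
    "dural_sac": 30.0,
    "epidural_fat": 190.0,
    "background": 110.0,
}


@dataclass(frozen=True)
class PhantomConfig:
    """Generation parameters for the phantom cohort.

    ``slices_per_patient`` is an inclusive integer range; each patient's
    slice count is drawn from it, emulating the 3–8 annotated slices per
    subject typical of lumbar protocols.  ``area_range_mm2`` bounds the
    sac's analytic area; 50–300 mm² spans severely stenotic through normal
    sacs.  ``perturb_amplitude`` is the total radial-Fourier perturbation
    as a fraction of the base radius, and must stay below 1 so the radius
    remains positive.
    """

    image_size: int = 320
    pixel_spacing_mm: float = 0.6875
    n_patients: int = 10
    slices_per_patient: tuple[int, int] = (3, 8)
    area_range_mm2: tuple[float, float] = (50.0, 300.0)
    n_harmonics: int = 4
    perturb_amplitude: float = 0.15
    noise_sigma: float = 6.0
    intensity_levels: dict = field(default_factory=lambda: dict(DEFAULT_INTENSITIES))
    bit_depth: int = 8
    seed: int = 0

    def __post_init__(self):
        if self.image_size <= 0:
            raise ValueError("image_size must be positive")
        if self.pixel_spacing_mm <= 0:
            raise ValueError("pixel_spacing_mm must be positive")
        lo, hi = self.area_range_mm2
        if not (0 < lo < hi):
            raise ValueError("area_range_mm2 must satisfy 0 < lo < hi")
        if not (0 <= self.perturb_amplitude < 1):
            raise ValueError(
                "perturb_amplitude must lie in [0, 1) to keep the radius positive")
        if self.n_harmonics < 0:
            raise ValueError("n_harmonics must be >= 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        lv = self.intensity_levels
        if lv["dural_sac"] >= min(lv["epidural_fat"], lv["background"]):
            raise ValueError("dural sac must be darker than its surroundings (T1 contrast)")
        lo_s, hi_s = self.slices_per_patient
        if not (1 <= lo_s <= hi_s):
            raise ValueError("slices_per_patient must be a valid inclusive range")
        if self.bit_depth not in (8, 12, 16):
            raise ValueError("bit_depth must be 8, 12 or 16")


@dataclass
class PhantomSample:
    """One generated slice with its analytic ground truth."""

    image: np.ndarray            # (H, W) float32 intensities in [0, 255]
    mask: np.ndarray             # (H, W) float32 {0, 1}
    boundary_polygon: np.ndarray  # (M, 2) vertices in mm, image coordinates
    analytic_area_mm2: float
    patient_id: str
    slice_id: str
    pixel_spacing_mm: float


def analytic_polygon_area(polygon) -> float:
    """Shoelace area (mm²) of a simple polygon given as (M, 2) vertices.

    Orientation-independent: the absolute value is returned.
    """
    poly = np.asarray(polygon, dtype=float)
    if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 3:
        raise ValueError("polygon must be an (M>=3, 2) vertex array")
    x, y = poly[:, 0], poly[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)


def _rng_for(config: PhantomConfig, patient_id: str, slice_index=None):
    ident = zlib.crc32(str(patient_id).encode())
    words = [config.seed & 0x7FFFFFFF, ident]
    if slice_index is not None:
        words.append(int(slice_index))
    return np.random.default_rng(np.random.SeedSequence(words))


def _fourier_radius_at(a, b, r0, theta):
    k = np.arange(1, len(a) + 1)
    pert = (a[:, None] * np.cos(np.multiply.outer(k, theta))
            + b[:, None] * np.sin(np.multiply.outer(k, theta))).sum(axis=0)
    return r0 * (1.0 + pert)


def generate_phantom(config: PhantomConfig, patient_id, slice_index) -> PhantomSample:
    """Generate one deterministic phantom slice.

    The target area is drawn per patient (with mild per-slice modulation)
    from ``config.area_range_mm2``; the boundary's base radius is then
    scaled so the polygon's shoelace area equals the target exactly.
    """
    patient_rng = _rng_for(config, patient_id)
    rng = _rng_for(config, patient_id, slice_index)

    lo, hi = config.area_range_mm2
    base_area = patient_rng.uniform(lo, hi)
    # adjacent slices of one patient have similar, not identical, areas
    target_area = float(np.clip(base_area * rng.uniform(0.9, 1.1), lo, hi))

    theta = np.linspace(0.0, 2.0 * np.pi, _N_VERTICES, endpoint=False)
    # draw Fourier coefficients (bounded so min radius stays positive)
    a = np.zeros(config.n_harmonics)
    b = np.zeros(config.n_harmonics)
    if config.perturb_amplitude > 0 and config.n_harmonics > 0:
        a = rng.normal(size=config.n_harmonics)
        b = rng.normal(size=config.n_harmonics)
        total = np.hypot(a, b).sum()
        scale = config.perturb_amplitude * rng.uniform(0.5, 1.0) / max(total, 1e-12)
        a, b = a * scale, b * scale

    r_unit = _fourier_radius_at(a, b, 1.0, theta)
    if np.any(r_unit <= 0):
        raise ValueError("radial perturbation produced a non-positive radius")
    unit_poly = np.column_stack([r_unit * np.cos(theta), r_unit * np.sin(theta)])
    unit_area = analytic_polygon_area(unit_poly)
    r0 = float(np.sqrt(target_area / unit_area))

    extent = config.image_size * config.pixel_spacing_mm
    r_max = r0 * float(r_unit.max())
    margin = 1.6 * r_max + 2 * config.pixel_spacing_mm
    if 2 * margin >= extent:
        raise ValueError(
            f"sac of max radius {r_max:.1f} mm does not fit a "
            f"{extent:.1f} mm field of view")
    cx = extent / 2 + rng.uniform(-1, 1) * (extent / 2 - margin) * 0.5
    cy = extent / 2 + rng.uniform(-1, 1) * (extent / 2 - margin) * 0.5

    polygon = np.column_stack([cx + r0 * r_unit * np.cos(theta),
                               cy + r0 * r_unit * np.sin(theta)])

    # rasterize by pixel-center inclusion against the radial function
    s = config.pixel_spacing_mm
    coords = (np.arange(config.image_size) + 0.5) * s
    xg, yg = np.meshgrid(coords, coords)       # xg: column coord, yg: row coord
    dx, dy = xg - cx, yg - cy
    r_pix = np.hypot(dx, dy)
    theta_pix = np.arctan2(dy, dx)
    r_bound = _fourier_radius_at(a, b, r0, theta_pix.ravel()).reshape(theta_pix.shape)
    mask = (r_pix <= r_bound).astype(np.float32)

    levels = config.intensity_levels
    image = np.full(mask.shape, levels["background"], dtype=np.float32)
    fat_ring = (r_pix <= 1.45 * r_bound) & (mask == 0)
    image[fat_ring] = levels["epidural_fat"]
    image[mask == 1] = levels["dural_sac"]
    if config.noise_sigma > 0:
        image = image + rng.normal(0.0, config.noise_sigma, size=image.shape).astype(np.float32)
    image = np.clip(image, 0.0, 255.0)

    return PhantomSample(
        image=image.astype(np.float32),
        mask=mask,
        boundary_polygon=polygon,
        analytic_area_mm2=analytic_polygon_area(polygon),
        patient_id=str(patient_id),
        slice_id=f"{patient_id}_s{int(slice_index):02d}",
        pixel_spacing_mm=config.pixel_spacing_mm,
    )


def generate_samples(config: PhantomConfig):
    """Yield phantom slices patient by patient (deterministic order)."""
    for p in range(config.n_patients):
        patient_id = f"P{p:04d}"
        lo, hi = config.slices_per_patient
        n_slices = int(_rng_for(config, patient_id + "#count").integers(lo, hi + 1))
        for s in range(n_slices):
            yield generate_phantom(config, patient_id, s)


def _to_uint(image: np.ndarray, bit_depth: int) -> np.ndarray:
    scale = 2 ** (bit_depth - 8)
    arr = np.round(np.asarray(image) * scale)
    if bit_depth == 8:
        return arr.astype(np.uint8)
    return np.clip(arr, 0, 2 ** bit_depth - 1).astype(np.uint16)


def _write_png(path: Path, arr: np.ndarray) -> None:
    mode = "L" if arr.dtype == np.uint8 else "I;16"
    Image.fromarray(arr, mode=mode).save(path)


def _write_dicom(path: Path, arr: np.ndarray, spacing_mm: float, patient_id: str) -> None:
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage, generate_uid

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = SecondaryCaptureImageStorage
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.PatientID = patient_id
    ds.Modality = "MR"
    ds.Rows, ds.Columns = arr.shape
    ds.PixelSpacing = [f"{spacing_mm:g}", f"{spacing_mm:g}"]
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 8 if arr.dtype == np.uint8 else 16
    ds.BitsStored = ds.BitsAllocated
    ds.HighBit = ds.BitsAllocated - 1
    ds.PixelRepresentation = 0
    ds.PixelData = arr.tobytes()
    ds.save_as(str(path), enforce_file_format=True)


def generate_dataset(config: PhantomConfig, out_dir, file_format: str = "png") -> pd.DataFrame:
    """Write a phantom cohort to disk and return its manifest.

    Creates ``images/`` and ``masks/`` under ``out_dir`` plus
    ``manifest.csv`` with columns patient_id, slice_id, image_path,
    mask_path, spacing_mm, analytic_area_mm2.  Mask files use foreground =
    255 so the standard 150/255 binarization applies unchanged.
    """
    if file_format not in ("png", "dicom"):
        raise ValueError("file_format must be 'png' or 'dicom'")
    out = Path(out_dir)
    try:
        (out / "images").mkdir(parents=True, exist_ok=True)
        (out / "masks").mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out}: {exc}") from exc

    rows = []
    ext = "png" if file_format == "png" else "dcm"
    for sample in generate_samples(config):
        img_rel = f"images/{sample.slice_id}.{ext}"
        mask_rel = f"masks/{sample.slice_id}.png"
        try:
            if file_format == "png":
                _write_png(out / img_rel, _to_uint(sample.image, config.bit_depth))
            else:
                _write_dicom(out / img_rel, _to_uint(sample.image, config.bit_depth),
                             sample.pixel_spacing_mm, sample.patient_id)
            _write_png(out / mask_rel, (sample.mask * 255).astype(np.uint8))
        except OSError as exc:
            raise OSError(f"failed writing {out / img_rel}: {exc}") from exc
        rows.append({
            "patient_id": sample.patient_id,
            "slice_id": sample.slice_id,
            "image_path": img_rel,
            "mask_path": mask_rel,
            "spacing_mm": sample.pixel_spacing_mm,
            "analytic_area_mm2": round(sample.analytic_area_mm2, 6),
        })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
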