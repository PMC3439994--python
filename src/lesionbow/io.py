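"""Dataset manifest handling and image/mask loading.

The pipeline operates on 2-D grayscale CT slices in an 8-bit domain
(gray values 0..255, background 0) with one binary lesion mask per slice.
Inputs are listed in a CSV manifest with one row per (patient, phase,
image); DICOM slices are converted to 8-bit via a configurable liver
window, 8-bit raster fixtures pass through unchanged.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

LABELS = ("HCC", "hemangioma", "cyst")
PHASES = ("AP", "PVP", "DP")

#: Default soft-tissue liver window (Hounsfield units).
DEFAULT_WINDOW_CENTER = 60.0
DEFAULT_WINDOW_WIDTH = 200.0

MANIFEST_COLUMNS = ("patient_id", "label", "phase", "image", "mask")


class ManifestError(ValueError):
    """Raised for malformed or inconsistent dataset manifests."""


@dataclass(frozen=True)
class ManifestRecord:
    """One (patient, phase, image, mask) row of the dataset manifest."""

    patient_id: str
    label: str
    phase: str
    image_path: Path
    mask_path: Path

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ManifestError(f"unknown label {self.label!r}; expected one of {LABELS}")
        if self.phase not in PHASES:
            raise ManifestError(f"unknown phase {self.phase!r}; expected one of {PHASES}")


@dataclass
class PhaseImage:
    """A 2-D 8-bit grayscale slice tagged with its phase and patient."""

    pixels: np.ndarray
    phase: str
    patient_id: str

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("PhaseImage pixels must be 2-D")
        if self.pixels.shape[0] < 16 or self.pixels.shape[1] < 16:
            raise ValueError(f"image too small: {self.pixels.shape}, need at least 16x16")
        if self.pixels.dtype != np.uint8:
            if self.pixels.min() < 0 or self.pixels.max() > 255:
                raise ValueError("pixel values outside [0, 255]")
            self.pixels = self.pixels.astype(np.uint8)


@dataclass
class LesionMask:
    """Binary lesion mask (1 = lesion, 0 = background), same shape as its slice."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = (np.asarray(self.pixels) != 0).astype(np.uint8)
        if self.pixels.ndim != 2:
            raise ValueError("LesionMask pixels must be 2-D")
        if not self.pixels.any():
            raise ValueError("empty lesion mask: no foreground pixel")


def read_manifest(path: str | Path) -> list[ManifestRecord]:
    """Read and validate a dataset manifest CSV.

    Relative image/mask paths are resolved against the manifest's directory.
    Raises :class:`ManifestError` naming the offending row for a missing
    column, an unknown phase or label token, or a patient whose rows carry
    conflicting disease labels.
    """
    path = Path(path)
    root = path.parent
    records: list[ManifestRecord] = []
    patient_label: dict[str, str] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in MANIFEST_COLUMNS if c not in header]
        if missing:
            raise ManifestError(f"manifest {path} is missing columns {missing}")
        for i, row in enumerate(reader, start=2):  # header is line 1
            try:
                rec = ManifestRecord(
                    patient_id=row["patient_id"],
                    label=row["label"],
                    phase=row["phase"],
                    image_path=root / row["image"],
                    mask_path=root / row["mask"],
                )
            except ManifestError as exc:
                raise ManifestError(f"row {i} of {path}: {exc}") from None
            prev = patient_label.setdefault(rec.patient_id, rec.label)
            if prev != rec.label:
                raise ManifestError(
                    f"row {i} of {path}: patient {rec.patient_id!r} has conflicting "
                    f"labels {prev!r} and {rec.label!r}"
                )
            records.append(rec)
    if not records:
        raise ManifestError(f"manifest {path} contains no records")
    return records


def write_manifest(records: list[ManifestRecord], path: str | Path) -> Path:
    """Write records back to CSV with paths relative to the manifest directory."""
    path = Path(path)
    root = path.parent
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(MANIFEST_COLUMNS)
        for rec in records:
            writer.writerow(
                [
                    rec.patient_id,
                    rec.label,
                    rec.phase,
                    _relativize(rec.image_path, root),
                    _relativize(rec.mask_path, root),
                ]
            )
    return path


def _relativize(p: Path, root: Path) -> str:
    try:
        return Path(p).relative_to(root).as_posix()
    except ValueError:
        return Path(p).as_posix()


def apply_window(hu: np.ndarray, center: float, width: float) -> np.ndarray:
    """Linear CT window map from Hounsfield units to 8-bit gray.

    Values at or below ``center - width/2`` map to 0, values at or above
    ``center + width/2`` map to 255, and the window interior maps linearly
    (so the window center lands on gray 128 after rounding).
    """
    if width <= 0:
        raise ValueError("window width must be positive")
    lo = center - width / 2.0
    frac = (np.asarray(hu, dtype=np.float64) - lo) / width
    return np.clip(np.round(frac * 255.0), 0, 255).astype(np.uint8)


def load_image(
    record: ManifestRecord,
    window_center: float = DEFAULT_WINDOW_CENTER,
    window_width: float = DEFAULT_WINDOW_WIDTH,
) -> PhaseImage:
    """Load one slice as an 8-bit :class:`PhaseImage`.

    DICOM input has the rescale slope/intercept applied and is then windowed
    to [0, 255]; 8-bit raster input (e.g. PNG phantom fixtures) is passed
    through unchanged.
    """
    path = Path(record.image_path)
    if path.suffix.lower() in (".dcm", ".dicom"):
        import pydicom

        ds = pydicom.dcmread(path)
        raw = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        pixels = apply_window(raw * slope + intercept, window_center, window_width)
    else:
        pixels = np.asarray(iio.imread(path))
        if pixels.ndim == 3:
            if not (pixels == pixels[..., :1]).all():
                raise ValueError(f"{path}: color raster is not grayscale")
            pixels = pixels[..., 0]
        if pixels.dtype != np.uint8:
            raise ValueError(f"{path}: raster image must be 8-bit grayscale")
    return PhaseImage(pixels=pixels, phase=record.phase, patient_id=record.patient_id)


def load_mask(record: ManifestRecord, image: PhaseImage | None = None) -> LesionMask:
    """Load the lesion mask for a record; nonzero pixels become foreground.

    If ``image`` is given, the mask shape is checked against it.
    """
    raw = np.asarray(iio.imread(Path(record.mask_path)))
    if raw.ndim == 3:
        raw = raw[..., 0]
    values = np.unique(raw)
    if len(values) > 2:
        raise ValueError(f"{record.mask_path}: mask has {len(values)} distinct values, expected 2")
    if image is not None and raw.shape != image.pixels.shape:
        raise ValueError(
            f"{record.mask_path}: mask shape {raw.shape} does not match image "
            f"shape {image.pixels.shape}"
        )
    return LesionMask(pixels=raw)


def group_by_patient(records: list[ManifestRecord]) -> dict[str, list[ManifestRecord]]:
    """Group manifest records by patient id, preserving manifest order."""
    groups: dict[str, list[ManifestRecord]] = {}
    for rec in records:
        groups.setdefault(rec.patient_id, []).append(rec)
    return groups
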