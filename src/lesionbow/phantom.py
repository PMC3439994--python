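"""Synthetic triple-phase liver-lesion phantoms.

Real triple-phase contrast-enhanced CT of focal liver lesions shows
class-specific enhancement dynamics relative to the surrounding
parenchyma, and the phantom generator encodes exactly those dynamics so
the whole retrieval pipeline can be exercised without clinical data:

* **HCC** — "fast in and fast out": hyper-dense in the arterial phase
  (AP) while the parenchyma has not yet peaked, then hypo-dense in the
  portal venous (PVP) and delayed (DP) phases.
* **Hemangioma** — "fast in and slow out": strong peripheral (rim)
  enhancement in AP with centripetal fill-in, the core brightening
  toward the rim value by DP.
* **Cyst** — uniform low density, unchanged by contrast in every phase.

Each phantom patient gets one elliptical lesion geometry reused (with
one-pixel jitter) across 3–10 slice images covering all three phases;
parenchyma fills the rest of the frame at a shared per-phase mean that
peaks in PVP. Additive Gaussian noise is clipped to [0, 255]. Everything
is a pure function of the parameters and the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .io import LABELS, PHASES, LesionMask, ManifestRecord, PhaseImage, write_manifest
from .partition import cityblock_distance_transform

#: Per-class, per-phase mean gray values for the lesion rim, lesion core and
#: surrounding parenchyma. Encodes the enhancement narratives above; the
#: parenchyma trajectory is shared by all classes and peaks in PVP.
ZoneMeans = dict[str, float]  # keys: rim, core, parenchyma
ClassProfile = dict[tuple[str, str], ZoneMeans]

_PARENCHYMA = {"AP": 110.0, "PVP": 150.0, "DP": 130.0}


def default_profile() -> ClassProfile:
    """The built-in enhancement profile (all gray values configurable)."""
    profile: ClassProfile = {}
    hcc = {"AP": 170.0, "PVP": 110.0, "DP": 105.0}
    hem_rim = {"AP": 200.0, "PVP": 170.0, "DP": 150.0}
    hem_core = {"AP": 90.0, "PVP": 120.0, "DP": 145.0}
    for phase in PHASES:
        par = _PARENCHYMA[phase]
        profile[("HCC", phase)] = {"rim": hcc[phase], "core": hcc[phase], "parenchyma": par}
        profile[("hemangioma", phase)] = {
            "rim": hem_rim[phase],
            "core": hem_core[phase],
            "parenchyma": par,
        }
        profile[("cyst", phase)] = {"rim": 40.0, "core": 40.0, "parenchyma": par}
    return profile


@dataclass(frozen=True)
class LesionGeometry:
    """One elliptical lesion: center (row, col), semi-axes and rotation."""

    center: tuple[float, float]
    axes: tuple[float, float]
    rotation: float  # radians


@dataclass
class PhantomParams:
    """Generation parameters for one synthetic dataset."""

    n_patients_per_class: int = 5
    images_per_patient: tuple[int, int] = (3, 10)
    image_size: tuple[int, int] = (96, 96)
    lesion_radius_range: tuple[float, float] = (8.0, 16.0)
    noise_sd: float = 5.0
    seed: int = 0
    class_profile: ClassProfile = field(default_factory=default_profile)

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.images_per_patient[0] < 3:
            raise ValueError(
                "images_per_patient lower bound must be >= 3 so that every "
                "patient can cover all three phases"
            )
        for means in self.class_profile.values():
            for v in means.values():
                if not 0 <= v <= 255:
                    raise ValueError(f"profile mean {v} outside [0, 255]")
        margin = 4 + max(self.lesion_radius_range)
        if margin * 2 >= min(self.image_size):
            raise ValueError("lesion does not fit inside the image with a 4-pixel margin")


def ellipse_mask(shape: tuple[int, int], geometry: LesionGeometry) -> np.ndarray:
    """Raster of the (filled) rotated ellipse as a uint8 {0,1} grid."""
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    dr = rr - geometry.center[0]
    dc = cc - geometry.center[1]
    cos, sin = math.cos(geometry.rotation), math.sin(geometry.rotation)
    u = dr * cos + dc * sin
    v = -dr * sin + dc * cos
    a, b = geometry.axes
    return ((u / a) ** 2 + (v / b) ** 2 <= 1.0).astype(np.uint8)


def render_image(
    label: str,
    phase: str,
    geometry: LesionGeometry,
    profile: ClassProfile,
    noise_sd: float,
    rng: np.random.Generator,
    image_size: tuple[int, int] = (96, 96),
    patient_id: str = "",
) -> tuple[PhaseImage, LesionMask]:
    """Render one noisy phase image and its exact lesion mask.

    The parenchyma fills the frame at its phase mean; the lesion rim (the
    outer third of its city-block distance layers) and core are filled at
    their phase means. The rim/core split reuses the same distance
    transform the retrieval method partitions lesions with, so hemangioma
    phantoms genuinely exercise the concentric-region structure.
    """
    means = profile[(label, phase)]
    mask = ellipse_mask(image_size, geometry)
    if not mask.any():
        raise ValueError("lesion ellipse rasters to nothing")
    interior = mask[1:-1, 1:-1]
    if mask.sum() != interior.sum():
        raise ValueError("lesion extends outside the image frame")

    img = np.full(image_size, means["parenchyma"], dtype=np.float64)
    dist = cityblock_distance_transform(mask)
    L = int(dist.max())
    rim_depth = math.ceil(L / 3)
    rim = (dist >= 1) & (dist <= rim_depth)
    core = dist > rim_depth
    img[rim] = means["rim"]
    img[core] = means["core"]
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=image_size)
    pixels = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return (
        PhaseImage(pixels=pixels, phase=phase, patient_id=patient_id),
        LesionMask(pixels=mask),
    )


def _sample_geometry(params: PhantomParams, rng: np.random.Generator) -> LesionGeometry:
    lo, hi = params.lesion_radius_range
    a = rng.uniform(lo, hi)
    b = rng.uniform(lo, hi)
    margin = 5 + max(a, b)
    center = (
        rng.uniform(margin, params.image_size[0] - margin),
        rng.uniform(margin, params.image_size[1] - margin),
    )
    return LesionGeometry(center=center, axes=(a, b), rotation=rng.uniform(0, math.pi))


def _sample_phases(n_images: int, rng: np.random.Generator) -> list[str]:
    """A phase per image such that all three phases are represented."""
    phases = list(PHASES) + [PHASES[rng.integers(0, 3)] for _ in range(n_images - 3)]
    rng.shuffle(phases)
    return phases


def generate_dataset(params: PhantomParams, out_dir: str | Path) -> Path:
    """Write a full phantom dataset (PNG images, PNG masks, CSV manifest).

    Returns the manifest path. The dataset — file names, pixel data and
    manifest bytes — is fully determined by ``params`` (including its
    seed).
    """
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(params.seed)
    records: list[ManifestRecord] = []
    lo, hi = params.images_per_patient
    for label in LABELS:
        for i in range(params.n_patients_per_class):
            pid = f"{label[:3].upper()}{i:03d}"
            geometry = _sample_geometry(params, rng)
            n_images = int(rng.integers(lo, hi + 1))
            for k, phase in enumerate(_sample_phases(n_images, rng)):
                jitter = rng.integers(-1, 2, size=2)
                geo_k = LesionGeometry(
                    center=(geometry.center[0] + jitter[0], geometry.center[1] + jitter[1]),
                    axes=geometry.axes,
                    rotation=geometry.rotation,
                )
                image, mask = render_image(
                    label,
                    phase,
                    geo_k,
                    params.class_profile,
                    params.noise_sd,
                    rng,
                    image_size=params.image_size,
                    patient_id=pid,
                )
                img_path = out_dir / "images" / f"{pid}_{k:02d}_{phase}.png"
                mask_path = out_dir / "masks" / f"{pid}_{k:02d}_{phase}.png"
                iio.imwrite(img_path, image.pixels)
                iio.imwrite(mask_path, (mask.pixels * 255).astype(np.uint8))
                records.append(
                    ManifestRecord(
                        patient_id=pid,
                        label=label,
                        phase=phase,
                        image_path=img_path,
                        mask_path=mask_path,
                    )
                )
    return write_manifest(records, out_dir / "manifest.csv")
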