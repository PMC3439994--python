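"""Concentric lesion partitioning via the city-block distance transform.

A lesion mask is turned into a distance image (each lesion pixel holds its
L1 distance to the nearest background pixel), the distance layers 1..L are
grouped into ``s`` concentric regions from the boundary inward, and the
normal liver parenchyma immediately around the lesion — the tissue whose
enhancement contrast against the lesion carries diagnostic weight — is
attached as region ``s+1`` via a bounding box expanded by a 2-pixel margin
on every side.

The city-block metric is used because its distance values are integers,
which makes the layer grouping exact. With ``p = L // s`` and
``q = L % s``, the ``s-1`` outer regions get ``p`` layers each and the
innermost region gets ``p + q``; when the lesion is thinner than ``s``
layers, the outermost regions get one layer each and the rest stay empty,
so even tiny lesions remain processable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import LesionMask, PhaseImage

PARENCHYMA_MARGIN = 2  # pixels added on every side of the tight lesion box


@dataclass
class LayerPartition:
    """Grouping of distance layers 1..L into s concentric regions.

    ``ranges[i]`` is the half-open interval ``(start, stop)`` of distance
    values belonging to region ``i+1`` (region 1 = outermost). Empty
    regions have ``start == stop``.
    """

    L: int
    s: int
    p: int
    q: int
    ranges: list[tuple[int, int]]


def cityblock_distance_transform(mask: LesionMask | np.ndarray) -> np.ndarray:
    """Exact L1 distance of every foreground pixel to the nearest background.

    The grid border counts as background, so a lesion touching the crop
    edge still gets layer 1 there. Background pixels hold 0.
    """
    pixels = mask.pixels if isinstance(mask, LesionMask) else np.asarray(mask)
    pixels = (pixels != 0).astype(np.uint8)
    if not pixels.any():
        raise ValueError("empty mask: nothing to transform")
    padded = np.pad(pixels, 1)
    dist = ndimage.distance_transform_cdt(padded, metric="taxicab")
    return np.asarray(dist[1:-1, 1:-1], dtype=np.int32)


def partition_layers(L: int, s: int) -> LayerPartition:
    """Group L distance layers into s regions, outermost first.

    Regions 1..s-1 get ``p = L // s`` layers each; the innermost region
    absorbs the remainder and gets ``p + L % s``. For ``L < s`` the first
    L regions get one layer each and the remaining regions are empty.
    """
    if L < 1:
        raise ValueError("layer count L must be >= 1")
    if s < 1:
        raise ValueError("region count s must be >= 1")
    if L < s:
        ranges = [(d, d + 1) if d <= L else (L + 1, L + 1) for d in range(1, s + 1)]
        return LayerPartition(L=L, s=s, p=0, q=L, ranges=ranges)
    p, q = divmod(L, s)
    ranges = [(1 + i * p, 1 + (i + 1) * p) for i in range(s - 1)]
    ranges.append((1 + (s - 1) * p, L + 1))
    return LayerPartition(L=L, s=s, p=p, q=q, ranges=ranges)


def label_regions(
    mask: LesionMask | np.ndarray, s: int, margin: int = PARENCHYMA_MARGIN
) -> np.ndarray:
    """Per-pixel region labels: 0 outside, 1..s lesion (outer to inner), s+1 parenchyma.

    Lesion pixels are assigned by their city-block distance layer; pixels
    inside the margin-expanded bounding box but outside the lesion become
    the surrounding-parenchyma region ``s+1``.
    """
    pixels = mask.pixels if isinstance(mask, LesionMask) else np.asarray(mask)
    pixels = (pixels != 0).astype(np.uint8)
    dist = cityblock_distance_transform(pixels)
    L = int(dist.max())
    part = partition_layers(L, s)

    lut = np.zeros(L + 1, dtype=np.int32)
    for i, (start, stop) in enumerate(part.ranges, start=1):
        lut[start:stop] = i

    labels = np.zeros(pixels.shape, dtype=np.int32)
    fg = pixels.astype(bool)
    labels[fg] = lut[dist[fg]]

    r0, r1, c0, c1 = expanded_bbox(pixels, margin)
    box = np.zeros_like(fg)
    box[r0:r1, c0:c1] = True
    labels[box & ~fg] = s + 1
    return labels


def expanded_bbox(mask: np.ndarray, margin: int = PARENCHYMA_MARGIN) -> tuple[int, int, int, int]:
    """Tight foreground bounding box grown by ``margin`` pixels per side, clipped to the grid.

    Returned as half-open ``(r0, r1, c0, c1)``.
    """
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    r0 = max(int(rows[0]) - margin, 0)
    r1 = min(int(rows[-1]) + 1 + margin, mask.shape[0])
    c0 = max(int(cols[0]) - margin, 0)
    c1 = min(int(cols[-1]) + 1 + margin, mask.shape[1])
    return r0, r1, c0, c1


@dataclass
class LesionROI:
    """A lesion crop with per-pixel region labels and its provenance.

    ``crop`` is the 8-bit gray window around the lesion (tight mask
    bounding box plus the parenchyma margin, clipped at image borders),
    ``labels`` the matching region labeling (0 outside, 1..s lesion
    outer-to-inner, s+1 parenchyma), ``bbox`` the half-open window in
    image coordinates.
    """

    crop: np.ndarray
    labels: np.ndarray
    bbox: tuple[int, int, int, int]
    s: int
    phase: str = ""
    patient_id: str = ""
    label: str = ""

    @property
    def lesion_mask(self) -> np.ndarray:
        """Boolean mask of lesion pixels (region labels 1..s) inside the crop."""
        return (self.labels >= 1) & (self.labels <= self.s)

    @property
    def lesion_pixels(self) -> np.ndarray:
        """Gray values of the lesion pixels, flattened."""
        return self.crop[self.lesion_mask]


def build_roi(
    image: PhaseImage,
    mask: LesionMask,
    s: int = 3,
    margin: int = PARENCHYMA_MARGIN,
    phase: str | None = None,
    patient_id: str | None = None,
    label: str = "",
) -> LesionROI:
    """Cut the margin-expanded lesion window out of a slice and label its regions."""
    if image.pixels.shape != mask.pixels.shape:
        raise ValueError(
            f"image shape {image.pixels.shape} does not match mask shape {mask.pixels.shape}"
        )
    labels = label_regions(mask, s=s, margin=margin)
    r0, r1, c0, c1 = expanded_bbox(mask.pixels, margin)
    return LesionROI(
        crop=image.pixels[r0:r1, c0:c1].copy(),
        labels=labels[r0:r1, c0:c1].copy(),
        bbox=(r0, r1, c0, c1),
        s=s,
        phase=phase if phase is not None else image.phase,
        patient_id=patient_id if patient_id is not None else image.patient_id,
        label=label,
    )
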