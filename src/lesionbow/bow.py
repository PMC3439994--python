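"""Regional bag-of-visual-words features.

This is the heart of the method: dense 7x7 raw-intensity patches are
extracted at every labeled pixel of a lesion ROI, patches dominated by
background (15 or fewer nonzero gray values) are dropped, the remaining
descriptors are quantized against a K-means visual codebook, and one
hard-assignment word histogram is accumulated *per concentric region*
(plus the surrounding-parenchyma region). Concatenating the per-region
histograms keeps the spatial enhancement structure — rim vs core vs
parenchyma — that a global bag of words would discard. Patient-level
features are the element-wise mean of the patient's image features over a
chosen phase subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.cluster import KMeans

from .partition import LesionROI

DEFAULT_PATCH_SIZE = 7
#: A patch is kept only if strictly more than this many of its gray values
#: are nonzero (the radiologic background gray value is 0).
DEFAULT_MIN_NONZERO = 15
DEFAULT_CODEBOOK_SIZE = 1024
DEFAULT_MAX_TRAINING_SAMPLES = 100_000


@dataclass(frozen=True)
class Patch:
    """One square patch: row-major gray values, crop position, region label."""

    descriptor: np.ndarray
    center: tuple[int, int]
    region: int


@dataclass
class PatchSet:
    """Dense container for many patches (rows of ``descriptors`` are patches)."""

    descriptors: np.ndarray  # (n, patch_size**2) float64
    centers: np.ndarray  # (n, 2) int
    regions: np.ndarray  # (n,) int
    patch_size: int

    def __len__(self) -> int:
        return self.descriptors.shape[0]

    def __getitem__(self, i: int) -> Patch:
        return Patch(
            descriptor=self.descriptors[i],
            center=(int(self.centers[i, 0]), int(self.centers[i, 1])),
            region=int(self.regions[i]),
        )


@dataclass
class Codebook:
    """The visual vocabulary: K-means centroids of patch descriptors."""

    words: np.ndarray  # (n_words, patch_size**2)
    patch_size: int
    seed: int
    n_training: int

    @property
    def n_words(self) -> int:
        return self.words.shape[0]

    def save(self, path) -> None:
        np.savez(
            path,
            words=self.words,
            patch_size=self.patch_size,
            seed=self.seed,
            n_training=self.n_training,
        )

    @classmethod
    def load(cls, path) -> "Codebook":
        data = np.load(path)
        return cls(
            words=data["words"],
            patch_size=int(data["patch_size"]),
            seed=int(data["seed"]),
            n_training=int(data["n_training"]),
        )


@dataclass
class RegionHistogram:
    """Normalized word-frequency histogram of one region."""

    x: np.ndarray
    n_patches: int


@dataclass
class FeatureVector:
    """A numeric lesion descriptor at image or patient level."""

    values: np.ndarray
    provenance: str  # regional_bow | lowlevel | combined
    level: str = "image"  # image | patient
    patient_id: str = ""
    label: str = ""
    phase: str = ""  # image level
    phase_subset: tuple[str, ...] = ()  # patient level

    @property
    def dimension(self) -> int:
        return self.values.shape[0]


def extract_patches(roi: LesionROI, patch_size: int = DEFAULT_PATCH_SIZE) -> PatchSet:
    """One candidate patch centered at every labeled crop pixel.

    Windows reaching past the crop are zero-padded; each patch carries the
    region label of its center pixel.
    """
    if patch_size < 3 or patch_size % 2 == 0:
        raise ValueError("patch_size must be odd and >= 3")
    half = patch_size // 2
    padded = np.pad(roi.crop.astype(np.float64), half)
    windows = sliding_window_view(padded, (patch_size, patch_size))
    keep = roi.labels > 0
    rows, cols = np.nonzero(keep)
    descriptors = windows[rows, cols].reshape(len(rows), patch_size * patch_size)
    return PatchSet(
        descriptors=np.ascontiguousarray(descriptors),
        centers=np.stack([rows, cols], axis=1),
        regions=roi.labels[rows, cols].astype(np.int64),
        patch_size=patch_size,
    )


def filter_patches(patches: PatchSet, min_nonzero: int = DEFAULT_MIN_NONZERO) -> PatchSet:
    """Drop background-dominated patches (nonzero count must exceed ``min_nonzero``)."""
    keep = (patches.descriptors != 0).sum(axis=1) > min_nonzero
    return PatchSet(
        descriptors=patches.descriptors[keep],
        centers=patches.centers[keep],
        regions=patches.regions[keep],
        patch_size=patches.patch_size,
    )


def train_codebook(
    descriptors: np.ndarray,
    n_words: int = DEFAULT_CODEBOOK_SIZE,
    seed: int = 0,
    max_samples: int = DEFAULT_MAX_TRAINING_SAMPLES,
) -> Codebook:
    """Learn the visual vocabulary by K-means on training-image descriptors.

    The pool is subsampled (seeded, uniform without replacement) to
    ``max_samples`` before clustering; training is deterministic given
    (descriptors, n_words, seed).
    """
    descriptors = np.asarray(descriptors, dtype=np.float64)
    if descriptors.ndim != 2:
        raise ValueError("descriptors must be a 2-D (n, d) array")
    rng = np.random.default_rng(seed)
    if descriptors.shape[0] > max_samples:
        idx = rng.choice(descriptors.shape[0], size=max_samples, replace=False)
        descriptors = descriptors[np.sort(idx)]
    n_distinct = np.unique(descriptors, axis=0).shape[0]
    if n_distinct < n_words:
        raise ValueError(
            f"only {n_distinct} distinct descriptors available for a {n_words}-word "
            f"codebook; use a smaller codebook size"
        )
    km = KMeans(
        n_clusters=n_words,
        init="k-means++",
        n_init=1,
        max_iter=300,
        tol=1e-4,
        random_state=int(rng.integers(0, 2**31 - 1)),
    ).fit(descriptors)
    patch_size = int(round(np.sqrt(descriptors.shape[1])))
    return Codebook(
        words=km.cluster_centers_,
        patch_size=patch_size,
        seed=seed,
        n_training=descriptors.shape[0],
    )


def assign_codewords(descriptors: np.ndarray, codebook: Codebook) -> np.ndarray:
    """Nearest-word index (Euclidean) per descriptor; ties go to the lowest index."""
    descriptors = np.atleast_2d(np.asarray(descriptors, dtype=np.float64))
    if descriptors.shape[1] != codebook.words.shape[1]:
        raise ValueError(
            f"descriptor dimension {descriptors.shape[1]} does not match codebook "
            f"word dimension {codebook.words.shape[1]}"
        )
    words = codebook.words.astype(np.float64)
    # ||d - w||^2 expanded; argmin returns the first (lowest-index) minimizer
    d2 = (
        (descriptors**2).sum(axis=1)[:, None]
        - 2.0 * descriptors @ words.T
        + (words**2).sum(axis=1)[None, :]
    )
    return np.argmin(d2, axis=1)


def assign_codeword(descriptor: np.ndarray, codebook: Codebook) -> int:
    """Single-descriptor convenience wrapper around :func:`assign_codewords`."""
    return int(assign_codewords(descriptor, codebook)[0])


def region_histogram(patches: PatchSet, region: int, codebook: Codebook) -> RegionHistogram:
    """Word-frequency histogram of one region's (already filtered) patches.

    Counts per word are normalized by the region's kept-patch count so a
    nonempty histogram is a probability vector; an empty region yields the
    all-zero vector.
    """
    sel = patches.regions == region
    n = int(sel.sum())
    x = np.zeros(codebook.n_words, dtype=np.float64)
    if n == 0:
        return RegionHistogram(x=x, n_patches=0)
    idx = assign_codewords(patches.descriptors[sel], codebook)
    counts = np.bincount(idx, minlength=codebook.n_words).astype(np.float64)
    return RegionHistogram(x=counts / n, n_patches=n)


def bow_feature(
    roi: LesionROI,
    codebook: Codebook,
    patch_size: int = DEFAULT_PATCH_SIZE,
    min_nonzero: int = DEFAULT_MIN_NONZERO,
) -> FeatureVector:
    """Full regional BoW descriptor of one ROI: histograms of regions 1..s then s+1.

    Dimension is ``(s + 1) * n_words``.
    """
    patches = filter_patches(extract_patches(roi, patch_size), min_nonzero)
    parts = [
        region_histogram(patches, region, codebook).x for region in range(1, roi.s + 2)
    ]
    return FeatureVector(
        values=np.concatenate(parts),
        provenance="regional_bow",
        level="image",
        patient_id=roi.patient_id,
        label=roi.label,
        phase=roi.phase,
    )


def patient_feature(
    image_features: list[FeatureVector], phase_subset: tuple[str, ...] | list[str]
) -> FeatureVector:
    """Element-wise mean of one patient's image features over a phase subset.

    Raises :class:`PhaseSubsetEmpty` when the patient has no image in the
    subset, so sweep code can skip that (patient, subset) cell explicitly.
    """
    subset = tuple(phase_subset)
    chosen = [f for f in image_features if f.phase in subset]
    if not chosen:
        raise PhaseSubsetEmpty(
            f"patient {image_features[0].patient_id if image_features else '?'} has "
            f"no image in phase subset {subset}"
        )
    dims = {f.dimension for f in chosen}
    provs = {f.provenance for f in chosen}
    if len(dims) != 1 or len(provs) != 1:
        raise ValueError("image features must share one dimension and provenance")
    return FeatureVector(
        values=np.mean([f.values for f in chosen], axis=0),
        provenance=chosen[0].provenance,
        level="patient",
        patient_id=chosen[0].patient_id,
        label=chosen[0].label,
        phase_subset=subset,
    )


class PhaseSubsetEmpty(ValueError):
    """A patient has no image in the requested phase subset."""
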