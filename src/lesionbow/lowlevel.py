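"""Classical low-level lesion descriptors: the 93-feature comparison bank.

Per lesion ROI: 5 gray-level histogram statistics, 16 co-occurrence
(Haralick) texture values, 48 Gabor-bank energy statistics, 12 wavelet
texture values and 12 radial-distance shape values — 93 in total, in a
fixed documented order (see :func:`feature_names`). Intensity, GLCM and
Gabor statistics are restricted to lesion pixels (region labels 1..s);
shape features depend only on the mask.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pywt
from scipy import ndimage
from skimage.filters import gabor

from .partition import LesionROI

GLCM_ANGLES_DEG = (0, 45, 90, 135)
#: (row, col) offsets per angle: (sin(theta), cos(theta)), the common
#: co-occurrence convention; under matrix symmetry each offset is
#: equivalent to its negation.
_GLCM_OFFSETS = {0: (0, 1), 45: (1, 1), 90: (1, 0), 135: (1, -1)}
GLCM_LEVELS = 32  # gray levels quantized 256 -> 32 to keep matrices well filled
GLCM_STATS = ("contrast", "homogeneity", "energy", "correlation")

GABOR_FREQUENCIES = (0.05, 0.1, 0.2, 0.4)  # cycles/pixel, one octave apart
GABOR_ORIENTATIONS = tuple(k * np.pi / 6 for k in range(6))

WAVELET = "db4"
TEXTURE_WAVELET_LEVELS = 3
SHAPE_WAVELET_LEVELS = 5
SIGNATURE_POINTS = 128


def intensity_features(roi: LesionROI) -> np.ndarray:
    """Mean, standard deviation, entropy, skewness and kurtosis of the lesion histogram.

    Entropy is base-2 over the 256-bin normalized gray histogram; kurtosis
    is the non-excess (normal = 3) variant; skewness and kurtosis are
    defined as 0 for a constant region.
    """
    values = roi.lesion_pixels.astype(np.float64)
    if values.size < 2:
        raise ValueError("intensity features need at least 2 lesion pixels")
    mean = values.mean()
    sd = values.std()
    hist = np.bincount(values.astype(np.int64), minlength=256) / values.size
    nz = hist[hist > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    if sd == 0:
        skew = kurt = 0.0
    else:
        z = (values - mean) / sd
        skew = float((z**3).mean())
        kurt = float((z**4).mean())
    return np.array([mean, sd, entropy, skew, kurt])


def _masked_glcm(quantized: np.ndarray, lesion: np.ndarray, offset: tuple[int, int]) -> np.ndarray:
    """Symmetric normalized co-occurrence matrix over pairs of lesion pixels."""
    dr, dc = offset
    h, w = quantized.shape
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    a = quantized[r0:r1, c0:c1]
    b = quantized[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    valid = lesion[r0:r1, c0:c1] & lesion[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    counts = np.zeros((GLCM_LEVELS, GLCM_LEVELS), dtype=np.float64)
    np.add.at(counts, (a[valid], b[valid]), 1.0)
    counts = counts + counts.T  # symmetric: count each pair in both directions
    total = counts.sum()
    return counts / total if total > 0 else counts


def _haralick(P: np.ndarray) -> tuple[float, float, float, float]:
    i = np.arange(P.shape[0], dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    diff = ii - jj
    contrast = float((P * diff**2).sum())
    homogeneity = float((P / (1.0 + diff**2)).sum())
    energy = float(np.sqrt((P**2).sum()))
    pi = P.sum(axis=1)
    mu = float((i * pi).sum())
    var = float(((i - mu) ** 2 * pi).sum())
    if var <= 0:
        correlation = 0.0  # degenerate marginals carry no linear dependence
    else:
        correlation = float((P * (ii - mu) * (jj - mu)).sum() / var)
    return contrast, homogeneity, energy, correlation


def glcm_features(roi: LesionROI) -> np.ndarray:
    """16 Haralick values: each statistic at angles 0/45/90/135 deg, distance 1.

    Pairs are counted only when both pixels are lesion pixels; gray values
    are quantized to 32 levels; matrices are symmetric and normalized.
    Order: contrast at the four angles, then homogeneity, energy,
    correlation. An angle with no valid pair contributes (0, 1, 1, 0).
    """
    lesion = roi.lesion_mask
    if lesion.sum() < 4:
        raise ValueError("GLCM features need a lesion area of at least 2x2 pixels")
    quantized = (roi.crop.astype(np.int64) * GLCM_LEVELS) // 256
    per_angle: dict[int, tuple[float, float, float, float]] = {}
    for angle in GLCM_ANGLES_DEG:
        P = _masked_glcm(quantized, lesion, _GLCM_OFFSETS[angle])
        if P.sum() == 0:
            warnings.warn(f"no valid lesion pixel pair at angle {angle}; using degenerate stats")
            per_angle[angle] = (0.0, 1.0, 1.0, 0.0)
        else:
            per_angle[angle] = _haralick(P)
    out = [per_angle[angle][k] for k in range(4) for angle in GLCM_ANGLES_DEG]
    return np.array(out)


def gabor_features(roi: LesionROI) -> np.ndarray:
    """48 values: response-magnitude mean and sd over lesion pixels per Gabor filter.

    The bank spans 4 center frequencies one octave apart (0.05 to 0.4
    cycles/pixel) and 6 orientations k*pi/6. Order is frequency-major,
    orientation-minor, mean before sd.
    """
    lesion = roi.lesion_mask
    crop = roi.crop.astype(np.float64)
    out = []
    for freq in GABOR_FREQUENCIES:
        for theta in GABOR_ORIENTATIONS:
            real, imag = gabor(crop, frequency=freq, theta=theta)
            magnitude = np.hypot(real, imag)[lesion]
            out.extend([magnitude.mean(), magnitude.std()])
    return np.array(out)


def wavelet_texture_features(roi: LesionROI) -> np.ndarray:
    """12 values from a 3-level 2-D Daubechies-4 decomposition of the masked crop.

    Non-lesion crop pixels are replaced by the lesion mean so the
    transform sees only lesion content (a constant lesion yields exactly
    zero detail statistics). Per level, the horizontal and vertical detail
    subbands are summarized by the mean and sd of absolute coefficients;
    levels are ordered coarse to fine.
    """
    lesion = roi.lesion_mask
    fill = roi.lesion_pixels.astype(np.float64).mean()
    arr = np.where(lesion, roi.crop.astype(np.float64), fill)
    pr = max(0, 16 - arr.shape[0])
    pc = max(0, 16 - arr.shape[1])
    if pr or pc:
        arr = np.pad(arr, ((0, pr), (0, pc)), constant_values=fill)
    with warnings.catch_warnings():
        # small lesions sit below pywt's advisory size for 3 levels; the
        # boundary-extended decomposition is still well defined
        warnings.simplefilter("ignore", UserWarning)
        coeffs = pywt.wavedec2(arr, WAVELET, level=TEXTURE_WAVELET_LEVELS)
    out = []
    for cH, cV, _cD in coeffs[1:]:  # pywt orders detail levels coarse -> fine
        for band in (cH, cV):
            absband = np.abs(band)
            out.extend([absband.mean(), absband.std()])
    return np.array(out)


@dataclass
class ShapeSignature:
    """Radial-distance shape signature of a lesion boundary.

    ``S[i]`` is the Euclidean distance of the i-th boundary point from the
    centroid of the filled lesion, with the boundary traced clockwise from
    the topmost-then-leftmost boundary pixel and arc-length resampled to
    ``n_points`` samples.
    """

    S: np.ndarray
    boundary: np.ndarray  # (n_points, 2) resampled (row, col) points
    centroid: tuple[float, float]
    n_points: int


def _trace_boundary(mask: np.ndarray) -> np.ndarray:
    """Outer boundary polygon of a single component, fixed orientation and start.

    The half-level (subpixel) contour is used so boundary points sit on the
    lesion's true silhouette rather than on staircase pixel centers. The
    polygon is oriented clockwise on screen (rows increase downward) and
    rotated to start at its topmost-then-leftmost vertex.
    """
    from skimage import measure

    contours = measure.find_contours(np.pad(mask.astype(float), 1), 0.5)
    contour = max(contours, key=len)[:-1] - 1.0  # open polygon, unpad
    # signed area in (x=col, y=row-down) coordinates; positive = clockwise on screen
    r, c = contour[:, 0], contour[:, 1]
    area = 0.5 * np.sum(c * np.roll(r, -1) - np.roll(c, -1) * r)
    if area < 0:
        contour = contour[::-1]
    start = np.lexsort((contour[:, 1], contour[:, 0]))[0]
    return np.roll(contour, -start, axis=0)


def boundary_signature(mask: np.ndarray, n_points: int = SIGNATURE_POINTS) -> ShapeSignature:
    """Radial-distance signature of the (largest) lesion component's outer boundary."""
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("empty mask has no boundary")
    labeled, n_comp = ndimage.label(mask, structure=np.ones((3, 3)))
    if n_comp > 1:
        warnings.warn(f"mask has {n_comp} components; using the largest")
        sizes = ndimage.sum_labels(mask, labeled, index=np.arange(1, n_comp + 1))
        mask = labeled == (int(np.argmax(sizes)) + 1)
    contour = _trace_boundary(mask)
    rr, cc = np.nonzero(mask)
    centroid = (float(rr.mean()), float(cc.mean()))
    closed = np.vstack([contour, contour[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    if total == 0:  # single-pixel lesion
        resampled = np.repeat(contour[:1], n_points, axis=0)
    else:
        t = np.linspace(0.0, total, n_points, endpoint=False)
        resampled = np.stack(
            [np.interp(t, arc, closed[:, 0]), np.interp(t, arc, closed[:, 1])], axis=1
        )
    S = np.linalg.norm(resampled - np.array(centroid), axis=1)
    return ShapeSignature(S=S, boundary=resampled, centroid=centroid, n_points=n_points)


def shape_features(signature: ShapeSignature) -> np.ndarray:
    """12 values from a 5-level 1-D Daubechies-4 decomposition of the signature.

    Six subbands (approximation plus five details, coarse to fine), each
    summarized by the mean and variance of absolute coefficients.
    """
    if signature.S.shape[0] < 32:
        raise ValueError("shape signature must have at least 32 points")
    with warnings.catch_warnings():
        # level 5 on a 128-sample signature exceeds pywt's advisory maximum;
        # the decomposition is still well defined (boundary-extended)
        warnings.simplefilter("ignore", UserWarning)
        coeffs = pywt.wavedec(signature.S, WAVELET, level=SHAPE_WAVELET_LEVELS)
    out = []
    for band in coeffs:  # [cA5, cD5, ..., cD1]: coarse -> fine
        absband = np.abs(band)
        out.extend([absband.mean(), absband.var()])
    return np.array(out)


@dataclass
class LowLevelBlock:
    """The five feature groups; ``concat`` is the canonical 93-vector."""

    intensity: np.ndarray
    glcm: np.ndarray
    gabor: np.ndarray
    wavelet: np.ndarray
    shape: np.ndarray

    @property
    def concat(self) -> np.ndarray:
        return np.concatenate(
            [self.intensity, self.glcm, self.gabor, self.wavelet, self.shape]
        )


def all_lowlevel(roi: LesionROI) -> LowLevelBlock:
    """All five groups of one ROI (5 + 16 + 48 + 12 + 12 = 93 values)."""
    return LowLevelBlock(
        intensity=intensity_features(roi),
        glcm=glcm_features(roi),
        gabor=gabor_features(roi),
        wavelet=wavelet_texture_features(roi),
        shape=shape_features(boundary_signature(roi.lesion_mask)),
    )


def lowlevel_feature(roi: LesionROI) -> "FeatureVector":
    """The 93-vector wrapped as an image-level :class:`~lesionbow.bow.FeatureVector`."""
    from .bow import FeatureVector

    return FeatureVector(
        values=all_lowlevel(roi).concat,
        provenance="lowlevel",
        level="image",
        patient_id=roi.patient_id,
        label=roi.label,
        phase=roi.phase,
    )


def feature_names() -> list[str]:
    """Names of the 93 features in canonical order (index i -> name of column f_i)."""
    names = ["intensity_mean", "intensity_sd", "intensity_entropy",
             "intensity_skewness", "intensity_kurtosis"]
    for stat in GLCM_STATS:
        names += [f"glcm_{stat}_{a}deg" for a in GLCM_ANGLES_DEG]
    for fi, freq in enumerate(GABOR_FREQUENCIES):
        for k in range(len(GABOR_ORIENTATIONS)):
            names += [f"gabor_f{fi}_o{k}_mean", f"gabor_f{fi}_o{k}_sd"]
    for level in range(TEXTURE_WAVELET_LEVELS, 0, -1):
        for band in ("H", "V"):
            names += [f"wavelet_L{level}{band}_absmean", f"wavelet_L{level}{band}_abssd"]
    for band in ["A5"] + [f"D{k}" for k in range(SHAPE_WAVELET_LEVELS, 0, -1)]:
        names += [f"shape_{band}_absmean", f"shape_{band}_absvar"]
    return names


def write_feature_name_manifest(path) -> None:
    """Write the index -> feature-name mapping as JSON."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({i: name for i, name in enumerate(feature_names())}, fh, indent=1)
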