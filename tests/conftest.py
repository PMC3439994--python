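import numpy as np
import pytest

from lesionbow import PhantomParams, generate_dataset
from lesionbow.partition import LesionROI, build_roi
from lesionbow.io import LesionMask, PhaseImage


@pytest.fixture(scope="session")
def phantom_manifest(tmp_path_factory):
    """Default phantom dataset (5 patients/class, seed 1), generated once."""
    out = tmp_path_factory.mktemp("phantom")
    return generate_dataset(PhantomParams(seed=1), out)


@pytest.fixture(scope="session")
def small_phantom_manifest(tmp_path_factory):
    """A smaller, faster phantom dataset for expensive end-to-end tests."""
    out = tmp_path_factory.mktemp("phantom_small")
    params = PhantomParams(
        n_patients_per_class=3,
        images_per_patient=(3, 4),
        lesion_radius_range=(6.0, 10.0),
        seed=2,
    )
    return generate_dataset(params, out)


def disk_mask(shape=(32, 32), center=(16, 16), radius=10):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (((yy - center[0]) ** 2 + (xx - center[1]) ** 2) <= radius**2).astype(np.uint8)


def make_roi(crop, lesion=None, s=3):
    """Build a LesionROI directly from arrays (labels: lesion region 1, rest parenchyma)."""
    crop = np.asarray(crop, dtype=np.uint8)
    labels = np.full(crop.shape, s + 1, dtype=np.int32)
    if lesion is None:
        labels[:] = 1
    else:
        labels[np.asarray(lesion, bool)] = 1
    return LesionROI(crop=crop, labels=labels, bbox=(0, crop.shape[0], 0, crop.shape[1]), s=s)


@pytest.fixture
def disk_roi():
    """A 32x32 ROI with a homogeneous disk lesion on darker parenchyma."""
    mask = disk_mask()
    rng = np.random.default_rng(5)
    crop = np.where(mask, 170.0, 110.0) + rng.normal(0, 4, mask.shape)
    image = PhaseImage(np.clip(crop, 0, 255).astype(np.uint8), phase="AP", patient_id="P1")
    return build_roi(image, LesionMask(mask), s=3, label="HCC")


def random_blob_mask(rng, shape=(20, 20)):
    """A random nonempty blob: thresholded smoothed noise, fallback to one pixel."""
    from scipy import ndimage

    noise = ndimage.gaussian_filter(rng.normal(size=shape), 2.0)
    mask = (noise > np.quantile(noise, 0.7)).astype(np.uint8)
    if not mask.any():
        mask[shape[0] // 2, shape[1] // 2] = 1
    return mask


def bfs_cityblock_oracle(mask):
    """Independent 4-neighbour breadth-first-search distance to background.

    The grid border counts as background; distances are exact L1 layer
    numbers (background itself is 0).
    """
    from collections import deque

    padded = np.pad(np.asarray(mask) != 0, 1)
    h, w = padded.shape
    dist = np.full((h, w), -1, dtype=int)
    queue = deque()
    for r in range(h):
        for c in range(w):
            if not padded[r, c]:
                dist[r, c] = 0
                queue.append((r, c))
    while queue:
        r, c = queue.popleft()
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and dist[rr, cc] == -1:
                dist[rr, cc] = dist[r, c] + 1
                queue.append((rr, cc))
    return dist[1:-1, 1:-1]
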