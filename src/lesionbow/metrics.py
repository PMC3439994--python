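"""Distance computation and learned linear projections.

Similarity between lesions is a distance between their feature vectors:
plain Manhattan (L1) or Euclidean (L2) in the raw feature space, or L2 in
a discriminatively learned linear subspace. Two learned projections are
provided:

* **RLDA** — regularized linear discriminant analysis. Because the
  feature dimension far exceeds the number M of training patients, the
  data are first reduced to M-1 principal components; the discriminant
  directions are then the leading generalized eigenvectors of the
  between-class scatter against the ridge-regularized within-class
  scatter ``S_w + alpha I`` (default ``alpha = 0.001``), keeping C-1
  directions for C classes.
* **LDP** — linear discriminant projections learned from pairwise sample
  differences: the leading generalized eigenvectors of the between-class
  difference covariance against the within-class difference covariance.
  No nearest-neighbor graph is needed, which keeps training fast.

Both learned fits z-score features with training statistics first; the
statistics are stored in the model so query-time transforms match.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from sklearn.decomposition import PCA

DEFAULT_RLDA_ALPHA = 0.001
DEFAULT_LDP_DIM = 64
LDP_MAX_PAIRS = 100_000


def l1_distance(x: np.ndarray, y: np.ndarray) -> float:
    """Manhattan distance: sum of absolute coordinate differences."""
    x, y = _check_pair(x, y)
    return float(np.abs(x - y).sum())


def l2_distance(x: np.ndarray, y: np.ndarray) -> float:
    """Euclidean distance."""
    x, y = _check_pair(x, y)
    return float(np.sqrt(((x - y) ** 2).sum()))


def _check_pair(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.shape != y.shape:
        raise ValueError(f"dimension mismatch: {x.shape[0]} vs {y.shape[0]}")
    return x, y


@dataclass
class ProjectionModel:
    """A fitted linear map applied before distance computation.

    ``transform`` computes ``((x - mean) / scale) @ matrix``; the identity
    model passes vectors through untouched (raw-space distances).
    """

    kind: str  # identity | pca | rlda | ldp
    mean: np.ndarray | None = None
    scale: np.ndarray | None = None
    matrix: np.ndarray | None = None  # (d_in, d_out)
    meta: dict = field(default_factory=dict)

    @property
    def output_dim(self) -> int | None:
        return None if self.matrix is None else self.matrix.shape[1]

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if self.kind == "identity":
            return X
        if self.matrix is not None and X.shape[1] != self.matrix.shape[0]:
            raise ValueError(
                f"input dimension {X.shape[1]} does not match model input "
                f"dimension {self.matrix.shape[0]}"
            )
        if self.mean is not None:
            X = X - self.mean
        if self.scale is not None:
            X = X / self.scale
        if self.matrix is not None:
            X = X @ self.matrix
        return X

    def save(self, path) -> None:
        np.savez(
            path,
            kind=self.kind,
            mean=self.mean if self.mean is not None else np.zeros(0),
            scale=self.scale if self.scale is not None else np.zeros(0),
            matrix=self.matrix if self.matrix is not None else np.zeros((0, 0)),
            **{f"meta_{k}": v for k, v in self.meta.items()},
        )

    @classmethod
    def load(cls, path) -> "ProjectionModel":
        data = np.load(path, allow_pickle=False)
        mean = data["mean"] if data["mean"].size else None
        scale = data["scale"] if data["scale"].size else None
        matrix = data["matrix"] if data["matrix"].size else None
        meta = {k[5:]: data[k].item() for k in data.files if k.startswith("meta_")}
        return cls(kind=str(data["kind"]), mean=mean, scale=scale, matrix=matrix, meta=meta)


@dataclass
class DistanceSpec:
    """A metric ('L1' or 'L2') paired with a projection model.

    Learned projections (rlda, ldp) always pair with L2 in the projected
    space.
    """

    metric: str
    model: ProjectionModel

    def __post_init__(self) -> None:
        if self.metric not in ("L1", "L2"):
            raise ValueError("metric must be 'L1' or 'L2'")
        if self.model.kind in ("rlda", "ldp") and self.metric != "L2":
            raise ValueError("learned projections pair with L2")


def identity_model() -> ProjectionModel:
    return ProjectionModel(kind="identity")


def _zscore_stats(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0  # constant features pass through centered
    return mean, scale


def _fix_signs(W: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-magnitude loading positive."""
    for j in range(W.shape[1]):
        k = int(np.argmax(np.abs(W[:, j])))
        if W[k, j] < 0:
            W[:, j] = -W[:, j]
    return W


def fit_pca(X: np.ndarray, n_components: int) -> ProjectionModel:
    """Centered PCA with orthonormal axes ordered by decreasing variance."""
    X = np.asarray(X, dtype=np.float64)
    M = X.shape[0]
    if n_components > min(M - 1, X.shape[1]):
        raise ValueError(
            f"n_components={n_components} exceeds min(M-1={M - 1}, dim={X.shape[1]})"
        )
    pca = PCA(n_components=n_components, svd_solver="full").fit(X)
    W = _fix_signs(pca.components_.T.copy())
    return ProjectionModel(
        kind="pca",
        mean=pca.mean_,
        scale=None,
        matrix=W,
        meta={"M": M, "explained_variance_ratio_sum": float(pca.explained_variance_ratio_.sum())},
    )


def _scatter_matrices(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Raw (unnormalized) within- and between-class scatter matrices."""
    overall = X.mean(axis=0)
    d = X.shape[1]
    Sw = np.zeros((d, d))
    Sb = np.zeros((d, d))
    for c in np.unique(y):
        Xc = X[y == c]
        mu = Xc.mean(axis=0)
        centered = Xc - mu
        Sw += centered.T @ centered
        diff = (mu - overall)[:, None]
        Sb += Xc.shape[0] * (diff @ diff.T)
    return Sw, Sb


def fit_rlda(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float = DEFAULT_RLDA_ALPHA,
    n_components: int | None = None,
) -> ProjectionModel:
    """Regularized LDA: z-score, PCA to M-1, then eigenvectors of (S_w + aI)^-1 S_b.

    Keeps the top C-1 directions (C classes) unless ``n_components`` asks
    for fewer. Deterministic: eigenvalues sorted descending, signs fixed.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("RLDA needs at least 2 classes")
    if counts.min() < 2:
        raise ValueError(f"class {classes[np.argmin(counts)]!r} has fewer than 2 samples")
    M = X.shape[0]
    mean, scale = _zscore_stats(X)
    Z = (X - mean) / scale
    n_pca = min(M - 1, X.shape[1])
    pca = PCA(n_components=n_pca, svd_solver="full").fit(Z)
    Zp = pca.transform(Z)
    Sw, Sb = _scatter_matrices(Zp, y)
    evals, evecs = linalg.eigh(Sb, Sw + alpha * np.eye(n_pca))
    order = np.argsort(evals)[::-1]
    k = len(classes) - 1 if n_components is None else min(n_components, len(classes) - 1)
    W = _fix_signs(pca.components_.T @ evecs[:, order[:k]])
    return ProjectionModel(
        kind="rlda",
        mean=mean,
        scale=scale,
        matrix=W,
        meta={"M": M, "alpha": alpha, "n_classes": len(classes)},
    )


def _difference_covariance(
    X: np.ndarray, pairs: np.ndarray
) -> np.ndarray:
    D = X[pairs[:, 0]] - X[pairs[:, 1]]
    return (D.T @ D) / pairs.shape[0]


def _sample_pairs(pairs: np.ndarray, max_pairs: int, rng: np.random.Generator) -> np.ndarray:
    if pairs.shape[0] <= max_pairs:
        return pairs
    idx = rng.choice(pairs.shape[0], size=max_pairs, replace=False)
    return pairs[np.sort(idx)]


def fit_ldp(
    X: np.ndarray,
    y: np.ndarray,
    out_dim: int | None = None,
    seed: int = 0,
    max_pairs: int = LDP_MAX_PAIRS,
) -> ProjectionModel:
    """Linear discriminant projections from sample-difference covariances.

    A = covariance of within-class differences, B = covariance of
    between-class differences (all pairs, or a seeded uniform sample when
    more than ``max_pairs`` of a kind exist); the projection is the top
    ``out_dim`` generalized eigenvectors of ``(A + eps I)^-1 B`` with
    ``eps = 1e-6 * trace(A) / dim``.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("LDP needs at least 2 classes")
    M, d = X.shape
    mean, scale = _zscore_stats(X)
    Z = (X - mean) / scale
    rng = np.random.default_rng(seed)
    i, j = np.triu_indices(M, k=1)
    same = y[i] == y[j]
    within = _sample_pairs(np.stack([i[same], j[same]], axis=1), max_pairs, rng)
    between = _sample_pairs(np.stack([i[~same], j[~same]], axis=1), max_pairs, rng)
    if within.shape[0] == 0 or between.shape[0] == 0:
        raise ValueError("LDP needs both within- and between-class pairs")
    A = _difference_covariance(Z, within)
    B = _difference_covariance(Z, between)
    eps = 1e-6 * np.trace(A) / d
    if not np.isfinite(eps) or eps <= 0:
        raise ValueError("degenerate within-class difference covariance")
    evals, evecs = linalg.eigh(B, A + eps * np.eye(d))
    if not np.all(np.isfinite(evals)):
        raise ValueError("LDP eigen-solution is not finite")
    order = np.argsort(evals)[::-1]
    k = min(DEFAULT_LDP_DIM if out_dim is None else out_dim, M - 1, d)
    W = _fix_signs(evecs[:, order[:k]].copy())
    return ProjectionModel(
        kind="ldp",
        mean=mean,
        scale=scale,
        matrix=W,
        meta={"M": M, "seed": seed, "eps": float(eps)},
    )


def metric_distance(spec: DistanceSpec, x: np.ndarray, y: np.ndarray) -> float:
    """Distance between two vectors in the (possibly projected) feature space."""
    px = spec.model.transform(x)[0]
    py = spec.model.transform(y)[0]
    return l1_distance(px, py) if spec.metric == "L1" else l2_distance(px, py)


def pairwise_distances(
    spec: DistanceSpec, queries: np.ndarray, database: np.ndarray
) -> np.ndarray:
    """Distance matrix (n_queries, n_database) under a distance spec."""
    Q = spec.model.transform(queries)
    D = spec.model.transform(database)
    diff = Q[:, None, :] - D[None, :, :]
    if spec.metric == "L1":
        return np.abs(diff).sum(axis=2)
    return np.sqrt((diff**2).sum(axis=2))


def make_distance_spec(
    method: str,
    X: np.ndarray | None = None,
    y: np.ndarray | None = None,
    alpha: float = DEFAULT_RLDA_ALPHA,
    out_dim: int | None = None,
    seed: int = 0,
) -> DistanceSpec:
    """Build the distance spec for one of the four methods: L1, L2, RLDA, LDP."""
    method = method.upper()
    if method == "L1":
        return DistanceSpec(metric="L1", model=identity_model())
    if method == "L2":
        return DistanceSpec(metric="L2", model=identity_model())
    if X is None or y is None:
        raise ValueError(f"{method} requires training features and labels")
    if method == "RLDA":
        return DistanceSpec(metric="L2", model=fit_rlda(X, y, alpha=alpha))
    if method == "LDP":
        return DistanceSpec(metric="L2", model=fit_ldp(X, y, out_dim=out_dim, seed=seed))
    raise ValueError(f"unknown metric method {method!r}")
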