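"""Patient-level retrieval and its cross-validated evaluation protocol.

The patient is the unit of query and retrieval: each test patient's
(phase-averaged) feature vector queries the database of training-fold
patients, rankings are scored by precision/recall over the same-disease
relevance relation, and results are aggregated over stratified K-fold
cross-validation. All fitting — codebook, projections, z-scoring — uses
training folds only.

Two conventions to note. P(n) is the mean over queries of the precision
after the top n patients are returned. MAP here is the mean of P(n) over
n = 1..T (T = database size), *not* the conventional
information-retrieval mean average precision: it averages precision at
every cutoff, so with R relevant patients in a database of T even a
perfect ranking scores (R + R * (H(T) - H(R))) / T < 1. Rankings should
be compared against that ceiling, not against 1.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import bow as _bow
from . import io as _io
from . import lowlevel as _lowlevel
from . import metrics as _metrics
from .bow import FeatureVector, PhaseSubsetEmpty
from .partition import build_roi

PHASE_SUBSETS = (
    ("AP",),
    ("PVP",),
    ("DP",),
    ("AP", "PVP"),
    ("PVP", "DP"),
    ("AP", "PVP", "DP"),
)


def parse_phases(text: str) -> tuple[str, ...]:
    """Parse 'AP,PVP' / 'AP+PVP' into a canonically ordered phase subset."""
    parts = [p.strip() for p in text.replace("+", ",").split(",") if p.strip()]
    unknown = [p for p in parts if p not in _io.PHASES]
    if unknown:
        raise ValueError(f"unknown phase tokens {unknown}; expected subset of {_io.PHASES}")
    return tuple(p for p in _io.PHASES if p in parts)


def kfold_split(
    patient_ids: list[str],
    labels: list[str],
    n_folds: int = 10,
    seed: int = 0,
) -> list[list[str]]:
    """Stratified, seeded split of patients into folds differing in size by <= 1.

    Within each class the (shuffled) patients are dealt to the currently
    smallest fold, so both overall fold sizes and per-class counts stay as
    even as possible.
    """
    ids = np.asarray(patient_ids)
    labs = np.asarray(labels)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate patient ids")
    if n_folds > len(ids):
        raise ValueError(f"cannot split {len(ids)} patients into {n_folds} folds")
    rng = np.random.default_rng(seed)
    folds: list[list[str]] = [[] for _ in range(n_folds)]
    for c in sorted(set(labs)):
        members = np.sort(ids[labs == c])
        rng.shuffle(members)
        for pid in members:
            sizes = [len(f) for f in folds]
            folds[int(np.argmin(sizes))].append(str(pid))
    return [sorted(f) for f in folds]


@dataclass
class RetrievalResult:
    """One query's ranking over the database (ascending distance)."""

    query_id: str
    query_label: str
    ranked_ids: list[str]
    ranked_labels: list[str]
    distances: np.ndarray

    @property
    def relevance(self) -> np.ndarray:
        return np.array([lab == self.query_label for lab in self.ranked_labels])


def rank_database(
    query: FeatureVector,
    database: list[FeatureVector],
    spec: _metrics.DistanceSpec,
) -> RetrievalResult:
    """Rank database patients by distance to the query; ties break lexicographically.

    Any database entry sharing the query's patient id is excluded.
    """
    entries = [f for f in database if f.patient_id != query.patient_id]
    if not entries:
        raise ValueError("empty database")
    X = np.stack([f.values for f in entries])
    dists = _metrics.pairwise_distances(spec, query.values[None, :], X)[0]
    order = sorted(range(len(entries)), key=lambda i: (dists[i], entries[i].patient_id))
    return RetrievalResult(
        query_id=query.patient_id,
        query_label=query.label,
        ranked_ids=[entries[i].patient_id for i in order],
        ranked_labels=[entries[i].label for i in order],
        distances=dists[order],
    )


def precision_at(result: RetrievalResult, n: int) -> float:
    """Fraction of the top-n ranked patients sharing the query's disease label."""
    T = len(result.ranked_ids)
    if not 1 <= n <= T:
        raise ValueError(f"n={n} outside 1..{T}")
    return float(result.relevance[:n].sum() / n)


def recall_at(result: RetrievalResult, n: int) -> float:
    """Fraction of all relevant database patients found in the top n."""
    T = len(result.ranked_ids)
    if not 1 <= n <= T:
        raise ValueError(f"n={n} outside 1..{T}")
    total = result.relevance.sum()
    return float(result.relevance[:n].sum() / total) if total else 0.0


def _precision_matrix(results: list[RetrievalResult]) -> np.ndarray:
    """(n_queries, T) matrix of per-query precision at every cutoff."""
    T = {len(r.ranked_ids) for r in results}
    if len(T) != 1:
        raise ValueError(f"results have inconsistent database sizes {sorted(T)}")
    T = T.pop()
    rel = np.stack([r.relevance for r in results]).astype(np.float64)
    return rel.cumsum(axis=1) / np.arange(1, T + 1)


def precision_profile(results: list[RetrievalResult]) -> np.ndarray:
    """P(n) for n = 1..T: per-cutoff precision averaged over queries."""
    return _precision_matrix(results).mean(axis=0)


def map_score(results: list[RetrievalResult]) -> float:
    """Mean of P(n) over n = 1..T (precision averaged over every cutoff)."""
    return float(precision_profile(results).mean())


def pr_curve(results: list[RetrievalResult]) -> np.ndarray:
    """(T, 2) points (mean recall(n), mean precision(n)), no interpolation."""
    prec = _precision_matrix(results)
    rel = np.stack([r.relevance for r in results]).astype(np.float64)
    totals = np.maximum(rel.sum(axis=1, keepdims=True), 1.0)
    recall = (rel.cumsum(axis=1) / totals).mean(axis=0)
    return np.stack([recall, prec.mean(axis=0)], axis=1)


@dataclass
class ExperimentConfig:
    """One cell of the evaluation grid."""

    feature: str = "regional_bow"  # regional_bow | lowlevel | combined
    phases: tuple[str, ...] = ("AP", "PVP", "DP")
    metric: str = "L2"  # L1 | L2 | RLDA | LDP
    s: int = 3
    codebook_size: int = 64
    n_folds: int = 10
    seed: int = 1
    patch_size: int = _bow.DEFAULT_PATCH_SIZE
    min_nonzero: int = _bow.DEFAULT_MIN_NONZERO
    max_codebook_samples: int = _bow.DEFAULT_MAX_TRAINING_SAMPLES
    rlda_alpha: float = _metrics.DEFAULT_RLDA_ALPHA
    ldp_dim: int | None = None

    def to_dict(self) -> dict:
        return {
            "feature": self.feature,
            "phases": "+".join(self.phases),
            "metric": self.metric,
            "s": self.s,
            "codebook_size": self.codebook_size,
            "n_folds": self.n_folds,
            "seed": self.seed,
        }


@dataclass
class EvalReport:
    """Aggregated retrieval metrics for one configuration."""

    config: ExperimentConfig
    p_at: np.ndarray  # P(n), n = 1..min fold database size
    map: float
    pr_points: np.ndarray
    per_fold: list[dict]
    n_queries: int

    def precision(self, n: int) -> float:
        if not 1 <= n <= len(self.p_at):
            raise ValueError(f"P({n}) undefined: database size is {len(self.p_at)}")
        return float(self.p_at[n - 1])

    def to_dict(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "map": self.map,
            "p_at": self.p_at.tolist(),
            "pr_points": self.pr_points.tolist(),
            "per_fold": self.per_fold,
            "n_queries": self.n_queries,
        }


def _load_rois(records, s: int):
    rois = []
    for rec in records:
        image = _io.load_image(rec)
        mask = _io.load_mask(rec, image)
        rois.append(build_roi(image, mask, s=s, label=rec.label))
    return rois


def run_experiment(manifest: str | Path | list, config: ExperimentConfig) -> EvalReport:
    """Run one cross-validated retrieval experiment on a manifest.

    Per fold: the codebook, any learned projection and all normalization
    statistics are fitted on training-fold patients only; every test-fold
    patient then queries the training-fold patient database. Reports
    aggregate P(n) (up to the smallest fold database size), the per-fold
    MAP mean, and the precision-recall curve.
    """
    records = manifest if isinstance(manifest, list) else _io.read_manifest(manifest)
    records = [r for r in records if r.phase in config.phases]
    if not records:
        raise ValueError(f"manifest has no image in phases {config.phases}")
    by_patient = _io.group_by_patient(records)
    patient_ids = sorted(by_patient)
    patient_labels = {pid: recs[0].label for pid, recs in by_patient.items()}

    rois = {pid: _load_rois(recs, config.s) for pid, recs in by_patient.items()}
    lowlevel_imgfeats: dict[str, list[FeatureVector]] = {}
    if config.feature in ("lowlevel", "combined"):
        lowlevel_imgfeats = {
            pid: [_lowlevel.lowlevel_feature(roi) for roi in rois[pid]] for pid in patient_ids
        }

    folds = kfold_split(
        patient_ids,
        [patient_labels[p] for p in patient_ids],
        n_folds=config.n_folds,
        seed=config.seed,
    )

    all_results: list[RetrievalResult] = []
    per_fold: list[dict] = []
    for fold_idx, test_patients in enumerate(folds):
        train_patients = sorted(set(patient_ids) - set(test_patients))
        blocks: dict[str, dict[str, FeatureVector]] = {}

        if config.feature in ("regional_bow", "combined"):
            pool = [
                _bow.filter_patches(
                    _bow.extract_patches(roi, config.patch_size), config.min_nonzero
                ).descriptors
                for pid in train_patients
                for roi in rois[pid]
            ]
            codebook = _bow.train_codebook(
                np.concatenate(pool),
                n_words=config.codebook_size,
                seed=config.seed * 1009 + fold_idx,
                max_samples=config.max_codebook_samples,
            )
            blocks["regional_bow"] = {
                pid: _bow.patient_feature(
                    [
                        _bow.bow_feature(roi, codebook, config.patch_size, config.min_nonzero)
                        for roi in rois[pid]
                    ],
                    config.phases,
                )
                for pid in patient_ids
            }
        if config.feature in ("lowlevel", "combined"):
            blocks["lowlevel"] = {
                pid: _bow.patient_feature(lowlevel_imgfeats[pid], config.phases)
                for pid in patient_ids
            }

        feats = _assemble_features(blocks, config.feature, train_patients, patient_ids)
        X_train = np.stack([feats[p].values for p in train_patients])
        y_train = np.array([patient_labels[p] for p in train_patients])
        spec = _metrics.make_distance_spec(
            config.metric,
            X_train,
            y_train,
            alpha=config.rlda_alpha,
            out_dim=config.ldp_dim,
            seed=config.seed * 1013 + fold_idx,
        )

        database = [feats[p] for p in train_patients]
        fold_results = [rank_database(feats[p], database, spec) for p in test_patients]
        fold_map = map_score(fold_results)
        profile = precision_profile(fold_results)
        per_fold.append(
            {
                "fold": fold_idx,
                "train_patients": train_patients,
                "test_patients": list(test_patients),
                "db_size": len(train_patients),
                "map": fold_map,
                "p10": float(profile[9]) if len(profile) >= 10 else None,
                "p20": float(profile[19]) if len(profile) >= 20 else None,
            }
        )
        all_results.extend(fold_results)

    # folds can differ in database size by one; aggregate P(n) up to the smallest
    min_T = min(len(r.ranked_ids) for r in all_results)
    rel = np.stack([r.relevance[:min_T] for r in all_results]).astype(np.float64)
    prec = rel.cumsum(axis=1) / np.arange(1, min_T + 1)
    totals = np.array([max(r.relevance.sum(), 1.0) for r in all_results])[:, None]
    recall = (rel.cumsum(axis=1) / totals).mean(axis=0)
    return EvalReport(
        config=config,
        p_at=prec.mean(axis=0),
        map=float(np.mean([f["map"] for f in per_fold])),
        pr_points=np.stack([recall, prec.mean(axis=0)], axis=1),
        per_fold=per_fold,
        n_queries=len(all_results),
    )


def _assemble_features(blocks, feature_kind, train_patients, patient_ids):
    """Single- or z-scored-concatenated-block patient features."""
    if feature_kind in ("regional_bow", "lowlevel"):
        return blocks[feature_kind]
    if feature_kind != "combined":
        raise ValueError(f"unknown feature kind {feature_kind!r}")
    scaled: dict[str, np.ndarray] = {pid: np.zeros(0) for pid in patient_ids}
    for name in ("regional_bow", "lowlevel"):
        train = np.stack([blocks[name][p].values for p in train_patients])
        mean = train.mean(axis=0)
        sd = train.std(axis=0)
        sd[sd == 0] = 1.0
        for pid in patient_ids:
            z = (blocks[name][pid].values - mean) / sd
            scaled[pid] = np.concatenate([scaled[pid], z])
    out = {}
    for pid in patient_ids:
        proto = blocks["regional_bow"][pid]
        out[pid] = FeatureVector(
            values=scaled[pid],
            provenance="combined",
            level="patient",
            patient_id=pid,
            label=proto.label,
            phase_subset=proto.phase_subset,
        )
    return out


def sweep(manifest: str | Path | list, grid: dict, base: ExperimentConfig | None = None) -> pd.DataFrame:
    """Run a grid of configurations and return one tidy row per cell.

    ``grid`` maps ExperimentConfig field names (e.g. ``s``,
    ``codebook_size``, ``metric``, ``phases``, ``feature``) to lists of
    values. Rows carry the full configuration plus MAP and P(5)/P(10)/P(20)
    where defined.
    """
    base = base or ExperimentConfig()
    keys = sorted(grid)
    rows = []
    for combo in itertools.product(*(grid[k] for k in keys)):
        config = replace(base, **dict(zip(keys, combo)))
        report = run_experiment(manifest, config)
        row = config.to_dict()
        row["map"] = report.map
        for n in (5, 10, 20):
            row[f"p{n}"] = report.precision(n) if len(report.p_at) >= n else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def save_features(features: list[FeatureVector], path: str | Path) -> Path:
    """Write features as CSV with columns patient_id, label, f0..f{d-1}."""
    dims = {f.dimension for f in features}
    if len(dims) != 1:
        raise ValueError("features must share one dimension")
    d = dims.pop()
    df = pd.DataFrame(
        np.stack([f.values for f in features]), columns=[f"f{i}" for i in range(d)]
    )
    df.insert(0, "label", [f.label for f in features])
    df.insert(0, "patient_id", [f.patient_id for f in features])
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def load_features(
    path: str | Path, provenance: str = "regional_bow", level: str = "patient"
) -> list[FeatureVector]:
    """Read a feature CSV written by :func:`save_features`."""
    df = pd.read_csv(path)
    cols = [c for c in df.columns if c.startswith("f")]
    return [
        FeatureVector(
            values=row[cols].to_numpy(dtype=np.float64),
            provenance=provenance,
            level=level,
            patient_id=str(row["patient_id"]),
            label=str(row["label"]),
        )
        for _, row in df.iterrows()
    ]
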