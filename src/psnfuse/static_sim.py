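"""Static patient similarity: per-feature scores, weighted aggregation, metrics.

The static channel scores each pair of patients feature by feature — an age
ratio for ages, exact match for categorical/Boolean fields, cosine over
one-hot encodings for free text — and aggregates the per-feature scores into
a single static patient similarity (STPS) as a weighted sum with weights
summing to one.

Also houses the five geometric distance measures used throughout the
pipeline (euclidean, manhattan, cosine, chebyshev, weighted manhattan) and
the bounded distance-to-similarity conversion s = 1/(1+d).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .cohort import SimilarityMatrix, StaticCohort
from .text import Vocabulary, fit_vocabulary, text_field_similarity

FeatureKind = Literal["age_ratio", "exact_match", "text_onehot", "numeric_passthrough"]

_METRICS = ("euclidean", "manhattan", "cosine", "chebyshev", "weighted_manhattan")


@dataclass
class FeatureSpec:
    """Similarity rule and weight for one static feature."""

    name: str
    kind: FeatureKind
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValueError(f"feature {self.name!r}: weight must be >= 0")
        if self.kind not in ("age_ratio", "exact_match", "text_onehot", "numeric_passthrough"):
            raise ValueError(f"feature {self.name!r}: unknown kind {self.kind!r}")


@dataclass
class DistanceMetric:
    """Named geometric distance, optionally with per-dimension weights."""

    name: str
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.name not in _METRICS:
            raise ValueError(f"unknown metric {self.name!r}; choose from {_METRICS}")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)


def normalize_weights(weights: Sequence[float]) -> np.ndarray:
    """Rescale feature weights to sum to 1 (required for STPS aggregation)."""
    w = np.asarray(weights, dtype=float)
    if (w < 0).any():
        raise ValueError("weights must be nonnegative")
    total = w.sum()
    if total <= 0:
        raise ValueError("weights sum to zero")
    return w / total


# ---------------------------------------------------------------------------
# Per-feature similarity functions
# ---------------------------------------------------------------------------

def age_similarity(age_i: float, age_j: float) -> float:
    """Similarity of two ages as the ratio of the smaller to the larger.

    Equal ages (including both zero) score 1.0; an age of zero against a
    positive age scores 0.0. Negative ages are rejected.
    """
    if age_i < 0 or age_j < 0:
        raise ValueError(f"ages must be nonnegative, got ({age_i}, {age_j})")
    if age_i == age_j:
        return 1.0
    return min(age_i, age_j) / max(age_i, age_j)


def match_similarity(v_i, v_j) -> int:
    """1 if the two categorical/Boolean values are equal, else 0."""
    return int(v_i == v_j)


def weighted_score(feature_scores: Sequence[float], weights: Sequence[float]) -> float:
    """Weighted sum of per-feature scores: the STPS aggregation.

    With weights summing to 1 and scores in [0, 1] this is the global static
    patient similarity; with raw option scores (e.g. a 1–4 prioritization
    grid) it is the weighted-scoring prioritization total. Weights are used
    as given — callers wanting the normalized STPS form pass them through
    :func:`normalize_weights` first.
    """
    s = np.asarray(feature_scores, dtype=float)
    w = np.asarray(weights, dtype=float)
    if s.shape != w.shape:
        raise ValueError(f"length mismatch: {s.shape} scores vs {w.shape} weights")
    return float(s @ w)


# ---------------------------------------------------------------------------
# STPS matrix construction
# ---------------------------------------------------------------------------

def _feature_similarity_matrix(cohort: StaticCohort, spec: FeatureSpec) -> np.ndarray:
    """N x N similarity for a single feature under its declared rule."""
    n = cohort.n_patients
    col = cohort.column(spec.name)

    if spec.kind == "age_ratio":
        ages = col.to_numpy(dtype=float)
        filled = np.where(np.isnan(ages), np.nanmean(ages), ages)
        if (filled < 0).any():
            raise ValueError(f"feature {spec.name!r}: negative ages")
        lo = np.minimum.outer(filled, filled)
        hi = np.maximum.outer(filled, filled)
        with np.errstate(invalid="ignore", divide="ignore"):
            m = np.where(hi > 0, lo / np.where(hi > 0, hi, 1.0), 1.0)
        np.fill_diagonal(m, 1.0)
        return m

    if spec.kind == "exact_match":
        vals = col.to_numpy(dtype=object)
        missing = np.array([v is None or v != v for v in vals])  # NaN-safe
        eq = (vals[:, None] == vals[None, :]).astype(float)
        # a missing value on either side is treated as a non-match off-diagonal
        eq[missing, :] = 0.0
        eq[:, missing] = 0.0
        np.fill_diagonal(eq, 1.0)
        return eq

    if spec.kind == "text_onehot":
        texts = ["" if v != v or v is None else str(v) for v in col.tolist()]
        vocab = fit_vocabulary(texts)
        enc = np.vstack([vocab.encode(t) for t in texts]).astype(float)
        norms = np.linalg.norm(enc, axis=1)
        sim = np.zeros((n, n))
        nz = norms > 0
        if nz.any():
            e = enc[nz] / norms[nz, None]
            sim[np.ix_(nz, nz)] = e @ e.T
        # two empty encodings are maximally similar (both symptom-free)
        both_empty = np.outer(~nz, ~nz)
        sim[both_empty] = 1.0
        np.fill_diagonal(sim, 1.0)
        return np.clip(sim, 0.0, 1.0)

    if spec.kind == "numeric_passthrough":
        vals = col.to_numpy(dtype=float)
        filled = np.where(np.isnan(vals), np.nanmean(vals), vals)
        d = np.abs(filled[:, None] - filled[None, :])
        return 1.0 / (1.0 + d)

    raise AssertionError(spec.kind)


def static_similarity_matrix(cohort: StaticCohort, specs: Sequence[FeatureSpec]) -> SimilarityMatrix:
    """Build the STPS matrix: weighted sum of per-feature similarity matrices.

    Feature weights are normalized to sum to 1, so entries lie in [0, 1]
    with a unit diagonal; the matrix is symmetric by construction.
    """
    if not specs:
        raise ValueError("at least one feature spec is required")
    for spec in specs:
        if spec.name not in cohort.data.columns:
            raise ValueError(f"feature {spec.name!r} not in cohort")
    w = normalize_weights([s.weight for s in specs])
    acc = np.zeros((cohort.n_patients, cohort.n_patients))
    for spec, wk in zip(specs, w):
        acc += wk * _feature_similarity_matrix(cohort, spec)
    acc = (acc + acc.T) / 2.0  # guard against tiny float asymmetry
    np.fill_diagonal(acc, 1.0)
    return SimilarityMatrix(acc, list(cohort.patient_ids), "similarity")


# ---------------------------------------------------------------------------
# Geometric distances
# ---------------------------------------------------------------------------

def pairwise_distance(x: Sequence[float], y: Sequence[float], metric: DistanceMetric) -> float:
    """Distance between two numeric vectors under the named metric."""
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape:
        raise ValueError(f"length mismatch: {xv.shape} vs {yv.shape}")
    name = metric.name
    if name == "euclidean":
        return float(np.linalg.norm(xv - yv))
    if name == "manhattan":
        return float(np.abs(xv - yv).sum())
    if name == "chebyshev":
        return float(np.abs(xv - yv).max()) if xv.size else 0.0
    if name == "cosine":
        nx, ny = np.linalg.norm(xv), np.linalg.norm(yv)
        if nx == 0 and ny == 0:
            warnings.warn("cosine distance of two zero vectors defined as 0")
            return 0.0
        if nx == 0 or ny == 0:
            return 1.0
        return float(1.0 - np.clip(xv @ yv / (nx * ny), -1.0, 1.0))
    if name == "weighted_manhattan":
        if metric.weights is None:
            raise ValueError("weighted_manhattan requires a weight vector")
        w = metric.weights
        if w.shape != xv.shape:
            raise ValueError(f"weight length {w.shape} != vector length {xv.shape}")
        return float((w * np.abs(xv - yv)).sum())
    raise AssertionError(name)


def pairwise_distance_matrix(
    vectors: np.ndarray, ids: Sequence[str], metric: DistanceMetric
) -> SimilarityMatrix:
    """All-pairs distances between row vectors, as a distance-tagged matrix."""
    v = np.asarray(vectors, dtype=float)
    name = metric.name
    if name == "weighted_manhattan":
        if metric.weights is None:
            raise ValueError("weighted_manhattan requires a weight vector")
        d = cdist(v, v, metric="minkowski", p=1.0, w=np.abs(metric.weights))
    elif name == "manhattan":
        d = cdist(v, v, metric="cityblock")
    elif name == "cosine":
        norms = np.linalg.norm(v, axis=1)
        d = np.zeros((len(v), len(v)))
        nz = norms > 0
        if nz.any():
            e = v[nz] / norms[nz, None]
            cos = np.clip(e @ e.T, -1.0, 1.0)
            d[np.ix_(nz, nz)] = 1.0 - cos
        d[np.ix_(nz, ~nz)] = 1.0
        d[np.ix_(~nz, nz)] = 1.0
    else:
        d = cdist(v, v, metric=name)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return SimilarityMatrix(np.maximum(d, 0.0), list(ids), "distance")


def distance_matrix_to_similarity(
    d: SimilarityMatrix, kernel: Literal["inverse", "gaussian"] = "inverse"
) -> SimilarityMatrix:
    """Convert a distance matrix to a similarity matrix.

    ``inverse`` (default): s = 1/(1+d) — bounded in (0, 1], monotone,
    parameter-free. ``gaussian``: s = exp(-d^2 / sigma^2) with sigma the
    median off-diagonal distance, an SNF-style kernel.
    """
    vals = d.values
    if (vals < 0).any():
        raise ValueError("distances must be nonnegative")
    if kernel == "inverse":
        s = 1.0 / (1.0 + vals)
    elif kernel == "gaussian":
        off = vals[~np.eye(d.n, dtype=bool)]
        sigma = np.median(off) if off.size and np.median(off) > 0 else 1.0
        s = np.exp(-(vals**2) / sigma**2)
    else:
        raise ValueError(f"unknown kernel {kernel!r}")
    np.fill_diagonal(s, 1.0)
    return SimilarityMatrix(s, list(d.patient_ids), "similarity")
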