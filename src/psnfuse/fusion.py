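"""Pairwise similarity network fusion of static and dynamic PSNs.

The fusion pipeline: row-normalize each input matrix to row-stochastic form,
symmetrize (W + W^T)/2, sparsify each row to its K strongest links with the
kept weights renormalized (KNN localization), then iterate the coupled
pairwise weighted-average recursion

    MP1_{t+1} = (wts * S' + (1 - wts) * MP2_t) / 2
    MP2_{t+1} = (wtd * D' + (1 - wtd) * MP1_t) / 2

for T rounds, and output FM = (MP1_T + MP2_T) / 2. The recursion is affine
and strictly contractive (two-step contraction factor (1-wts)(1-wtd)/4 < 1),
so it has a unique elementwise fixed point, exposed analytically by
:func:`snf_fixed_point` as an exact oracle for the iteration. Because the
averaging shrinks absolute values, fused entries are meaningful ordinally
(as a ranking of pairs), not as calibrated similarities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .cohort import SimilarityMatrix


@dataclass
class FusionConfig:
    """Parameters of the fusion: neighbors K, rounds T, channel weights.

    ``wts``/``wtd`` weight how strongly each recursion leans on its own
    localized matrix versus the other channel's evolving state. ``mode``
    "converge" stops early once the largest elementwise change drops below
    ``tolerance``.
    """

    K: int = 5
    T: int = 20
    wts: float = 0.5
    wtd: float = 0.5
    neighbor_source: Literal["self", "union"] = "self"
    mode: Literal["fixed", "converge"] = "fixed"
    tolerance: float = 1e-9
    initialization: Literal["raw", "localized"] = "raw"

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.T < 1:
            raise ValueError("T must be >= 1")
        for name in ("wts", "wtd"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


def row_normalize(m: SimilarityMatrix) -> SimilarityMatrix:
    """Divide each row by its sum so every row sums to 1.

    All-zero rows (a patient with no remaining links) become uniform rows,
    with a warning, so downstream iterations stay finite.
    """
    vals = m.values
    if (vals < 0).any():
        raise ValueError("row_normalize requires nonnegative entries")
    sums = vals.sum(axis=1, keepdims=True)
    zero = sums[:, 0] == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} all-zero row(s) replaced by uniform rows")
    out = np.where(sums > 0, vals / np.where(sums > 0, sums, 1.0), 1.0 / m.n)
    return m.with_values(out)


def symmetrize(m: SimilarityMatrix) -> SimilarityMatrix:
    """(W + W^T) / 2 — exactly symmetric output, idempotent."""
    return m.with_values((m.values + m.values.T) / 2.0)


def knn_localize(m: SimilarityMatrix, k: int, reference: SimilarityMatrix | None = None) -> SimilarityMatrix:
    """Keep each row's K strongest off-diagonal links, renormalized to sum 1.

    Neighbors are ranked by ``reference`` if given (e.g. a combined static +
    dynamic view), else by ``m`` itself; kept weights always come from ``m``.
    The diagonal is excluded from neighbor candidacy and zeroed. Ties at the
    K-th neighbor break toward the lower patient index. The output rows are
    renormalized over the kept entries only, so the result is generally
    asymmetric.
    """
    n = m.n
    if k >= n:
        raise ValueError(f"K={k} must be < number of patients {n}")
    rank_vals = (reference.values if reference is not None else m.values).copy()
    np.fill_diagonal(rank_vals, -np.inf)
    # argsort descending, stable: equal weights keep ascending index order
    order = np.argsort(-rank_vals, axis=1, kind="stable")
    keep = order[:, :k]
    out = np.zeros_like(m.values)
    rows = np.repeat(np.arange(n), k)
    cols = keep.ravel()
    out[rows, cols] = m.values[rows, cols]
    sums = out.sum(axis=1, keepdims=True)
    zero = sums[:, 0] == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} row(s) with zero kept weight; uniform fallback")
        zi = np.flatnonzero(zero)
        out[zi] = 1.0 / (n - 1)
        out[zi, zi] = 0.0
        sums = out.sum(axis=1, keepdims=True)
    out = out / sums
    return m.with_values(out)


def _prepare(s: SimilarityMatrix, d: SimilarityMatrix, cfg: FusionConfig):
    if s.patient_ids != d.patient_ids:
        raise ValueError("static and dynamic matrices index different patients")
    s_ns = symmetrize(row_normalize(s))
    d_ns = symmetrize(row_normalize(d))
    if cfg.neighbor_source == "union":
        ref = s_ns.with_values((s_ns.values + d_ns.values) / 2.0)
        s_loc = knn_localize(s_ns, cfg.K, reference=ref)
        d_loc = knn_localize(d_ns, cfg.K, reference=ref)
    else:
        s_loc = knn_localize(s_ns, cfg.K)
        d_loc = knn_localize(d_ns, cfg.K)
    return s_ns, d_ns, s_loc, d_loc


def snf_fuse(s: SimilarityMatrix, d: SimilarityMatrix, cfg: FusionConfig) -> SimilarityMatrix:
    """Fuse static and dynamic similarity matrices into one PSN matrix.

    Returns FM = (MP1_T + MP2_T)/2, symmetrized. The initial states MP0 are
    the normalized-symmetrized (pre-localization) matrices by default;
    ``cfg.initialization="localized"`` starts from the localized ones
    instead. In ``converge`` mode the loop stops early once the largest
    elementwise change in either state falls below ``cfg.tolerance``; the
    number of rounds actually run is stored on the result as
    ``fm.n_iterations``.
    """
    s_ns, d_ns, s_loc, d_loc = _prepare(s, d, cfg)
    if cfg.initialization == "raw":
        mp1, mp2 = s_ns.values.copy(), d_ns.values.copy()
    else:
        mp1, mp2 = s_loc.values.copy(), d_loc.values.copy()
    sp, dp = s_loc.values, d_loc.values
    ran = 0
    for _ in range(cfg.T):
        new1 = (cfg.wts * sp + (1.0 - cfg.wts) * mp2) / 2.0
        new2 = (cfg.wtd * dp + (1.0 - cfg.wtd) * mp1) / 2.0
        delta = max(np.abs(new1 - mp1).max(), np.abs(new2 - mp2).max())
        mp1, mp2 = new1, new2
        ran += 1
        if cfg.mode == "converge" and delta < cfg.tolerance:
            break
    fm = (mp1 + mp2) / 2.0
    fm = (fm + fm.T) / 2.0
    result = SimilarityMatrix(np.maximum(fm, 0.0), list(s.patient_ids), "similarity")
    result.n_iterations = ran
    return result


def snf_fixed_point(s: SimilarityMatrix, d: SimilarityMatrix, cfg: FusionConfig) -> SimilarityMatrix:
    """Analytic fixed point of the fusion recursion (exact oracle).

    Solves elementwise  p = (wts*S' + (1-wts)*q)/2,  q = (wtd*D' + (1-wtd)*p)/2
    and returns FM* = (p + q)/2, where S'/D' are the localized matrices the
    iteration uses. The coupling factor (1-wts)(1-wtd)/4 is < 1 for any
    weights in [0, 1], so the solution is unique.
    """
    _, _, s_loc, d_loc = _prepare(s, d, cfg)
    a, b = cfg.wts, cfg.wtd
    sp, dp = s_loc.values, d_loc.values
    coupling = (1.0 - a) * (1.0 - b) / 4.0
    p = (a * sp / 2.0 + (1.0 - a) * b * dp / 4.0) / (1.0 - coupling)
    q = (b * dp + (1.0 - b) * p) / 2.0
    fm = (p + q) / 2.0
    fm = (fm + fm.T) / 2.0
    return SimilarityMatrix(np.maximum(fm, 0.0), list(s.patient_ids), "similarity")


def original_snf(s: SimilarityMatrix, d: SimilarityMatrix, cfg: FusionConfig) -> SimilarityMatrix:
    """Classic message-passing SNF (P_v <- S_v P_other S_v^T), as a labeled
    comparison baseline only; the package's fusion operator is :func:`snf_fuse`."""
    s_ns, d_ns, s_loc, d_loc = _prepare(s, d, cfg)
    p1, p2 = s_ns.values.copy(), d_ns.values.copy()
    for _ in range(cfg.T):
        new1 = s_loc.values @ p2 @ s_loc.values.T
        new2 = d_loc.values @ p1 @ d_loc.values.T
        p1 = (new1 + new1.T) / 2.0
        p2 = (new2 + new2.T) / 2.0
    fm = (p1 + p2) / 2.0
    return SimilarityMatrix(np.maximum(fm, 0.0), list(s.patient_ids), "similarity")
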