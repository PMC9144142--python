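"""End-to-end drivers tying the stages together.

These are the functions the CLI and the reproduction script call: build the
static PSN from a cohort, the dynamic PSN from visit sequences via the
autoencoder, fuse the two, and score any of the three matrices by
cross-validated patient-KNN outcome prediction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autoencoder import (
    AutoencoderConfig,
    LSTMAutoencoder,
    PatientEmbedding,
    dynamic_similarity_matrix,
    embed_patients,
    train_autoencoder,
)
from .cohort import SimilarityMatrix, StaticCohort, VisitSequences
from .evaluation import EvalProtocol, crossvalidate, cv_summary
from .fusion import FusionConfig, snf_fuse
from .static_sim import DistanceMetric, FeatureSpec, static_similarity_matrix


def default_static_specs(cohort: StaticCohort) -> list[FeatureSpec]:
    """Reasonable per-column similarity rules inferred from declared kinds.

    Ages get the min/max ratio rule, Boolean/categorical fields exact match,
    text fields one-hot cosine; weights are uniform before normalization.
    """
    kind_map = {
        "numeric": "numeric_passthrough",
        "boolean": "exact_match",
        "categorical": "exact_match",
        "text": "text_onehot",
    }
    specs = []
    for name, kind in cohort.column_kinds.items():
        fk = "age_ratio" if (kind == "numeric" and "age" in name.lower()) else kind_map[kind]
        specs.append(FeatureSpec(name, fk, 1.0))
    return specs


def build_static_psn(cohort: StaticCohort, specs=None) -> SimilarityMatrix:
    return static_similarity_matrix(cohort, specs or default_static_specs(cohort))


def build_dynamic_psn(
    seqs: VisitSequences,
    cfg: AutoencoderConfig | None = None,
    metric: DistanceMetric | None = None,
) -> tuple[SimilarityMatrix, LSTMAutoencoder, PatientEmbedding]:
    cfg = cfg or AutoencoderConfig(n_features=seqs.width)
    model = train_autoencoder(seqs, cfg)
    emb = embed_patients(seqs, model)
    return dynamic_similarity_matrix(emb, metric), model, emb


def fuse_psns(stm: SimilarityMatrix, dsm: SimilarityMatrix, cfg: FusionConfig | None = None) -> SimilarityMatrix:
    return snf_fuse(stm, dsm, cfg or FusionConfig())


def knn_cv_accuracy(
    m: SimilarityMatrix,
    outcomes,
    k: int = 5,
    folds: int = 5,
    seed: int = 0,
    p_percent: float | None = None,
) -> tuple[float, float]:
    """Mean and std of 5-fold patient-KNN accuracy for a similarity matrix."""
    protocol = EvalProtocol(mode="patient_knn", folds=folds, seed=seed)
    res = crossvalidate(
        m,
        np.asarray(outcomes, dtype=object),
        protocol,
        k=None if p_percent is not None else k,
        p_percent=p_percent,
    )
    return cv_summary(res, "accuracy")
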