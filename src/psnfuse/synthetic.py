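"""Synthetic cohort generation with controllable outcome signal.

Two generators emulate the shapes of the data the pipeline targets, so every
stage is testable without any external download:

* :func:`make_static_cohort` — a line-list style static cohort (default 155
  patients, 4 outcome classes): age, gender, Boolean chronic-disease flag,
  and free-text symptom / chronic-disease / additional-information fields.
* :func:`make_longitudinal_cohort` — a cardiovascular-cohort style dataset
  (binary outcome): a small static profile plus 2-10 visits per patient of
  9 numeric measurements (bmi, sbp, dbp, chol, hdl, ldl, trig, and the
  derived non_hdl = chol - hdl and chol_hdl_ratio = chol / hdl), generated
  from a low-dimensional latent trajectory whose level and drift depend on
  the outcome class.

Outcomes are drawn first and features generated conditionally on them, so
the signal strengths ``beta_static`` and ``beta_dynamic`` in [0, 1] have a
clean operational meaning: 0 removes all class information from that channel
(features are pure noise with respect to the outcome) and 1 maximizes the
class-conditional effect sizes. All randomness flows through one seeded
generator; a recipe fully determines its cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import StaticCohort, VisitSequences

STATIC_OUTCOMES_4 = ["death", "discharged", "recovered", "stable"]
VISIT_FEATURES = [
    "bmi", "sbp", "dbp", "chol", "hdl", "ldl", "trig", "non_hdl", "chol_hdl_ratio",
]

# symptom token pools for the text fields
_SYMPTOMS = [
    "fever", "cough", "fatigue", "headache", "dyspnea", "myalgia", "anosmia",
    "nausea", "diarrhea", "sorethroat", "chills", "congestion", "dizziness",
    "chestpain", "sweating", "rash",
]
_CHRONIC = [
    "diabetes", "hypertension", "copd", "asthma", "ckd", "cad",
    "obesity", "stroke", "cancer", "arrhythmia", "hepatitis", "dementia",
]


@dataclass
class CohortRecipe:
    """Knobs of the synthetic generators; the seed fully determines output."""

    n_patients: int = 155
    n_classes: int = 4
    class_proportions: Sequence[float] | None = None
    beta_static: float = 0.5
    beta_dynamic: float = 0.5
    latent_dim: int = 3
    visit_min: int = 2
    visit_max: int = 10
    noise_scale: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 10:
            raise ValueError("n_patients must be >= 10")
        for name in ("beta_static", "beta_dynamic"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.class_proportions is not None:
            p = np.asarray(self.class_proportions, dtype=float)
            if len(p) != self.n_classes or abs(p.sum() - 1.0) > 1e-9 or (p < 0).any():
                raise ValueError("class_proportions must be a simplex vector of length n_classes")

    def proportions(self) -> np.ndarray:
        if self.class_proportions is None:
            return np.full(self.n_classes, 1.0 / self.n_classes)
        return np.asarray(self.class_proportions, dtype=float)


def _draw_outcomes(recipe: CohortRecipe, rng: np.random.Generator) -> np.ndarray:
    return rng.choice(recipe.n_classes, size=recipe.n_patients, p=recipe.proportions())


def _biased_flag(classes: np.ndarray, beta: float, signs: np.ndarray, rng) -> np.ndarray:
    """Class-biased Bernoulli flag: p = 0.5 + 0.45*beta*sign(class)."""
    p = np.clip(0.5 + 0.45 * beta * signs[classes], 0.02, 0.98)
    return rng.random(classes.size) < p


def _class_tokens(pool: list[str], n_classes: int) -> list[list[str]]:
    """Disjoint per-class preferred token sets carved from a pool."""
    per = len(pool) // n_classes
    return [pool[c * per : (c + 1) * per] for c in range(n_classes)]


def _text_field(classes, beta, pool, rng, n_tokens_range=(1, 4)) -> list[str]:
    """Comma-joined tokens; each token comes from the patient's class set with
    probability beta, else from the whole pool."""
    sets = _class_tokens(pool, int(classes.max()) + 1)
    out = []
    for c in classes:
        k = rng.integers(n_tokens_range[0], n_tokens_range[1] + 1)
        toks = []
        for _ in range(k):
            src = sets[c] if rng.random() < beta else pool
            toks.append(src[rng.integers(len(src))])
        out.append(", ".join(sorted(set(toks))))
    return out


def make_static_cohort(recipe: CohortRecipe) -> StaticCohort:
    """Line-list style static cohort with a multi-class outcome.

    Ages are Uniform(18, 90) shifted apart by class in proportion to
    ``beta_static`` (about 18 years between adjacent classes at beta = 1);
    gender is an unbiased coin (pure noise); the Boolean chronic flag and
    all three text fields are class-biased by ``beta_static``.
    """
    rng = np.random.default_rng(recipe.seed)
    classes = _draw_outcomes(recipe, rng)
    n, nc = recipe.n_patients, recipe.n_classes

    ids = [f"P{i:04d}" for i in range(n)]
    centered = classes - (nc - 1) / 2.0
    ages = np.clip(rng.uniform(18, 90, n) + recipe.beta_static * 18.0 * centered, 18, 90)
    gender = np.where(rng.random(n) < 0.5, "female", "male")
    signs = np.where(np.arange(nc) % 2 == 0, 1.0, -1.0)
    chronic_flag = _biased_flag(classes, recipe.beta_static, signs, rng)
    symptoms = _text_field(classes, recipe.beta_static, _SYMPTOMS, rng)
    chronic_text = _text_field(classes, recipe.beta_static, _CHRONIC, rng, (0, 2))
    addl = _text_field(classes, recipe.beta_static, _SYMPTOMS[::-1], rng, (0, 2))

    labels = (
        [STATIC_OUTCOMES_4[c] for c in classes]
        if nc <= len(STATIC_OUTCOMES_4)
        else [f"class{c}" for c in classes]
    )
    data = pd.DataFrame(
        {
            "age": np.round(ages, 1),
            "gender": gender,
            "symptoms": symptoms,
            "additional_information": addl,
            "chronic_disease_binary": chronic_flag,
            "chronic_disease": chronic_text,
        },
        index=ids,
    )
    kinds = {
        "age": "numeric",
        "gender": "categorical",
        "symptoms": "text",
        "additional_information": "text",
        "chronic_disease_binary": "boolean",
        "chronic_disease": "text",
    }
    return StaticCohort(ids, data, kinds, pd.Series(labels, index=ids))


# latent -> observed loading structure: each latent axis pushes a different
# blood-lipid / pressure group, scaled to each feature's natural spread
_BASE = np.array([27.0, 125.0, 80.0, 200.0, 50.0, 120.0, 140.0])  # bmi..trig
_SCALE = np.array([4.0, 15.0, 9.0, 35.0, 12.0, 30.0, 60.0])
_LOADINGS = np.array(
    [
        [0.9, 0.1, 0.2],   # bmi
        [0.2, 0.9, 0.1],   # sbp
        [0.1, 0.8, 0.2],   # dbp
        [0.8, 0.2, 0.4],   # chol
        [-0.6, -0.1, 0.3], # hdl
        [0.7, 0.2, 0.3],   # ldl
        [0.5, 0.3, 0.7],   # trig
    ]
)


def make_longitudinal_cohort(recipe: CohortRecipe) -> tuple[StaticCohort, VisitSequences]:
    """Cardiovascular-style cohort: static profile + visit sequences.

    Visit counts are drawn on [visit_min, visit_max] from a distribution
    peaked near 7. Each patient follows a latent trajectory in
    ``latent_dim`` dimensions whose starting level and per-visit drift are
    shifted by the outcome class in proportion to ``beta_dynamic``; the
    trajectory maps linearly to the 7 primary measurements plus Gaussian
    noise ``noise_scale`` (in units of each feature's natural spread), and
    the two derived lipid features are computed from the generated ones, so
    the derived identities hold exactly on every row.
    """
    rng = np.random.default_rng(recipe.seed)
    nc = 2  # binary event outcome for the longitudinal analog
    props = recipe.proportions() if recipe.n_classes == 2 else np.array([0.5, 0.5])
    classes = rng.choice(nc, size=recipe.n_patients, p=props)
    n = recipe.n_patients
    ids = [f"L{i:05d}" for i in range(n)]

    counts = np.arange(recipe.visit_min, recipe.visit_max + 1)
    peak = min(max(7, recipe.visit_min), recipe.visit_max)
    w = 1.0 / (1.0 + np.abs(counts - peak))
    w = w**1.5
    w /= w.sum()
    n_visits = rng.choice(counts, size=n, p=w)

    ld = recipe.latent_dim
    delta = np.resize(np.array([1.6, -1.2, 1.0]), ld)
    drift_delta = np.resize(np.array([0.25, 0.2, -0.15]), ld)
    loadings = np.resize(_LOADINGS, (7, ld))

    sequences: dict[str, np.ndarray] = {}
    for pid, c, m in zip(ids, classes, n_visits):
        z = rng.normal(0.0, 1.0, ld) + recipe.beta_dynamic * delta * (c - 0.5) * 2.0
        drift = recipe.beta_dynamic * drift_delta * (c - 0.5) * 2.0
        rows = np.zeros((m, 9))
        for t in range(m):
            obs = _BASE + _SCALE * (loadings @ z + recipe.noise_scale * rng.normal(size=7))
            obs[4] = max(obs[4], 10.0)  # hdl floor keeps the ratio finite
            chol, hdl = obs[3], obs[4]
            rows[t, :7] = obs
            rows[t, 7] = chol - hdl
            rows[t, 8] = chol / hdl
            z = z + drift + rng.normal(0.0, 0.15, ld)
        sequences[pid] = rows
    seqs = VisitSequences(ids, sequences, list(VISIT_FEATURES))

    # static profile: age + three class-biased Boolean risk flags
    centered = classes - 0.5
    ages = np.clip(rng.uniform(35, 75, n) + recipe.beta_static * 14.0 * centered * 2.0, 30, 85)
    gender = np.where(rng.random(n) < 0.5, "female", "male")
    pos = np.array([1.0, -1.0])  # class 1 raises smoke/diab, lowers hypermed
    smoke = _biased_flag(classes, recipe.beta_static, -pos, rng)
    diab = _biased_flag(classes, recipe.beta_static, -pos, rng)
    hypermed = _biased_flag(classes, recipe.beta_static, pos, rng)
    data = pd.DataFrame(
        {
            "age": np.round(ages, 1),
            "gender": gender,
            "smoke": smoke,
            "diab": diab,
            "hypermed": hypermed,
        },
        index=ids,
    )
    kinds = {
        "age": "numeric",
        "gender": "categorical",
        "smoke": "boolean",
        "diab": "boolean",
        "hypermed": "boolean",
    }
    outcome = pd.Series(["event" if c == 1 else "no_event" for c in classes], index=ids)
    static = StaticCohort(ids, data, kinds, outcome)
    return static, seqs


# ---------------------------------------------------------------------------
# CSV export in the formats the readers consume
# ---------------------------------------------------------------------------

def write_static_csv(cohort: StaticCohort, path) -> None:
    frame = cohort.data.copy()
    frame.insert(0, "id", cohort.patient_ids)
    frame["outcome"] = cohort.outcome.to_numpy()
    frame.to_csv(path, index=False)


def write_visits_csv(seqs: VisitSequences, path) -> None:
    rows = []
    for pid, seq in seqs:
        for t, vec in enumerate(seq):
            rows.append([pid, t, *vec])
    pd.DataFrame(rows, columns=["id", "visit", *seqs.feature_names]).to_csv(path, index=False)
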