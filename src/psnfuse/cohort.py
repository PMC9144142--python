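"""Core data containers and CSV I/O for patient-similarity analysis.

Three containers underpin the pipeline: :class:`StaticCohort` (one row per
patient: demographics, Boolean flags, free-text fields, outcome label),
:class:`VisitSequences` (per-patient ordered sequences of fixed-width numeric
visit vectors), and :class:`SimilarityMatrix` (a square patient-by-patient
score matrix tagged as similarity or distance).

All matrices produced downstream share the patient index order of the cohort
they were built from: order of first appearance in the source CSV.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ColumnKind = Literal["numeric", "boolean", "categorical", "text"]


class CohortError(ValueError):
    """Raised on malformed cohort or visit-table input."""


@dataclass
class StaticCohort:
    """Per-patient static records with a declared type for every column.

    Parameters
    ----------
    patient_ids
        Unique patient identifiers, in fixed index order.
    data
        Frame indexed like ``patient_ids`` holding the typed feature columns.
    column_kinds
        Mapping of column name to one of ``numeric | boolean | categorical |
        text``.
    outcome
        Per-patient class label, aligned with ``patient_ids``.
    """

    patient_ids: list[str]
    data: pd.DataFrame
    column_kinds: dict[str, ColumnKind]
    outcome: pd.Series
    n_parse_failures: int = 0

    def __post_init__(self) -> None:
        if len(set(self.patient_ids)) != len(self.patient_ids):
            raise CohortError("duplicate patient IDs")
        unknown = set(self.column_kinds) - set(self.data.columns)
        if unknown:
            raise CohortError(f"column kinds declared for missing columns: {sorted(unknown)}")
        if self.outcome.isna().any():
            raise CohortError("outcome must be defined for every patient")

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)

    def column(self, name: str) -> pd.Series:
        return self.data[name]


@dataclass
class VisitSequences:
    """Ordered variable-length visit vectors, one sequence per patient.

    Every visit vector has the same width (the number of measured medical
    events); sequence lengths differ across patients.
    """

    patient_ids: list[str]
    sequences: dict[str, np.ndarray]  # id -> (n_visits, width) float array
    feature_names: list[str]

    def __post_init__(self) -> None:
        width = self.width
        for pid in self.patient_ids:
            seq = self.sequences[pid]
            if seq.ndim != 2 or seq.shape[1] != width:
                raise CohortError(f"patient {pid!r}: visit width {seq.shape} != {width}")
            if seq.shape[0] < 1:
                raise CohortError(f"patient {pid!r} has no visits")

    @property
    def width(self) -> int:
        return len(self.feature_names)

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)

    @property
    def total_visits(self) -> int:
        return sum(self.sequences[p].shape[0] for p in self.patient_ids)

    def __iter__(self):
        return ((pid, self.sequences[pid]) for pid in self.patient_ids)


@dataclass
class SimilarityMatrix:
    """Square pairwise-score matrix with a patient-ID index.

    ``kind`` declares semantics: ``"similarity"`` (higher = more alike,
    entries >= 0) or ``"distance"`` (lower = more alike).
    """

    values: np.ndarray
    patient_ids: list[str]
    kind: Literal["similarity", "distance"] = "similarity"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.patient_ids)
        if self.values.shape != (n, n):
            raise CohortError(f"matrix shape {self.values.shape} != ({n}, {n})")
        if self.kind == "similarity" and (self.values < 0).any():
            raise CohortError("similarity matrix has negative entries")

    @property
    def n(self) -> int:
        return len(self.patient_ids)

    def is_symmetric(self, tol: float = 0.0) -> bool:
        return bool(np.all(np.abs(self.values - self.values.T) <= tol))

    def with_values(self, values: np.ndarray, kind: str | None = None) -> "SimilarityMatrix":
        return SimilarityMatrix(values, list(self.patient_ids), kind or self.kind)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_static_cohort(
    path,
    column_kinds: Mapping[str, ColumnKind],
    id_col: str = "id",
    outcome_col: str = "outcome",
) -> StaticCohort:
    """Read a static patient table from CSV.

    ``column_kinds`` declares the type of every modeled feature column; the
    ID and outcome columns are named separately. Cells in numeric columns
    that fail to parse become missing values and are counted (one warning is
    logged with the total). Patients with a missing outcome are excluded
    with a warning. Duplicate IDs and schema columns absent from the file
    are hard errors.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in (id_col, outcome_col, *column_kinds):
        if col not in raw.columns:
            raise CohortError(f"column {col!r} not present in {path}")
    ids = raw[id_col].tolist()
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise CohortError(f"duplicate patient IDs: {dupes}")

    outcome = raw[outcome_col].replace("", np.nan)
    missing_outcome = outcome.isna()
    if missing_outcome.any():
        dropped = [ids[i] for i in np.flatnonzero(missing_outcome.to_numpy())]
        warnings.warn(f"excluding {len(dropped)} patient(s) with missing outcome: {dropped}")
        raw = raw.loc[~missing_outcome.to_numpy()].reset_index(drop=True)
        ids = raw[id_col].tolist()
        outcome = raw[outcome_col]

    n_failures = 0
    cols: dict[str, pd.Series] = {}
    for name, kind in column_kinds.items():
        s = raw[name]
        if kind == "numeric":
            parsed = pd.to_numeric(s.replace("", np.nan), errors="coerce")
            n_failures += int((parsed.isna() & (s != "")).sum())
            cols[name] = parsed
        elif kind == "boolean":
            cols[name] = s.str.strip().str.lower().map(
                {"1": True, "true": True, "yes": True, "0": False, "false": False, "no": False}
            )
        else:  # categorical / text kept as strings
            cols[name] = s
    if n_failures:
        warnings.warn(f"{n_failures} unparseable numeric cell(s) set to missing")

    data = pd.DataFrame(cols)
    data.index = pd.Index(ids)
    return StaticCohort(
        patient_ids=[str(i) for i in ids],
        data=data,
        column_kinds=dict(column_kinds),
        outcome=pd.Series(outcome.to_numpy(), index=ids),
        n_parse_failures=n_failures,
    )


def read_visit_table(
    path,
    id_col: str,
    order_col: str,
    feature_cols: Sequence[str],
) -> VisitSequences:
    """Read a long-format visit table (one row per visit) into sequences.

    Rows are grouped by patient and sorted ascending by ``order_col``
    (integer order or fractional time — only the ordering is used).
    Patients with zero rows cannot occur in long format; rows with any
    unparseable feature value raise, since ragged visit vectors would break
    every downstream matrix.
    """
    df = pd.read_csv(path)
    for col in (id_col, order_col, *feature_cols):
        if col not in df.columns:
            raise CohortError(f"column {col!r} not present in {path}")
    feats = df[list(feature_cols)].apply(pd.to_numeric, errors="coerce")
    if feats.isna().any().any():
        bad = feats.columns[feats.isna().any()].tolist()
        raise CohortError(f"non-numeric values in visit feature columns: {bad}")
    df = df.assign(**{c: feats[c] for c in feature_cols})

    patient_ids: list[str] = []
    sequences: dict[str, np.ndarray] = {}
    for pid, grp in df.groupby(id_col, sort=False):
        grp = grp.sort_values(order_col, kind="stable")
        patient_ids.append(str(pid))
        sequences[str(pid)] = grp[list(feature_cols)].to_numpy(dtype=float)
    return VisitSequences(patient_ids, sequences, list(feature_cols))


def write_similarity_matrix(m: SimilarityMatrix, path) -> None:
    """Write a similarity/distance matrix as CSV with an ID header row and column."""
    if not np.isfinite(m.values).all():
        raise CohortError("matrix contains NaN or infinite entries")
    frame = pd.DataFrame(m.values, index=m.patient_ids, columns=m.patient_ids)
    frame.to_csv(path, float_format="%.17g")


def read_similarity_matrix(path, kind: Literal["similarity", "distance"] = "similarity") -> SimilarityMatrix:
    frame = pd.read_csv(path, index_col=0)
    ids = [str(i) for i in frame.index]
    if [str(c) for c in frame.columns] != ids:
        raise CohortError("row and column patient IDs disagree")
    return SimilarityMatrix(frame.to_numpy(dtype=float), ids, kind)


def write_edge_list(m: SimilarityMatrix, path, threshold: float = 0.0) -> int:
    """Export the upper triangle as a 3-column weighted edge list CSV.

    Returns the number of edges written; edges with weight <= ``threshold``
    are dropped.
    """
    rows = []
    ids = m.patient_ids
    iu, ju = np.triu_indices(m.n, k=1)
    for i, j in zip(iu, ju):
        w = m.values[i, j]
        if w > threshold:
            rows.append((ids[i], ids[j], w))
    pd.DataFrame(rows, columns=["id_i", "id_j", "weight"]).to_csv(path, index=False)
    return len(rows)
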