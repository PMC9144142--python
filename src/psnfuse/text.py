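"""Free-text clinical field encoding.

Line-list style text fields ("fever, cough", "diabetes; hypertension") are
turned into multi-hot presence vectors over a vocabulary fitted on training
data. Similarity between two fields is the cosine of their encodings.

An adapter protocol lets users plug in external contextual embedders (e.g.
precomputed transformer sentence vectors); no pretrained model is bundled
and the built-in encoder is the one-hot bag of tokens.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Callable, Protocol, Sequence, runtime_checkable

import numpy as np
import pandas as pd

_TOKEN_SPLIT = re.compile(r"[,;\s]+")
_PUNCT = re.compile(r"[^\w\-']+")


def tokenize(text: str) -> list[str]:
    """Lowercase, split on comma/semicolon/whitespace, strip punctuation."""
    out = []
    for raw in _TOKEN_SPLIT.split(text.lower()):
        tok = _PUNCT.sub("", raw.strip())
        if tok:
            out.append(tok)
    return out


@dataclass
class Vocabulary:
    """Fitted token vocabulary with stable 0..V-1 indices."""

    tokens: list[str]
    index: dict[str, int] = field(init=False)
    n_oov_seen: int = field(default=0, init=False)

    def __post_init__(self) -> None:
        self.index = {t: i for i, t in enumerate(self.tokens)}

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def dim(self) -> int:
        return len(self.tokens)

    def encode(self, text: str) -> np.ndarray:
        """Multi-hot presence vector; out-of-vocabulary tokens are counted and ignored."""
        vec = np.zeros(len(self.tokens))
        for tok in tokenize(text):
            idx = self.index.get(tok)
            if idx is None:
                self.n_oov_seen += 1
            else:
                vec[idx] = 1.0
        return vec


def fit_vocabulary(texts: Sequence[str]) -> Vocabulary:
    """Fit a vocabulary of unique normalized tokens, sorted lexicographically.

    Fit on the training fold only; encoding held-out text never grows the
    vocabulary (unknown tokens are ignored).
    """
    if len(texts) == 0:
        raise ValueError("texts must be a nonempty list (empty strings allowed)")
    seen: set[str] = set()
    for t in texts:
        seen.update(tokenize(t))
    return Vocabulary(sorted(seen))


@runtime_checkable
class EmbedderAdapter(Protocol):
    """Contract for external text embedders: pure text -> fixed-length vector."""

    dim: int

    def encode(self, text: str) -> np.ndarray: ...


@dataclass
class FileEmbedderAdapter:
    """Embeddings precomputed elsewhere, looked up by exact text.

    Reads a CSV with a ``text`` column followed by ``dim`` numeric columns.
    Lets users bring their own contextual-model output without the package
    depending on any language model.
    """

    table: dict[str, np.ndarray]
    dim: int

    @classmethod
    def from_csv(cls, path, text_col: str = "text") -> "FileEmbedderAdapter":
        df = pd.read_csv(path)
        value_cols = [c for c in df.columns if c != text_col]
        table = {
            str(row[text_col]): row[value_cols].to_numpy(dtype=float)
            for _, row in df.iterrows()
        }
        return cls(table=table, dim=len(value_cols))

    def encode(self, text: str) -> np.ndarray:
        if text not in self.table:
            raise KeyError(f"no precomputed embedding for text {text!r}")
        vec = self.table[text]
        if vec.shape != (self.dim,):
            raise ValueError(f"embedding dimension {vec.shape} != declared {self.dim}")
        return vec


def text_field_similarity(text_i: str, text_j: str, encoder: Vocabulary | EmbedderAdapter) -> float:
    """Cosine similarity of two text fields' encodings.

    Two empty encodings (e.g. both patients symptom-free) score 1.0; one
    empty against one non-empty scores 0.0.
    """
    a = encoder.encode(text_i)
    b = encoder.encode(text_j)
    if a.shape != b.shape:
        raise ValueError(f"encoder produced mismatched dimensions {a.shape} vs {b.shape}")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 and nb == 0:
        return 1.0
    if na == 0 or nb == 0:
        return 0.0
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))
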