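"""Semantic spaces: LSA construction, cosine similarity and semantic distance.

A semantic space maps each word of a vocabulary to a real vector; the
cosine of the angle between two word vectors measures their semantic
similarity, and the *semantic distance* (SmD) is ``1 - cosine`` with
negative cosines clamped to an SmD of exactly 1 (a negative cosine has no
interpretation as a distance, so it is treated as "maximally unrelated").

Spaces can be built from a small corpus by classical LSA — log-entropy
weighting of the word-by-document count matrix followed by a truncated
singular value decomposition — or read from / written to the word2vec
text interchange format (header line ``"<n_words> <dim>"``, then one
``word v1 ... vd`` line per word).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import (
    InvalidInputError,
    InvalidParameterError,
    OutOfVocabularyError,
    VectorFormatError,
)

__all__ = [
    "Corpus",
    "SemanticSpace",
    "build_space",
    "cosine",
    "smd",
    "read_vectors",
    "write_vectors",
]


@dataclass(frozen=True)
class Corpus:
    """A list of tokenised documents (lowercased words).

    At least two documents and two distinct tokens are required: a
    single-column term-document matrix has no co-occurrence structure to
    decompose.
    """

    documents: Sequence[Sequence[str]]

    def __post_init__(self):
        if len(self.documents) < 2:
            raise InvalidInputError(
                "corpus must contain at least 2 documents "
                f"(got {len(self.documents)})"
            )
        vocab = {t for doc in self.documents for t in doc}
        if len(vocab) < 2:
            raise InvalidInputError(
                "corpus must contain at least 2 distinct tokens"
            )

    @property
    def vocabulary(self) -> list[str]:
        """Corpus vocabulary in first-occurrence order."""
        seen: dict[str, None] = {}
        for doc in self.documents:
            for tok in doc:
                seen.setdefault(tok, None)
        return list(seen)


class SemanticSpace:
    """Vocabulary plus one d-dimensional vector per word.

    Lookup is case-insensitive: words are stored lowercased and queries
    are lowercased before lookup.  Every vector must be finite with a
    nonzero norm, and every word unique.
    """

    def __init__(self, vocabulary: Sequence[str], vectors: np.ndarray):
        vocab = [w.lower() for w in vocabulary]
        vectors = np.asarray(vectors, dtype=float)
        if vectors.ndim != 2 or vectors.shape[0] != len(vocab):
            raise InvalidInputError(
                f"vectors must be a {len(vocab)}-row matrix, "
                f"got shape {vectors.shape}"
            )
        if len(set(vocab)) != len(vocab):
            dupes = {w for w in vocab if vocab.count(w) > 1}
            raise InvalidInputError(f"duplicate words in vocabulary: {sorted(dupes)}")
        if not np.all(np.isfinite(vectors)):
            raise InvalidInputError("vectors must be finite")
        norms = np.linalg.norm(vectors, axis=1)
        if np.any(norms == 0):
            bad = [vocab[i] for i in np.flatnonzero(norms == 0)]
            raise InvalidInputError(f"zero-norm vectors for words: {bad}")
        self._vocab = vocab
        self._index = {w: i for i, w in enumerate(vocab)}
        self._vectors = vectors
        self._norms = norms

    # -- container protocol -------------------------------------------------
    @property
    def vocabulary(self) -> list[str]:
        return list(self._vocab)

    @property
    def vectors(self) -> np.ndarray:
        return self._vectors

    @property
    def dim(self) -> int:
        return self._vectors.shape[1]

    def __len__(self) -> int:
        return len(self._vocab)

    def __contains__(self, word: str) -> bool:
        return word.lower() in self._index

    def index(self, word: str) -> int:
        try:
            return self._index[word.lower()]
        except KeyError:
            raise OutOfVocabularyError(word) from None

    def vector(self, word: str) -> np.ndarray:
        return self._vectors[self.index(word)]

    def unit_vectors(self) -> np.ndarray:
        """All vectors normalised to unit length (rows)."""
        return self._vectors / self._norms[:, None]


def _log_entropy_weight(counts: np.ndarray) -> np.ndarray:
    """Log-entropy reweighting of a term-document count matrix.

    Local weight ``log(1 + tf)``; global weight ``1 - H_t / log(n_docs)``
    where ``H_t`` is the Shannon entropy of the term's distribution over
    documents.  A term spread evenly over every document has entropy
    ``log(n_docs)`` and global weight 0; a term concentrated in a single
    document keeps full weight — rare, specific terms gain impact and
    ubiquitous terms lose it.
    """
    counts = np.asarray(counts, dtype=float)
    n_docs = counts.shape[1]
    gf = counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(gf > 0, counts / gf, 0.0)
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    entropy = -plogp.sum(axis=1)
    global_w = 1.0 - entropy / math.log(n_docs)
    return np.log1p(counts) * global_w[:, None]


def build_space(corpus: Corpus, target_dim: int = 300) -> SemanticSpace:
    """Build an LSA space from a corpus.

    The word-by-document count matrix is log-entropy weighted, then a
    truncated SVD keeps ``min(target_dim, rank)`` dimensions (the common
    choice in the literature is around 300).  Word vectors are the
    singular-value-scaled left singular vectors ``U_k Σ_k``.
    """
    if target_dim < 1:
        raise InvalidParameterError(f"target_dim must be >= 1, got {target_dim}")
    vocab = corpus.vocabulary
    doc_index = [{t: doc.count(t) for t in set(doc)} for doc in corpus.documents]
    counts = np.zeros((len(vocab), len(doc_index)))
    for j, doc_counts in enumerate(doc_index):
        for tok, c in doc_counts.items():
            counts[vocab.index(tok), j] = c

    weighted = _log_entropy_weight(counts)
    u, s, _ = np.linalg.svd(weighted, full_matrices=False)
    tol = max(weighted.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    rank = int(np.sum(s > tol))
    if rank == 0:
        raise InvalidInputError("weighted term-document matrix has rank 0")
    k = min(target_dim, rank)
    vectors = u[:, :k] * s[:k]
    # A word whose weighted row is annihilated by truncation would violate
    # the nonzero-norm invariant; give it a tiny deterministic component.
    norms = np.linalg.norm(vectors, axis=1)
    if np.any(norms == 0):
        vectors[norms == 0, 0] = np.finfo(float).eps
    return SemanticSpace(vocab, vectors)


def cosine(space: SemanticSpace, a: str, b: str) -> float:
    """Signed cosine similarity of two vocabulary words, in [-1, 1]."""
    if space.index(a) == space.index(b):
        return 1.0  # exact self-similarity, no float round-off
    va, vb = space.vector(a), space.vector(b)
    c = float(va @ vb / (np.linalg.norm(va) * np.linalg.norm(vb)))
    return max(-1.0, min(1.0, c))


def smd(space: SemanticSpace, a: str, b: str) -> float:
    """Semantic distance ``1 - cosine``, clamped to 1 for negative cosines.

    0 means identical meaning, 1 maximally unrelated.  A negative cosine
    cannot be interpreted as a distance and is set to one.
    """
    c = cosine(space, a, b)
    return 1.0 if c < 0 else 1.0 - c


def write_vectors(space: SemanticSpace, path: str | Path) -> None:
    """Write a space in word2vec text format (UTF-8, '.' decimals)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"{len(space)} {space.dim}\n")
        for word, vec in zip(space.vocabulary, space.vectors):
            fh.write(word + " " + " ".join(repr(float(v)) for v in vec) + "\n")


def read_vectors(path: str | Path) -> SemanticSpace:
    """Read a word2vec-text vector file.

    Raises :class:`VectorFormatError` (with the offending line number) on
    header mismatch, wrong per-line dimensionality, non-numeric entries
    or duplicated words.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline()
        parts = header.split()
        if len(parts) != 2:
            raise VectorFormatError(
                f"expected header '<n_words> <dim>', got {header.strip()!r}", line=1
            )
        try:
            n_words, dim = int(parts[0]), int(parts[1])
        except ValueError:
            raise VectorFormatError(
                f"non-integer header fields {header.strip()!r}", line=1
            ) from None
        vocab: list[str] = []
        seen: set[str] = set()
        rows = np.empty((n_words, dim))
        lineno = 1
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            i = lineno - 2
            if i >= n_words:
                raise VectorFormatError(
                    f"more than the declared {n_words} word lines", line=lineno
                )
            fields = line.rstrip("\n").split(" ")
            word, values = fields[0], fields[1:]
            if len(values) != dim:
                raise VectorFormatError(
                    f"expected {dim} values for word {word!r}, got {len(values)}",
                    line=lineno,
                )
            if word.lower() in seen:
                raise VectorFormatError(f"duplicate word {word!r}", line=lineno)
            seen.add(word.lower())
            try:
                rows[i] = [float(v) for v in values]
            except ValueError:
                raise VectorFormatError(
                    f"non-numeric vector entry for word {word!r}", line=lineno
                ) from None
            vocab.append(word)
        if len(vocab) != n_words:
            raise VectorFormatError(
                f"header declared {n_words} words but file has {len(vocab)}",
                line=lineno,
            )
    return SemanticSpace(vocab, rows)
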