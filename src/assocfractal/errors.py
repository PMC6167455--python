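"""Exception hierarchy shared across the package.

A deliberate distinction is drawn between *numeric* failures (degenerate
series, infeasible estimator parameters) and *data* failures (malformed
files, words absent from the semantic space).  Out-of-vocabulary lookups
are a signal, not an error: callers that build time series convert them
into missing values instead of aborting.
"""


class AssocFractalError(Exception):
    """Base class for all package errors."""


class InvalidInputError(AssocFractalError, ValueError):
    """Structurally invalid input (empty corpus, too-short chain, ...)."""


class InvalidParameterError(AssocFractalError, ValueError):
    """Estimator or generator parameter outside its feasible range."""


class VectorFormatError(AssocFractalError, ValueError):
    """Malformed word-vector file; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class OutOfVocabularyError(AssocFractalError, KeyError):
    """A word is not in the semantic space (missing-word signal)."""

    def __init__(self, word: str):
        self.word = word
        super().__init__(f"word not in vocabulary: {word!r}")


class EmptySeriesError(AssocFractalError, ValueError):
    """A series contains no observed values after missing handling."""


class DegenerateSeriesError(AssocFractalError, ValueError):
    """A series carries no signal (e.g. constant: zero spectral power)."""


class CollinearityError(AssocFractalError, ValueError):
    """Rank-deficient regression design; names the offending term."""

    def __init__(self, term: str):
        self.term = term
        super().__init__(f"design matrix is rank deficient at term {term!r}")


class GenerationError(AssocFractalError, RuntimeError):
    """A synthetic generator could not satisfy its contract."""
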