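"""From raw association chains to analysis-ready SmD time series.

An association chain is one participant's ordered word productions from a
chain task (each word is the stimulus for the next association).  The
chain is turned into a time series of semantic distances between adjacent
words; tokens are cleaned (lowercased, non-letter characters stripped),
words missing from the semantic space become missing values, missing
values are dropped or interpolated, and the series is zero-padded to the
next power-of-two length before spectral estimation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import EmptySeriesError, InvalidInputError, OutOfVocabularyError
from .space import SemanticSpace, smd

__all__ = [
    "AssociationChain",
    "SmdSeries",
    "clean_token",
    "chain_to_series",
    "handle_missing",
    "zero_pad",
    "read_chains_csv",
    "write_oov_report",
]

#: Shortest series the complexity estimators will accept after missing
#: handling.  Fractal estimates on shorter series are too unreliable to
#: interpret; the pipeline excludes such participants and logs them.
MIN_SERIES_LENGTH = 32


@dataclass(frozen=True)
class AssociationChain:
    """One participant's ordered word productions, optionally timed."""

    participant_id: str
    words: tuple[str, ...]
    response_times: tuple[float, ...] | None = None

    def __post_init__(self):
        object.__setattr__(self, "words", tuple(self.words))
        if self.response_times is not None:
            rts = tuple(float(t) for t in self.response_times)
            if len(rts) != len(self.words):
                raise InvalidInputError(
                    f"chain {self.participant_id}: {len(self.words)} words but "
                    f"{len(rts)} response times"
                )
            if any(t <= 0 for t in rts):
                raise InvalidInputError(
                    f"chain {self.participant_id}: response times must be positive"
                )
            object.__setattr__(self, "response_times", rts)

    def __len__(self) -> int:
        return len(self.words)


@dataclass
class SmdSeries:
    """Ordered semantic distances for one participant.

    ``values`` holds SmD values in [0, 1] with NaN marking missing pairs
    (invalid token or out-of-vocabulary word on either side).
    ``padded_length`` stays 0 until :func:`zero_pad` is applied.
    """

    participant_id: str
    values: np.ndarray
    padded_length: int = 0
    missing_policy: str | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        observed = self.values[~np.isnan(self.values)]
        if observed.size and (observed.min() < 0 or observed.max() > 1):
            raise InvalidInputError("SmD values must lie in [0, 1]")

    @property
    def n_observed(self) -> int:
        return int(np.sum(~np.isnan(self.values)))

    def __len__(self) -> int:
        return len(self.values)


def clean_token(raw: str) -> str | None:
    """Normalise a raw response token.

    Lowercases, strips whitespace and removes every non-letter character;
    Unicode letters (umlauts, ß, accented letters) are kept.  Returns
    ``None`` when nothing survives — the invalid marker.
    """
    cleaned = "".join(ch for ch in raw.strip().lower() if ch.isalpha())
    return cleaned or None


def chain_to_series(chain: AssociationChain, space: SemanticSpace) -> SmdSeries:
    """Semantic distance between each pair of adjacent chain words.

    The series has length ``len(chain) - 1``; a pair with an invalid or
    out-of-vocabulary member yields NaN at that position.
    """
    if len(chain) < 2:
        raise InvalidInputError(
            f"chain {chain.participant_id}: need at least 2 words, got {len(chain)}"
        )
    cleaned = [clean_token(w) for w in chain.words]
    values = np.full(len(chain) - 1, np.nan)
    for t in range(len(chain) - 1):
        a, b = cleaned[t], cleaned[t + 1]
        if a is None or b is None:
            continue
        try:
            values[t] = smd(space, a, b)
        except OutOfVocabularyError:
            continue
    return SmdSeries(chain.participant_id, values)


def handle_missing(
    series: SmdSeries, policy: Literal["drop", "linear-interpolate"] = "drop"
) -> SmdSeries:
    """Remove missing values by dropping or linear interpolation.

    ``drop`` concatenates the observed values (default — the temporal
    spacing distortion is accepted rather than inventing values);
    ``linear-interpolate`` fills interior gaps linearly and deletes
    leading/trailing missing runs.
    """
    values = series.values
    if not np.any(~np.isnan(values)):
        raise EmptySeriesError(
            f"series {series.participant_id}: all values missing"
        )
    if policy == "drop":
        out = values[~np.isnan(values)]
    elif policy == "linear-interpolate":
        s = pd.Series(values).interpolate(method="linear", limit_area="inside")
        out = s.to_numpy()
        out = out[~np.isnan(out)]
    else:
        raise InvalidInputError(f"unknown missing policy {policy!r}")
    return SmdSeries(series.participant_id, out, missing_policy=policy)


def next_power_of_two(n: int) -> int:
    """Smallest power of 2 that is >= n (n >= 1)."""
    if n < 1:
        raise InvalidInputError(f"need n >= 1, got {n}")
    return 1 << (n - 1).bit_length()


def zero_pad(series: SmdSeries) -> SmdSeries:
    """Append zeros until the length is the next power of two.

    E.g. 115 observations gain 13 zeros to reach 128, 230 gain 26 to
    reach 256; a power-of-two length is left unchanged.  The original
    values are preserved bit-identically as a prefix.
    """
    values = series.values
    if np.any(np.isnan(values)):
        raise InvalidInputError(
            "zero_pad requires a series without missing values "
            "(apply handle_missing first)"
        )
    n = len(values)
    target = next_power_of_two(n)
    padded = np.concatenate([values, np.zeros(target - n)])
    return SmdSeries(
        series.participant_id,
        padded,
        padded_length=target,
        missing_policy=series.missing_policy,
    )


# ---------------------------------------------------------------------------
# CSV interfaces


def read_chains_csv(path: str | Path) -> list[AssociationChain]:
    """Read association chains from CSV.

    Expected columns: ``participant_id``, ``trial_index``, ``word`` and
    optionally ``rt_seconds``; one row per produced word, ordered within
    participant by ``trial_index``.
    """
    df = pd.read_csv(path, dtype={"participant_id": str, "word": str})
    required = {"participant_id", "trial_index", "word"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidInputError(f"chains CSV missing columns: {sorted(missing)}")
    chains = []
    for pid, grp in df.groupby("participant_id", sort=True):
        grp = grp.sort_values("trial_index")
        if grp["trial_index"].duplicated().any():
            raise InvalidInputError(
                f"chain {pid}: duplicate trial_index values"
            )
        rts = None
        if "rt_seconds" in grp.columns and grp["rt_seconds"].notna().all():
            rts = tuple(grp["rt_seconds"].astype(float))
        chains.append(AssociationChain(str(pid), tuple(grp["word"]), rts))
    return chains


def oov_report(
    chain: AssociationChain, space: SemanticSpace
) -> list[dict[str, object]]:
    """Per-token report of why a raw token contributes missing values."""
    rows = []
    for t, raw in enumerate(chain.words):
        tok = clean_token(raw)
        if tok is None:
            reason = "invalid"
        elif tok not in space:
            reason = "out_of_vocabulary"
        else:
            continue
        rows.append(
            {
                "participant_id": chain.participant_id,
                "trial_index": t,
                "raw_token": raw,
                "reason": reason,
            }
        )
    return rows


def write_oov_report(
    chains: Sequence[AssociationChain], space: SemanticSpace, path: str | Path
) -> pd.DataFrame:
    """Write the out-of-vocabulary report TSV and return it as a frame."""
    rows = [r for chain in chains for r in oov_report(chain, space)]
    df = pd.DataFrame(
        rows, columns=["participant_id", "trial_index", "raw_token", "reason"]
    )
    df.to_csv(path, sep="\t", index=False)
    return df
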