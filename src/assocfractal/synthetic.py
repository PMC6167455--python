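"""Synthetic data: power-law series, semantic spaces, chains, full studies.

The study this pipeline targets used undeposited human data, so every
stage is exercised on synthetic inputs with *known* ground truth:

* :func:`gen_powerlaw` — spectral synthesis of series whose power
  spectrum follows f^β for a chosen exponent β (β = 0 random, −1
  flexible-stable, −2 persistent);
* :func:`gen_space` — a clustered random semantic space with
  controllable within-cluster cosine;
* :func:`gen_chain` — a greedy word walk whose realised semantic
  distances track a prescribed SmD trajectory;
* :func:`gen_study` — a complete pipeline-ready dataset (chains CSV,
  vector file, scores CSV) in which divergent-thinking scores carry a
  planted quadratic (inverted-U) dependence on each participant's true
  DFA exponent α = (1 − β)/2, plus a planted response-time → SmD
  coupling.

Every generator is deterministic under its seed and emits its ground
truth so recovery tests can compare estimates against it.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import GenerationError, InvalidParameterError
from .prep import AssociationChain
from .space import SemanticSpace, write_vectors

__all__ = [
    "PowerLawSpec",
    "StudySpec",
    "StudyData",
    "gen_powerlaw",
    "gen_space",
    "gen_chain",
    "gen_study",
    "write_study",
    "map_to_unit",
]


@dataclass(frozen=True)
class PowerLawSpec:
    """Target for spectral synthesis: power ∝ frequency^beta."""

    beta: float
    n: int
    seed: int

    def __post_init__(self):
        if not -3.0 <= self.beta <= 0.5:
            raise InvalidParameterError(
                f"beta must be in [-3, 0.5], got {self.beta}"
            )
        if self.n < 32 or self.n & (self.n - 1):
            raise InvalidParameterError(
                f"n must be a power of 2 and >= 32, got {self.n}"
            )


def gen_powerlaw(spec: PowerLawSpec) -> np.ndarray:
    """Synthesize a standardized series with spectral exponent beta.

    Fourier amplitudes are set proportional to f^(beta/2), phases drawn
    independently and uniformly, Hermitian symmetry imposed, and the
    inverse transform standardized to mean 0, SD 1.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    k = np.arange(1, n // 2 + 1, dtype=float)
    amplitude = k ** (spec.beta / 2.0)
    phase = rng.uniform(0.0, 2.0 * np.pi, n // 2)
    spectrum = np.zeros(n // 2 + 1, dtype=complex)
    spectrum[1:] = amplitude * np.exp(1j * phase)
    spectrum[-1] = spectrum[-1].real  # Nyquist bin must be real
    x = np.fft.irfft(spectrum, n)
    x = (x - x.mean()) / x.std()
    return x


def map_to_unit(
    series: np.ndarray, lo: float = 0.05, hi: float = 0.95
) -> np.ndarray:
    """Affine min-max map of a series into [lo, hi].

    Keeps the target SmD trajectory away from the hard [0, 1] boundary
    so the greedy chain construction does not saturate.  DFA and PSD
    slopes are invariant under this affine map.
    """
    x = np.asarray(series, dtype=float)
    span = x.max() - x.min()
    if span == 0:
        return np.full_like(x, (lo + hi) / 2.0)
    return lo + (hi - lo) * (x - x.min()) / span


def gen_space(
    vocab_size: int,
    dim: int,
    n_clusters: int,
    within_cluster_cosine: float,
    seed: int,
) -> SemanticSpace:
    """Clustered random semantic space of unit vectors.

    Each word vector is ``sqrt(c)·center + sqrt(1−c)·noise`` (then
    normalised), giving expected within-cluster cosine ≈ c and
    cross-cluster cosine ≈ 0 (± 1/sqrt(dim) sampling spread).  Words are
    named ``w000001`` ... and assigned to clusters round-robin.
    """
    if dim < 2:
        raise InvalidParameterError(f"dim must be >= 2, got {dim}")
    if not (vocab_size >= n_clusters >= 1):
        raise InvalidParameterError(
            f"need vocab_size >= n_clusters >= 1, got {vocab_size}, {n_clusters}"
        )
    if not 0 <= within_cluster_cosine < 1:
        raise InvalidParameterError(
            f"within_cluster_cosine must be in [0, 1), got {within_cluster_cosine}"
        )
    rng = np.random.default_rng(seed)
    centers = rng.standard_normal((n_clusters, dim))
    centers /= np.linalg.norm(centers, axis=1, keepdims=True)
    noise = rng.standard_normal((vocab_size, dim))
    noise /= np.linalg.norm(noise, axis=1, keepdims=True)
    assignment = np.arange(vocab_size) % n_clusters
    c = within_cluster_cosine
    vectors = np.sqrt(c) * centers[assignment] + np.sqrt(1.0 - c) * noise
    vectors /= np.linalg.norm(vectors, axis=1, keepdims=True)
    words = [_letter_id(i, vocab_size) for i in range(vocab_size)]
    return SemanticSpace(words, vectors)


def _letter_id(i: int, vocab_size: int) -> str:
    """Letters-only synthetic word (token cleaning strips digits)."""
    width = max(1, math.ceil(math.log(vocab_size, 26)))
    letters = []
    for _ in range(width):
        i, rem = divmod(i, 26)
        letters.append(chr(ord("a") + rem))
    return "w" + "".join(reversed(letters))


#: Words may not repeat within this many steps of the greedy walk.
REUSE_EXCLUSION = 10


def gen_chain(
    space: SemanticSpace,
    target_smd: Sequence[float],
    start_word: str,
    seed: int,
) -> AssociationChain:
    """Greedy word walk realising a target SmD trajectory.

    From the current word, the next word is the vocabulary entry (not
    used in the last 10 steps) whose semantic distance to the current
    word is closest to the target value; ties are broken at random under
    the seed.  The chain has ``len(target_smd) + 1`` words.
    """
    target = np.asarray(target_smd, dtype=float)
    if target.size and (target.min() < 0 or target.max() > 1):
        raise InvalidParameterError("target SmD values must lie in [0, 1]")
    if len(space) <= REUSE_EXCLUSION + 1:
        raise GenerationError(
            f"vocabulary of {len(space)} words is exhausted by the "
            f"{REUSE_EXCLUSION}-step reuse exclusion; use a larger space"
        )
    rng = np.random.default_rng(seed)
    unit = space.unit_vectors()
    vocab = space.vocabulary
    current = space.index(start_word)
    recent = [current]
    words = [vocab[current]]
    for t_val in target:
        cos = unit @ unit[current]
        cand_smd = 1.0 - np.clip(cos, 0.0, None)  # negative cosine -> SmD 1
        dist = np.abs(cand_smd - t_val)
        dist[recent[-REUSE_EXCLUSION:]] = np.inf
        pick = int(np.argmin(dist))
        best = dist[pick]
        if not np.isfinite(best):
            raise GenerationError("vocabulary exhausted during chain generation")
        ties = np.flatnonzero(dist <= best + 1e-12)
        if len(ties) > 1:  # random tie-break, seeded
            pick = int(ties[rng.integers(len(ties))])
        current = pick
        recent.append(current)
        words.append(vocab[current])
    return AssociationChain("synthetic", tuple(words))


@dataclass(frozen=True)
class StudySpec:
    """Conditions for a full synthetic study.

    Defaults emulate the target study's conditions: 59 participants,
    chain lengths 42–370 words, generating spectral exponents spanning
    random to persistent (β ∈ [−2, 0], i.e. true α ∈ [0.5, 1.5]), and a
    planted inverted-U score model

        score = b0 + b1·α + b2·α² + Normal(0, noise_sd)

    peaking at the flexible-stable anchor α = 1 with mean ≈ 2.3 and SD
    ≈ 0.4 on the 1–5 rating scale.  Response times emulate a fixed
    35-minute session (mean RT ≈ 2100 s / chain length) and couple
    positively into the level of the SmD trajectory (serial-order
    effect, slope ``rt_coupling`` per second).
    """

    n_participants: int = 59
    chain_length_range: tuple[int, int] = (42, 370)
    beta_range: tuple[float, float] = (-2.0, 0.0)
    quad_coefficients: tuple[float, float, float] = (-0.55, 6.0, -3.0)
    rt_coupling: float = 0.01
    noise_sd: float = 0.3
    vocab_size: int = 5000
    space_dim: int = 12
    n_clusters: int = 50
    within_cluster_cosine: float = 0.6
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.chain_length_range
        if not (2 <= lo <= hi):
            raise InvalidParameterError("chain_length_range must be non-empty, >= 2")
        blo, bhi = self.beta_range
        if blo > bhi:
            raise InvalidParameterError("beta_range must be non-empty")
        if self.noise_sd <= 0:
            raise InvalidParameterError("noise_sd must be positive")
        if self.n_participants < 1:
            raise InvalidParameterError("need at least one participant")


@dataclass
class StudyData:
    """A generated study: inputs plus ground truth for recovery tests."""

    chains: list[AssociationChain]
    space: SemanticSpace
    scores: pd.DataFrame
    ground_truth: dict


def _session_rt(length: int, rng: np.random.Generator) -> float:
    """Mean response time (s) of a participant producing `length` words
    in an (approximately) 35-minute session."""
    return 2100.0 / length * rng.lognormal(0.0, 0.15)


def gen_study(spec: StudySpec) -> StudyData:
    """Generate a complete synthetic study.

    Per participant: a true spectral exponent β is drawn uniformly from
    ``beta_range`` and realised as a chain whose SmD trajectory follows a
    synthesized f^β series mapped into the unit interval; scores are
    drawn from the planted quadratic model on the true α = (1 − β)/2.
    The window into which the trajectory is mapped shifts upward with the
    participant's mean response time (rt_coupling), planting the
    serial-order effect.
    """
    rng = np.random.default_rng(spec.seed)
    space = gen_space(
        spec.vocab_size,
        spec.space_dim,
        spec.n_clusters,
        spec.within_cluster_cosine,
        seed=int(rng.integers(2**31 - 1)),
    )
    vocab = space.vocabulary
    b0, b1, b2 = spec.quad_coefficients
    lo_len, hi_len = spec.chain_length_range
    chains: list[AssociationChain] = []
    rows = []
    truth = {
        "spec": asdict(spec),
        "participants": {},
    }
    mean_rt_pop = 2100.0 / ((lo_len + hi_len) / 2.0)
    for i in range(spec.n_participants):
        pid = f"p{i + 1:03d}"
        beta = float(rng.uniform(*spec.beta_range))
        alpha = (1.0 - beta) / 2.0
        length = int(rng.integers(lo_len, hi_len + 1))
        mean_rt = _session_rt(length, rng)
        # plant the serial-order effect in the trajectory level
        shift = spec.rt_coupling * (mean_rt - mean_rt_pop)
        # window kept inside [0.05, 0.95] to avoid boundary saturation
        center = float(np.clip(0.5 + shift, 0.33, 0.67))
        half_width = 0.28
        n_fft = 1 << (length - 2).bit_length() if length > 2 else 32
        n_fft = max(n_fft, 32)
        raw = gen_powerlaw(
            PowerLawSpec(beta=beta, n=n_fft, seed=int(rng.integers(2**31 - 1)))
        )[: length - 1]
        target = map_to_unit(raw, center - half_width, center + half_width)
        start = vocab[int(rng.integers(len(vocab)))]
        chain = gen_chain(space, target, start, seed=int(rng.integers(2**31 - 1)))
        # per-word response times around the participant mean
        rts = np.maximum(
            rng.gamma(shape=16.0, scale=mean_rt / 16.0, size=length), 0.2
        )
        chains.append(AssociationChain(pid, chain.words, tuple(rts)))
        creativity = b0 + b1 * alpha + b2 * alpha**2 + rng.normal(0, spec.noise_sd)
        novelty = b0 + 0.14 + b1 * alpha + b2 * alpha**2 + rng.normal(0, spec.noise_sd)
        rows.append(
            {
                "participant_id": pid,
                "aut_creativity": float(np.clip(creativity, 1.0, 5.0)),
                "aut_novelty": float(np.clip(novelty, 1.0, 5.0)),
                "aut_usefulness": float(np.clip(rng.normal(3.51, 0.57), 1.0, 5.0)),
                "aut_fluency": int(np.clip(rng.poisson(7.5), 2, None)),
                "crat": int(np.clip(rng.binomial(20, 0.21), 0, 20)),
                "caq": float(np.round(np.clip(rng.gamma(4.0, 1.3), 0, None), 2)),
            }
        )
        truth["participants"][pid] = {
            "beta": beta,
            "alpha": alpha,
            "chain_length": length,
            "mean_rt": float(np.mean(rts)),
            "target_center": center,
        }
    scores = pd.DataFrame(rows)
    return StudyData(chains=chains, space=space, scores=scores, ground_truth=truth)


def write_study(study: StudyData, out_dir: str | Path) -> dict[str, Path]:
    """Write a generated study as the file set the pipeline consumes.

    Emits ``chains.csv``, ``space.vec`` (word2vec text), ``scores.csv``
    and ``ground_truth.json``; returns the paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "chains": out / "chains.csv",
        "vectors": out / "space.vec",
        "scores": out / "scores.csv",
        "ground_truth": out / "ground_truth.json",
    }
    rows = []
    for chain in study.chains:
        for t, word in enumerate(chain.words):
            rows.append(
                {
                    "participant_id": chain.participant_id,
                    "trial_index": t,
                    "word": word,
                    "rt_seconds": chain.response_times[t]
                    if chain.response_times
                    else np.nan,
                }
            )
    pd.DataFrame(rows).to_csv(paths["chains"], index=False)
    write_vectors(study.space, paths["vectors"])
    study.scores.to_csv(paths["scores"], index=False)
    with paths["ground_truth"].open("w", encoding="utf-8") as fh:
        json.dump(study.ground_truth, fh, indent=1)
    return paths
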