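"""Chunk extraction and hierarchy building.

A transition is *chunkable* when both its transition probability and its
reliability are outliers among everything the model has observed: z-scores
are computed separately over the posterior-mean probabilities and the
reliabilities of all observed (context, symbol) pairs, and a transition
qualifies when both z-scores are positive and their product exceeds a
threshold c. Maximal runs of consecutive chunkable transitions in the
training stream become multi-symbol chunks; a second-level model is then
trained on the stream with chunk occurrences replaced by unit symbols,
giving a two-level hierarchical representation (local chunks, and the
arrangement of chunked units).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .learner import DirichletMarkovModel
from .symbolic import TokenSequence

__all__ = [
    "ChunkScore",
    "Chunk",
    "HierarchicalModel",
    "score_transitions",
    "extract_chunks",
    "build_hierarchy",
]


@dataclass(frozen=True)
class ChunkScore:
    """Normalized probability/reliability scores for one observed transition."""

    context: tuple[int, ...]
    symbol: int
    z_prob: float
    z_rel: float

    @property
    def product(self) -> float:
        return self.z_prob * self.z_rel


@dataclass
class Chunk:
    """A contiguous token pattern treated as a unit at the next level."""

    tokens: tuple[int, ...]
    occurrences: list[int] = field(default_factory=list)  # start positions
    level: int = 0

    def __len__(self) -> int:
        return len(self.tokens)


def _zscores(values: np.ndarray) -> np.ndarray:
    sd = values.std()
    if sd == 0:
        return np.zeros_like(values)
    return (values - values.mean()) / sd


def score_transitions(model: DirichletMarkovModel) -> list[ChunkScore]:
    """z-normalized (probability, reliability) for every observed transition.

    Observed means count > 0. The two dimensions are z-scored separately
    over all observed pairs of this model; a zero-variance dimension yields
    all-zero z-scores.
    """
    pairs: list[tuple[tuple[int, ...], int]] = []
    probs: list[float] = []
    rels: list[float] = []
    for context in model.contexts:
        counts = model.counts(context)
        means = model.predictive(context)
        for symbol in np.nonzero(counts > 0)[0]:
            est = model.transition_estimate(context, int(symbol))
            pairs.append((context, int(symbol)))
            probs.append(means[symbol])
            rels.append(est.reliability)
    if not pairs:
        return []
    z_prob = _zscores(np.asarray(probs))
    z_rel = _zscores(np.asarray(rels))
    return [
        ChunkScore(ctx, sym, float(zp), float(zr))
        for (ctx, sym), zp, zr in zip(pairs, z_prob, z_rel)
    ]


def extract_chunks(
    model: DirichletMarkovModel, tokens: Sequence[int], c: float = 5.0
) -> list[Chunk]:
    """Extract chunks from the training stream the model was trained on.

    A transition qualifies when z_prob > 0, z_rel > 0 and
    z_prob * z_rel > c. Maximal runs of consecutive qualifying transitions
    in ``tokens`` are merged into chunks (length >= 2); duplicate token
    patterns are collapsed into one chunk with multiple occurrences.
    """
    scores = score_transitions(model)
    chunkable = {
        (s.context, s.symbol)
        for s in scores
        if s.z_prob > 0 and s.z_rel > 0 and s.product > c
    }
    if not chunkable:
        return []
    order = model.order
    chunks: dict[tuple[int, ...], Chunk] = {}
    run_start: int | None = None
    for t in range(order, len(tokens) + 1):
        qualifies = False
        if t < len(tokens):
            context = tuple(tokens[t - order : t])
            qualifies = (context, tokens[t]) in chunkable
        if qualifies and run_start is None:
            run_start = t - order
        elif not qualifies and run_start is not None:
            pattern = tuple(tokens[run_start:t])
            chunk = chunks.setdefault(pattern, Chunk(pattern))
            chunk.occurrences.append(run_start)
            run_start = None
    return list(chunks.values())


@dataclass
class HierarchicalModel:
    """Two-level model: token-level Markov rows plus a model over chunk units.

    The level-1 alphabet is the K level-0 tokens followed by one unit symbol
    per chunk (ids K .. K+n_chunks-1).
    """

    level0: DirichletMarkovModel
    chunks: list[Chunk]
    level1: DirichletMarkovModel

    @property
    def K0(self) -> int:
        return self.level0.K

    def expand(self, encoded: Sequence[int]) -> list[int]:
        """Replace unit symbols by their token patterns."""
        out: list[int] = []
        for sym in encoded:
            if sym < self.K0:
                out.append(int(sym))
            else:
                out.extend(self.chunks[sym - self.K0].tokens)
        return out


def encode_with_chunks(
    tokens: Sequence[int], chunks: Sequence[Chunk], k0: int
) -> list[int]:
    """Greedy longest-then-leftmost replacement of chunk patterns by units."""
    by_length = sorted(range(len(chunks)), key=lambda j: -len(chunks[j]))
    out: list[int] = []
    i = 0
    n = len(tokens)
    while i < n:
        for j in by_length:
            pattern = chunks[j].tokens
            m = len(pattern)
            if i + m <= n and tuple(tokens[i : i + m]) == pattern:
                out.append(k0 + j)
                i += m
                break
        else:
            out.append(int(tokens[i]))
            i += 1
    return out


def build_hierarchy(
    tokens: Sequence[int] | TokenSequence,
    chunks: Sequence[Chunk],
    level0: DirichletMarkovModel,
    training_trials: int = 1,
) -> tuple[list[int], HierarchicalModel]:
    """Re-encode the stream with chunk units and train the level-1 model.

    The level-1 model shares the level-0 model's order, sensitivity regime
    and prior, over the extended alphabet (K0 + number of chunks), and is
    trained ``training_trials`` times on the re-encoded stream (matching
    the number of passes the level-0 model received).
    """
    from .learner import learn_sequence

    if isinstance(tokens, TokenSequence):
        tokens = tokens.tokens
    encoded = encode_with_chunks(tokens, chunks, level0.K)
    level1 = DirichletMarkovModel(
        level0.K + len(chunks),
        order=level0.order,
        sensitivity_factor=level0.sensitivity_factor,
        base_concentration=level0.base_concentration,
        sensitivity_mode=level0.sensitivity_mode,
    )
    for trial in range(training_trials):
        learn_sequence(level1, encoded, trial_index=trial + 1, record=False)
    return encoded, HierarchicalModel(level0, list(chunks), level1)
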