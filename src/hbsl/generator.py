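"""Probabilistic composition from a learned hierarchy, and corpus comparison.

Pieces are sampled at the chunk level (level 1): each step draws the next
unit from the posterior-mean transition distribution of the current
context, chunk units are expanded to their token patterns, and the piece is
truncated to the requested token length. Corpora are compared to the
training piece through their average empirical bigram distributions using
the Jensen-Shannon divergence; a seeded t-SNE embedding is available for
visualization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import rel_entr

from .chunker import HierarchicalModel
from .symbolic import TokenSequence

__all__ = [
    "GeneratedCorpus",
    "generate_sequence",
    "generate_corpus",
    "bigram_distribution",
    "average_bigram_distribution",
    "distance_to_reference",
    "embed_distributions",
]

Bigram = tuple[int, int]


@dataclass
class GeneratedCorpus:
    pieces: list[TokenSequence]
    model_id: tuple[str, int]  # (sensitivity regime, trial count)
    seed: int = 0


def generate_sequence(
    hmodel: HierarchicalModel,
    length: int,
    seed: int,
    start: str = "first_training_token",
    first_token: int | None = None,
    alphabet: list | None = None,
    scheme: str = "pitch",
) -> TokenSequence:
    """Sample one piece of exactly ``length`` level-0 tokens.

    Sampling happens in the level-1 alphabet from posterior-mean transition
    probabilities; emitted chunk units are expanded to their token patterns.
    ``start="first_training_token"`` begins from ``first_token`` (a level-1
    symbol, normally the first symbol of the re-encoded training stream);
    ``start="stationary_sample"`` draws the initial context uniformly from
    the observed contexts of the level-1 model. Deterministic for a fixed
    seed.
    """
    if length < 2:
        raise ValueError("length must be at least 2")
    model = hmodel.level1
    if model.order != 1:
        raise NotImplementedError("generation currently supports order-1 models")
    rng = np.random.default_rng(seed)
    if start == "first_training_token":
        if first_token is None:
            raise ValueError("first_token is required for start='first_training_token'")
        current = int(first_token)
    elif start == "stationary_sample":
        contexts = model.contexts
        if contexts:
            current = int(contexts[rng.integers(len(contexts))][0])
        else:
            current = int(rng.integers(model.K))
    else:
        raise ValueError(f"unknown start policy {start!r}")
    units = [current]
    tokens = hmodel.expand([current])
    while len(tokens) < length:
        p = model.predictive((current,))
        current = int(rng.choice(model.K, p=p))
        units.append(current)
        tokens = hmodel.expand(units)
    tokens = tokens[:length]
    if alphabet is None:
        alphabet = list(range(hmodel.K0))
    return TokenSequence(tokens, alphabet, scheme)


def generate_corpus(
    hmodel: HierarchicalModel,
    n_pieces: int,
    length: int,
    seed: int,
    model_id: tuple[str, int] = ("normal", 0),
    first_token: int | None = None,
    alphabet: list | None = None,
    scheme: str = "pitch",
) -> GeneratedCorpus:
    """Sample ``n_pieces`` independent pieces with per-piece derived seeds."""
    child_seeds = np.random.SeedSequence(seed).generate_state(n_pieces) % (2**31)
    pieces = [
        generate_sequence(
            hmodel,
            length,
            int(s),
            first_token=first_token,
            alphabet=alphabet,
            scheme=scheme,
        )
        for s in child_seeds
    ]
    return GeneratedCorpus(pieces, model_id, seed)


def bigram_distribution(piece: TokenSequence | Sequence[int]) -> dict[Bigram, float]:
    """Empirical relative frequencies of adjacent token pairs in one piece."""
    tokens = piece.tokens if isinstance(piece, TokenSequence) else list(piece)
    if len(tokens) < 2:
        raise ValueError("piece must contain at least 2 tokens")
    counts: dict[Bigram, float] = {}
    for a, b in zip(tokens, tokens[1:]):
        counts[(a, b)] = counts.get((a, b), 0) + 1
    total = len(tokens) - 1
    return {bg: n / total for bg, n in counts.items()}


def average_bigram_distribution(corpus: GeneratedCorpus) -> dict[Bigram, float]:
    """Unweighted mean of the per-piece bigram distributions, renormalized."""
    if not corpus.pieces:
        raise ValueError("corpus has no pieces")
    acc: dict[Bigram, float] = {}
    for piece in corpus.pieces:
        for bg, p in bigram_distribution(piece).items():
            acc[bg] = acc.get(bg, 0.0) + p
    total = sum(acc.values())
    return {bg: p / total for bg, p in acc.items()}


def _align(
    dist: Mapping[Bigram, float], reference: Mapping[Bigram, float], eps: float = 1e-9
) -> tuple[np.ndarray, np.ndarray]:
    support = sorted(set(dist) | set(reference))
    p = np.array([dist.get(bg, 0.0) for bg in support]) + eps
    q = np.array([reference.get(bg, 0.0) for bg in support]) + eps
    return p / p.sum(), q / q.sum()


def distance_to_reference(
    dist: Mapping[Bigram, float], reference: Mapping[Bigram, float]
) -> float:
    """Jensen-Shannon divergence (nats, <= log 2) between two bigram distributions.

    Distributions are aligned on the union support with epsilon smoothing
    (1e-9) before comparison.
    """
    p, q = _align(dist, reference)
    m = 0.5 * (p + q)
    js = 0.5 * float(rel_entr(p, m).sum()) + 0.5 * float(rel_entr(q, m).sum())
    return max(js, 0.0)


def embed_distributions(
    dists: Sequence[Mapping[Bigram, float]], seed: int = 0
) -> np.ndarray:
    """Seeded 2-D t-SNE embedding of a set of bigram distributions.

    Visualization aid only; use :func:`distance_to_reference` for
    quantitative similarity.
    """
    from sklearn.manifold import TSNE

    support = sorted(set().union(*dists))
    matrix = np.array([[d.get(bg, 0.0) for bg in support] for d in dists])
    perplexity = min(30.0, max(1.0, (len(dists) - 1) / 3))
    tsne = TSNE(
        n_components=2, random_state=seed, perplexity=perplexity, init="pca"
    )
    return tsne.fit_transform(matrix)
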