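"""Incremental Dirichlet-prior Markov learning with per-transition reliability.

The model keeps, for every observed context (a tuple of preceding tokens),
a Dirichlet concentration vector over the K possible continuations. A
symmetric prior Dirichlet(a, ..., a) is updated conjugately: observing
symbol ``i`` after a context adds one count to that context's row. The
predictive transition probability is the posterior mean ``alpha_i/alpha_0``;
the *reliability* of that probability is the inverse of its marginal Beta
variance, which grows as evidence accumulates.

Sensory-sensitivity regimes rescale the prior concentration: a hyper-
sensitive learner (factor 4) starts with a concentrated prior whose
predictive distribution barely moves per observation (small Bayesian
surprise, high reliability); a hypo-sensitive learner (factor 0.25) starts
nearly flat, so every observation swings the predictive distribution (large
surprise, low reliability). Bayesian surprise per event is the KL divergence
between the predictive row before and after the conjugate update.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import rel_entr, xlogy

__all__ = [
    "DirichletMarkovModel",
    "TransitionEstimate",
    "LearningTrace",
    "init_model",
    "observe",
    "transition_estimate",
    "bayesian_surprise",
    "conditional_entropy",
    "empirical_context_weights",
    "learn_sequence",
]

Context = tuple[int, ...]

#: Eq.-style sensitivity factors for the three regimes
SENSITIVITY_FACTORS = {"hypo": 0.25, "normal": 1.0, "hyper": 4.0}


@dataclass(frozen=True)
class TransitionEstimate:
    """Point estimate of one transition probability with its reliability."""

    mean: float
    variance: float
    reliability: float


@dataclass
class LearningTrace:
    """Per-event Bayesian surprise (nats) for one pass over a sequence."""

    per_event_surprise: list[float] = field(default_factory=list)
    trial_index: int = 1

    @property
    def total_surprise(self) -> float:
        return float(sum(self.per_event_surprise))


def beta_variance(alpha_i: float, alpha_0: float) -> float:
    """Marginal Beta variance of one Dirichlet component."""
    return alpha_i * (alpha_0 - alpha_i) / (alpha_0**2 * (alpha_0 + 1.0))


class DirichletMarkovModel:
    """Order-``order`` Markov model with symmetric Dirichlet priors per context.

    Parameters
    ----------
    K:
        Alphabet size (number of categories), >= 2.
    order:
        Context length; 1 gives the classic first-order transition model.
    sensitivity_factor:
        Regime multiplier for the Dirichlet concentration (0.25 hypo,
        1 normal, 4 hyper).
    base_concentration:
        Symmetric prior concentration per category before the regime
        scaling; 1 gives a uniform (Laplace) prior.
    sensitivity_mode:
        ``"prior"`` (default): the factor scales the prior concentrations,
        observations add +1. ``"increment"``: the prior is unscaled and each
        observation adds +factor instead.
    """

    def __init__(
        self,
        K: int,
        order: int = 1,
        sensitivity_factor: float = 1.0,
        base_concentration: float = 1.0,
        sensitivity_mode: str = "prior",
    ):
        if K < 2:
            raise ValueError("alphabet size K must be at least 2")
        if sensitivity_factor <= 0:
            raise ValueError("sensitivity_factor must be positive")
        if base_concentration <= 0:
            raise ValueError("base_concentration must be positive")
        if order < 1:
            raise ValueError("order must be at least 1")
        if sensitivity_mode not in ("prior", "increment"):
            raise ValueError("sensitivity_mode must be 'prior' or 'increment'")
        self.K = K
        self.order = order
        self.sensitivity_factor = float(sensitivity_factor)
        self.base_concentration = float(base_concentration)
        self.sensitivity_mode = sensitivity_mode
        # observation counts per context; the Dirichlet row is prior + counts
        self._counts: dict[Context, np.ndarray] = {}

    @property
    def prior_concentration(self) -> float:
        """Per-category prior concentration after regime scaling."""
        if self.sensitivity_mode == "prior":
            return self.base_concentration * self.sensitivity_factor
        return self.base_concentration

    @property
    def increment(self) -> float:
        """Pseudo-count added per observation."""
        return 1.0 if self.sensitivity_mode == "prior" else self.sensitivity_factor

    @property
    def contexts(self) -> list[Context]:
        return list(self._counts)

    def _check_tokens(self, tokens: Iterable[int]) -> None:
        for t in tokens:
            if not 0 <= t < self.K:
                raise IndexError(f"token {t} outside alphabet of size {self.K}")

    def counts(self, context: Context) -> np.ndarray:
        context = tuple(context)
        row = self._counts.get(context)
        return row.copy() if row is not None else np.zeros(self.K)

    def row_alpha(self, context: Context) -> np.ndarray:
        """Current Dirichlet concentration vector for a context."""
        return self.counts(context) + self.prior_concentration

    def predictive(self, context: Context) -> np.ndarray:
        """Posterior-mean transition distribution for a context."""
        alpha = self.row_alpha(context)
        return alpha / alpha.sum()

    def observe(self, context: Context, symbol: int) -> "DirichletMarkovModel":
        """Conjugate update: add one observation of ``symbol`` after ``context``."""
        context = tuple(context)
        if len(context) != self.order:
            raise ValueError(f"context length {len(context)} != order {self.order}")
        self._check_tokens(context)
        self._check_tokens((symbol,))
        row = self._counts.setdefault(context, np.zeros(self.K))
        row[symbol] += self.increment
        return self

    def transition_estimate(
        self, context: Context, symbol: int, estimator: str = "posterior_mean"
    ) -> TransitionEstimate:
        """Estimate one transition probability and its reliability.

        ``estimator="posterior_mean"`` returns ``alpha_i/alpha_0``;
        ``"count_ratio"`` returns the raw observed-count fraction (1/K for
        an unobserved context). The reliability is always the inverse
        marginal Beta variance of the current Dirichlet row.
        """
        context = tuple(context)
        self._check_tokens(context)
        self._check_tokens((symbol,))
        alpha = self.row_alpha(context)
        alpha_0 = float(alpha.sum())
        variance = beta_variance(float(alpha[symbol]), alpha_0)
        if estimator == "posterior_mean":
            mean = float(alpha[symbol]) / alpha_0
        elif estimator == "count_ratio":
            counts = self.counts(context)
            total = counts.sum()
            mean = float(counts[symbol]) / total if total > 0 else 1.0 / self.K
        else:
            raise ValueError(f"unknown estimator {estimator!r}")
        return TransitionEstimate(mean, variance, 1.0 / variance)

    def copy(self) -> "DirichletMarkovModel":
        dup = DirichletMarkovModel(
            self.K,
            self.order,
            self.sensitivity_factor,
            self.base_concentration,
            self.sensitivity_mode,
        )
        dup._counts = {c: row.copy() for c, row in self._counts.items()}
        return dup

    # ------------------------------------------------------------------ #
    # serialization

    def to_json(self) -> str:
        payload = {
            "K": self.K,
            "order": self.order,
            "sensitivity_factor": self.sensitivity_factor,
            "base_concentration": self.base_concentration,
            "sensitivity_mode": self.sensitivity_mode,
            "rows": {
                ",".join(map(str, ctx)): row.tolist()
                for ctx, row in sorted(self._counts.items())
            },
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "DirichletMarkovModel":
        payload = json.loads(text)
        model = cls(
            payload["K"],
            payload["order"],
            payload["sensitivity_factor"],
            payload["base_concentration"],
            payload["sensitivity_mode"],
        )
        for key, row in payload["rows"].items():
            ctx = tuple(int(x) for x in key.split(","))
            model._counts[ctx] = np.asarray(row, dtype=float)
        return model


def init_model(
    K: int,
    order: int = 1,
    sensitivity_factor: float = 1.0,
    base_concentration: float = 1.0,
    sensitivity_mode: str = "prior",
) -> DirichletMarkovModel:
    """Create an untrained model (functional alias for the constructor)."""
    return DirichletMarkovModel(
        K, order, sensitivity_factor, base_concentration, sensitivity_mode
    )


def observe(
    model: DirichletMarkovModel, context: Context, symbol: int
) -> DirichletMarkovModel:
    """Add one observation (updates ``model`` in place and returns it)."""
    return model.observe(context, symbol)


def transition_estimate(
    model: DirichletMarkovModel,
    context: Context,
    symbol: int,
    estimator: str = "posterior_mean",
) -> TransitionEstimate:
    return model.transition_estimate(context, symbol, estimator)


def bayesian_surprise(row_before: Sequence[float], row_after: Sequence[float]) -> float:
    """KL divergence D(before || after) in nats between two predictive rows.

    Both inputs must be strictly positive probability vectors of equal
    length summing to 1 (Dirichlet posterior means always are).
    """
    p = np.asarray(row_before, dtype=float)
    q = np.asarray(row_after, dtype=float)
    if p.shape != q.shape:
        raise ValueError("distribution length mismatch")
    if abs(p.sum() - 1.0) > 1e-9 or abs(q.sum() - 1.0) > 1e-9:
        raise ValueError("inputs must sum to 1")
    if np.any(p <= 0) or np.any(q <= 0):
        raise ValueError("inputs must be strictly positive")
    return float(rel_entr(p, q).sum())


def conditional_entropy(
    model: DirichletMarkovModel, weights: Mapping[Context, float]
) -> float:
    """Conditional entropy H(next | context) in bits.

    ``-sum_c w(c) sum_i p(i|c) log2 p(i|c)`` over the given context weights
    (a probability distribution over contexts), using the model's current
    posterior-mean transition rows.
    """
    total_weight = float(sum(weights.values()))
    if abs(total_weight - 1.0) > 1e-9:
        raise ValueError("context weights must sum to 1")
    entropy = 0.0
    for context, w in weights.items():
        p = model.predictive(tuple(context))
        entropy -= w * float(xlogy(p, p).sum()) / np.log(2.0)
    return entropy


def empirical_context_weights(
    tokens: Sequence[int], order: int = 1
) -> dict[Context, float]:
    """Relative frequencies of contexts in a token stream."""
    counts: dict[Context, int] = {}
    for t in range(order, len(tokens)):
        ctx = tuple(tokens[t - order : t])
        counts[ctx] = counts.get(ctx, 0) + 1
    total = sum(counts.values())
    return {c: n / total for c, n in counts.items()}


def learn_sequence(
    model: DirichletMarkovModel,
    tokens: Sequence[int],
    trial_index: int = 1,
    record: bool = True,
) -> tuple[DirichletMarkovModel, LearningTrace]:
    """One learning pass over a token stream.

    For each position t >= order: capture the predictive row of the current
    context, observe the symbol, and record the Bayesian surprise between
    the before/after predictive rows. A sequence shorter than order+1 leaves
    the model unchanged and yields an empty trace.
    """
    trace = LearningTrace(trial_index=trial_index)
    if len(tokens) < model.order + 1:
        return model, trace
    for t in range(model.order, len(tokens)):
        context = tuple(tokens[t - model.order : t])
        symbol = tokens[t]
        if record:
            before = model.predictive(context)
            model.observe(context, symbol)
            after = model.predictive(context)
            trace.per_event_surprise.append(bayesian_surprise(before, after))
        else:
            model.observe(context, symbol)
    return model, trace
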