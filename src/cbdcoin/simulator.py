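"""Generalized-coin simulator.

A generalized coin with n facet pairs is a black box: a "toss" in context
Ci = {Ai, A(i+1) mod n} reveals outcomes for the two adjacent facets with
perfect anticorrelation — exactly one of the pair comes up top.  The ideal
coin is fair (designated probability 0.5 in every context); biased variants
with arbitrary per-context probabilities cover the empirical face "coins",
so one sampling engine serves both.

Only the behavior P(a|x) is modelled; rotation axes and detector geometry
add nothing to the statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Tuple

import numpy as np

from cbdcoin.cbd import CycleBehavior, context_correlation
from cbdcoin.datamodel import ContextJoint, ContextLabel

#: outcome pair for the ordered facets (Ai, A(i+1)): True = top (dark / fake)
Outcome = Tuple[bool, bool]

TOP_BOT: Outcome = (True, False)
BOT_TOP: Outcome = (False, True)


@dataclass(frozen=True)
class CoinSpec:
    """A generalized coin: cycle length and per-context designated probability.

    ``designated_prob[i]`` is P(top, bot | Ci) — the chance the *first* facet
    of context i's ordered pair comes up top.  The ideal coin uses 0.5
    everywhere.
    """

    n_cycle: int = 4
    designated_prob: Tuple[float, ...] = (0.5, 0.5, 0.5, 0.5)

    def __post_init__(self) -> None:
        if self.n_cycle < 3:
            raise ValueError("generalized coins need n >= 3")
        if len(self.designated_prob) != self.n_cycle:
            raise ValueError("one designated probability per context required")
        for p in self.designated_prob:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")

    @classmethod
    def ideal(cls, n_cycle: int = 4) -> "CoinSpec":
        return cls(n_cycle=n_cycle, designated_prob=tuple(0.5 for _ in range(n_cycle)))


def _context_index(spec: CoinSpec, context: ContextLabel | int) -> int:
    i = context.index if isinstance(context, ContextLabel) else int(context)
    if not 0 <= i < spec.n_cycle:
        raise ValueError(f"context index {i} invalid for an n={spec.n_cycle} coin")
    return i


def toss(spec: CoinSpec, context: ContextLabel | int, rng: np.random.Generator) -> Outcome:
    """One toss: (top, bot) with the context's designated probability, else
    (bot, top); (top, top) and (bot, bot) never occur."""
    i = _context_index(spec, context)
    return TOP_BOT if rng.random() < spec.designated_prob[i] else BOT_TOP


def toss_stream(
    spec: CoinSpec, context: ContextLabel | int, n_tosses: int, rng: np.random.Generator
) -> Iterator[Outcome]:
    """Lazy stream of tosses in one context, consuming ``rng`` sequentially."""
    for _ in range(n_tosses):
        yield toss(spec, context, rng)


def context_rng(seed: int, context_index: int) -> np.random.Generator:
    """Per-context substream so streamed and batch sampling agree exactly."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(context_index,)))


def estimate_behavior(
    spec: CoinSpec, n_tosses: int, seed: int
) -> Tuple[List[ContextJoint], CycleBehavior]:
    """Empirical joint distributions and behavior from n_tosses per context.

    Each context uses its own seed-derived substream; a batch draw consumes
    the substream identically to sequential ``toss`` calls, so streamed and
    batch estimates coincide for the same seed.  Single marginals pool each
    facet's outcomes over the two contexts containing it; non-adjacent
    pairwise-top entries are not measurable and are recorded as 0.
    """
    if n_tosses < 1:
        raise ValueError("n_tosses must be >= 1")
    n = spec.n_cycle
    joints: List[ContextJoint] = []
    # top counts per facet pooled over its two contexts
    facet_top = np.zeros(n)
    correlations = []
    pairwise: Dict[Tuple[int, int], float] = {}
    for i in range(n):
        rng = context_rng(seed, i)
        first_top = rng.random(n_tosses) < spec.designated_prob[i]
        a = float(np.mean(first_top))  # empirical P(top, bot | Ci)
        probs = (0.0, a, 1.0 - a, 0.0)
        joint = ContextJoint(context=ContextLabel(i, n_facets=n), probs=probs)
        joints.append(joint)
        correlations.append(context_correlation(joint))
        j = (i + 1) % n
        facet_top[i] += a * n_tosses
        facet_top[j] += (1.0 - a) * n_tosses
        pairwise[tuple(sorted((i, j)))] = 0.0  # forced choice: never both top
    for pair in [(i, j) for i in range(n) for j in range(i + 1, n)]:
        pairwise.setdefault(pair, 0.0)
    behavior = CycleBehavior(
        n_cycle=n,
        single_marginals=tuple(float(x) for x in facet_top / (2 * n_tosses)),
        pairwise_top=pairwise,
        context_correlations=tuple(correlations),
    )
    return joints, behavior
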