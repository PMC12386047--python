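"""Core statistics for cyclic systems of binary random variables.

A rank-n cyclic system measures n dichotomous variables A0..A(n-1) in n
contexts Ci = {Ai, A(i+1) mod n}.  Contextuality in the presence of
disturbance is diagnosed by the criterion

    s_odd - (n - 2) - Delta > 0

where s_odd aggregates the context correlations with an odd number of sign
flips and Delta measures how much each variable's marginal shifts between
the two contexts containing it.

Two s_odd conventions are implemented and kept strictly separate:

* ``canonical`` — the standard cyclic-systems definition: the maximum of
  sum(lambda_i * c_i) over sign vectors lambda in {-1,+1}^n with an odd
  number of -1 entries.  Four perfect anticorrelations give s_odd = 2.
* ``paper`` — the convention required to reproduce the published face-study
  table, under which four perfect anticorrelations give s_odd = 3 and the
  criterion value reduces to 1 - Delta for every forced-choice coin.  It is
  read as: the maximal sum of correlation magnitudes over a subset of
  contexts containing an odd number of negative correlations.

Delta here is on the probability scale (sum of absolute marginal
differences), not the +/-1-expectation scale used elsewhere in the cyclic
systems literature (which would double it).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Sequence, Tuple

from cbdcoin.datamodel import (
    CoinMarginals,
    ContextCounts,
    ContextJoint,
    N_FACETS,
)


@dataclass(frozen=True)
class CycleBehavior:
    """Complete statistical description of a rank-n cyclic system.

    ``single_marginals[i]`` is P(top | Ai); ``pairwise_top[(i, j)]`` is
    P(top, top | Ai, Aj) for i < j — adjacent pairs are measured in a
    context, non-adjacent pairs are not measurable in the cyclic design and
    must be supplied by assumption; ``context_correlations[i]`` is the
    expectation of the +/-1-coded product in context Ci.
    """

    n_cycle: int
    single_marginals: Tuple[float, ...]
    pairwise_top: Mapping[Tuple[int, int], float]
    context_correlations: Tuple[float, ...]

    def __post_init__(self) -> None:
        if self.n_cycle < 3:
            raise ValueError("cyclic systems need n >= 3")
        if len(self.single_marginals) != self.n_cycle:
            raise ValueError("one single marginal per facet required")
        if len(self.context_correlations) != self.n_cycle:
            raise ValueError("one correlation per context required")
        for p in self.single_marginals:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"marginal {p} outside [0, 1]")
        for q in self.pairwise_top.values():
            if not 0.0 <= q <= 1.0:
                raise ValueError(f"pairwise probability {q} outside [0, 1]")
        for c in self.context_correlations:
            if not -1.0 <= c <= 1.0:
                raise ValueError(f"correlation {c} outside [-1, 1]")


def marginals_from_counts(
    counts: Sequence[ContextCounts] | Mapping[int, ContextCounts],
    gender_group: str = "F",
) -> CoinMarginals:
    """Estimate a coin's marginals p0..p3 as k/n from its four context tallies.

    All four contexts must be present with n > 0; the designated-outcome
    convention is already baked into each tally's k.
    """
    if isinstance(counts, Mapping):
        by_ctx: Dict[int, ContextCounts] = {i: c for i, c in counts.items()}
    else:
        by_ctx = {c.context.index: c for c in counts}
    missing = sorted(set(range(N_FACETS)) - set(by_ctx))
    if missing:
        raise ValueError(f"missing context cell(s): {['C%d' % i for i in missing]}")
    coin_ids = {c.coin_id for c in by_ctx.values()}
    if len(coin_ids) != 1:
        raise ValueError(f"counts span multiple coins: {sorted(coin_ids)}")
    p = tuple(by_ctx[i].k / by_ctx[i].n for i in range(N_FACETS))
    return CoinMarginals(coin_id=coin_ids.pop(), gender_group=gender_group, p=p)


def disturbance_delta(m: CoinMarginals | Sequence[float]) -> float:
    """Disturbance Delta: sum of absolute marginal differences around the cycle.

    Each facet appears in two contexts; Delta adds up how far its two
    marginal estimates disagree:

        Delta = |p0 - p3| + |p1 - p0| + |p1 - p2| + |p3 - p2|

    (F0 across C0/C3, R1 across C0/C1, F2 across C1/C2, R3 across C2/C3).
    Zero disturbance means a marginally selective (nondisturbing) system.
    """
    p0, p1, p2, p3 = m.p if isinstance(m, CoinMarginals) else tuple(m)
    return abs(p0 - p3) + abs(p1 - p0) + abs(p1 - p2) + abs(p3 - p2)


def context_correlation(joint: ContextJoint) -> float:
    """Expectation of the outcome product with top coded +1 and bot coded -1."""
    bb, tb, bt, tt = joint.probs
    return bb + tt - tb - bt


def s_odd(correlations: Sequence[float], convention: str = "paper") -> float:
    """Odd-signed aggregate of context correlations.

    canonical: max over sign vectors with an odd number of -1 entries of the
    signed sum; computed in closed form (sum of |c_i|, minus twice the
    smallest |c_i| when the count of negative correlations is even).

    paper: max over context subsets containing an odd number of negative
    correlations of the sum of |c_i| over the subset.  For four perfect
    anticorrelations this yields 3 (drop one of the four -1 terms), so the
    forced-choice criterion value is 1 - Delta; for the maximally contextual
    pattern (+1, +1, +1, -1) both conventions yield 4.
    """
    c = [float(x) for x in correlations]
    if len(c) < 3:
        raise ValueError("s_odd needs at least 3 context correlations")
    for x in c:
        if not -1.0 <= x <= 1.0:
            raise ValueError(f"correlation {x} outside [-1, 1]")
    n_neg = sum(1 for x in c if x < 0)
    total = sum(abs(x) for x in c)
    if convention == "canonical":
        if n_neg % 2 == 1:
            return total
        return total - 2.0 * min(abs(x) for x in c)
    if convention == "paper":
        if n_neg == 0:
            raise ValueError(
                "paper-convention s_odd requires at least one negative "
                "correlation (forced-choice contexts anticorrelate)"
            )
        if n_neg % 2 == 1:
            return total
        # drop the weakest negative correlation to make the count odd
        return total - min(abs(x) for x in c if x < 0)
    raise ValueError(f"unknown convention {convention!r}")


def cbd_statistic(s_odd_value: float, n_cycle: int, delta: float) -> float:
    """Left-hand side of the cyclic contextuality criterion.

    Returns s_odd - (n - 2) - Delta; a positive value indicates the system
    is contextual by the point criterion.
    """
    if n_cycle < 3:
        raise ValueError("cyclic systems need n >= 3")
    if delta < 0:
        raise ValueError("delta must be nonnegative")
    return s_odd_value - (n_cycle - 2) - delta


def forced_choice_correlations(n_cycle: int = 4) -> Tuple[float, ...]:
    """Context correlations of any forced-choice behavior: all exactly -1."""
    return tuple(-1.0 for _ in range(n_cycle))


def analyze_marginals(
    m: CoinMarginals | Sequence[float], convention: str = "paper"
) -> Tuple[float, float, float]:
    """(Delta, s_odd, criterion value) of a forced-choice 4-cycle coin."""
    delta = disturbance_delta(m)
    s = s_odd(forced_choice_correlations(N_FACETS), convention=convention)
    return delta, s, cbd_statistic(s, N_FACETS, delta)


def boole_lhs(behavior: CycleBehavior) -> Tuple[float, bool]:
    """Boole's condition of possible experience for four binary events.

    Evaluates sum(p_i) - sum(p_ij) over the four singles and all six pairs
    and returns (value, value <= 1).  A value above 1 means no joint
    probability distribution over A0..A3 can reproduce the behavior — for a
    nondisturbing system, the signature of contextuality.  The two
    non-adjacent pairwise probabilities (A0,A2) and (A1,A3) are not
    measurable in the cyclic design; the caller supplies them explicitly
    (the coin analysis passes 0).
    """
    if behavior.n_cycle != 4:
        raise ValueError("this inequality is specific to the 4-cycle")
    pairs = [(i, j) for i in range(4) for j in range(i + 1, 4)]
    missing = [p for p in pairs if p not in behavior.pairwise_top]
    if missing:
        raise ValueError(f"missing pairwise_top entries: {missing}")
    value = float(
        sum(behavior.single_marginals) - sum(behavior.pairwise_top[p] for p in pairs)
    )
    return value, value <= 1.0
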