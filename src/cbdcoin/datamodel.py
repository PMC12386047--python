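"""Domain types for the 4-cycle forced-choice design.

Conventions, fixed once here and relied on everywhere else:

* Facets are indexed 0-3.  Even indices are AI-generated ("fake") faces,
  odd indices are real faces; the labels are F0, R1, F2, R3.
* Context i pairs facets (i, (i+1) mod 4): C0={F0,R1}, C1={R1,F2},
  C2={F2,R3}, C3={R3,F0}.
* Each context has a *designated* facet whose probability of being judged
  fake defines that context's marginal p_i: the fake member of the pair
  (F0 for C0 and C3, F2 for C1 and C2).
* Joint-outcome probabilities are ordered (bot_bot, top_bot, bot_top,
  top_top) where "top" means judged fake.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

N_FACETS = 4

FACET_LABELS: Tuple[str, ...] = ("F0", "R1", "F2", "R3")

#: designated facet per context index: the fake face of the pair
_DESIGNATED = {0: 0, 1: 2, 2: 2, 3: 0}


@dataclass(frozen=True)
class FacetRole:
    """One facet of the coin: a single face image and its ground-truth role."""

    index: int

    def __post_init__(self) -> None:
        if not 0 <= self.index < N_FACETS:
            raise ValueError(f"facet index must be 0-3, got {self.index}")

    @property
    def role(self) -> str:
        """'fake' for even indices (AI-generated), 'real' for odd."""
        return "fake" if self.index % 2 == 0 else "real"

    @property
    def label(self) -> str:
        return FACET_LABELS[self.index]


@dataclass(frozen=True)
class ContextLabel:
    """Measurement context Ci: the pair of adjacent facets shown together.

    The face study is a 4-cycle; ``n_facets`` generalizes the label for
    simulated coins with other cycle lengths.
    """

    index: int
    n_facets: int = N_FACETS

    def __post_init__(self) -> None:
        if self.n_facets < 3:
            raise ValueError("cyclic systems need at least 3 facets")
        if not 0 <= self.index < self.n_facets:
            raise ValueError(
                f"context index must be 0-{self.n_facets - 1}, got {self.index}"
            )

    @property
    def facet_pair(self) -> Tuple[int, int]:
        return (self.index, (self.index + 1) % self.n_facets)

    @property
    def label(self) -> str:
        return f"C{self.index}"

    @classmethod
    def from_string(cls, s: str) -> "ContextLabel":
        s = s.strip()
        if len(s) == 2 and s[0] in "Cc" and s[1].isdigit():
            return cls(int(s[1]))
        if s.isdigit():
            return cls(int(s))
        raise ValueError(f"cannot parse context label {s!r} (expected C0-C3)")


def designated_outcome(context: ContextLabel) -> int:
    """Facet whose top-probability defines the context's marginal p_i.

    In every context exactly one member of the pair is AI-generated; the
    marginal p_i is the probability that *that* facet is judged fake.  Hence
    C0 -> F0, C1 -> F2, C2 -> F2, C3 -> F0.
    """
    if not isinstance(context, ContextLabel):
        context = ContextLabel(int(context))
    if context.n_facets != N_FACETS:
        raise ValueError("designated outcomes are defined for the 4-cycle design")
    return _DESIGNATED[context.index]


@dataclass(frozen=True)
class JudgmentRecord:
    """One participant's forced-choice judgment of one coin in one context.

    ``judged_fake_facet`` is the facet the participant clicked as fake; the
    other facet of the pair is implicitly judged real.  Joint outcomes
    (fake, fake) and (real, real) are impossible by task design.
    ``position_swapped`` records counterbalancing (real face shown on the
    right when True); it is carried through I/O but ignored by statistics.
    """

    coin_id: int
    gender_group: str
    context: ContextLabel
    participant_id: str
    position_swapped: bool
    judged_fake_facet: int

    def __post_init__(self) -> None:
        if not 1 <= self.coin_id <= 20:
            raise ValueError(f"coin_id must be 1-20, got {self.coin_id}")
        if self.gender_group not in ("F", "M"):
            raise ValueError(f"gender_group must be 'F' or 'M', got {self.gender_group!r}")
        if self.judged_fake_facet not in self.context.facet_pair:
            raise ValueError(
                f"judged facet {self.judged_fake_facet} not in context "
                f"{self.context.label}'s pair {self.context.facet_pair}"
            )


@dataclass(frozen=True)
class ContextCounts:
    """Per-(coin, context) tally: n judgments, k of the designated outcome."""

    coin_id: int
    context: ContextLabel
    n: int
    k: int

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError(f"n must be positive, got {self.n}")
        if not 0 <= self.k <= self.n:
            raise ValueError(f"k must satisfy 0 <= k <= n, got k={self.k}, n={self.n}")

    @property
    def frequency(self) -> float:
        return self.k / self.n


@dataclass(frozen=True)
class CoinMarginals:
    """The four marginal probabilities p0..p3 of one coin.

    p_i is the probability that the designated (fake) facet of context Ci is
    judged fake: p0 = P(F0 top | C0), p1 = P(F2 top | C1),
    p2 = P(F2 top | C2), p3 = P(F0 top | C3).
    """

    coin_id: int
    gender_group: str
    p: Tuple[float, float, float, float]

    def __post_init__(self) -> None:
        if len(self.p) != 4:
            raise ValueError("expected exactly four marginals")
        for i, pi in enumerate(self.p):
            if not 0.0 <= pi <= 1.0:
                raise ValueError(f"p{i}={pi} outside [0, 1]")

    def __getitem__(self, i: int) -> float:
        return self.p[i]


@dataclass(frozen=True)
class ContextJoint:
    """Joint outcome distribution of one context.

    Probabilities ordered (bot_bot, top_bot, bot_top, top_top) for the
    ordered facet pair of the context.  Forced-choice data has
    P(bot_bot) = P(top_top) = 0 exactly.
    """

    context: ContextLabel
    probs: Tuple[float, float, float, float]

    def __post_init__(self) -> None:
        if len(self.probs) != 4:
            raise ValueError("expected four joint probabilities")
        for q in self.probs:
            if not 0.0 <= q <= 1.0:
                raise ValueError(f"joint probability {q} outside [0, 1]")
        if abs(sum(self.probs) - 1.0) > 1e-12:
            raise ValueError(f"joint probabilities sum to {sum(self.probs)}, not 1")

    @property
    def is_forced_choice(self) -> bool:
        return self.probs[0] == 0.0 and self.probs[3] == 0.0


@dataclass(frozen=True)
class ContextualityResult:
    """Per-coin analysis output: disturbance, criterion value, interval, flag."""

    coin_id: int
    delta: float
    s_odd: float
    cbd_value: float
    ci_lower: float
    ci_upper: float
    ci_level: float
    n_boot: int
    seed: int
    contextual: bool
    convention: str = "paper"
    marginals: Optional[CoinMarginals] = None
    #: bootstrap standard error of the criterion value (beyond the published
    #: table, which reports intervals only)
    boot_se: Optional[float] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.delta < 0:
            raise ValueError("delta must be nonnegative")
        if self.ci_lower > self.ci_upper:
            raise ValueError("ci_lower must not exceed ci_upper")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must lie in (0, 1)")
        if self.n_boot < 1:
            raise ValueError("n_boot must be positive")
        if self.convention not in ("paper", "canonical"):
            raise ValueError(f"unknown convention {self.convention!r}")
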