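"""Synthetic judgment-data generator emulating the crowdsourced study design.

Design emulated: a between-subjects layout with four measurement contexts,
50 participants per context (200 total), each participant judging all 20
coins (10 female image sets followed by 10 male), one forced-choice
judgment per coin, with left/right presentation counterbalanced within
every (context, face-pair) cell.

Judgments are conditionally independent Bernoulli draws given the coin's
per-context marginal — the minimal model consistent with an analysis that
uses only cell frequencies.  No participant random effects are modelled.
Default true marginals are the published study estimates, so a
study-shaped dataset regenerates from a seed alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np

from cbdcoin.cbd import marginals_from_counts
from cbdcoin.datamodel import (
    CoinMarginals,
    ContextCounts,
    ContextLabel,
    JudgmentRecord,
    N_FACETS,
    designated_outcome,
)
from cbdcoin.io import tally
from cbdcoin.reference import STUDY_N_PER_CONTEXT, study_marginals


@dataclass(frozen=True)
class ExperimentDesign:
    """Between-subjects design parameters for the generator."""

    n_participants_per_context: int = STUDY_N_PER_CONTEXT
    true_marginals: Mapping[int, CoinMarginals] = field(default_factory=study_marginals)
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants_per_context < 1:
            raise ValueError("need at least one participant per context")
        if not self.true_marginals:
            raise ValueError("true_marginals must cover at least one coin")

    @property
    def coin_ids(self) -> Tuple[int, ...]:
        return tuple(sorted(self.true_marginals))


def generate_judgments(design: ExperimentDesign) -> List[JudgmentRecord]:
    """Draw one full synthetic dataset.

    For each coin, context and participant, the designated (fake) facet is
    judged fake with probability p_i(coin), otherwise the other facet of the
    pair is.  position_swapped alternates with participant parity, so within
    every (coin, context) cell the swapped/unswapped counts differ by at
    most one (exact 50/50 when the participant count is even).  Fully
    reproducible from ``master_seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(design.master_seed))
    n_pp = design.n_participants_per_context
    records: List[JudgmentRecord] = []
    for ctx_i in range(N_FACETS):
        ctx = ContextLabel(ctx_i)
        designated = designated_outcome(ctx)
        other = ctx.facet_pair[0] if ctx.facet_pair[1] == designated else ctx.facet_pair[1]
        for coin_id in design.coin_ids:
            m = design.true_marginals[coin_id]
            hits = rng.random(n_pp) < m[ctx_i]
            for p_idx in range(n_pp):
                records.append(
                    JudgmentRecord(
                        coin_id=coin_id,
                        gender_group=m.gender_group,
                        context=ctx,
                        participant_id=f"C{ctx_i}-P{p_idx + 1:03d}",
                        position_swapped=bool(p_idx % 2),
                        judged_fake_facet=designated if hits[p_idx] else other,
                    )
                )
    return records


def generate_counts(design: ExperimentDesign) -> Dict[int, List["ContextCounts"]]:
    """Cell tallies of the same synthetic experiment, without materializing
    per-record objects.

    Consumes the master-seed random stream exactly as
    :func:`generate_judgments` does, so for equal designs
    ``tally(generate_judgments(d))`` and ``generate_counts(d)`` agree
    count-for-count; use this path for large simulated sample sizes.
    """
    rng = np.random.default_rng(np.random.SeedSequence(design.master_seed))
    n_pp = design.n_participants_per_context
    out: Dict[int, List[ContextCounts]] = {c: [] for c in design.coin_ids}
    for ctx_i in range(N_FACETS):
        for coin_id in design.coin_ids:
            m = design.true_marginals[coin_id]
            k = int(np.sum(rng.random(n_pp) < m[ctx_i]))
            out[coin_id].append(
                ContextCounts(coin_id=coin_id, context=ContextLabel(ctx_i), n=n_pp, k=k)
            )
    return out


def recover_marginals(records: Sequence[JudgmentRecord]) -> Dict[int, CoinMarginals]:
    """Point estimates k/n per coin from raw records (tally then divide)."""
    counts = tally(records)
    by_coin: Dict[int, list] = {}
    gender: Dict[int, str] = {}
    for c in counts:
        by_coin.setdefault(c.coin_id, []).append(c)
    for r in records:
        gender.setdefault(r.coin_id, r.gender_group)
    return {
        coin: marginals_from_counts(cell_list, gender_group=gender[coin])
        for coin, cell_list in sorted(by_coin.items())
    }
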