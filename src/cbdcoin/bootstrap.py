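"""Percentile-bootstrap confidence intervals for the contextuality statistic.

The resampling unit is the individual judgment within each (coin, context)
cell: a replicate redraws each context's k* ~ Binomial(n, k/n), recomputes
the marginals, the disturbance Delta, and the criterion value, and the
interval is formed from empirical quantiles of the replicates.  Because
every participant contributes exactly one judgment per coin, this is
marginally equivalent to resampling participants, and it permits analysis
straight from a published marginals table without the raw records.

Seeding: one master seed per run; each coin draws from an independent
substream derived via ``numpy.random.SeedSequence(master, spawn_key=(coin,))``
so any coin can be recomputed on its own.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from cbdcoin.cbd import cbd_statistic, forced_choice_correlations, s_odd
from cbdcoin.datamodel import ContextCounts, ContextualityResult, N_FACETS


@dataclass(frozen=True)
class BootstrapConfig:
    n_iter: int = 10_000
    ci_level: float = 0.95
    seed: int = 0
    convention: str = "paper"

    def __post_init__(self) -> None:
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must lie in (0, 1)")
        if self.convention not in ("paper", "canonical"):
            raise ValueError(f"unknown convention {self.convention!r}")


def coin_rng(master_seed: int, coin_id: int) -> np.random.Generator:
    """Independent, reproducible random stream for one coin."""
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=(coin_id,)))


def _deltas(p: np.ndarray) -> np.ndarray:
    """Disturbance for each row of a (B, 4) marginal array."""
    return (
        np.abs(p[:, 0] - p[:, 3])
        + np.abs(p[:, 1] - p[:, 0])
        + np.abs(p[:, 1] - p[:, 2])
        + np.abs(p[:, 3] - p[:, 2])
    )


def bootstrap_cbd(
    counts: Sequence[ContextCounts] | Mapping[int, ContextCounts],
    config: BootstrapConfig,
) -> ContextualityResult:
    """Point estimate plus percentile CI of the criterion value for one coin.

    Forced choice fixes every context correlation at -1 in every replicate,
    so s_odd is constant and only Delta is resampled: under the paper
    convention each replicate's criterion value is 1 - Delta*.  Quantiles
    use numpy's default linear interpolation.
    """
    if isinstance(counts, Mapping):
        by_ctx = dict(counts)
    else:
        by_ctx = {c.context.index: c for c in counts}
    missing = sorted(set(range(N_FACETS)) - set(by_ctx))
    if missing:
        raise ValueError(f"missing context cell(s): {['C%d' % i for i in missing]}")
    coin_ids = {c.coin_id for c in by_ctx.values()}
    if len(coin_ids) != 1:
        raise ValueError(f"counts span multiple coins: {sorted(coin_ids)}")
    coin_id = coin_ids.pop()

    n = np.array([by_ctx[i].n for i in range(N_FACETS)])
    k = np.array([by_ctx[i].k for i in range(N_FACETS)])
    phat = k / n

    s = s_odd(forced_choice_correlations(N_FACETS), convention=config.convention)
    point_delta = float(_deltas(phat[None, :])[0])
    point_cbd = cbd_statistic(s, N_FACETS, point_delta)

    rng = coin_rng(config.seed, coin_id)
    k_star = rng.binomial(n[None, :], phat[None, :], size=(config.n_iter, N_FACETS))
    cbd_star = s - (N_FACETS - 2) - _deltas(k_star / n[None, :])

    alpha = 1.0 - config.ci_level
    lo, hi = np.quantile(cbd_star, [alpha / 2.0, 1.0 - alpha / 2.0])

    result = ContextualityResult(
        coin_id=coin_id,
        delta=point_delta,
        s_odd=s,
        cbd_value=point_cbd,
        ci_lower=float(lo),
        ci_upper=float(hi),
        ci_level=config.ci_level,
        n_boot=config.n_iter,
        seed=config.seed,
        contextual=False,
        convention=config.convention,
        marginals=None,
        boot_se=float(np.std(cbd_star, ddof=1)) if config.n_iter > 1 else None,
    )
    return ContextualityResult(
        **{**result.__dict__, "contextual": classify_contextual(result)}
    )


def classify_contextual(result: ContextualityResult) -> bool:
    """Study classification rule: the point value lies inside the interval
    (inclusive) and the interval's lower endpoint is strictly above 0."""
    return (
        result.ci_lower <= result.cbd_value <= result.ci_upper
        and result.ci_lower > 0.0
    )
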