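"""Published per-coin marginal estimates from the crowdsourced face study.

Twenty image sets ("coins"), each of two AI-generated and two real faces of
the same gender: coins 1-10 female, 11-20 male.  Each entry gives the
estimated marginals (p0, p1, p2, p3) — the per-context frequencies with
which the designated fake face was judged fake by 50 participants per
context.  These are the default true marginals of the synthetic-data
generator, so a study-shaped dataset can be regenerated with no download,
and the default input of the marginals-table analysis path.
"""

from __future__ import annotations

from typing import Dict, Tuple

from cbdcoin.datamodel import CoinMarginals

STUDY_MARGINALS: Dict[int, Tuple[float, float, float, float]] = {
    1: (0.56, 0.46, 0.42, 0.46),
    2: (0.62, 0.72, 0.60, 0.60),
    3: (0.32, 0.30, 0.78, 0.72),
    4: (0.32, 0.78, 0.36, 0.12),
    5: (0.76, 0.80, 0.38, 0.20),
    6: (0.64, 0.54, 0.36, 0.36),
    7: (0.66, 0.30, 0.38, 0.64),
    8: (0.76, 0.84, 0.55, 0.66),
    9: (0.28, 0.58, 0.52, 0.30),
    10: (0.50, 0.66, 0.30, 0.22),
    11: (0.80, 0.62, 0.28, 0.22),
    12: (0.72, 0.74, 0.50, 0.54),
    13: (0.16, 0.34, 0.26, 0.18),
    14: (0.50, 0.32, 0.84, 0.66),
    15: (0.42, 0.48, 0.56, 0.44),
    16: (0.48, 0.62, 0.36, 0.36),
    17: (0.50, 0.26, 0.24, 0.42),
    18: (0.40, 0.70, 0.54, 0.14),
    19: (0.40, 0.38, 0.76, 0.88),
    20: (0.18, 0.22, 0.52, 0.50),
}

STUDY_GENDERS: Dict[int, str] = {c: ("F" if c <= 10 else "M") for c in STUDY_MARGINALS}

#: participants per measurement context in the study
STUDY_N_PER_CONTEXT = 50


def study_marginals() -> Dict[int, CoinMarginals]:
    """The study's marginal table as domain objects, keyed by coin id."""
    return {
        c: CoinMarginals(coin_id=c, gender_group=STUDY_GENDERS[c], p=p)
        for c, p in STUDY_MARGINALS.items()
    }
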