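"""Shared fixtures: the published study table and small synthetic designs."""

import pytest

from cbdcoin.reference import study_marginals
from cbdcoin.synthetic import ExperimentDesign

#: published per-coin results used as expected values throughout the suite:
#: coin -> (Delta, CbD, interval lower, interval upper)
STUDY_RESULTS = {
    1: (0.28, 0.72, 0.24, 0.88),
    2: (0.24, 0.76, 0.24, 0.88),
    3: (0.96, 0.04, -0.32, 0.26),
    4: (1.32, -0.32, -0.60, -0.02),
    5: (1.20, -0.20, -0.52, 0.06),
    6: (0.56, 0.44, 0.02, 0.66),
    7: (0.72, 0.28, -0.12, 0.52),
    8: (0.58, 0.42, 0.06, 0.70),
    9: (0.60, 0.40, 0.00, 0.62),
    10: (0.88, 0.12, -0.22, 0.42),
    11: (1.16, -0.16, -0.48, 0.12),
    12: (0.48, 0.52, 0.10, 0.72),
    13: (0.36, 0.64, 0.26, 0.82),
    14: (1.04, -0.04, -0.38, 0.28),
    15: (0.26, 0.74, 0.24, 0.88),
    16: (0.52, 0.48, 0.04, 0.72),
    17: (0.52, 0.48, 0.08, 0.70),
    18: (1.12, -0.12, -0.44, 0.20),
    19: (1.00, 0.00, -0.43, 0.22),
    20: (0.68, 0.32, -0.06, 0.52),
}

#: coins the study classified as contextual
STUDY_CONTEXTUAL = {1, 2, 6, 8, 12, 13, 15, 16, 17}


@pytest.fixture(scope="session")
def study():
    return study_marginals()


@pytest.fixture
def small_design():
    """Four participants per context over the full 20 coins: fast but exercises
    every code path."""
    return ExperimentDesign(n_participants_per_context=4, master_seed=7)
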