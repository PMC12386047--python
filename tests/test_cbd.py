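"""Core cyclic-system statistics, with brute-force oracles for s_odd and
Boole's inequality."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cbdcoin.cbd import (
    CycleBehavior,
    analyze_marginals,
    boole_lhs,
    cbd_statistic,
    context_correlation,
    disturbance_delta,
    forced_choice_correlations,
    marginals_from_counts,
    s_odd,
)
from cbdcoin.datamodel import CoinMarginals, ContextCounts, ContextJoint, ContextLabel


def counts_for(coin_id, ks, n=50):
    return [
        ContextCounts(coin_id=coin_id, context=ContextLabel(i), n=n, k=k)
        for i, k in enumerate(ks)
    ]


class TestMarginals:
    @pytest.mark.parametrize(
        "ks,expected",
        [
            ((28, 23, 21, 23), (0.56, 0.46, 0.42, 0.46)),
            ((50, 50, 50, 50), (1.0, 1.0, 1.0, 1.0)),
            ((8, 17, 13, 9), (0.16, 0.34, 0.26, 0.18)),
        ],
    )
    def test_frequencies_from_counts(self, ks, expected):
        m = marginals_from_counts(counts_for(1, ks))
        assert m.p == pytest.approx(expected, abs=1e-12)

    def test_missing_context_rejected(self):
        with pytest.raises(ValueError, match="missing context"):
            marginals_from_counts(counts_for(1, (28, 23, 21, 23))[:3])

    def test_mixed_coins_rejected(self):
        cells = counts_for(1, (28, 23, 21, 23))[:2] + counts_for(2, (1, 2, 3, 4))[2:]
        with pytest.raises(ValueError, match="multiple coins"):
            marginals_from_counts(cells)


class TestDisturbance:
    @pytest.mark.parametrize(
        "p,expected",
        [
            ((0.56, 0.46, 0.42, 0.46), 0.28),
            ((0.32, 0.78, 0.36, 0.12), 1.32),
            ((0.3, 0.3, 0.3, 0.3), 0.0),
            ((0.16, 0.34, 0.26, 0.18), 0.36),
        ],
    )
    def test_delta_values(self, p, expected):
        assert disturbance_delta(p) == pytest.approx(expected, abs=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=4, max_size=4))
    @settings(derandomize=True, deadline=None)
    def test_delta_bounded_and_reflection_invariant(self, p):
        d = disturbance_delta(p)
        assert 0.0 <= d <= 4.0
        assert disturbance_delta(p[::-1]) == pytest.approx(d, abs=1e-12)


class TestCorrelation:
    def test_forced_choice_anticorrelates(self):
        for a in (0.0, 0.3, 1.0):
            j = ContextJoint(ContextLabel(0), (0.0, a, 1.0 - a, 0.0))
            assert context_correlation(j) == -1.0

    def test_perfect_and_zero_correlation(self):
        assert context_correlation(ContextJoint(ContextLabel(0), (0.5, 0, 0, 0.5))) == 1.0
        assert context_correlation(ContextJoint(ContextLabel(0), (0.25,) * 4)) == 0.0


def s_odd_bruteforce(c):
    """Enumeration oracle: max signed sum over all odd-negative sign vectors."""
    best = -np.inf
    for signs in itertools.product((-1, 1), repeat=len(c)):
        if signs.count(-1) % 2 == 1:
            best = max(best, sum(s * x for s, x in zip(signs, c)))
    return best


class TestSOdd:
    def test_paper_convention_on_perfect_anticorrelation(self):
        assert s_odd((-1, -1, -1, -1), "paper") == 3.0

    def test_canonical_on_perfect_anticorrelation(self):
        assert s_odd((-1, -1, -1, -1), "canonical") == 2.0

    def test_canonical_maximally_contextual_pattern(self):
        assert s_odd((1, 1, 1, -1), "canonical") == 4.0

    def test_too_few_correlations_rejected(self):
        with pytest.raises(ValueError):
            s_odd((-1, -1), "canonical")

    def test_paper_convention_needs_an_anticorrelation(self):
        with pytest.raises(ValueError, match="negative"):
            s_odd((1, 1, 1, 1), "paper")

    @given(
        st.lists(st.floats(-1, 1), min_size=3, max_size=8).map(tuple)
    )
    @settings(derandomize=True, max_examples=200, deadline=None)
    def test_canonical_matches_enumeration(self, c):
        assert s_odd(c, "canonical") == pytest.approx(s_odd_bruteforce(c), abs=1e-12)


class TestCriterion:
    @pytest.mark.parametrize(
        "s,n,delta,expected",
        [(3, 4, 0, 1.0), (3, 4, 0.28, 0.72), (3, 4, 1.32, -0.32)],
    )
    def test_criterion_values(self, s, n, delta, expected):
        assert cbd_statistic(s, n, delta) == pytest.approx(expected, abs=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=4, max_size=4))
    @settings(derandomize=True, deadline=None)
    def test_paper_convention_reduces_to_one_minus_delta(self, p):
        delta, s, cbd = analyze_marginals(p)
        assert s == 3.0
        assert cbd == pytest.approx(1.0 - delta, abs=1e-12)
        assert -3.0 - 1e-12 <= cbd <= 1.0 + 1e-12


def behavior_from_joint(atoms):
    """Build a 4-cycle CycleBehavior by marginalizing an explicit joint
    distribution over (A0, A1, A2, A3) in {bot, top}^4."""
    atoms = np.asarray(atoms, dtype=float).reshape((2, 2, 2, 2))
    atoms = atoms / atoms.sum()
    singles = tuple(
        float(atoms.sum(axis=tuple(j for j in range(4) if j != i))[1])
        for i in range(4)
    )
    pairwise = {}
    for i in range(4):
        for j in range(i + 1, 4):
            marg = atoms.sum(axis=tuple(k for k in range(4) if k not in (i, j)))
            pairwise[(i, j)] = float(marg[1, 1])
    corrs = []
    for i in range(4):
        j = (i + 1) % 4
        a, b = sorted((i, j))
        marg = atoms.sum(axis=tuple(k for k in range(4) if k not in (a, b)))
        corrs.append(float(marg[0, 0] + marg[1, 1] - marg[0, 1] - marg[1, 0]))
    return CycleBehavior(4, singles, pairwise, tuple(corrs))


class TestBoole:
    def test_ideal_coin_violates(self):
        b = CycleBehavior(
            4, (0.5,) * 4,
            {(i, j): 0.0 for i in range(4) for j in range(i + 1, 4)},
            (-1.0,) * 4,
        )
        value, satisfied = boole_lhs(b)
        assert value == pytest.approx(2.0)
        assert not satisfied

    def test_never_top_satisfies(self):
        b = CycleBehavior(
            4, (0.0,) * 4,
            {(i, j): 0.0 for i in range(4) for j in range(i + 1, 4)},
            (1.0,) * 4,
        )
        assert boole_lhs(b) == (0.0, True)

    def test_independent_fair_coins_satisfy(self):
        atoms = np.full((2, 2, 2, 2), 1 / 16)
        value, satisfied = boole_lhs(behavior_from_joint(atoms))
        assert value == pytest.approx(0.5)
        assert satisfied

    def test_missing_pairwise_entries_rejected(self):
        b_pairs = {(0, 1): 0.0, (1, 2): 0.0, (2, 3): 0.0, (0, 3): 0.0}
        b = CycleBehavior(4, (0.5,) * 4, b_pairs, (-1.0,) * 4)
        with pytest.raises(ValueError, match="missing pairwise"):
            boole_lhs(b)

    @given(st.lists(st.floats(0.01, 1.0), min_size=16, max_size=16))
    @settings(derandomize=True, max_examples=100, deadline=None)
    def test_any_explicit_joint_satisfies(self, atoms):
        value, satisfied = boole_lhs(behavior_from_joint(atoms))
        assert satisfied, f"joint distribution produced Boole value {value} > 1"


def test_forced_choice_correlations_are_all_minus_one():
    assert forced_choice_correlations(5) == (-1.0,) * 5
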