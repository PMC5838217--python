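from fractions import Fraction

import networkx as nx
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import brute_force
from conftest import random_discretized
from lprp.discretization import DiscretizedMatrix
from lprp.interaction_detection import (
    CandidateInteraction,
    JointStateTable,
    classify_pair,
    con_score,
    detect_interactions,
    joint_probabilities,
    pair_count_stats,
    re_score,
    strength_count_cutoff,
    theta_sweep,
)


def _disc(rows, gene_ids=None):
    rows = np.atleast_2d(np.asarray(rows, dtype=np.int8))
    gene_ids = gene_ids or [f"G{i}" for i in range(rows.shape[0])]
    return DiscretizedMatrix(gene_ids, [f"S{j}" for j in range(rows.shape[1])], rows)


joint_counts = st.lists(st.integers(0, 20), min_size=9, max_size=9).filter(
    lambda c: sum(c) > 0)


def _table_from_list(counts):
    states = [(a, b) for a in (-1, 0, 1) for b in (-1, 0, 1)]
    return JointStateTable.from_counts(dict(zip(states, counts)), sum(counts))


class TestJointProbabilities:
    def test_identical_rows_put_mass_on_diagonal(self):
        d = _disc([[-1, 0, 1], [-1, 0, 1]])
        t = joint_probabilities(d, 0, 1)
        for s in (-1, 0, 1):
            assert t.p[(s, s)] == pytest.approx(1 / 3)
        assert t.p[(-1, 1)] == 0.0

    def test_hand_counted_example(self):
        d = _disc([[1, 1, -1, 0], [1, -1, -1, 0]])
        t = joint_probabilities(d, 0, 1)
        assert t.p[(1, 1)] == t.p[(1, -1)] == t.p[(-1, -1)] == t.p[(0, 0)] == 0.25
        assert sum(v for k, v in t.p.items()
                   if k not in {(1, 1), (1, -1), (-1, -1), (0, 0)}) == 0.0

    def test_probabilities_sum_to_one(self, rng):
        d = random_discretized(rng, 6, 11)
        for j in range(1, 6):
            t = joint_probabilities(d, 0, j)
            assert sum(t.p.values()) == pytest.approx(1.0, abs=1e-12)

    def test_same_gene_rejected(self, rng):
        d = random_discretized(rng, 3, 5)
        with pytest.raises(ValueError):
            joint_probabilities(d, 1, 1)


class TestScores:
    def test_identical_zero_free_profiles_saturate_con(self):
        d = _disc([[1, -1, 1, -1], [1, -1, 1, -1]])
        t = joint_probabilities(d, 0, 1)
        assert con_score(t) == (1.0, 1.0)

    def test_all_zero_profiles_score_zero(self):
        d = _disc([[0, 0, 0], [0, 0, 0]])
        t = joint_probabilities(d, 0, 1)
        assert con_score(t) == (0.0, 0.0)
        assert classify_pair(t, 0.0) == "none"

    def test_hand_counted_con_example(self):
        d = _disc([[1, 1, -1, 0], [1, -1, -1, 0]])
        margin, strength = con_score(joint_probabilities(d, 0, 1))
        assert margin == pytest.approx(0.25)
        assert strength == pytest.approx(0.5)

    def test_sign_flipped_profiles_saturate_re(self):
        d = _disc([[1, -1, 1], [-1, 1, -1]])
        t = joint_probabilities(d, 0, 1)
        assert re_score(t) == (1.0, 1.0)

    def test_hand_counted_re_example(self):
        d = _disc([[1, -1, 0], [-1, 1, 0]])
        margin, strength = re_score(joint_probabilities(d, 0, 1))
        assert margin == pytest.approx(2 / 3)
        assert strength == pytest.approx(2 / 3)

    @given(joint_counts)
    def test_re_margin_is_negated_con_margin(self, counts):
        t = _table_from_list(counts)
        assert re_score(t)[0] == pytest.approx(-con_score(t)[0], abs=1e-12)

    @given(joint_counts)
    def test_zero_zero_term_cancels(self, counts):
        # The literal decision expressions include P(0,0) on both sides;
        # they must equal the simplified forms without it.
        t = _table_from_list(counts)
        p = t.p
        margin, strength = con_score(t)
        simple_margin = (p[(-1, -1)] + p[(1, 1)]) - (p[(-1, 1)] + p[(1, -1)])
        simple_strength = (p[(-1, -1)] + p[(1, 1)]) - (
            p[(-1, 0)] + p[(0, -1)] + p[(1, 0)] + p[(0, 1)])
        assert margin == pytest.approx(simple_margin, abs=1e-12)
        assert strength == pytest.approx(simple_strength, abs=1e-12)

    @given(joint_counts)
    def test_strength_difference_identity(self, counts):
        # the mixed-zero mass cancels in the strength difference:
        # con_strength - re_strength = con_direction_margin
        t = _table_from_list(counts)
        c_m, c_s = con_score(t)
        _, r_s = re_score(t)
        assert c_s - r_s == pytest.approx(c_m, abs=1e-12)

    @given(joint_counts)
    def test_swap_symmetry(self, counts):
        # transposing the joint table (swapping the two genes) leaves both
        # scores unchanged
        t = _table_from_list(counts)
        swapped = JointStateTable({(b, a): v for (a, b), v in t.p.items()}, t.n)
        assert con_score(t) == pytest.approx(con_score(swapped), abs=1e-12)
        assert re_score(t) == pytest.approx(re_score(swapped), abs=1e-12)

    @given(joint_counts)
    def test_strength_times_n_is_integer(self, counts):
        t = _table_from_list(counts)
        for fn in (con_score, re_score):
            _, strength = fn(t)
            assert round(strength * t.n) == pytest.approx(strength * t.n, abs=1e-9)


class TestClassifyPair:
    def test_identical_profiles_con(self):
        d = _disc([[1, -1, 1, -1, 0], [1, -1, 1, -1, 0]])
        assert classify_pair(joint_probabilities(d, 0, 1), 0.1) == "con"

    def test_flipped_profiles_re(self):
        d = _disc([[1, -1, 1, -1, 0], [-1, 1, -1, 1, 0]])
        assert classify_pair(joint_probabilities(d, 0, 1), 0.1) == "re"

    def test_independent_profiles_rarely_pass_high_theta(self, rng):
        # At theta = 0.6 random uniform ternary profiles essentially never
        # qualify; the reference protocol observed no detections past 0.6.
        d = random_discretized(rng, 40, 30)
        hits = sum(classify_pair(joint_probabilities(d, i, j), 0.6) != "none"
                   for i in range(40) for j in range(i + 1, 40))
        assert hits == 0

    def test_matches_exact_rational_rule(self, rng):
        d = random_discretized(rng, 10, 12)
        for theta in (0.0, 0.1, 1 / 3, 0.5):
            for i in range(10):
                for j in range(i + 1, 10):
                    t = joint_probabilities(d, i, j)
                    expected, _ = brute_force.classify(
                        brute_force.joint_table(d.states[i], d.states[j]), theta)
                    assert classify_pair(t, theta) == expected


class TestStrengthCutoff:
    @pytest.mark.parametrize("theta,n,expected", [
        (0.0, 10, 1),     # any positive count
        (0.1, 20, 3),     # 2/20 = 0.1 is not > 0.1
        (0.5, 4, 3),      # 2/4 = 0.5 ties
        (1.0, 7, 8),      # unreachable: strength can never exceed 1
    ])
    def test_exact_boundaries(self, theta, n, expected):
        assert strength_count_cutoff(theta, n) == expected

    @given(st.floats(0, 1), st.integers(1, 200))
    def test_agrees_with_rational_definition(self, theta, n):
        cutoff = strength_count_cutoff(theta, n)
        assert Fraction(cutoff, n) > Fraction(theta)
        assert Fraction(cutoff - 1, n) <= Fraction(theta)


class TestDetectInteractions:
    def test_single_obvious_pair(self):
        d = _disc([[1, -1, 1, -1], [1, -1, 1, -1], [0, 0, 0, 0]],
                  gene_ids=["A", "B", "C"])
        out = detect_interactions(d, 0.1)
        assert [(c.gene_a, c.gene_b, c.reg_type) for c in out] == [("A", "B", "con")]
        assert out[0].score == 1.0
        assert out[0].stage == "candidate"

    def test_theta_one_is_vacuous(self):
        d = _disc([[1, -1, 1, -1], [1, -1, 1, -1]])
        assert detect_interactions(d, 1.0) == []

    def test_brute_force_oracle_equivalence(self, rng):
        # independent exact-rational evaluation over all pairs
        for _ in range(5):
            d = random_discretized(rng, 15, 20)
            for theta in (0.0, 0.1, 0.3, 0.6):
                got = [(c.gene_a, c.gene_b, c.reg_type,
                        Fraction(round(c.score * 20), 20))
                       for c in detect_interactions(d, theta)]
                expected = brute_force.detect_all_pairs(d.states, d.gene_ids, theta)
                assert got == expected

    def test_canonical_output_order(self, rng):
        d = random_discretized(rng, 12, 15)
        out = detect_interactions(d, 0.0)
        pairs = [c.pair for c in out]
        assert pairs == sorted(pairs)
        assert all(a < b for a, b in pairs)

    def test_backbone_source_restricts_pairs(self):
        d = _disc([[1, -1, 1], [1, -1, 1], [-1, 1, -1]], gene_ids=["A", "B", "C"])
        kp = nx.Graph([("A", "C"), ("A", "Z")])
        out = detect_interactions(d, 0.1, pair_source=kp)
        assert [(c.gene_a, c.gene_b, c.reg_type) for c in out] == [("A", "C", "re")]

    def test_backbone_disjoint_from_matrix_is_error(self):
        d = _disc([[1, -1], [1, 1]], gene_ids=["A", "B"])
        kp = nx.Graph([("X", "Y")])
        with pytest.raises(ValueError):
            detect_interactions(d, 0.1, pair_source=kp)

    def test_blocked_computation_matches_unblocked(self, rng):
        d = random_discretized(rng, 23, 14)
        full = pair_count_stats(d.states, block_size=1024)
        blocked = pair_count_stats(d.states, block_size=5)
        for a, b in zip(full, blocked):
            np.testing.assert_array_equal(a, b)


class TestThetaSweep:
    def test_counts_non_increasing(self, rng):
        d = random_discretized(rng, 30, 25)
        grid = [round(0.05 * k, 10) for k in range(13)]
        table = theta_sweep(d, grid)
        for col in ("n_interactions", "n_genes", "n_con", "n_re"):
            assert (np.diff(table[col]) <= 0).all()

    def test_interactions_split_into_con_re(self, rng):
        d = random_discretized(rng, 30, 25)
        table = theta_sweep(d, [0.0, 0.1, 0.3])
        assert (table.n_interactions == table.n_con + table.n_re).all()

    def test_con_re_balance_on_independent_data(self, rng):
        # Independent profiles have no preferred direction, so forward and
        # reverse detections should agree within binomial noise.
        d = random_discretized(rng, 60, 40)
        table = theta_sweep(d, [0.05])
        n_con, n_re = int(table.n_con[0]), int(table.n_re[0])
        assert n_con + n_re > 0
        assert abs(n_con - n_re) <= 3 * np.sqrt(n_con + n_re)

    def test_theta_beyond_max_strength_empty(self):
        d = _disc([[1, 0, -1], [0, 1, -1]])
        table = theta_sweep(d, [0.9, 1.0])
        assert (table.n_interactions == 0).all()

    def test_unsorted_grid_rejected(self, rng):
        d = random_discretized(rng, 5, 5)
        with pytest.raises(ValueError):
            theta_sweep(d, [0.3, 0.1])


class TestCandidateInteraction:
    def test_canonicalizes_gene_order(self):
        c = CandidateInteraction("B", "A", "con", 0.5)
        assert (c.gene_a, c.gene_b) == ("A", "B")

    def test_self_pair_rejected(self):
        with pytest.raises(ValueError):
            CandidateInteraction("A", "A", "con", 0.5)

    def test_unknown_type_rejected(self):
        with pytest.raises(ValueError):
            CandidateInteraction("A", "B", "forward", 0.5)
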