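"""Sequence validation, transition counts, redundancy G, and synthesis."""

import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wagertrack.sequences import (
    G_FLOOR,
    SearchFailure,
    SymbolSequence,
    generate_sequence,
    random_training_sequence,
    redundancy_G,
    round_half_up,
    transition_counts,
    validate_sequence,
)

G79 = "2-3-1-4-1-4-1-4-2-3-1-4-2-3-1-4-2-3-1-4-2-3-1-4-2-3-2-3-2-3-2-3-1-4-1-4-2-3-1-4-2-3-1-4-2-3-1-4"


def oracle_G(items):
    """Independent brute-force G: explicit transition scan, term-by-term entropy."""
    trans = Counter(zip(items, items[1:]))
    entropies = []
    for s in (1, 2, 3, 4):
        row = [trans[(s, t)] for t in (1, 2, 3, 4)]
        total = sum(row)
        if total == 0:
            entropies.append(0.0)
            continue
        h = 0.0
        for c in row:
            if c > 0:
                p = c / total
                h -= p * math.log2(p)
        entropies.append(h)
    return 1.0 - (sum(entropies) / 4.0) / 2.0


class TestValidation:
    def test_table1_row_passes(self, stimulus_table):
        seq = SymbolSequence.from_string(stimulus_table["sequence"].iloc[0])
        assert validate_sequence(seq, "training").passed

    def test_consecutive_repeat_reported_with_index(self):
        rep = validate_sequence(SymbolSequence((1, 1, 2, 3)), "training")
        assert not rep.passed
        assert any("index 1" in v for v in rep.violations)

    def test_balanced_cycle_passes(self):
        seq = SymbolSequence((1, 2, 3, 4) * 12)
        assert validate_sequence(seq, "training").passed

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            validate_sequence(SymbolSequence(()), "training")

    def test_recall_role_constraints(self):
        assert validate_sequence(SymbolSequence((1, 1, 2, 3) * 6, role="recall")).passed
        assert not validate_sequence(SymbolSequence((1, 2), role="recall")).passed


class TestTransitionCounts:
    def test_hand_count(self):
        table = transition_counts(SymbolSequence((1, 2, 1, 2)))
        expected = np.zeros((4, 4), dtype=int)
        expected[0, 1] = 2
        expected[1, 0] = 1
        assert (table.counts == expected).all()

    def test_printed_sequence_rows(self):
        # hand-enumerated rows of the G=.79 stimulus sequence
        table = transition_counts(SymbolSequence.from_string(G79))
        assert table.counts[1, 2] == 12 and table.counts[1].sum() == 12
        assert table.counts[2, 0] == 9 and table.counts[2, 1] == 3
        assert table.counts[3, 0] == 3 and table.counts[3, 1] == 8
        assert table.counts[3].sum() == 11  # final item has no successor
        assert table.counts.sum() == 47

    def test_no_repeat_sequence_has_zero_diagonal(self, rng):
        seq = random_training_sequence(rng)
        assert (np.diag(transition_counts(seq).counts) == 0).all()

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            transition_counts(SymbolSequence((1,)))


class TestRedundancyG:
    @pytest.mark.parametrize(
        "text, expected",
        [
            ("-".join(["2-1-3-4"] * 12), 1.0),
            (
                "3-2-3-2-4-1-3-2-4-1-4-1-3-2-3-2-3-2-4-1-3-2-4-1-3-2-3-2-4-1-3-2-4-1-4-1-3-2-4-1-4-1-4-1-4-1-3-2",
                0.76,
            ),
            (G79, 0.79),
        ],
    )
    def test_printed_values(self, text, expected):
        assert redundancy_G(SymbolSequence.from_string(text)).rounded == pytest.approx(expected)

    def test_matches_oracle_on_short_sequences(self, rng):
        for _ in range(300):
            n = int(rng.integers(2, 11))
            items = tuple(int(v) for v in rng.integers(1, 5, size=n))
            got = redundancy_G(SymbolSequence(items, role="recall")).G
            assert got == pytest.approx(oracle_G(items), abs=1e-12)

    @given(st.permutations([1, 2, 3, 4]), st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_relabeling_equivariance(self, perm, seed):
        seq = random_training_sequence(np.random.default_rng(seed))
        relabeled = SymbolSequence(tuple(perm[v - 1] for v in seq.items))
        assert redundancy_G(relabeled).G == pytest.approx(redundancy_G(seq).G, abs=1e-12)

    def test_G_is_one_iff_deterministic_rows(self):
        assert redundancy_G(SymbolSequence((1, 2, 3, 4) * 12)).G == 1.0
        # one stochastic row pushes G strictly below 1
        seq = SymbolSequence.from_string(G79)
        assert redundancy_G(seq).G < 1.0

    def test_bounds_on_random_training_sequences(self, rng):
        for _ in range(2000):
            g = redundancy_G(random_training_sequence(rng)).G
            assert G_FLOOR - 1e-12 <= g <= 1.0

    def test_table1_reproduction_with_flagged_row(self, stimulus_table):
        mismatches = stimulus_table[~stimulus_table["printed_matches"]]
        assert list(mismatches["printed_G"]) == [0.68]
        assert mismatches["G"].iloc[0] == pytest.approx(0.69)
        ok = stimulus_table[stimulus_table["printed_matches"]]
        assert len(ok) == 10
        assert np.allclose(ok["G"], ok["printed_G"])


class TestRoundHalfUp:
    @pytest.mark.parametrize("x, expected", [(0.685, 0.69), (0.684, 0.68), (0.5649, 0.56), (1.0, 1.0)])
    def test_examples(self, x, expected):
        assert round_half_up(x, 2) == expected


class TestGenerateSequence:
    def test_perfect_regularity_shortcut(self):
        seq = generate_sequence(1.0, seed=3)
        assert validate_sequence(seq, "training").passed
        assert redundancy_G(seq).G == 1.0

    def test_target_mid_regularity(self):
        seq = generate_sequence(0.55, seed=7)
        assert validate_sequence(seq, "training").passed
        assert 0.53 <= redundancy_G(seq).G <= 0.57

    def test_unreachable_target_fails_with_best_found(self):
        with pytest.raises(SearchFailure):
            generate_sequence(0.10, seed=0)

    def test_deterministic_for_fixed_seed(self):
        assert generate_sequence(0.6, seed=11).items == generate_sequence(0.6, seed=11).items
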