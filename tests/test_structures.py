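"""Dot-bracket parsing/writing (pseudoknots included) and base-pair consensus."""

from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from probekit.errors import DotBracketError, InputCountError, ReconciliationError
from probekit.structures import (
    SecondaryStructure,
    consensus,
    parse_dotbracket,
    write_dotbracket,
)

from .conftest import random_structure


def brute_force_consensus(structs, threshold=0.5):
    """Independent oracle: count every pair, filter, resolve conflicts."""
    n = len(structs)
    counts = Counter(p for s in structs for p in s.pairs)
    cands = sorted(
        ((pair, c / n) for pair, c in counts.items() if c / n >= threshold - 1e-12),
        key=lambda pf: (-pf[1], pf[0]),
    )
    used, kept = set(), {}
    for (i, j), f in cands:
        if i not in used and j not in used:
            kept[(i, j)] = f
            used |= {i, j}
    return kept


class TestParse:
    def test_nested_stem(self):
        s = parse_dotbracket("((...))")
        assert s.pairs == {(1, 7), (2, 6)}

    def test_pseudoknot_two_families(self):
        s = parse_dotbracket("((..[[..))..]]")
        assert s.pairs == {(1, 10), (2, 9), (5, 14), (6, 13)}
        assert s.is_crossing()

    def test_letter_families(self):
        s = parse_dotbracket("A.a")
        assert s.pairs == {(1, 3)}

    def test_unclosed_opener(self):
        with pytest.raises(DotBracketError) as exc:
            parse_dotbracket("((.")
        assert exc.value.position == 1
        assert exc.value.family == "()"

    def test_unmatched_closer(self):
        with pytest.raises(DotBracketError) as exc:
            parse_dotbracket("..]..")
        assert exc.value.position == 3

    def test_illegal_character(self):
        with pytest.raises(DotBracketError, match="illegal"):
            parse_dotbracket("..*..")

    def test_length_check(self):
        with pytest.raises(DotBracketError, match="length"):
            parse_dotbracket("....", length=5)


class TestWrite:
    def test_inverse_of_parse(self):
        s = SecondaryStructure(length=7, pairs=frozenset({(1, 7), (2, 6)}))
        assert write_dotbracket(s) == "((...))"

    def test_greedy_layering(self):
        s = SecondaryStructure(
            length=14, pairs=frozenset({(1, 10), (2, 9), (5, 14), (6, 13)})
        )
        assert write_dotbracket(s) == "((..[[..))..]]"

    def test_empty_structure(self):
        assert write_dotbracket(SecondaryStructure(length=4, pairs=frozenset())) == "...."

    def test_non_crossing_uses_parentheses_only(self, rng):
        for _ in range(20):
            # nested-only structure: pairs drawn as matched intervals
            length = 30
            pairs = {(3, 28), (4, 27), (10, 20), (11, 19), (22, 26)}
            out = write_dotbracket(SecondaryStructure(length=length, pairs=frozenset(pairs)))
            assert set(out) <= {".", "(", ")"}

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(0, 100_000))
    def test_round_trip_identity(self, seed):
        rng = np.random.default_rng(seed)
        s = random_structure(rng, int(rng.integers(1, 61)))
        assert parse_dotbracket(write_dotbracket(s)).pairs == s.pairs


class TestConsensus:
    def test_counting_example(self):
        mk = lambda pairs: SecondaryStructure(length=8, pairs=frozenset(pairs))
        result = consensus(
            [mk({(1, 8), (2, 7)}), mk({(1, 8), (2, 7)}), mk({(1, 8), (3, 6)})]
        )
        assert result.structure.pairs == {(1, 8), (2, 7)}
        assert result.frequency[(1, 8)] == 1.0
        assert result.frequency[(2, 7)] == pytest.approx(2 / 3)

    def test_half_occurrence_included(self):
        mk = lambda pairs: SecondaryStructure(length=8, pairs=frozenset(pairs))
        result = consensus([mk({(1, 8)}), mk(set())])
        assert result.structure.pairs == {(1, 8)}

    def test_unanimity(self):
        s = SecondaryStructure(length=10, pairs=frozenset({(1, 10), (2, 9)}))
        result = consensus([s] * 5)
        assert result.structure.pairs == s.pairs
        assert all(f == 1.0 for f in result.frequency.values())

    def test_fewer_than_two_inputs(self):
        s = SecondaryStructure(length=4, pairs=frozenset())
        with pytest.raises(InputCountError):
            consensus([s])

    def test_length_mismatch(self):
        a = SecondaryStructure(length=4, pairs=frozenset())
        b = SecondaryStructure(length=5, pairs=frozenset())
        with pytest.raises(ReconciliationError):
            consensus([a, b])

    def test_conflicts_resolved_by_frequency_then_lex(self):
        mk = lambda pairs: SecondaryStructure(length=10, pairs=frozenset(pairs))
        # (2,9) in 3/4, (2,8) in 2/4: frequency wins; then (1,10) vs nothing
        structs = [
            mk({(2, 9), (1, 10)}), mk({(2, 9)}), mk({(2, 9)}), mk({(2, 8), (1, 10)}),
        ]
        result = consensus(structs)
        assert (2, 9) in result.structure.pairs
        assert (2, 8) not in result.structure.pairs

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 9))
            length = int(rng.integers(4, 41))
            structs = [random_structure(rng, length) for _ in range(n)]
            result = consensus(structs)
            assert result.frequency == brute_force_consensus(structs)

    def test_permutation_invariant(self, rng):
        structs = [random_structure(rng, 25) for _ in range(5)]
        base = consensus(structs).structure.pairs
        for _ in range(5):
            perm = list(rng.permutation(len(structs)))
            assert consensus([structs[i] for i in perm]).structure.pairs == base

    def test_threshold_anti_monotone(self, rng):
        structs = [random_structure(rng, 30) for _ in range(6)]
        previous = None
        for thr in (0.2, 0.4, 0.5, 0.7, 0.9, 1.0):
            pairs = set(consensus(structs, threshold=thr).structure.pairs)
            if previous is not None:
                # raising the threshold never adds a candidate pair
                assert not (pairs - previous)
            previous = pairs
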