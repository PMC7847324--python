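"""Unit and property tests for the permutation/breakpoint/strip model."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from revsort import (
    DESCENDING,
    IncompatibleGenomesError,
    Reversal,
    ValidationError,
    adjacencies,
    apply_reversal,
    breakpoint_count,
    breakpoint_delta,
    breakpoints,
    compose,
    extend,
    identity,
    interior,
    inverse,
    is_identity,
    reduce_pair,
    strips,
    validate_gene_order,
)
PAPER_EXAMPLE = (2, 1, 3, 4, 5, 8, 7, 6)  # extends to (0,2,1,3,4,5,8,7,6,9)

permutations = st.integers(min_value=0, max_value=8).flatmap(
    lambda n: st.permutations(list(range(1, n + 1)))
)


class TestValidateGeneOrder:
    @pytest.mark.parametrize(
        "raw, ok, is_perm",
        [
            ([1, 2, 3], True, True),
            ([2, 1, 4], True, False),  # distinct but not 1..3
            (["tp53", "brca1"], True, False),
            ([], True, True),
        ],
    )
    def test_verdicts(self, raw, ok, is_perm):
        rep = validate_gene_order(raw)
        assert (rep.ok, rep.is_permutation) == (ok, is_perm)

    def test_duplicate_and_empty_tokens_rejected(self):
        assert not validate_gene_order(["a", "a", "b"]).ok
        assert "duplicate" in validate_gene_order([1, 1]).message
        assert not validate_gene_order(["x", ""]).ok


class TestExtend:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ((2, 1, 3, 4, 5, 8, 7, 6), (0, 2, 1, 3, 4, 5, 8, 7, 6, 9)),
            ((), (0, 1)),
            ((1,), (0, 1, 2)),
        ],
    )
    def test_sentinels(self, p, expected):
        assert extend(p) == expected

    def test_rejects_non_permutation(self):
        with pytest.raises(ValidationError):
            extend((1, 3))


class TestBreakpointsAndStrips:
    def test_worked_example(self):
        """The 8-gene example: 4 breakpoints, 5 adjacencies, 2 desc + 3 asc strips."""
        e = extend(PAPER_EXAMPLE)
        assert sorted(breakpoints(e)) == [0, 2, 5, 8]  # (0,2),(1,3),(5,8),(6,9)
        assert len(breakpoints(e)) == 4
        adj = sorted(adjacencies(e))
        assert [(e[k], e[k + 1]) for k in adj] == [(2, 1), (3, 4), (4, 5), (8, 7), (7, 6)]
        ss = strips(e)
        desc = [e[s.start : s.end + 1] for s in ss if s.descending]
        asc = [e[s.start : s.end + 1] for s in ss if not s.descending]
        assert desc == [(2, 1), (8, 7, 6)]
        assert asc == [(0,), (3, 4, 5), (9,)]

    def test_identity_has_no_breakpoints_one_strip(self):
        e = extend(identity(6))
        assert breakpoints(e) == frozenset()
        assert len(adjacencies(e)) == 7
        assert len(strips(e)) == 1 and not strips(e)[0].descending

    def test_singleton_convention(self):
        # (0,3,1,2,4): singleton (3) is descending, sentinels ascending
        e = (0, 3, 1, 2, 4)
        assert sorted(breakpoints(e)) == [0, 1, 3]
        assert sorted(adjacencies(e)) == [2]
        orients = [(e[s.start : s.end + 1], s.orientation) for s in strips(e)]
        assert orients == [
            ((0,), "ascending"),
            ((3,), DESCENDING),
            ((1, 2), "ascending"),
            ((4,), "ascending"),
        ]

    @pytest.mark.parametrize("n", range(0, 8))
    def test_counting_identities_exhaustive(self, n):
        """breakpoints + adjacencies = n + 1 and strips = breakpoints + 1."""
        for p in itertools.permutations(range(1, n + 1)):
            e = extend(p)
            assert len(breakpoints(e)) + len(adjacencies(e)) == n + 1
            assert len(strips(e)) == len(breakpoints(e)) + 1
            covered = [pos for s in strips(e) for pos in range(s.start, s.end + 1)]
            assert covered == list(range(n + 2))


class TestApplyReversal:
    def test_basic(self):
        assert apply_reversal((0, 2, 1, 3), Reversal(1, 2)) == (0, 1, 2, 3)

    def test_sentinels_protected(self):
        with pytest.raises(ValidationError):
            apply_reversal((0, 2, 1, 3), Reversal(1, 3))

    @settings(max_examples=200, derandomize=True)
    @given(permutations, st.data())
    def test_involution(self, p, data):
        if not p:
            return
        e = extend(p)
        n = len(p)
        i = data.draw(st.integers(1, n))
        j = data.draw(st.integers(i, n))
        r = Reversal(i, j)
        assert apply_reversal(apply_reversal(e, r), r) == e
        assert apply_reversal(e, Reversal(i, i)) == e


class TestBreakpointDelta:
    @pytest.mark.parametrize(
        "p, r, expected",
        [
            ((2, 1, 3, 4, 5, 8, 7, 6), (1, 2), -2),
            ((1, 2, 3, 4), (2, 4), 2),
            ((3, 4, 1, 2), (1, 3), -1),
        ],
    )
    def test_examples(self, p, r, expected):
        assert breakpoint_delta(extend(p), Reversal(*r)) == expected

    @settings(max_examples=300, derandomize=True)
    @given(permutations, st.data())
    def test_boundary_computation_equals_full_recount(self, p, data):
        if not p:
            return
        e = extend(p)
        n = len(p)
        i = data.draw(st.integers(1, n))
        j = data.draw(st.integers(i, n))
        r = Reversal(i, j)
        delta = breakpoint_delta(e, r)
        assert delta == breakpoint_count(apply_reversal(e, r)) - breakpoint_count(e)
        assert abs(delta) <= 2


class TestInverseAndReduce:
    def test_inverse_examples(self):
        assert inverse((2, 3, 1)) == (3, 1, 2)
        assert inverse(identity(5)) == identity(5)

    @pytest.mark.parametrize("n", range(0, 7))
    def test_inverse_composition_exhaustive(self, n):
        for p in itertools.permutations(range(1, n + 1)):
            assert compose(inverse(p), p) == identity(n)
            assert inverse(inverse(p)) == p

    def test_reduce_pair_examples(self):
        assert reduce_pair(("c", "a", "b"), ("a", "b", "c")) == (3, 1, 2)
        assert reduce_pair((5, 3, 1), (5, 3, 1)) == identity(3)

    def test_reduce_pair_mismatch(self):
        with pytest.raises(IncompatibleGenomesError):
            reduce_pair(("a", "b"), ("a", "c"))

    def test_reduce_identity_iff_equal(self):
        for sigma in itertools.permutations("abcd"):
            is_id = reduce_pair(sigma, tuple("abcd")) == identity(4)
            assert is_id == (sigma == tuple("abcd"))

    def test_sorting_reduction_sorts_source_to_target(self):
        """A reversal sequence sorting pi = reduce_pair(sigma, tau), applied
        to sigma, must yield tau."""
        from revsort import bpelim_sort

        sigma, tau = ("d", "c", "a", "b", "e"), ("a", "b", "c", "d", "e")
        pi = reduce_pair(sigma, tau)
        res = bpelim_sort(pi)
        genome = list(sigma)
        for r in res.reversals:
            genome[r.i - 1 : r.j] = genome[r.i - 1 : r.j][::-1]
        assert tuple(genome) == tau

    def test_is_identity(self):
        assert is_identity(extend(identity(193)))
        assert not is_identity(extend((2, 1)))
        assert interior(extend((2, 1))) == (2, 1)
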