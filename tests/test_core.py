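"""Unit and property tests for the exact assembly index machinery."""

import pytest
from hypothesis import given, strategies as st

from string_assembly.core import (
    AssemblyPathway,
    JoinStep,
    addition_chain_min,
    brute_force_assembly_index,
    candidate_substrings,
    canonical_form,
    exact_assembly_index,
    greedy_upper_bound,
    junction_lower_bound,
    lower_bound,
    verify_pathway,
)

short_ab = st.text(alphabet="ab", min_size=1, max_size=8)
short_abc = st.text(alphabet="abc", min_size=1, max_size=7)
medium = st.text(alphabet="abc", min_size=1, max_size=12)


class TestCandidateSubstrings:
    @pytest.mark.parametrize(
        "target, expected",
        [
            ("aaa", {"a", "aa", "aaa"}),
            ("ab", {"a", "b", "ab"}),
        ],
    )
    def test_enumeration(self, target, expected):
        assert candidate_substrings(target) == expected

    def test_against_double_loop_oracle(self):
        s = "zbzbzc"
        oracle = set()
        for i in range(len(s)):
            for j in range(i + 1, len(s) + 1):
                oracle.add(s[i:j])
        assert len(oracle) == 15
        assert candidate_substrings(s) == oracle

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            candidate_substrings("")


class TestBounds:
    @pytest.mark.parametrize(
        "target, expected",
        [("a", 0), ("a" * 16, 4), ("zbzbzc", 3)],
    )
    def test_lower_bound(self, target, expected):
        assert lower_bound(target) == expected

    @pytest.mark.parametrize(
        "target, expected",
        [("aaaaaa", 3), ("zbzbzc", 4), ("ab", 1)],
    )
    def test_greedy_upper_bound_length(self, target, expected):
        result = greedy_upper_bound(target)
        assert result.index == expected
        assert not result.exact
        assert verify_pathway(result.pathway)

    @given(medium)
    def test_sandwich(self, s):
        exact = exact_assembly_index(s).index
        assert lower_bound(s) <= exact <= greedy_upper_bound(s).index
        assert junction_lower_bound(s) <= exact

    @given(medium)
    def test_greedy_pathway_is_valid(self, s):
        result = greedy_upper_bound(s)
        check = verify_pathway(result.pathway)
        assert check.ok, check.reason
        assert len(result.pathway) == result.index


class TestExactIndex:
    @pytest.mark.parametrize(
        "target, expected",
        [
            ("z", 0),
            ("ab", 1),
            ("abc", 2),  # no repeats: l - 1 joins
            ("zbzbzc", 4),
            ("zzzbbc", 5),
            ("a" * 8, 3),  # pure doubling
            ("abab", 2),
        ],
    )
    def test_examples(self, target, expected):
        result = exact_assembly_index(target)
        assert result.index == expected
        assert result.exact
        assert len(result.pathway) == expected
        assert verify_pathway(result.pathway)

    @pytest.mark.parametrize("k", range(7))
    def test_doubling_law(self, k):
        assert exact_assembly_index("a" * 2**k).index == k

    def test_all_distinct_worst_case(self):
        for n in range(1, 9):
            s = "abcdefgh"[:n]
            assert exact_assembly_index(s).index == n - 1
            assert brute_force_assembly_index(s) == n - 1

    @given(short_ab)
    def test_matches_brute_force_binary(self, s):
        assert exact_assembly_index(s).index == brute_force_assembly_index(s)

    @given(short_abc)
    def test_matches_brute_force_ternary(self, s):
        assert exact_assembly_index(s).index == brute_force_assembly_index(s)

    @given(medium)
    def test_reversal_invariance(self, s):
        assert exact_assembly_index(s).index == exact_assembly_index(s[::-1]).index

    @given(medium)
    def test_relabeling_invariance(self, s):
        relabeled = s.translate(str.maketrans("abc", "xyz"))
        assert exact_assembly_index(s).index == exact_assembly_index(relabeled).index

    def test_deterministic_witness(self):
        r1 = exact_assembly_index("zbzbzcabzb")
        r2 = exact_assembly_index("zbzbzcabzb")
        assert r1 == r2

    def test_budget_exhaustion_reports_bounds(self):
        # true index 11; a depth budget of 8 cannot prove optimality
        s = "acabcbcabaabbcba"
        truth = exact_assembly_index(s)
        assert truth.exact and truth.index == 11
        result = exact_assembly_index(s, budget=8)
        assert not result.exact
        assert result.lower <= truth.index <= result.upper
        assert result.index == result.upper
        assert verify_pathway(result.pathway)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            exact_assembly_index("")


class TestBruteForce:
    @pytest.mark.parametrize(
        "target, expected", [("zz", 1), ("abab", 2), ("zbzbzc", 4)]
    )
    def test_examples(self, target, expected):
        assert brute_force_assembly_index(target) == expected

    def test_refuses_long_input(self):
        with pytest.raises(ValueError):
            brute_force_assembly_index("a" * 11)


class TestVerifyPathway:
    def test_doubling_pathway_accepted(self):
        p = AssemblyPathway(
            "aaaa",
            (JoinStep("a", "a", "aa"), JoinStep("aa", "aa", "aaaa")),
        )
        assert verify_pathway(p).ok

    def test_unconstructed_operand_rejected(self):
        p = AssemblyPathway(
            "aaaa",
            (JoinStep("aa", "aa", "aaaa"),),  # "aa" was never built
        )
        check = verify_pathway(p)
        assert not check.ok
        assert check.reason == "unavailable_operand"

    def test_bad_concatenation_rejected(self):
        p = AssemblyPathway("ab", (JoinStep("a", "a", "ab"),))
        assert verify_pathway(p).reason == "bad_concatenation"

    def test_wrong_final_product_rejected(self):
        p = AssemblyPathway("aab", (JoinStep("a", "a", "aa"),))
        assert verify_pathway(p).reason == "final_product_not_target"

    def test_witness_of_worked_example(self):
        result = exact_assembly_index("zbzbzc")
        assert verify_pathway(result.pathway).ok


class TestAdditionChain:
    @pytest.mark.parametrize(
        "l, expected",
        [
            (1, 0),
            (2, 1),
            (8, 3),  # pure doubling
            (15, 5),  # frozen from an exhaustive chain enumerator
            (23, 6),
            (31, 7),
            (32, 5),
        ],
    )
    def test_known_values(self, l, expected):
        assert addition_chain_min(l) == expected

    def test_equals_unary_assembly_index(self):
        for l in range(1, 21):
            assert addition_chain_min(l) == exact_assembly_index("a" * l).index

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            addition_chain_min(0)


class TestCanonicalForm:
    @given(medium)
    def test_idempotent_and_invariant(self, s):
        c = canonical_form(s)
        assert canonical_form(c) == c
        assert canonical_form(s[::-1]) == c
        relabeled = s.translate(str.maketrans("abc", "cab"))
        assert canonical_form(relabeled) == c
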