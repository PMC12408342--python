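"""Tests for the entropy, Huffman and LZW baselines."""

import math

import pytest
from hypothesis import given, strategies as st

from string_assembly.baselines import (
    LZW_SIZE_POLICIES,
    frequency_table,
    huffman_code,
    huffman_decode,
    huffman_encode,
    lzw_compress,
    lzw_decompress,
    lzw_max_length,
    lzw_size,
    shannon_entropy,
)
from string_assembly.core import addition_chain_min, exact_assembly_index

texts = st.text(alphabet="abcz", min_size=1, max_size=40)


class TestEntropy:
    def test_single_symbol_is_zero(self):
        assert shannon_entropy("zzzz") == 0.0

    def test_two_equiprobable_symbols(self):
        assert shannon_entropy("zb") == 1.0

    def test_anagrams_share_entropy(self):
        assert shannon_entropy("zbzbzc") == shannon_entropy("zzzbbc")

    @given(texts)
    def test_bounded_by_log_alphabet(self, s):
        h = shannon_entropy(s)
        assert 0.0 <= h <= math.log2(len(set(s))) + 1e-12

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            shannon_entropy("")


class TestHuffman:
    def test_worked_code_map(self):
        code = huffman_code("zbzbzc")
        assert code.code == {"z": "1", "b": "01", "c": "00"}

    def test_anagram_has_identical_code_map(self):
        assert huffman_code("zzzbbc").code == huffman_code("zbzbzc").code

    def test_worked_encodings(self):
        assert huffman_encode("zbzbzc") == "101101100"
        assert huffman_encode("zzzbbc") == "111010100"

    def test_two_symbols_get_single_bits(self):
        code = huffman_code("ab")
        assert sorted(len(v) for v in code.code.values()) == [1, 1]

    def test_single_symbol_input(self):
        code = huffman_code("aaaa")
        assert code.code == {"a": "0"}
        assert huffman_decode(huffman_encode("aaaa", code), code) == "aaaa"

    @given(texts)
    def test_roundtrip(self, s):
        code = huffman_code(s)
        assert huffman_decode(huffman_encode(s, code), code) == s

    @given(texts.filter(lambda s: len(set(s)) >= 2))
    def test_kraft_equality(self, s):
        code = huffman_code(s)
        assert sum(2 ** -len(v) for v in code.code.values()) == pytest.approx(1.0)

    @given(texts.filter(lambda s: len(set(s)) >= 2))
    def test_optimality_bound(self, s):
        # H(s) |s| <= encoded bits < (H(s) + 1) |s|
        bits = len(huffman_encode(s))
        h = shannon_entropy(s)
        assert h * len(s) - 1e-9 <= bits < (h + 1) * len(s)

    @given(texts)
    def test_encoded_length_is_frequency_weighted(self, s):
        code = huffman_code(s)
        expected = sum(
            count * len(code.code[ch]) for ch, count in frequency_table(s).items()
        )
        assert len(huffman_encode(s, code)) == expected

    def test_undecodable_bits_rejected(self):
        code = huffman_code("zbzbzc")
        with pytest.raises(ValueError):
            huffman_decode("101101100" + "0", code)  # trailing orphan bit


class TestLZW:
    def test_unary_recurrence(self):
        assert lzw_compress("aaaaaa").codes == (0, 1, 2)

    def test_no_reuse_two_codes(self):
        assert len(lzw_compress("ab").codes) == 2

    def test_worked_strings_against_reference_counts(self):
        # frozen from an independent textbook LZW implementation
        assert lzw_compress("zbzbzc").codes == (0, 1, 3, 0, 2)
        assert lzw_compress("zzzbbc").codes == (0, 3, 1, 1, 2)

    @given(texts)
    def test_roundtrip(self, s):
        assert lzw_decompress(lzw_compress(s)) == s

    @given(texts)
    def test_roundtrip_byte_alphabet(self, s):
        assert lzw_decompress(lzw_compress(s, byte_alphabet=True)) == s

    def test_triangular_law(self):
        # exactly n codes at the n-th triangular length, and the least
        # n with n(n+1)/2 >= l codes in between
        for n in range(1, 12):
            l = lzw_max_length(n)
            assert len(lzw_compress("a" * l).codes) == n
        for l in range(1, 70):
            n = next(m for m in range(1, 20) if m * (m + 1) // 2 >= l)
            assert len(lzw_compress("a" * l).codes) == n

    def test_size_policies(self):
        r = lzw_compress("aaaaaa")  # 3 codes, dictionary {a, aa, aaa}
        assert lzw_size(r, "code_count") == 3
        assert lzw_size(r, "fixed12_bytes") == 5  # ceil(36/8)
        assert lzw_size(r, "minwidth_bytes") == math.ceil(3 * 2 / 8)
        with pytest.raises(ValueError):
            lzw_size(r, "zip")

    def test_max_length_values(self):
        assert [lzw_max_length(n) for n in (1, 3, 10)] == [1, 6, 55]
        with pytest.raises(ValueError):
            lzw_max_length(0)


class TestAnagramDegeneracy:
    @given(st.permutations(list("zzzbbcaa")))
    def test_identical_codes_and_lengths(self, perm):
        s = "".join(perm)
        ref = "aabbczzz"
        assert huffman_code(s).code == huffman_code(ref).code
        assert len(huffman_encode(s)) == len(huffman_encode(ref))
        assert shannon_entropy(s) == pytest.approx(shannon_entropy(ref))


class TestScalingDivergence:
    def test_assembly_beats_lzw_on_unary_strings(self):
        # steps grow ~sqrt(l) for LZW but ~log2(l) for assembly: never
        # more joins than codes from length 16 on (with equality only at
        # l = 19 and 21, where ceil-effects let the chain catch up), and
        # a gap that widens with length (exhaustive to 64, then powers
        # of two to 2^10)
        lengths = list(range(16, 65)) + [128, 256, 512, 1024]
        gaps = {}
        for l in lengths:
            lzw_steps = len(lzw_compress("a" * l).codes)
            if l <= 64:
                a = addition_chain_min(l)
            else:
                a = exact_assembly_index("a" * l).index
            gaps[l] = lzw_steps - a
            if l in (19, 21):
                assert a == lzw_steps
            else:
                assert a < lzw_steps
        assert gaps[64] > gaps[16]
        assert gaps[1024] > gaps[64]
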