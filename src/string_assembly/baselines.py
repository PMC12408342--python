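"""Comparison complexity measures: Shannon entropy, Huffman coding, LZW.

These are the statistical and dictionary-compression baselines the
assembly index is contrasted with.  They are all computable in
polynomial time and depend only on character frequencies (entropy,
Huffman) or on a left-to-right greedy parse (LZW), which is why two
strings with identical composition — anagrams — are indistinguishable
to entropy and Huffman coding even when their assembly indices differ.

Huffman tree construction is deterministic under an explicit
tie-breaking convention (see :func:`huffman_code`) so encoded
bitstrings are reproducible bit-exactly.
"""

from __future__ import annotations

import heapq
import math
from collections import Counter
from dataclasses import dataclass

__all__ = [
    "FrequencyTable",
    "HuffmanCode",
    "LZWResult",
    "frequency_table",
    "shannon_entropy",
    "huffman_code",
    "huffman_encode",
    "huffman_decode",
    "lzw_compress",
    "lzw_decompress",
    "lzw_size",
    "lzw_max_length",
    "LZW_SIZE_POLICIES",
]

FrequencyTable = Counter


def _require_nonempty(s: str) -> None:
    if not s:
        raise ValueError("input string must be non-empty")


def frequency_table(s: str) -> Counter:
    """Character occurrence counts of ``s``."""
    _require_nonempty(s)
    return Counter(s)


def shannon_entropy(s: str) -> float:
    """Shannon entropy of the character distribution, in bits per symbol.

    ``H = -sum p_c log2 p_c`` over character frequencies; lies in
    ``[0, log2(alphabet size)]`` and is identical for any two strings of
    the same composition.
    """
    freqs = frequency_table(s)
    n = len(s)
    return -sum((c / n) * math.log2(c / n) for c in freqs.values()) + 0.0


@dataclass(frozen=True)
class HuffmanCode:
    """A deterministic prefix-free code for one string's frequency table.

    ``tree`` is nested pairs ``(child0, child1)`` with single characters
    as leaves; ``code`` maps each character to its bitstring.
    """

    code: dict[str, str]
    tree: object
    freqs: Counter


def huffman_code(s: str) -> HuffmanCode:
    """Build the Huffman code of ``s`` under a fixed tie-breaking rule.

    Nodes are merged in order of (weight, leaves before internal nodes,
    creation order), where leaves are created in lexicographic character
    order so that any two strings of identical composition build the
    identical tree.  When labelling a merged pair, the heavier child
    receives bit ``1``; on equal weights the leaf (or the
    earlier-created node) receives ``1``.  Huffman trees are highly
    degenerate, and this convention pins down one member of the
    degeneracy class so that outputs are bit-exact.

    A single-symbol input gets code ``"0"``.
    """
    freqs = frequency_table(s)
    if len(freqs) == 1:
        ch = next(iter(freqs))
        return HuffmanCode({ch: "0"}, ch, freqs)
    rank = {ch: i for i, ch in enumerate(sorted(freqs))}
    # heap entries: (weight, kind, order, payload); kind 0 = leaf, 1 = internal
    heap = [(freqs[ch], 0, rank[ch], ch) for ch in freqs]
    heapq.heapify(heap)
    counter = len(heap)
    while len(heap) > 1:
        a = heapq.heappop(heap)
        b = heapq.heappop(heap)
        # decide which child is labelled '1': heavier wins, then leaf,
        # then earlier creation
        wa, ka, oa, _ = a
        wb, kb, ob, _ = b
        if (-wa, -1 if ka == 0 else 1, oa) <= (-wb, -1 if kb == 0 else 1, ob):
            one, zero = a, b
        else:
            one, zero = b, a
        node = (a[0] + b[0], 1, counter, (zero[3], one[3]))
        counter += 1
        heapq.heappush(heap, node)
    tree = heap[0][3]
    code: dict[str, str] = {}

    def walk(node, prefix: str) -> None:
        if isinstance(node, str):
            code[node] = prefix
            return
        walk(node[0], prefix + "0")
        walk(node[1], prefix + "1")

    walk(tree, "")
    return HuffmanCode(code, tree, freqs)


def huffman_encode(s: str, code: HuffmanCode | None = None) -> str:
    """Encode ``s`` as a bitstring under its (or a supplied) Huffman code."""
    _require_nonempty(s)
    if code is None:
        code = huffman_code(s)
    return "".join(code.code[ch] for ch in s)


def huffman_decode(bits: str, code: HuffmanCode) -> str:
    """Inverse of :func:`huffman_encode`; raises on undecodable input."""
    inverse = {v: k for k, v in code.code.items()}
    out = []
    cur = ""
    for b in bits:
        cur += b
        if cur in inverse:
            out.append(inverse[cur])
            cur = ""
    if cur:
        raise ValueError(f"bitstring has undecodable trailing bits {cur!r}")
    return "".join(out)


# ---------------------------------------------------------------------------
# LZW
# ---------------------------------------------------------------------------

LZW_SIZE_POLICIES = ("code_count", "fixed12_bytes", "minwidth_bytes")


@dataclass(frozen=True)
class LZWResult:
    """Output of one LZW compression run.

    ``alphabet`` is the initial dictionary (distinct characters in first
    appearance order unless byte initialisation was requested);
    ``dictionary`` is the final lookup table substring -> code.
    """

    codes: tuple[int, ...]
    dictionary: dict[str, int]
    alphabet: tuple[str, ...]

    @property
    def code_count(self) -> int:
        return len(self.codes)


def lzw_compress(s: str, byte_alphabet: bool = False) -> LZWResult:
    """Left-to-right greedy dictionary compression.

    At each step the longest dictionary match is emitted and that match
    extended by the next input character is added to the table.  By
    default the initial dictionary holds the distinct characters of the
    input in first-appearance order (so a fresh unary string costs one
    code); ``byte_alphabet=True`` initialises with all 256 byte values
    instead.
    """
    _require_nonempty(s)
    if byte_alphabet:
        alphabet = tuple(chr(i) for i in range(256))
    else:
        seen = dict.fromkeys(s)
        alphabet = tuple(seen)
    table = {ch: i for i, ch in enumerate(alphabet)}
    codes = []
    w = ""
    for ch in s:
        if w + ch in table:
            w += ch
        else:
            codes.append(table[w])
            table[w + ch] = len(table)
            w = ch
    codes.append(table[w])
    return LZWResult(tuple(codes), table, alphabet)


def lzw_decompress(r: LZWResult) -> str:
    """Exact inverse of :func:`lzw_compress` given the same alphabet."""
    table = list(r.alphabet)
    out = []
    prev: str | None = None
    for code in r.codes:
        if code < len(table):
            entry = table[code]
        elif code == len(table) and prev is not None:
            entry = prev + prev[0]  # the just-added, not-yet-known entry
        else:
            raise ValueError(f"invalid LZW code {code}")
        out.append(entry)
        if prev is not None:
            table.append(prev + entry[0])
        prev = entry
    return "".join(out)


def lzw_size(r: LZWResult, policy: str) -> int:
    """Compressed size of an LZW result under a stated packing policy.

    ``code_count``: the number of emitted codes.  ``fixed12_bytes``:
    bytes with every code packed into 12 bits.  ``minwidth_bytes``:
    bytes with every code packed into the smallest fixed width that can
    address the final dictionary.
    """
    if policy == "code_count":
        return len(r.codes)
    if policy == "fixed12_bytes":
        return math.ceil(12 * len(r.codes) / 8)
    if policy == "minwidth_bytes":
        bits = max(1, math.ceil(math.log2(len(r.dictionary))))
        return math.ceil(len(r.codes) * bits / 8)
    raise ValueError(f"unknown LZW size policy {policy!r}")


def lzw_max_length(n: int) -> int:
    """Longest unary string reachable by ``n`` LZW compression steps.

    On a repeated single letter each step emits one code and lengthens
    the longest dictionary entry by one, so reachable length follows
    ``l_1 = 1``, ``l_{i+1} = l_i + i + 1``, i.e. the triangular numbers
    ``n (n + 1) / 2``.
    """
    if not isinstance(n, int) or n < 1:
        raise ValueError("n must be a positive integer")
    return n * (n + 1) // 2
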