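"""Why entropy and Huffman coding cannot see what the assembly index sees.

Anagrams share a frequency table, hence the same Shannon entropy, the
same Huffman tree and code map, and equal encoded lengths — while their
assembly indices differ.  LZW, which parses left to right, does assign
them different code sequences, but only weakly related to the index.
"""

from string_assembly import (
    exact_assembly_index,
    huffman_code,
    huffman_encode,
    lzw_compress,
    shannon_entropy,
)

for s in ("zbzbzc", "zzzbbc"):
    code = huffman_code(s)
    lzw = lzw_compress(s)
    print(f"{s}:")
    print(f"    entropy          = {shannon_entropy(s):.4f} bits/symbol")
    print(f"    huffman code map = {dict(sorted(code.code.items()))}")
    print(f"    huffman encoding = {huffman_encode(s, code)}")
    print(f"    lzw codes        = {list(lzw.codes)}")
    print(f"    assembly index   = {exact_assembly_index(s).index}")
print(
    "Same entropy and code map, different indices: frequency statistics "
    "are many-to-one over assembly structure."
)
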