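"""Exact assembly index of a string, with its witnessing pathway.

The assembly index counts the minimal number of concatenation joins
needed to build a string from its single characters, reusing any
previously built piece for free.  The two strings below are anagrams —
identical length, composition, entropy and Huffman code — yet their
indices differ (4 vs 5), because "zbzbzc" contains a reusable block
("zb") and "zzzbbc" does not.
"""

from string_assembly import exact_assembly_index, verify_pathway

for target in ("zbzbzc", "zzzbbc"):
    result = exact_assembly_index(target)
    print(f"{target}: assembly index = {result.index} (exact={result.exact})")
    for step in result.pathway.steps:
        print(f"    {step.left} + {step.right} -> {step.product}")
    assert verify_pathway(result.pathway)
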