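"""The Assembly observable A of an ensemble of observed strings.

A = sum_i e^{a_i} (n_i - 1) / N combines each distinguishable object's
assembly index a_i with its copy number n_i.  Single observations
contribute nothing; many identical copies of a complex object dominate.
This is the quantity conjectured to separate products of selection from
random generation.
"""

from string_assembly import assembly_observable, ensemble_from_observations

# ten identical copies of a complex string vs. ten distinct simple ones
selected = ensemble_from_observations(["zbzbzc"] * 10)
random_like = ensemble_from_observations(
    ["ab", "ba", "ac", "ca", "bc", "cb", "aa", "bb", "cc", "abc"]
)

for name, e in (("10x zbzbzc", selected), ("10 distinct strings", random_like)):
    a_val = assembly_observable(e)
    print(f"{name}: N = {e.total_count}, A = {a_val:.4f}")
print(
    "High copy number of a high-index object gives large A; "
    "unique observations give A = 0."
)
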