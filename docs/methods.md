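# Methods

## Model

An assembly object is a non-empty finite string.  Its elementary parts
are the distinct characters it contains, available at zero cost; the
only operation is a binary join concatenating two already-available
objects, and every join product may be reused arbitrarily often.  The
assembly index `a(s)` is the minimal number of joins over all pathways
that end at `s`; a pathway witnessing that minimum is returned
alongside the index.  The index counts joins only, so `a = n − 1` for a
pathway of `n` constructed objects ending at the target, `a("x") = 0`,
and `a(s) = |s| − 1` whenever `s` has no repeated structure to exploit.

Two modelling choices deserve note.  The empty string is rejected:
objects must be breakable into parts, and an empty object has none.
Each join produces one new contiguous object; occurrences of a reused
intermediate in the final string are disjoint blocks of the
concatenation tree (overlapping occurrences of a substring cannot both
be reused copies).

## Exact search

Minimality is equivalent to a covering formulation: `a(s)` is the size
of the smallest set `S` of substrings of `s` (length ≥ 2, `s ∈ S`) such
that every member splits into two parts, each a single character or
another member.  Parts are strictly shorter than their product, so any
such set orders into a valid pathway by increasing length, and a
minimal pathway never rebuilds a product; both directions of the
equivalence are elementary.  Restricting candidates to substrings is
sound because every product in a minimal pathway is eventually
incorporated into the target contiguously.

The solver runs iterative deepening over the target size `k` of `S`,
from a lower bound up to a greedy upper bound, branching on the
decompositions of a not-yet-resolved element and memoising failed
(set, unresolved) states by remaining budget.  Search order is fixed
(most-constrained element first; decompositions by fewest new elements,
then by whether their junction covers a still-missing bigram, then by
split position), so results and witnesses are reproducible.

Three admissible bounds prune the search:

* **Doubling**: a join at most doubles the longest available object, so
  `a(s) ≥ ceil(log2 |s|)`, and reaching the larger part of a pending
  element's split needs at least a doubling chain from the longest
  shorter element.
* **Junctions**: every join creates exactly one junction bigram (last
  character of the left operand, first of the right), and single
  characters contain no bigrams, so every distinct bigram of the target
  must be the junction of some join: `a(s) ≥ #distinct bigrams`.
* **Run demands**: for a maximal run of character `x` of length `M`,
  the longest `x`-run inside an element at most doubles per join and
  every strict increase straddles an `xx` junction, so at least
  `ceil(log2 M)` distinct joins have junction `xx`.  Tracked per bigram
  against the junctions of already-resolved elements.

The greedy upper bound repeatedly builds the longest substring with two
non-overlapping occurrences (ties: leftmost, then lexicographic) and
then concatenates the tokenised target left to right; its pathway seeds
the search and serves as the witness when a budget is exhausted.  A
`budget` (maximum search depth) below the true index yields a result
flagged inexact with the best proven `[lower, upper]` interval rather
than a guess.

The hot loop is compiled with numba (`_fast.py`): sets of required
substrings become pairs of 64-bit masks and the DFS uses an explicit
stack.  The pure-Python search is retained as the reference
implementation and as fallback for targets with more than 128 distinct
substrings or 64 distinct bigrams; tests assert both engines agree.
Indices for large batches are memoised by canonical form (first-
appearance relabeling, minimised with the reversal), which is sound
because the index is invariant under alphabet bijections and reversal.
An independent brute-force breadth-first search over pools of built
substrings (`brute_force_assembly_index`, inputs up to length 10)
serves as the oracle in tests, exhaustively on all binary strings up to
length 8 and all ternary strings up to length 6.

For unary strings the problem is exactly the shortest addition chain
problem; `addition_chain_min` solves it by exhaustive iterative
deepening (practical to l ≈ 64) and tests assert equality with the
string search for l ≤ 32.

## Ensemble observable

`A = Σ exp(a_i) (n_i − 1)/N` is evaluated verbatim with the natural
exponential; `N` counts all copies.  Identity of objects is exact
string equality — the measurement-uncertainty notion of "identical"
collapses to equality for symbolic strings.  `A = 0` iff every copy
number is 1, and `A` is strictly increasing in each `a_i` and `n_i`.

## Baselines

*Shannon entropy* is the character-frequency entropy in bits per
symbol.  *Huffman coding* merges the two least frequent nodes under a
fixed tie-breaking convention: priority (weight, leaves before internal
nodes, creation order) with leaves created in lexicographic character
order, and the heavier child of each merge labelled `1` (ties: the
leaf, then the earlier-created node).  Lexicographic leaf order — not
first-appearance order — is used so that any two strings of identical
composition build the identical tree and code map, which is the
many-to-one degeneracy the comparison turns on; the convention is
otherwise immaterial to code lengths.  A single-symbol input is coded
`"0"`.

*LZW* parses left to right, emitting the longest dictionary match and
inserting that match plus the next character.  The initial dictionary
is the distinct characters of the input in first-appearance order, so a
fresh unary string costs one code and reachable unary length after `n`
steps is the triangular number `n(n+1)/2`; a full 256-entry byte
alphabet is available behind a flag.  Because the literature reports
"compressed bytes" without a packing convention, sizes are reported
under three policies: `code_count` (number of codes), `fixed12_bytes`
(12 bits per code) and `minwidth_bytes` (smallest fixed width
addressing the final dictionary).  `minwidth_bytes` is the default
experiment metric, being closest to a byte count of the emitted stream;
all policies are always computed alongside.

## Experiments

The scaling table tabulates reachable unary length per step for both
algorithms (`n(n+1)/2` vs `2^n`) and cross-validates the closed forms
for `n ≤ 6` by running the real implementations.

The permutation study samples uniform random rearrangements of
`aaaaaabbbbbbcccc` (16 characters, 1,681,680 distinct permutations —
anagrams, hence identical entropy and Huffman code), computes each
sample's exact index and LZW sizes, and reports the Pearson correlation
per packing policy plus the integer-binned histogram and moments of the
difference (LZW code count − index).  Both the ratio mean and the
correlation are reported since the text describes the former and the
figure the latter.  Sampling is with replacement across draws from a
seeded generator; full enumeration of all permutations is available
behind a flag.  The library default is 10,000 samples; the bundled
acceptance run uses 2,000 samples per seed and two disjoint seeds with
a 0.07 agreement band, the documented reduced-sample protocol for exact
search (≈ 80 ms per exact index at length 16 on one CPU).  At these
sizes the sampling standard error of `r` is about 0.02.

## Synthetic fixtures

The fixture generator emulates only the combinatorics the experiments
need: multiset shuffles of a stated composition and uniform i.i.d.
strings over a stated alphabet, all driven by one explicit seed.  It
does not emulate any natural sequence statistics (codon structure,
long-range correlation, unequal base composition drift), so passing
tests demonstrate correctness of the measures and their contrasts on
controlled ensembles, not performance claims about natural data.

## Numerical and degenerate-input choices

Entropy returns +0.0 for single-symbol strings.  Pearson correlation
raises on zero-variance input rather than returning NaN.  Histogram
bins are unit-width and centred on integers.  `minwidth_bytes` uses at
least one bit per code (a one-entry dictionary would otherwise pack to
zero).  All randomness flows through explicitly passed seeds; no global
state is mutated.

## Known limitations

Exact search beyond a few dozen characters depends strongly on internal
repetition; pathological inputs fall back to the bounded result with
`exact=False` when a budget is set.  The greedy upper bound exploits
one repeated substring per level and can exceed the optimum by a few
joins.  Only the string assembly model is implemented: molecular
(bond-graph) assembly indices, and spectroscopy-based measurement of
them, are out of scope, as is any empirical biosignature threshold.
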