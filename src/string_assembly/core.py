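"""Exact assembly index of strings and witnessing assembly pathways.

The assembly index of an object is the minimal number of recursive
joining operations needed to construct it from its elementary parts,
where every product of an earlier join may be reused arbitrarily often.
For strings the elementary parts are the single characters occurring in
the target (available at zero cost) and the only join is binary
concatenation of two already-available objects.  The index therefore
counts joins only: a single character has index 0, and a string of
length ``l`` with no internal repetition has index ``l - 1``.

The search space can be restricted to contiguous substrings of the
target: in a minimal pathway every product is used by a later join
(otherwise the step could be dropped), so by induction every product
occurs contiguously inside the final string.  A minimal pathway also
never constructs the same product twice.  Consequently the index equals
the size of the smallest set ``S`` of substrings (of length >= 2,
containing the target) such that every member of ``S`` splits into two
parts, each of which is a single character or another member of ``S``.
The exact solver below runs an iterative-deepening branch-and-bound
search over such closure sets; :func:`brute_force_assembly_index` is an
independent forward breadth-first search used as a test oracle.

Computing the index exactly is NP-complete in general, so worst-case
runtime is exponential; the solver is practical for strings of a few
dozen characters and, with memoisation, for large batches of short
strings.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from . import _fast

__all__ = [
    "JoinStep",
    "AssemblyPathway",
    "AssemblyResult",
    "VerifyResult",
    "candidate_substrings",
    "lower_bound",
    "junction_lower_bound",
    "greedy_upper_bound",
    "exact_assembly_index",
    "brute_force_assembly_index",
    "verify_pathway",
    "addition_chain_min",
    "canonical_form",
]


def _require_nonempty(target: str) -> None:
    if not isinstance(target, str):
        raise TypeError(f"target must be a string, got {type(target).__name__}")
    if not target:
        raise ValueError("assembly objects are non-empty strings")


@dataclass(frozen=True)
class JoinStep:
    """One joining operation: ``product`` is ``left`` followed by ``right``."""

    left: str
    right: str
    product: str


@dataclass(frozen=True)
class AssemblyPathway:
    """An ordered witness of joins from free characters to ``target``.

    Each step's operands must be single characters of the target's
    alphabet or products of earlier steps; the last product must equal
    the target.  Use :func:`verify_pathway` to check these invariants.
    """

    target: str
    steps: tuple[JoinStep, ...]

    def __len__(self) -> int:
        return len(self.steps)

    def products(self) -> tuple[str, ...]:
        return tuple(step.product for step in self.steps)


@dataclass(frozen=True)
class AssemblyResult:
    """A string's assembly index with one witnessing pathway.

    When ``exact`` is True, ``index == len(pathway)`` is the true
    minimum.  When False (search budget exhausted, or the greedy
    heuristic alone was run) ``index`` is the best known upper bound and
    ``lower``/``upper`` bracket the true value.
    """

    target: str
    index: int
    pathway: AssemblyPathway
    exact: bool
    lower: int
    upper: int


class VerifyResult(NamedTuple):
    ok: bool
    reason: str

    def __bool__(self) -> bool:  # allows ``assert verify_pathway(p)``
        return self.ok


def candidate_substrings(target: str) -> set[str]:
    """All distinct non-empty contiguous substrings of ``target``.

    In a minimal pathway every intermediate occurs contiguously in the
    target, so this set bounds the search space of the exact solver.
    """
    _require_nonempty(target)
    n = len(target)
    return {target[i:j] for i in range(n) for j in range(i + 1, n + 1)}


def lower_bound(target: str) -> int:
    """Doubling lower bound: each join at most doubles the longest object.

    ``ceil(log2 l)`` joins are needed to reach length ``l`` from single
    characters, hence the index of any string of length ``l`` is at
    least this value.
    """
    _require_nonempty(target)
    return max(math.ceil(math.log2(len(target))), 0)


# ---------------------------------------------------------------------------
# Greedy upper bound: exploit the longest repeated substring.
# ---------------------------------------------------------------------------


def _longest_repeat(s: str) -> str | None:
    # Longest substring of length >= 2 with at least two non-overlapping
    # occurrences.  Ties: leftmost first occurrence, then lexicographic
    # (the leftmost rule already determines the winner for a fixed length).
    n = len(s)
    for length in range(n // 2, 1, -1):
        for i in range(n - 2 * length + 1):
            w = s[i : i + length]
            if s.find(w, i + length) != -1:
                return w
    return None


def _greedy_steps(s: str) -> list[JoinStep]:
    if len(s) == 1:
        return []
    w = _longest_repeat(s)
    if w is None:
        tokens = list(s)
        steps: list[JoinStep] = []
    else:
        steps = _greedy_steps(w)
        tokens = []
        i = 0
        while i < len(s):
            if s.startswith(w, i):
                tokens.append(w)
                i += len(w)
            else:
                tokens.append(s[i])
                i += 1
    cur = tokens[0]
    for tok in tokens[1:]:
        steps.append(JoinStep(cur, tok, cur + tok))
        cur += tok
    return steps


def greedy_upper_bound(target: str) -> AssemblyResult:
    """Valid (not necessarily minimal) pathway via longest repeated substring.

    Repeatedly builds the longest substring that occurs at least twice
    without overlap, then concatenates the tokenised target left to
    right.  The result's length is an upper bound on the exact index and
    seeds the exact solver's iterative deepening.
    """
    _require_nonempty(target)
    steps = _greedy_steps(target)
    # Drop duplicate constructions (a product built once is reusable).
    seen: set[str] = set()
    deduped = []
    for st in steps:
        if st.product not in seen:
            seen.add(st.product)
            deduped.append(st)
    pathway = AssemblyPathway(target, tuple(deduped))
    return AssemblyResult(
        target=target,
        index=len(pathway),
        pathway=pathway,
        exact=False,
        lower=lower_bound(target),
        upper=len(pathway),
    )


def verify_pathway(p: AssemblyPathway) -> VerifyResult:
    """Check all pathway invariants; returns ``(ok, reason)``.

    Reasons: ``ok``, ``empty_target``, ``no_steps``, ``bad_concatenation``,
    ``unavailable_operand``, ``product_not_substring``,
    ``final_product_not_target``.
    """
    if not isinstance(p, AssemblyPathway) or not p.target:
        return VerifyResult(False, "empty_target")
    if len(p.target) == 1:
        if p.steps:
            return VerifyResult(False, "final_product_not_target")
        return VerifyResult(True, "ok")
    if not p.steps:
        return VerifyResult(False, "no_steps")
    chars = set(p.target)
    available: set[str] = set()
    for step in p.steps:
        if step.left + step.right != step.product:
            return VerifyResult(False, "bad_concatenation")
        for operand in (step.left, step.right):
            if not (operand in available or (len(operand) == 1 and operand in chars)):
                return VerifyResult(False, "unavailable_operand")
        if step.product not in p.target:
            return VerifyResult(False, "product_not_substring")
        available.add(step.product)
    if p.steps[-1].product != p.target:
        return VerifyResult(False, "final_product_not_target")
    return VerifyResult(True, "ok")


# ---------------------------------------------------------------------------
# Exact solver: iterative-deepening branch and bound over closure sets.
# ---------------------------------------------------------------------------


def junction_lower_bound(target: str) -> int:
    """Junction bound: the index is at least the number of distinct bigrams.

    Every join creates exactly one junction bigram (last character of
    the left operand followed by the first of the right).  Single
    characters contain no bigrams, so by induction every distinct
    adjacent pair occurring in the target must be the junction of some
    join in any valid pathway.
    """
    _require_nonempty(target)
    return len({target[i : i + 2] for i in range(len(target) - 1)})


def _run_demands(target: str) -> dict[str, int]:
    """Required junction-slot count per distinct bigram.

    A bigram ``xy`` with ``x != y`` must be the junction of at least one
    join.  A repeated-letter bigram ``xx`` whose longest run in the
    target has length ``M`` must be the junction of at least
    ``ceil(log2 M)`` distinct joins: the longest ``x``-run inside an
    element at most doubles at each join, and every strict increase
    straddles an ``xx`` junction.
    """
    demands: dict[str, int] = {}
    for b in {target[i : i + 2] for i in range(len(target) - 1)}:
        if b[0] == b[1]:
            runs = [len(m) for m in re.findall(re.escape(b[0]) + "+", target)]
            demands[b] = max(1, math.ceil(math.log2(max(runs))))
        else:
            demands[b] = 1
    return demands


def _chain_deficit(longest: int, below: int) -> int:
    # Admissible estimate of how many further objects (all longer than
    # ``below``, so not yet counted) are needed before something of
    # length ``longest`` can be split: the larger part of its split has
    # length >= ceil(longest/2) and lengths at most double per object.
    need = (longest + 1) // 2
    cur = below
    extra = 0
    while cur < need:
        cur *= 2
        extra += 1
    return extra


class _ClosureProblem:
    """Precomputed split structure of one target, shared across depths.

    Substrings of length >= 2 are mapped to integer ids ordered by
    (length, lexicographic), so sets of required substrings become
    bitmasks and the longest unresolved element is the highest set bit.
    """

    def __init__(self, target: str):
        self.target = target
        subs = sorted(
            (s for s in candidate_substrings(target) if len(s) >= 2),
            key=lambda x: (len(x), x),
        )
        self.subs = subs
        self.sid = {s: i for i, s in enumerate(subs)}
        self.lengths = [len(s) for s in subs]
        bigrams = sorted({target[i : i + 2] for i in range(len(target) - 1)})
        bg = {b: 1 << i for i, b in enumerate(bigrams)}
        self.bigram_id = {b: i for i, b in enumerate(bigrams)}
        self.d_mask = (1 << len(bigrams)) - 1
        # bits of all ids strictly shorter than a given length
        self.below_len: dict[int, int] = {}
        for length in {len(s) for s in subs}:
            mask = 0
            for i, s in enumerate(subs):
                if len(s) < length:
                    mask |= 1 << i
            self.below_len[length] = mask
        # per element: deduplicated (parts_mask, junction_bit, left, right)
        self.splits: list[list[tuple[int, int, str, str]]] = []
        for s in subs:
            options = []
            seen = set()
            for i in range(1, len(s)):
                u, v = s[:i], s[i:]
                parts = 0
                if len(u) >= 2:
                    parts |= 1 << self.sid[u]
                if len(v) >= 2:
                    parts |= 1 << self.sid[v]
                jbit = bg[u[-1] + v[0]]
                if (parts, jbit) in seen:
                    continue
                seen.add((parts, jbit))
                options.append((parts, jbit, u, v))
            self.splits.append(options)
        self.memo: dict[tuple[int, int], int] = {}
        self.n_bigrams = len(bigrams)
        self._packed = None

    def _pack(self):
        # Flatten the split table into numpy arrays for the compiled engine.
        ns = len(self.subs)
        sstart = np.zeros(ns, np.int64)
        send = np.zeros(ns, np.int64)
        p_lo, p_hi, jb, jbid = [], [], [], []
        pos = 0
        for e, options in enumerate(self.splits):
            sstart[e] = pos
            for parts, jbit, _, _ in options:
                p_lo.append(parts & 0xFFFFFFFFFFFFFFFF)
                p_hi.append(parts >> 64)
                jb.append(jbit)
                jbid.append(jbit.bit_length() - 1)
                pos += 1
            send[e] = pos
        bl_lo = np.zeros(ns, np.uint64)
        bl_hi = np.zeros(ns, np.uint64)
        for e in range(ns):
            mask = self.below_len[self.lengths[e]]
            bl_lo[e] = mask & 0xFFFFFFFFFFFFFFFF
            bl_hi[e] = mask >> 64
        demands = _run_demands(self.target)
        demand = np.zeros(self.n_bigrams, np.int64)
        for b, d in demands.items():
            demand[self.bigram_id[b]] = d
        self._packed = dict(
            tid=self.sid[self.target],
            lens=np.asarray(self.lengths, np.int64),
            sstart=sstart,
            send=send,
            p_lo=np.asarray(p_lo, np.uint64),
            p_hi=np.asarray(p_hi, np.uint64),
            jb=np.asarray(jb, np.uint64),
            jbid=np.asarray(jbid, np.int64),
            demand=demand,
            d_mask=np.uint64(self.d_mask),
            bl_lo=bl_lo,
            bl_hi=bl_hi,
            memo=_fast.make_memo(),
        )

    def search(self, k: int) -> dict[str, tuple[str, str]] | None:
        """Find a closure set of size <= k, or None; deterministic order."""
        if _fast.HAVE_NUMBA and len(self.subs) <= 128 and self.n_bigrams <= 64:
            if self._packed is None:
                self._pack()
            p = self._packed
            choice = np.full(len(self.subs), -1, np.int64)
            ok = _fast._search_k(
                k, p["tid"], p["lens"], p["sstart"], p["send"],
                p["p_lo"], p["p_hi"], p["jb"], p["jbid"], p["demand"],
                p["d_mask"], p["bl_lo"], p["bl_hi"], p["memo"], choice,
            )
            if not ok:
                return None
            chosen: dict[str, tuple[str, str]] = {}
            for e, c in enumerate(choice):
                if c >= 0:
                    _, _, u, v = self.splits[e][c - int(p["sstart"][e])]
                    chosen[self.subs[e]] = (u, v)
            return chosen
        return self._search_pure(k)

    def _search_pure(self, k: int) -> dict[str, tuple[str, str]] | None:
        subs, lengths, splits = self.subs, self.lengths, self.splits
        d_mask, below_len, memo = self.d_mask, self.below_len, self.memo
        chosen: dict[str, tuple[str, str]] = {}

        def dfs(S: int, unresolved: int, covered: int) -> bool:
            if not unresolved:
                return True
            size = S.bit_count()
            rem = k - size
            resolved = size - unresolved.bit_count()
            missing = (d_mask & ~covered).bit_count()
            if resolved + missing > k:
                return False
            e = unresolved.bit_length() - 1
            length = lengths[e]
            m = S & below_len[length]
            below = lengths[m.bit_length() - 1] if m else 1
            if _chain_deficit(length, below) > rem:
                return False
            key = (S, unresolved)
            if memo.get(key, -1) >= rem:
                return False
            s = subs[e]
            rest = unresolved & ~(1 << e)
            free = None
            candidates = []
            for parts, jbit, u, v in splits[e]:
                new = parts & ~S
                nc = new.bit_count()
                if nc == 0:
                    # Free split: costs nothing, so no other split of this
                    # element needs branching; prefer one whose junction
                    # covers a still-missing bigram.
                    if free is None or (jbit & ~covered and not (free[1] & ~covered)):
                        free = (parts, jbit, u, v)
                elif free is None and size + nc <= k:
                    candidates.append((nc, parts, jbit, u, v, new))
            if free is not None:
                _, jbit, u, v = free
                chosen[s] = (u, v)
                if dfs(S, rest, covered | jbit):
                    return True
                del chosen[s]
            else:
                candidates.sort(key=lambda c: c[0])
                for _, parts, jbit, u, v, new in candidates:
                    chosen[s] = (u, v)
                    if dfs(S | new, rest | new, covered | jbit):
                        return True
                    del chosen[s]
            memo[key] = max(memo.get(key, -1), rem)
            return False

        root = 1 << self.sid[self.target]
        if dfs(root, root, 0):
            return dict(chosen)
        return None


def _pathway_from_splits(target: str, splits: dict[str, tuple[str, str]]) -> AssemblyPathway:
    ordered = sorted(splits, key=lambda x: (len(x), x))
    steps = tuple(JoinStep(splits[s][0], splits[s][1], s) for s in ordered)
    return AssemblyPathway(target, steps)


def exact_assembly_index(target: str, budget: int | None = None) -> AssemblyResult:
    """Minimal number of joins building ``target``, with a witnessing pathway.

    Iterative deepening runs from the doubling lower bound up to the
    greedy upper bound (or ``budget``, a maximum search depth, if
    given).  Branching resolves the longest not-yet-constructed required
    substring over its canonical decompositions, memoising on the set of
    required substrings, so the witnessing pathway is reproducible.

    If the budget is exhausted without a proof of optimality, the result
    carries ``exact=False`` with the best known ``(lower, upper)`` pair
    and the greedy pathway as witness.
    """
    _require_nonempty(target)
    if len(target) == 1:
        pathway = AssemblyPathway(target, ())
        return AssemblyResult(target, 0, pathway, True, 0, 0)
    greedy = greedy_upper_bound(target)
    lb = max(lower_bound(target), sum(_run_demands(target).values()))
    ub = greedy.index
    if budget is None:
        budget = ub
    if lb == ub:
        return AssemblyResult(target, ub, greedy.pathway, True, ub, ub)
    problem = _ClosureProblem(target)
    k = lb
    while k <= min(budget, ub - 1):
        splits = problem.search(k)
        if splits is not None:
            pathway = _pathway_from_splits(target, splits)
            return AssemblyResult(target, k, pathway, True, k, k)
        k += 1
    if k >= ub:
        # All depths below the greedy length failed: greedy is optimal.
        return AssemblyResult(target, ub, greedy.pathway, True, ub, ub)
    return AssemblyResult(target, ub, greedy.pathway, False, k, ub)


def brute_force_assembly_index(target: str, limit: int = 10) -> int:
    """Exact index by breadth-first search over pools of built substrings.

    Independent oracle for :func:`exact_assembly_index`; exhaustive and
    deliberately simple, hence restricted to ``len(target) <= limit``.
    """
    _require_nonempty(target)
    if len(target) > limit:
        raise ValueError(
            f"brute force oracle is limited to strings of length <= {limit}"
        )
    if len(target) == 1:
        return 0
    subs = candidate_substrings(target)
    chars = sorted(set(target))
    frontier: set[frozenset[str]] = {frozenset()}
    depth = 0
    while frontier:
        depth += 1
        nxt: set[frozenset[str]] = set()
        for pool in frontier:
            avail = list(pool) + chars
            for u in avail:
                for v in avail:
                    prod = u + v
                    if prod == target:
                        return depth
                    if prod in subs and prod not in pool:
                        nxt.add(pool | {prod})
        frontier = nxt
    raise RuntimeError("unreachable: every string is constructible")  # pragma: no cover


def addition_chain_min(l: int) -> int:
    """Length of the shortest addition chain for ``l``.

    A chain ``1 = c0, ..., ck = l`` where every term is the sum of two
    earlier (not necessarily distinct) terms; the minimum ``k`` equals
    the assembly index of the unary string of length ``l``.  Exhaustive
    iterative-deepening search, feasible for ``l`` up to roughly 64.
    """
    if not isinstance(l, int) or l < 1:
        raise ValueError("l must be a positive integer")
    if l == 1:
        return 0

    def extend(chain: tuple[int, ...], rem: int) -> bool:
        last = chain[-1]
        if last == l:
            return True
        if rem == 0 or (last << rem) < l:
            return False
        sums = sorted(
            {a + b for a in chain for b in chain if last < a + b <= l},
            reverse=True,
        )
        return any(extend(chain + (s,), rem - 1) for s in sums)

    k = math.ceil(math.log2(l))
    while True:
        if extend((1,), k):
            return k
        k += 1


def canonical_form(s: str) -> str:
    """Canonical representative under alphabet relabeling and reversal.

    The assembly index is invariant under bijective renaming of the
    alphabet and under reversal, so strings sharing a canonical form
    share an index; used to memoise batch computations.
    """
    _require_nonempty(s)

    def relabel(x: str) -> str:
        mapping: dict[str, str] = {}
        out = []
        for ch in x:
            if ch not in mapping:
                mapping[ch] = chr(ord("a") + len(mapping))
            out.append(mapping[ch])
        return "".join(out)

    return min(relabel(s), relabel(s[::-1]))
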