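"""Numba-accelerated engine for the exact assembly index search.

Implements the same iterative-deepening branch-and-bound over closure
sets as :mod:`string_assembly.core`, with sets of required substrings
packed into pairs of 64-bit masks and an explicit DFS stack, so the
inner loop compiles to machine code.  Beyond the pure-Python reference
search it adds two admissible sharpenings:

* a per-bigram *demand* count — a maximal run of character ``x`` of
  length ``M`` forces at least ``ceil(log2 M)`` distinct elements whose
  junction is ``xx``, because the longest run inside an element at most
  doubles at each join and every strict increase straddles an ``xx``
  junction — tracked dynamically against the junctions of already
  resolved elements;
* most-constrained-element selection (resolve the element with fewest
  viable decompositions first).

Both engines must return identical indices; tests assert this.  Falls
back silently (``HAVE_NUMBA = False``) if numba is unavailable.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit, types
    from numba.typed import Dict as NumbaDict

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

if HAVE_NUMBA:
    _U64 = np.uint64

    @njit(cache=True, inline="always")
    def _pc(x):
        # SWAR popcount on uint64
        x = x - ((x >> _U64(1)) & _U64(0x5555555555555555))
        x = (x & _U64(0x3333333333333333)) + ((x >> _U64(2)) & _U64(0x3333333333333333))
        x = (x + (x >> _U64(4))) & _U64(0x0F0F0F0F0F0F0F0F)
        return int((x * _U64(0x0101010101010101)) >> _U64(56))

    @njit(cache=True, inline="always")
    def _bl(x):
        n = 0
        while x:
            x >>= _U64(1)
            n += 1
        return n

    @njit(cache=True)
    def _search_k(
        k, tid, lens, sstart, send, p_lo, p_hi, jb, jbid, demand,
        d_mask, bl_lo, bl_hi, memo, choice_out,
    ):
        """Is there a closure set of size <= k?  Fills choice_out on success.

        memo maps (S_lo, S_hi, unres_lo, unres_hi) -> largest failed
        remaining budget; shared across deepening iterations.
        """
        maxf = k + 2
        fr_S_lo = np.zeros(maxf, np.uint64)
        fr_S_hi = np.zeros(maxf, np.uint64)
        fr_un_lo = np.zeros(maxf, np.uint64)
        fr_un_hi = np.zeros(maxf, np.uint64)
        fr_cov = np.zeros(maxf, np.uint64)
        fr_elem = np.zeros(maxf, np.int64)
        fr_nc = np.zeros(maxf, np.int64)
        fr_ptr = np.zeros(maxf, np.int64)
        fr_rem = np.zeros(maxf, np.int64)
        cand = np.zeros((maxf, 64), np.int64)
        ckey = np.zeros((maxf, 64), np.int64)
        nb = demand.shape[0]
        fr_cnt = np.zeros((maxf, nb), np.int64)

        one = _U64(1)
        zero = _U64(0)

        f = 0
        if tid < 64:
            fr_S_lo[0] = one << _U64(tid)
        else:
            fr_S_hi[0] = one << _U64(tid - 64)
        fr_un_lo[0] = fr_S_lo[0]
        fr_un_hi[0] = fr_S_hi[0]
        entering = True

        while f >= 0:
            if entering:
                S_lo, S_hi = fr_S_lo[f], fr_S_hi[f]
                un_lo, un_hi = fr_un_lo[f], fr_un_hi[f]
                covered = fr_cov[f]
                if un_lo == zero and un_hi == zero:
                    # success: record chosen split per resolved element
                    for g in range(f):
                        choice_out[fr_elem[g]] = cand[g, fr_ptr[g] - 1]
                    return 1
                size = _pc(S_lo) + _pc(S_hi)
                un_cnt = _pc(un_lo) + _pc(un_hi)
                rem = k - size
                resolved = size - un_cnt
                miss_mask = d_mask & ~covered
                # junction-slot deficit against per-bigram demands
                deficit = 0
                for bi in range(nb):
                    d = demand[bi] - fr_cnt[f, bi]
                    if d > 0:
                        deficit += d
                fail = resolved + deficit > k
                etop = 0
                if not fail:
                    if un_hi:
                        etop = 64 + _bl(un_hi) - 1
                    else:
                        etop = _bl(un_lo) - 1
                    # doubling-chain deficit for the longest unresolved
                    length = lens[etop]
                    m_lo = S_lo & bl_lo[etop]
                    m_hi = S_hi & bl_hi[etop]
                    if m_hi:
                        below = lens[64 + _bl(m_hi) - 1]
                    elif m_lo:
                        below = lens[_bl(m_lo) - 1]
                    else:
                        below = 1
                    need = (length + 1) // 2
                    extra = 0
                    while below < need:
                        below *= 2
                        extra += 1
                    if size + extra > k:
                        fail = True
                if not fail:
                    key = (S_lo, S_hi, un_lo, un_hi)
                    if key in memo and memo[key] >= rem:
                        fail = True
                if fail:
                    entering = False
                    f -= 1
                    continue
                # resolve the most constrained element (fewest viable
                # decompositions); a free split wins outright
                e = etop
                best_n = 1 << 30
                for half in range(2):
                    uu = un_lo if half == 0 else un_hi
                    base_id = 0 if half == 0 else 64
                    while uu:
                        b = uu & (~uu + one)
                        i = base_id + _bl(b) - 1
                        uu &= uu - one
                        nopts = 0
                        has_free = False
                        for o in range(sstart[i], send[i]):
                            nl = p_lo[o] & ~S_lo
                            nh = p_hi[o] & ~S_hi
                            if nl == zero and nh == zero:
                                has_free = True
                                break
                            if size + _pc(nl) + _pc(nh) <= k:
                                nopts += 1
                        if has_free:
                            e = i
                            best_n = -1
                            break
                        if nopts < best_n or (nopts == best_n and i > e):
                            best_n = nopts
                            e = i
                    if best_n == -1:
                        break
                fr_elem[f] = e
                fr_rem[f] = rem
                n_cand = 0
                free_opt = -1
                free_covers = False
                for o in range(sstart[e], send[e]):
                    new_lo = p_lo[o] & ~S_lo
                    new_hi = p_hi[o] & ~S_hi
                    nc = _pc(new_lo) + _pc(new_hi)
                    if nc == 0:
                        covers = (jb[o] & miss_mask) != zero
                        if free_opt < 0 or (covers and not free_covers):
                            free_opt = o
                            free_covers = covers
                    elif free_opt < 0 and size + nc <= k:
                        cand[f, n_cand] = o
                        # order: fewest new elements, junction covering a
                        # missing bigram preferred within ties
                        ckey[f, n_cand] = nc * 2 + (0 if (jb[o] & miss_mask) else 1)
                        n_cand += 1
                if free_opt >= 0:
                    cand[f, 0] = free_opt
                    ckey[f, 0] = 0
                    n_cand = 1
                else:
                    # stable insertion sort (ties keep option order)
                    for a in range(1, n_cand):
                        co, cn = cand[f, a], ckey[f, a]
                        b2 = a - 1
                        while b2 >= 0 and ckey[f, b2] > cn:
                            cand[f, b2 + 1] = cand[f, b2]
                            ckey[f, b2 + 1] = ckey[f, b2]
                            b2 -= 1
                        cand[f, b2 + 1] = co
                        ckey[f, b2 + 1] = cn
                fr_nc[f] = n_cand
                fr_ptr[f] = 0
                entering = False
                # fall through to candidate advance

            if fr_ptr[f] >= fr_nc[f]:
                # exhausted: memoise failure and backtrack
                key = (fr_S_lo[f], fr_S_hi[f], fr_un_lo[f], fr_un_hi[f])
                prev = memo.get(key, np.int64(-1))
                if fr_rem[f] > prev:
                    memo[key] = fr_rem[f]
                f -= 1
                continue
            o = cand[f, fr_ptr[f]]
            fr_ptr[f] += 1
            e = fr_elem[f]
            S_lo, S_hi = fr_S_lo[f], fr_S_hi[f]
            new_lo = p_lo[o] & ~S_lo
            new_hi = p_hi[o] & ~S_hi
            if e < 64:
                ebit_lo, ebit_hi = one << _U64(e), zero
            else:
                ebit_lo, ebit_hi = zero, one << _U64(e - 64)
            f += 1
            fr_S_lo[f] = S_lo | new_lo
            fr_S_hi[f] = S_hi | new_hi
            fr_un_lo[f] = (fr_un_lo[f - 1] & ~ebit_lo) | new_lo
            fr_un_hi[f] = (fr_un_hi[f - 1] & ~ebit_hi) | new_hi
            fr_cov[f] = fr_cov[f - 1] | jb[o]
            for bi in range(nb):
                fr_cnt[f, bi] = fr_cnt[f - 1, bi]
            fr_cnt[f, jbid[o]] += 1
            entering = True

        return 0

    def make_memo():
        return NumbaDict.empty(
            types.UniTuple(types.uint64, 4), types.int64
        )
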