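"""Comparison experiments: scaling of LZW vs assembly steps, and the
correlation between assembly index and LZW size over anagrams.

Two experiments quantify how the assembly index differs from
dictionary compression:

* **Scaling.**  On a repeated single letter, ``n`` LZW steps reach
  length ``n (n + 1) / 2`` (so steps grow like ``sqrt(l)``) while ``n``
  assembly joins reach length ``2**n`` (steps grow like ``log2 l``).
  The table of both closed forms can be cross-validated by actually
  running both algorithms.

* **Permutation correlation.**  Across random rearrangements of a fixed
  string — same length, same composition, hence identical entropy and
  Huffman code — the exact assembly index varies while LZW size varies
  too, but the two are only weakly correlated.  The study computes both
  for each sampled permutation, their Pearson correlation under each
  LZW packing policy, and the histogram of the difference
  (LZW code count minus index).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from collections import Counter
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .baselines import lzw_compress, lzw_max_length, lzw_size, LZW_SIZE_POLICIES
from .core import canonical_form, exact_assembly_index

__all__ = [
    "ScalingTable",
    "CorrelationResult",
    "scaling_table",
    "count_permutations",
    "sample_permutations",
    "enumerate_permutations",
    "pearson",
    "correlation_experiment",
    "cached_assembly_index",
]

ScalingTable = pd.DataFrame


def scaling_table(max_steps: int, cross_validate: bool = True) -> ScalingTable:
    """Closed-form reachable lengths after ``n`` steps of each algorithm.

    Columns: ``steps`` (n), ``lzw_reachable_length`` (n(n+1)/2) and
    ``assembly_reachable_length`` (2**n).  With ``cross_validate`` the
    closed forms for ``n <= 6`` are checked by running real LZW on the
    triangular-length unary string and the exact index search on the
    power-of-two one; a mismatch raises ``AssertionError``.
    """
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    steps = np.arange(1, max_steps + 1)
    table = pd.DataFrame(
        {
            "steps": steps,
            "lzw_reachable_length": steps * (steps + 1) // 2,
            "assembly_reachable_length": 2 ** steps.astype(object),
        }
    )
    if cross_validate:
        for n in range(1, min(max_steps, 6) + 1):
            ln = lzw_max_length(n)
            emitted = len(lzw_compress("a" * ln).codes)
            assert emitted == n, f"LZW emitted {emitted} codes for length {ln}"
            a = exact_assembly_index("a" * 2**n).index
            assert a == n, f"index of unary 2^{n} string is {a}"
    return table


def count_permutations(base: str) -> int:
    """Number of distinct rearrangements: |base|! / prod(count_c!)."""
    if not base:
        raise ValueError("base string must be non-empty")
    total = math.factorial(len(base))
    for c in Counter(base).values():
        total //= math.factorial(c)
    return total


def sample_permutations(base: str, k: int, seed: int) -> list[str]:
    """``k`` uniform random shuffles of ``base``, reproducible from seed."""
    if k < 0:
        raise ValueError("k must be >= 0")
    rng = np.random.default_rng(seed)
    chars = np.array(list(base))
    return ["".join(rng.permutation(chars)) for _ in range(k)]


def enumerate_permutations(base: str) -> Iterator[str]:
    """All distinct rearrangements of ``base`` in lexicographic order."""
    counts = Counter(base)
    alphabet = sorted(counts)
    n = len(base)
    out: list[str] = []

    def rec():
        if len(out) == n:
            yield "".join(out)
            return
        for ch in alphabet:
            if counts[ch]:
                counts[ch] -= 1
                out.append(ch)
                yield from rec()
                out.pop()
                counts[ch] += 1

    yield from rec()


def pearson(xs: Sequence[float], ys: Sequence[float]) -> float:
    """Product-moment correlation; raises on zero variance."""
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.shape != ys.shape or xs.size < 2:
        raise ValueError("need two equal-length sequences of length >= 2")
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        raise ValueError("Pearson correlation undefined for constant input")
    return float(scipy.stats.pearsonr(xs, ys).statistic)


def cached_assembly_index(s: str, cache: dict[str, int]) -> int:
    """Exact index memoised by canonical form.

    The index is invariant under alphabet relabeling and reversal, so
    anagram samples that coincide up to those symmetries share one
    search.
    """
    key = canonical_form(s)
    a = cache.get(key)
    if a is None:
        a = exact_assembly_index(s).index
        cache[key] = a
    return a


@dataclass
class CorrelationResult:
    """Output of one permutation-correlation run.

    ``records`` holds one row per sampled string with its exact index
    and LZW sizes under every packing policy; ``pearson_r`` maps policy
    name to the correlation between index and that size.  The histogram
    bins the difference (LZW code count - index) at integer width.
    """

    base: str
    sample_size: int
    seed: int | None
    records: pd.DataFrame
    pearson_r: dict[str, float]
    ratio_mean: dict[str, float]
    hist_edges: np.ndarray
    hist_counts: np.ndarray
    diff_moments: dict[str, float] = field(default_factory=dict)


def correlation_experiment(
    base: str = "aaaaaabbbbbbcccc",
    k: int = 10_000,
    seed: int = 0,
    full: bool = False,
    cache: dict[str, int] | None = None,
    progress: bool = False,
) -> CorrelationResult:
    """Exact assembly index vs LZW size over rearrangements of ``base``.

    Samples ``k`` uniform random shuffles (or, with ``full=True``,
    enumerates every distinct permutation — slow for long bases).  For
    each string the exact index and the LZW sizes under all packing
    policies are computed; both the correlation and the ratio mean are
    reported per policy since the byte-packing convention materially
    changes the numbers.

    A shared ``cache`` dict may be passed to reuse exact indices across
    runs (keyed by canonical form).
    """
    if full:
        strings: Sequence[str] = list(enumerate_permutations(base))
        seed_used = None
    else:
        strings = sample_permutations(base, k, seed)
        seed_used = seed
    if not strings:
        raise ValueError("no strings to analyse (k=0 and full=False?)")
    if cache is None:
        cache = {}
    iterator = strings
    if progress:
        from tqdm import tqdm

        iterator = tqdm(strings, desc="assembly indices", unit="str")
    rows = []
    for s in iterator:
        a = cached_assembly_index(s, cache)
        r = lzw_compress(s)
        row = {"string": s, "assembly_index": a}
        for policy in LZW_SIZE_POLICIES:
            row[f"lzw_{policy}"] = lzw_size(r, policy)
        rows.append(row)
    records = pd.DataFrame(rows)
    a_vals = records["assembly_index"].to_numpy(dtype=float)
    pearson_r = {}
    ratio_mean = {}
    for policy in LZW_SIZE_POLICIES:
        size_vals = records[f"lzw_{policy}"].to_numpy(dtype=float)
        pearson_r[policy] = pearson(a_vals, size_vals)
        ratio_mean[policy] = float(np.mean(a_vals / size_vals))
    diff = records["lzw_code_count"].to_numpy(dtype=float) - a_vals
    lo, hi = int(diff.min()), int(diff.max())
    edges = np.arange(lo - 0.5, hi + 1.5, 1.0)
    counts, _ = np.histogram(diff, bins=edges)
    moments = {
        "mean": float(diff.mean()),
        "std": float(diff.std(ddof=1)) if diff.size > 1 else 0.0,
        "skew": float(scipy.stats.skew(diff)) if diff.size > 2 else 0.0,
    }
    return CorrelationResult(
        base=base,
        sample_size=len(strings),
        seed=seed_used,
        records=records,
        pearson_r=pearson_r,
        ratio_mean=ratio_mean,
        hist_edges=edges,
        hist_counts=counts,
        diff_moments=moments,
    )
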