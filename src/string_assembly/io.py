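"""Readers, writers and the seeded fixture generator.

Strings come in as plain text (one per line) or FASTA; results go out
as JSON or CSV.  All randomness is driven by an explicit seed so that
generated fixtures are reproducible.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .core import AssemblyResult

__all__ = [
    "FixtureSpec",
    "read_strings",
    "write_strings",
    "generate_fixtures",
    "result_to_dict",
    "results_to_frame",
]


def read_strings(path, format: str = "plain") -> list[tuple[str, str]]:
    """Read labeled strings from a file.

    ``plain``: one string per non-empty line, labeled ``line1``,
    ``line2``, ... by original line number.  ``fasta``: one string per
    record (sequence lines concatenated, uppercased, whitespace
    stripped), labeled by the record id.  A FASTA file whose first
    non-blank line is not a header raises with the offending line
    number.  An empty file yields an empty list with a warning.
    """
    path = Path(path)
    if format == "plain":
        out = []
        with open(path, encoding="utf-8") as fh:
            for i, line in enumerate(fh, start=1):
                line = line.strip()
                if line:
                    out.append((f"line{i}", line))
    elif format == "fasta":
        with open(path, encoding="utf-8") as fh:
            for i, line in enumerate(fh, start=1):
                if line.strip():
                    if not line.startswith(">"):
                        raise ValueError(
                            f"{path}:{i}: sequence data before first FASTA header"
                        )
                    break
        out = [
            (rec.id, str(rec.seq).upper().replace(" ", ""))
            for rec in SeqIO.parse(path, "fasta")
        ]
    else:
        raise ValueError(f"unknown format {format!r} (expected 'plain' or 'fasta')")
    if not out:
        warnings.warn(f"no strings read from {path}", stacklevel=2)
    return out


def write_strings(path, labeled: list[tuple[str, str]], format: str = "plain") -> None:
    """Inverse of :func:`read_strings` (plain labels are regenerated)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        if format == "plain":
            for _, value in labeled:
                fh.write(value + "\n")
        elif format == "fasta":
            for label, value in labeled:
                fh.write(f">{label}\n{value}\n")
        else:
            raise ValueError(f"unknown format {format!r}")


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for seeded random strings.

    Either ``composition`` (character -> count; every string is a
    shuffle of that multiset) or ``alphabet`` + ``length`` (uniform
    i.i.d. characters) must be given.
    """

    count: int
    seed: int
    composition: dict[str, int] | None = None
    alphabet: str | None = None
    length: int | None = None


def generate_fixtures(spec: FixtureSpec) -> list[str]:
    """Generate ``spec.count`` reproducible random strings."""
    if spec.count < 0:
        raise ValueError("count must be >= 0")
    rng = np.random.default_rng(spec.seed)
    if spec.composition is not None:
        if not spec.composition or any(c < 1 for c in spec.composition.values()):
            raise ValueError("composition counts must be positive")
        chars = np.array(
            [ch for ch, c in spec.composition.items() for _ in range(c)]
        )
        return ["".join(rng.permutation(chars)) for _ in range(spec.count)]
    if spec.alphabet and spec.length:
        letters = np.array(list(spec.alphabet))
        return [
            "".join(rng.choice(letters, size=spec.length))
            for _ in range(spec.count)
        ]
    raise ValueError("spec needs either a composition or alphabet + length")


def result_to_dict(r: AssemblyResult) -> dict:
    """JSON-ready view of an assembly result (pathway as triples)."""
    return {
        "target": r.target,
        "index": r.index,
        "exact": r.exact,
        "lower": r.lower,
        "upper": r.upper,
        "pathway": [[s.left, s.right, s.product] for s in r.pathway.steps],
    }


def results_to_frame(results: list[tuple[str, AssemblyResult]]) -> pd.DataFrame:
    """CSV-ready summary table: label, target, index, exact, bounds."""
    return pd.DataFrame(
        [
            {
                "label": label,
                "target": r.target,
                "index": r.index,
                "exact": r.exact,
                "lower": r.lower,
                "upper": r.upper,
            }
            for label, r in results
        ]
    )
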