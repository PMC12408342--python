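"""The Assembly observable A of an observed ensemble.

An ensemble is a collection of distinguishable objects, each observed
in some copy number.  For ``N`` total (non-unique) objects the Assembly
is

    A = sum_i exp(a_i) * (n_i - 1) / N

where ``a_i`` is the assembly index and ``n_i`` the copy number of the
i-th distinguishable object.  Objects observed exactly once contribute
nothing: a single copy of even a very complex object is no evidence of
selection, whereas many identical copies of a high-index object make
``A`` large.  For strings, "identical" means exact string equality.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from collections import Counter
from typing import Sequence

import pandas as pd

from .core import exact_assembly_index

__all__ = [
    "ObservedObject",
    "Ensemble",
    "assembly_observable",
    "ensemble_from_observations",
    "read_ensemble_csv",
    "ensemble_report",
]


@dataclass(frozen=True)
class ObservedObject:
    """One distinguishable object: its string, copy number and index."""

    value: str
    copy_number: int
    index: int

    def __post_init__(self):
        if not self.value:
            raise ValueError("observed objects are non-empty strings")
        if self.copy_number < 1:
            raise ValueError("copy number must be >= 1")
        if self.index < 0:
            raise ValueError("assembly index must be >= 0")


@dataclass(frozen=True)
class Ensemble:
    """A multiset of distinguishable objects with copy numbers."""

    objects: tuple[ObservedObject, ...]

    def __post_init__(self):
        values = [o.value for o in self.objects]
        if len(set(values)) != len(values):
            raise ValueError("ensemble objects must be distinguishable (distinct values)")

    @property
    def total_count(self) -> int:
        """N: the total number of (non-unique) objects."""
        return sum(o.copy_number for o in self.objects)


def assembly_observable(e: Ensemble) -> float:
    """Evaluate A = sum_i exp(a_i) (n_i - 1) / N for the ensemble.

    Zero exactly when every object is observed once; strictly
    increasing in every copy number and every index.
    """
    if not e.objects:
        raise ValueError("cannot compute Assembly of an empty ensemble")
    n_total = e.total_count
    return sum(math.exp(o.index) * (o.copy_number - 1) / n_total for o in e.objects)


def ensemble_from_observations(
    values: Sequence[str], indices: dict[str, int] | None = None
) -> Ensemble:
    """Group identical strings into an Ensemble, computing indices.

    ``indices`` may supply precomputed assembly indices per distinct
    value; anything missing is computed exactly.
    """
    if len(values) == 0:
        raise ValueError("no observations given")
    counts = Counter(values)
    objects = []
    for value, n in counts.items():
        if indices is not None and value in indices:
            a = indices[value]
        else:
            a = exact_assembly_index(value).index
        objects.append(ObservedObject(value, n, a))
    return Ensemble(tuple(objects))


def read_ensemble_csv(path) -> Ensemble:
    """Read an ensemble from CSV with columns value, copy_number[, index]."""
    df = pd.read_csv(path, dtype={"value": str})
    if not {"value", "copy_number"} <= set(df.columns):
        raise ValueError("ensemble CSV needs columns 'value' and 'copy_number'")
    has_index = "index" in df.columns
    objects = []
    for i in range(len(df)):
        value = str(df["value"].iloc[i])
        if has_index and not pd.isna(df["index"].iloc[i]):
            a = int(df["index"].iloc[i])
        else:
            a = exact_assembly_index(value).index
        objects.append(ObservedObject(value, int(df["copy_number"].iloc[i]), a))
    return Ensemble(tuple(objects))


def ensemble_report(e: Ensemble) -> dict:
    """Per-object contribution terms and the total A, as plain data."""
    n_total = e.total_count
    terms = [
        {
            "value": o.value,
            "copy_number": o.copy_number,
            "index": o.index,
            "term": math.exp(o.index) * (o.copy_number - 1) / n_total,
        }
        for o in e.objects
    ]
    return {"N": n_total, "objects": terms, "assembly": assembly_observable(e)}
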