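"""Pairwise distance computations, index-set selection, and the
self-priming screen.

Demultiplexing tolerates sequencing errors only if every pair of indexes in
use is sufficiently far apart in edit (Levenshtein) distance, which also
covers the insertions/deletions that plain Hamming distance misses.  The
self-priming screen rejects indexes whose assembled primer could fold back
and extend off its own 3' end.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass
from typing import Sequence

import edlib
from Bio.Seq import Seq

from .index_pool import normalize_sequence

logger = logging.getLogger(__name__)


@dataclass
class DistanceParams:
    """Minimum Levenshtein distances for index compatibility.

    ``min_dist_existing`` applies against a user-supplied existing index
    set; ``min_dist_internal`` applies pairwise within the selected set.
    "Within d" removes: a candidate at distance < d from any existing index
    is dropped, distance exactly d is kept.
    """

    min_dist_existing: int = 3
    min_dist_internal: int = 3

    def __post_init__(self) -> None:
        if self.min_dist_existing < 1 or self.min_dist_internal < 1:
            raise ValueError("distance thresholds must be >= 1")


class SelectionError(RuntimeError):
    """Raised when too few mutually compatible indexes can be found."""


def levenshtein(a: str, b: str) -> int:
    """Edit distance (unit-cost substitutions, insertions, deletions)."""
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


def _within_distance(a: str, b: str, d: int) -> bool:
    """True iff levenshtein(a, b) < d.  Bounded edlib search: cheap in the
    common case where the distance exceeds the threshold."""
    return edlib.align(a, b, mode="NW", task="distance", k=d - 1)["editDistance"] != -1


def hamming(a: str, b: str) -> int:
    """Number of mismatched positions between equal-length sequences."""
    if len(a) != len(b):
        raise ValueError(f"hamming distance needs equal lengths ({len(a)} != {len(b)})")
    return sum(x != y for x, y in zip(a, b))


def reverse_complement(seq: str) -> str:
    """Watson–Crick reverse complement of an unambiguous DNA string."""
    return str(Seq(normalize_sequence(seq)).reverse_complement())


def filter_against_existing(
    candidates: Sequence[str],
    existing: Sequence[str],
    min_dist_existing: int = 3,
) -> list[str]:
    """Drop candidates within ``min_dist_existing`` Levenshtein distance of
    any existing index (distance < threshold removes; order preserved).

    Existing indexes may differ in length from the candidates; edit distance
    handles unequal lengths.  An empty existing set is a no-op.
    """
    if not existing:
        return list(candidates)
    survivors = [
        c
        for c in candidates
        if not any(_within_distance(c, e, min_dist_existing) for e in existing)
    ]
    logger.info(
        "existing-set exclusion: %d -> %d candidates (threshold %d, %d existing)",
        len(candidates), len(survivors), min_dist_existing, len(existing),
    )
    return survivors


def select_mutually_distant(
    candidates: Sequence[str],
    min_dist_internal: int = 3,
    n_required: int = 1,
    seed: int | None = None,
    shuffle: bool = True,
) -> list[str]:
    """Greedy selection of ``n_required`` indexes with pairwise Levenshtein
    distance ≥ ``min_dist_internal``.

    Candidates are scanned once (shuffled first when ``shuffle`` to avoid
    lexicographic clustering of the accepted set; deterministic under
    ``seed``); a candidate is accepted iff it is far enough from everything
    accepted so far.  Greedy selection makes no optimality claim, but every
    returned set is verified pairwise before returning.
    """
    if n_required < 1:
        raise ValueError("n_required must be >= 1")
    order = list(candidates)
    if shuffle:
        random.Random(seed).shuffle(order)
    accepted: list[str] = []
    for c in order:
        if all(not _within_distance(c, a, min_dist_internal) for a in accepted):
            accepted.append(c)
            if len(accepted) == n_required:
                break
    if len(accepted) < n_required:
        raise SelectionError(
            f"only {len(accepted)} of the required {n_required} indexes are mutually "
            f"separated by >= {min_dist_internal} edit distance; supply more candidates "
            f"(longer k, larger pool, or relaxed filters)"
        )
    _assert_pairwise_distant(accepted, min_dist_internal)
    return accepted


def _assert_pairwise_distant(indexes: Sequence[str], min_dist: int) -> None:
    # post-hoc audit of the greedy invariant; O(n^2) bounded edlib calls
    for i, a in enumerate(indexes):
        for b in indexes[i + 1 :]:
            if _within_distance(a, b, min_dist):
                raise AssertionError(
                    f"selected indexes {a} and {b} are closer than {min_dist}"
                )


def min_pairwise_distance(indexes: Sequence[str]) -> int:
    """Smallest Levenshtein distance over all pairs (audit helper)."""
    best = None
    for i, a in enumerate(indexes):
        for b in indexes[i + 1 :]:
            d = levenshtein(a, b)
            best = d if best is None else min(best, d)
    if best is None:
        raise ValueError("need at least two indexes")
    return best


def is_self_priming(
    full_primer: str,
    index_start: int,
    index_end: int,
    window: int = 8,
    min_hamming: int = 3,
) -> bool:
    """Screen an assembled primer for 3'-end self-priming onto its index.

    The probe is the reverse complement of the primer's 3'-terminal
    ``window`` bases.  Every ``window``-length window of the primer that
    overlaps the index span ``[index_start, index_end)`` by at least one
    base is compared to the probe; a Hamming distance below ``min_hamming``
    at any window means the 3' end could anneal there and extend, so the
    index is rejected (returns True).
    """
    n = len(full_primer)
    if window > n:
        raise ValueError(f"window ({window}) exceeds primer length ({n})")
    if not (0 <= index_start < index_end <= n):
        raise ValueError(f"invalid index span [{index_start}, {index_end}) for length {n}")
    probe = reverse_complement(full_primer[-window:])
    lo = max(0, index_start - window + 1)
    hi = min(n - window, index_end - 1)
    for s in range(lo, hi + 1):
        if hamming(probe, full_primer[s : s + window]) < min_hamming:
            return True
    return False
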