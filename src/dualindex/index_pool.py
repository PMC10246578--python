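"""Candidate index generation and per-sequence (context-free) filters.

Indexes are short DNA barcodes, represented as plain uppercase strings over
{A, C, G, T} and always stored in *index-read orientation* — the sequence the
sequencer reports for the index read.  The filters here inspect one sequence
at a time; pairwise compatibility lives in :mod:`dualindex.compatibility`.

Filter rationale (two-channel Illumina chemistry and oligo synthesis):

* a leading G is dark in two-channel chemistry and can abort index
  registration when low-plex pools start with all-dark cycles;
* extreme GC content hurts amplification and cluster quality;
* homopolymer and dinucleotide repeats are associated with synthesis errors.
"""

from __future__ import annotations

import itertools
import logging
import random
from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

DNA_ALPHABET = "ACGT"
_VALID_BASES = frozenset(DNA_ALPHABET)

#: Largest index length for which the candidate pool is enumerated
#: exhaustively (4^9 ≈ 262k); longer indexes are randomly sampled.
MAX_EXHAUSTIVE_K = 9

#: Pool size drawn when sampling candidates for k > MAX_EXHAUSTIVE_K.
DEFAULT_POOL_SIZE = 5000

#: Seed used by default so that default runs are reproducible.
DEFAULT_SEED = 0


class SequenceError(ValueError):
    """Raised for sequences outside the unambiguous DNA alphabet."""


def normalize_sequence(seq: str) -> str:
    """Validate and canonicalize a DNA sequence.

    Lowercase input is upcased.  RNA (U), IUPAC ambiguity codes (N, R, ...)
    and gap characters are rejected with an explicit error.
    """
    s = seq.strip().upper()
    if not s:
        raise SequenceError("empty sequence")
    bad = set(s) - _VALID_BASES
    if bad:
        detail = ", ".join(sorted(bad))
        hint = ""
        if "U" in bad:
            hint = " (RNA? use T, not U)"
        elif bad & set("RYSWKMBDHVN"):
            hint = " (ambiguity codes are not allowed)"
        raise SequenceError(f"invalid DNA character(s): {detail}{hint}")
    return s


@dataclass
class FilterConfig:
    """Thresholds for the per-sequence filter cascade.

    Parameters
    ----------
    gc_min, gc_max
        GC-content bounds as fractions.  Boundaries are exclusive for
        keeping: an index with GC exactly ``gc_min`` or ``gc_max`` is
        removed (the removal condition is "≤ 25% or ≥ 75%").
    max_repeat_units
        Maximum tolerated number of consecutive repeat units; a run of
        ``max_repeat_units + 1`` identical bases, or that many consecutive
        copies of a 2-nt unit, rejects the index.
    forbid_leading_g
        Drop indexes whose index read starts with G (dark base in
        two-channel chemistry).
    min_dist_existing
        Minimum Levenshtein distance to every index of a user-supplied
        existing set (applied in :mod:`dualindex.compatibility`).
    selfprime_window, selfprime_min_hamming
        3'-end window length and Hamming threshold for the self-priming
        screen (applied in :mod:`dualindex.compatibility`).
    pool_size
        Number of random candidates drawn when k > 9.
    seed
        Seed for candidate sampling and downstream shuffles.
    """

    gc_min: float = 0.25
    gc_max: float = 0.75
    max_repeat_units: int = 2
    forbid_leading_g: bool = True
    min_dist_existing: int = 3
    selfprime_window: int = 8
    selfprime_min_hamming: int = 3
    pool_size: int = DEFAULT_POOL_SIZE
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if not 0 <= self.gc_min < self.gc_max <= 1:
            raise ValueError("need 0 <= gc_min < gc_max <= 1")
        if self.selfprime_window < 1:
            raise ValueError("selfprime_window must be >= 1")
        if self.min_dist_existing < 1:
            raise ValueError("min_dist_existing must be >= 1")
        if self.max_repeat_units < 1:
            raise ValueError("max_repeat_units must be >= 1")


def enumerate_kmers(k: int) -> list[str]:
    """All 4^k DNA k-mers in lexicographic order, for k ≤ 9.

    For longer indexes the exhaustive pool is impractically large; use
    :func:`sample_kmers` instead (the raised error says so).
    """
    if not 1 <= k <= MAX_EXHAUSTIVE_K:
        raise ValueError(
            f"exhaustive enumeration supports 1 <= k <= {MAX_EXHAUSTIVE_K}; "
            f"for k={k} use sample_kmers()"
        )
    return ["".join(p) for p in itertools.product(DNA_ALPHABET, repeat=k)]


def sample_kmers(k: int, pool_size: int = DEFAULT_POOL_SIZE, seed: int = DEFAULT_SEED) -> list[str]:
    """Draw ``pool_size`` distinct random k-mers (without replacement).

    Identical ``(k, pool_size, seed)`` always yields the identical pool.
    """
    if k <= MAX_EXHAUSTIVE_K:
        raise ValueError(
            f"k={k} is small enough to enumerate exhaustively; use enumerate_kmers()"
        )
    if pool_size < 1:
        raise ValueError("pool_size must be >= 1")
    if pool_size > 4**k:
        raise ValueError(f"cannot draw {pool_size} distinct {k}-mers (only 4^{k} exist)")
    rng = random.Random(seed)
    seen: set[str] = set()
    pool: list[str] = []
    while len(pool) < pool_size:
        s = "".join(rng.choice(DNA_ALPHABET) for _ in range(k))
        if s not in seen:
            seen.add(s)
            pool.append(s)
    return pool


def gc_fraction(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq)


def passes_leading_g(index: str) -> bool:
    """False iff the first base of the index read is G."""
    return index[0] != "G"


def passes_gc(index: str, gc_min: float = 0.25, gc_max: float = 0.75) -> bool:
    """False iff GC fraction ≤ gc_min or ≥ gc_max (boundaries removed)."""
    return gc_min < gc_fraction(index) < gc_max


def passes_repeats(index: str, max_repeat_units: int = 2) -> bool:
    """False iff any base or 2-nt unit repeats more than ``max_repeat_units``
    times consecutively (defaults: reject AAA... and ATATAT...)."""
    run = 1
    for i in range(1, len(index)):
        run = run + 1 if index[i] == index[i - 1] else 1
        if run > max_repeat_units:
            return False
    # a dinucleotide tract of max_repeat_units + 1 consecutive copies
    n_units = max_repeat_units + 1
    tract = 2 * n_units
    for i in range(len(index) - tract + 1):
        unit = index[i : i + 2]
        if all(index[i + 2 * j : i + 2 * j + 2] == unit for j in range(1, n_units)):
            return False
    return True


def apply_sequence_filters(
    candidates: Sequence[str],
    config: FilterConfig | None = None,
    stats: dict[str, int] | None = None,
) -> list[str]:
    """Apply all per-sequence filters, preserving input order.

    The three predicates are independent per sequence, so the survivor set
    does not depend on the order in which they are applied.  Removal counts
    per filter are logged and, if ``stats`` is given, recorded there under
    keys ``leading_g``, ``gc_content`` and ``repeats`` (each counts the
    candidates failing that rule, regardless of other rules).
    """
    cfg = config or FilterConfig()
    n_lead = n_gc = n_rep = 0
    survivors: list[str] = []
    for c in candidates:
        ok = True
        if cfg.forbid_leading_g and not passes_leading_g(c):
            n_lead += 1
            ok = False
        if not passes_gc(c, cfg.gc_min, cfg.gc_max):
            n_gc += 1
            ok = False
        if not passes_repeats(c, cfg.max_repeat_units):
            n_rep += 1
            ok = False
        if ok:
            survivors.append(c)
    logger.info(
        "sequence filters: %d candidates -> %d survivors "
        "(leading G: %d, GC content: %d, repeats: %d fail)",
        len(candidates), len(survivors), n_lead, n_gc, n_rep,
    )
    if stats is not None:
        stats.update(
            input=len(candidates),
            leading_g=n_lead,
            gc_content=n_gc,
            repeats=n_rep,
            survivors=len(survivors),
        )
    if candidates and not survivors:
        logger.warning("all candidates removed by sequence filters")
    return survivors


def write_pool_txt(indexes: Iterable[str], path) -> None:
    """Debug export: one sequence per line."""
    with open(path, "w") as fh:
        for s in indexes:
            fh.write(s + "\n")


def write_pool_fasta(indexes: Sequence[str], path) -> None:
    """Debug export: FASTA with running identifiers."""
    records = [
        SeqRecord(Seq(s), id=f"index_{i + 1}", description="")
        for i, s in enumerate(indexes)
    ]
    SeqIO.write(records, path, "fasta")


def read_index_list(path, column: str | None = None) -> list[str]:
    """Read an index list: plain text (one per line) or CSV with a column.

    If ``column`` is None and the file looks like a CSV, the first column is
    used; a header row that is not valid DNA is skipped.
    """
    import pandas as pd

    text_first: list[str] = []
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if column is not None or any("," in ln for ln in lines):
        df = pd.read_csv(path)
        col = column if column is not None else df.columns[0]
        if col not in df.columns:
            raise ValueError(f"column {col!r} not found in {path}")
        text_first = [str(v) for v in df[col]]
    else:
        text_first = lines
        # tolerate a single non-DNA header line in plain-text input
        if text_first:
            try:
                normalize_sequence(text_first[0])
            except SequenceError:
                text_first = text_first[1:]
    return [normalize_sequence(s) for s in text_first]
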