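"""Embedding indexes into constant primer context.

An indexing PCR primer is ``flank_5prime + inserted_index + flank_3prime``.
The inserted segment is the index itself or its reverse complement,
depending on how the sequencer reads that index relative to the inserted
strand: on the P7 side the index-1 read is the reverse complement of the
segment in the primer, while on the P5 side (forward-strand workflow) the
index-2 read matches the inserted segment.  Index sequences are therefore
stored in index-read orientation everywhere, and the template records the
mapping, so sample sheets never need to re-derive orientation.

The default templates are the standard Illumina TruSeq dual-index PCR
primer constants (P5 grafting + i5 + TruSeq read-1 binding site; P7
grafting + i7 + TruSeq read-2 binding site), shipped as package data so
users can substitute arbitrary constant regions for other platforms.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import yaml

from .compatibility import reverse_complement
from .index_pool import normalize_sequence

ROLES = ("i5", "i7")
AS_INSERTED = "as-inserted"
REVERSE_COMPLEMENT = "reverse-complement"
_ORIENTATIONS = (AS_INSERTED, REVERSE_COMPLEMENT)


@dataclass(frozen=True)
class PrimerTemplate:
    """Constant flanks and index orientation for one primer role.

    ``index_read_orientation`` says how the sequencer's index read relates
    to the segment physically inserted in this primer: ``as-inserted``
    means the read equals the segment, ``reverse-complement`` means the
    read is its reverse complement.
    """

    role: str
    flank_5prime: str
    flank_3prime: str
    index_read_orientation: str = AS_INSERTED

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")
        if self.index_read_orientation not in _ORIENTATIONS:
            raise ValueError(
                f"index_read_orientation must be one of {_ORIENTATIONS}"
            )
        if not self.flank_5prime or not self.flank_3prime:
            raise ValueError(
                "primer flanks must be non-empty (a bare index cannot be "
                "screened for self-priming or function as a primer)"
            )
        object.__setattr__(self, "flank_5prime", normalize_sequence(self.flank_5prime))
        object.__setattr__(self, "flank_3prime", normalize_sequence(self.flank_3prime))

    def inserted_segment(self, index: str) -> str:
        """The physical segment for an index given in read orientation."""
        if self.index_read_orientation == REVERSE_COMPLEMENT:
            return reverse_complement(index)
        return index

    def full_sequence(self, index: str) -> str:
        return self.flank_5prime + self.inserted_segment(index) + self.flank_3prime

    def index_span(self, k: int) -> tuple[int, int]:
        """Half-open [start, end) of the index in primer coordinates."""
        start = len(self.flank_5prime)
        return start, start + k

    def extract_index(self, full_sequence: str) -> str:
        """Recover the index (read orientation) from an assembled primer."""
        n5, n3 = len(self.flank_5prime), len(self.flank_3prime)
        if (
            full_sequence[:n5] != self.flank_5prime
            or full_sequence[len(full_sequence) - n3 :] != self.flank_3prime
        ):
            raise ValueError("primer does not match template flanks")
        segment = full_sequence[n5 : len(full_sequence) - n3]
        if self.index_read_orientation == REVERSE_COMPLEMENT:
            return reverse_complement(segment)
        return segment


@dataclass(frozen=True)
class PrimerRecord:
    """One assembled, order-ready primer.

    ``index`` is always in index-read orientation; ``order_sequence``
    differs from ``full_sequence`` only by the phosphorothioate mark
    between the final two 3' bases (when enabled).
    """

    name: str
    well: str
    role: str
    index: str
    full_sequence: str
    order_sequence: str


def annotate_phosphorothioate(full_sequence: str) -> str:
    """Mark a single phosphorothioate bond between the last two 3' bases
    ("*" inter-base ordering convention), protecting the primer from
    3'→5' exonuclease proofreading degradation."""
    if len(full_sequence) < 2:
        raise ValueError("sequence must have at least two bases")
    return full_sequence[:-1] + "*" + full_sequence[-1]


def primer_name(plate_id: str, role: str, well: str) -> str:
    """Deterministic unique name, e.g. ``P1_i7_A1``."""
    return f"{plate_id}_{role}_{well}"


def build_primer(
    index: str,
    template: PrimerTemplate,
    name: str,
    well: str,
    phosphorothioate: bool = True,
) -> PrimerRecord:
    """Assemble a primer record for an index in read orientation."""
    index = normalize_sequence(index)
    full = template.full_sequence(index)
    order = annotate_phosphorothioate(full) if phosphorothioate else full
    return PrimerRecord(
        name=name,
        well=well,
        role=template.role,
        index=index,
        full_sequence=full,
        order_sequence=order,
    )


def load_templates(path=None) -> dict[str, PrimerTemplate]:
    """Load primer templates keyed by role from YAML.

    With no path, the packaged Illumina TruSeq defaults are used.  The YAML
    maps each role to ``flank_5prime``, ``flank_3prime`` and
    ``index_read_orientation``.
    """
    if path is None:
        raw = yaml.safe_load(
            resources.files("dualindex.data").joinpath("truseq_templates.yaml").read_text()
        )
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    templates: dict[str, PrimerTemplate] = {}
    for role, spec in raw.items():
        templates[role] = PrimerTemplate(
            role=role,
            flank_5prime=spec["flank_5prime"],
            flank_3prime=spec["flank_3prime"],
            index_read_orientation=spec.get("index_read_orientation", AS_INSERTED),
        )
    missing = set(ROLES) - set(templates)
    if missing:
        raise ValueError(f"template file missing roles: {sorted(missing)}")
    return templates


def write_primers_fasta(records, path) -> None:
    """FASTA export of assembled primers (no chemistry marks)."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    SeqIO.write(
        [SeqRecord(Seq(r.full_sequence), id=r.name, description="") for r in records],
        path,
        "fasta",
    )
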