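"""Pipeline orchestration and file outputs.

A run turns a configuration into, per plate: two order-ready CSVs (one per
primer role) and two Illumina demultiplexing sample sheets (forward and
index2-reverse-complement variants, because some instruments read index 2
in the reverse complement direction), plus a plain-text run report with
per-stage candidate counts.

Indexes for the i5 and i7 roles are selected as two disjoint sets, each
internally separated by the minimum edit distance across *all* plates of
the run (so any subset of wells from any plates can be pooled).  The two
roles are read in separate index reads, so no cross-role distance
constraint is needed for demultiplexing.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import index_pool
from .compatibility import (
    DistanceParams,
    filter_against_existing,
    is_self_priming,
    min_pairwise_distance,
    reverse_complement,
    select_mutually_distant,
)
from .index_pool import (
    FilterConfig,
    apply_sequence_filters,
    enumerate_kmers,
    read_index_list,
    sample_kmers,
)
from .plate_layout import PLATE_SIZE, WELLS, PlateLayout, arrange_plate, audit_plate
from .primer_assembly import (
    PrimerRecord,
    PrimerTemplate,
    build_primer,
    load_templates,
    primer_name,
    write_primers_fasta,
)

logger = logging.getLogger(__name__)

UNIQUE_DUAL = "unique-dual"
COMBINATORIAL = "combinatorial"

ORDER_SHEET_COLUMNS = ["Well Position", "Name", "Sequence"]
MIN_INDEX_LENGTH = 4  # shorter indexes cannot hold edit distance 3 usefully


class PipelineError(RuntimeError):
    """Raised when a pipeline stage cannot meet its quota."""


@dataclass
class RunConfig:
    """Everything a pipeline run needs.

    ``k`` is the index length in nucleotides; ``n_plates`` full 96-well
    plates are produced per primer role.  ``existing_indexes`` optionally
    points to a text/CSV list of indexes already in use, which new indexes
    must stay Levenshtein-distant from.
    """

    k: int = 8
    n_plates: int = 3
    seed: int = index_pool.DEFAULT_SEED
    filters: FilterConfig = field(default_factory=FilterConfig)
    distances: DistanceParams = field(default_factory=DistanceParams)
    templates: dict[str, PrimerTemplate] | None = None
    existing_indexes: str | Path | Sequence[str] | None = None
    output_dir: str | Path = "dualindex_output"
    phosphorothioate: bool = True
    pairing_mode: str = UNIQUE_DUAL
    write_fasta: bool = False

    def __post_init__(self) -> None:
        if self.n_plates < 1:
            raise ValueError("n_plates must be >= 1")
        if self.k < MIN_INDEX_LENGTH:
            raise ValueError(
                f"k must be >= {MIN_INDEX_LENGTH}: shorter indexes cannot be "
                f"demultiplexed at edit distance {self.distances.min_dist_internal}"
            )
        if self.pairing_mode not in (UNIQUE_DUAL, COMBINATORIAL):
            raise ValueError(f"unknown pairing mode {self.pairing_mode!r}")


@dataclass
class SampleSheetTable:
    """Demultiplexing rows for one plate pair.

    ``rows`` holds (sample_id, index1, index2) with both indexes in
    index-read orientation of the forward workflow; the writer derives the
    index2-reverse-complement variant.
    """

    plate_id: str
    rows: list[tuple[str, str, str]]
    orientation_variant: str = "forward"


@dataclass
class RunResult:
    config: RunConfig
    plates_i5: list[PlateLayout]
    plates_i7: list[PlateLayout]
    primers: dict[tuple[str, str], list[PrimerRecord]]  # (plate_id, role) -> 96 records
    stage_counts: dict[str, int]
    output_files: list[Path]


def _generate_candidates(cfg: RunConfig) -> list[str]:
    if cfg.k <= index_pool.MAX_EXHAUSTIVE_K:
        return enumerate_kmers(cfg.k)
    return sample_kmers(cfg.k, cfg.filters.pool_size, cfg.seed)


def _load_existing(cfg: RunConfig) -> list[str]:
    src = cfg.existing_indexes
    if src is None:
        return []
    if isinstance(src, (str, Path)):
        return read_index_list(src)
    return [index_pool.normalize_sequence(s) for s in src]


def _passes_selfprime_both_roles(
    index: str, templates: dict[str, PrimerTemplate], filters: FilterConfig
) -> bool:
    # an index must be clean in every primer context it could be used in
    for tpl in templates.values():
        full = tpl.full_sequence(index)
        start, end = tpl.index_span(len(index))
        if is_self_priming(
            full, start, end, filters.selfprime_window, filters.selfprime_min_hamming
        ):
            return False
    return True


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute the full pipeline and write all output files.

    Stages: candidate generation → per-sequence filters → optional
    existing-set exclusion → self-priming screen (both primer contexts) →
    greedy distance selection per role → color-balanced plate arrangement →
    primer assembly → order sheets + sample sheets + run report.
    Deterministic under ``config.seed``: identical configs give
    byte-identical outputs.
    """
    cfg = config
    templates = cfg.templates or load_templates()
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    candidates = _generate_candidates(cfg)
    counts["generated"] = len(candidates)

    filter_stats: dict[str, int] = {}
    candidates = apply_sequence_filters(candidates, cfg.filters, stats=filter_stats)
    counts["removed_leading_g"] = filter_stats["leading_g"]
    counts["removed_gc_content"] = filter_stats["gc_content"]
    counts["removed_repeats"] = filter_stats["repeats"]
    counts["after_sequence_filters"] = len(candidates)

    existing = _load_existing(cfg)
    if existing:
        candidates = filter_against_existing(
            candidates, existing, cfg.distances.min_dist_existing
        )
    counts["after_existing_exclusion"] = len(candidates)

    candidates = [
        c for c in candidates if _passes_selfprime_both_roles(c, templates, cfg.filters)
    ]
    counts["after_selfprime_screen"] = len(candidates)

    n_per_role = cfg.n_plates * PLATE_SIZE
    rng = random.Random(cfg.seed)
    shuffled = list(candidates)
    rng.shuffle(shuffled)
    try:
        i7_set = select_mutually_distant(
            shuffled, cfg.distances.min_dist_internal, n_per_role, shuffle=False
        )
        remainder = [c for c in shuffled if c not in set(i7_set)]
        i5_set = select_mutually_distant(
            remainder, cfg.distances.min_dist_internal, n_per_role, shuffle=False
        )
    except Exception as exc:
        raise PipelineError(
            f"distance selection: could not find 2 x {n_per_role} mutually "
            f"compatible indexes among {len(candidates)} candidates ({exc})"
        ) from exc
    counts["selected_per_role"] = n_per_role

    plates_i5: list[PlateLayout] = []
    plates_i7: list[PlateLayout] = []
    for p in range(cfg.n_plates):
        plate_id = f"P{p + 1}"
        chunk5 = i5_set[p * PLATE_SIZE : (p + 1) * PLATE_SIZE]
        chunk7 = i7_set[p * PLATE_SIZE : (p + 1) * PLATE_SIZE]
        # independent deterministic seed stream per plate/role
        plates_i5.append(arrange_plate(chunk5, plate_id, seed=rng.randrange(2**31)))
        plates_i7.append(arrange_plate(chunk7, plate_id, seed=rng.randrange(2**31)))
    counts["plates_per_role"] = cfg.n_plates

    primers: dict[tuple[str, str], list[PrimerRecord]] = {}
    output_files: list[Path] = []
    for role, plates in (("i5", plates_i5), ("i7", plates_i7)):
        tpl = templates[role]
        for plate in plates:
            records = [
                build_primer(
                    plate.assignments[w],
                    tpl,
                    primer_name(plate.plate_id, role, w),
                    w,
                    phosphorothioate=cfg.phosphorothioate,
                )
                for w in WELLS
            ]
            primers[(plate.plate_id, role)] = records
            path = outdir / f"{plate.plate_id}_{role}_order.csv"
            write_order_sheet(records, path)
            output_files.append(path)

    for p5, p7 in zip(plates_i5, plates_i7):
        table = pair_for_demux(
            p5, p7, mode=cfg.pairing_mode, plate_id=p5.plate_id
        )
        stem = outdir / f"{p5.plate_id}_samplesheet"
        output_files.extend(write_sample_sheets(table, stem))

    if cfg.write_fasta:
        all_records = [r for recs in primers.values() for r in recs]
        fasta = outdir / "primers.fasta"
        write_primers_fasta(all_records, fasta)
        output_files.append(fasta)

    report = outdir / "run_report.txt"
    _write_report(report, cfg, counts)
    output_files.append(report)

    result = RunResult(cfg, plates_i5, plates_i7, primers, counts, output_files)
    validate_run(result)
    for stage, n in counts.items():
        logger.info("%s: %d", stage, n)
    return result


def _write_report(path: Path, cfg: RunConfig, counts: dict[str, int]) -> None:
    lines = [
        "dualindex run report",
        f"index length k: {cfg.k}",
        f"plates per role: {cfg.n_plates}",
        f"seed: {cfg.seed}",
        f"min internal edit distance: {cfg.distances.min_dist_internal}",
        f"min distance to existing set: {cfg.distances.min_dist_existing}",
        "",
        "stage counts:",
    ]
    lines += [f"  {stage}: {n}" for stage, n in counts.items()]
    path.write_text("\n".join(lines) + "\n")


def write_order_sheet(records: Sequence[PrimerRecord], path) -> None:
    """Order-ready CSV: Well Position, Name, Sequence (with chemistry
    marks), 96 rows in row-major well order."""
    if len(records) != PLATE_SIZE:
        raise ValueError(f"order sheet needs a full plate of {PLATE_SIZE} primers")
    by_well = {r.well: r for r in records}
    missing = [w for w in WELLS if w not in by_well]
    if missing:
        raise ValueError(f"plate is missing wells: {missing[:5]}")
    df = pd.DataFrame(
        [
            {
                "Well Position": w,
                "Name": by_well[w].name,
                "Sequence": by_well[w].order_sequence,
            }
            for w in WELLS
        ],
        columns=ORDER_SHEET_COLUMNS,
    )
    df.to_csv(path, index=False)


def read_order_sheet(path) -> pd.DataFrame:
    """Re-parse an order sheet written by :func:`write_order_sheet`."""
    df = pd.read_csv(path)
    missing = set(ORDER_SHEET_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"order sheet {path} lacks columns: {sorted(missing)}")
    return df


def pair_for_demux(
    plate_i5: PlateLayout,
    plate_i7: PlateLayout,
    mode: str = UNIQUE_DUAL,
    plate_id: str | None = None,
) -> SampleSheetTable:
    """Pair i7 (index 1) with i5 (index 2) wells into demultiplexing rows.

    ``unique-dual`` (default) pairs well n of the i7 plate with well n of
    the i5 plate: 96 samples where index 1 and index 2 are each unique and
    redundant, so either read alone identifies the sample and index-hopped
    reads (chimeric pairs) are detectable.  ``combinatorial`` enumerates
    all 96 × 96 pairs for maximum capacity.
    """
    w5 = set(plate_i5.assignments)
    w7 = set(plate_i7.assignments)
    if w5 != set(WELLS) or w7 != set(WELLS):
        raise ValueError("both plates must be fully assigned")
    pid = plate_id or plate_i7.plate_id
    rows: list[tuple[str, str, str]] = []
    if mode == UNIQUE_DUAL:
        for w in WELLS:
            rows.append(
                (f"Sample_{w}", plate_i7.assignments[w], plate_i5.assignments[w])
            )
    elif mode == COMBINATORIAL:
        for w7_name in WELLS:
            for w5_name in WELLS:
                rows.append(
                    (
                        f"Sample_{w7_name}_{w5_name}",
                        plate_i7.assignments[w7_name],
                        plate_i5.assignments[w5_name],
                    )
                )
    else:
        raise ValueError(f"unknown pairing mode {mode!r}")
    return SampleSheetTable(plate_id=pid, rows=rows)


_SHEET_HEADER = [
    "[Header]",
    "IEMFileVersion,4",
    "Workflow,GenerateFASTQ",
    "",
    "[Data]",
    "Sample_ID,index,index2",
]


def write_sample_sheets(table: SampleSheetTable, path_stem) -> list[Path]:
    """Write the forward and index2-reverse-complement sample sheets.

    Some instruments read index 2 in the reverse complement direction, so
    both variants are always emitted; they differ only in the index2
    column.  Layout is bcl2fastq-compatible ([Header]/[Data]).
    """
    stem = Path(path_stem)
    out: list[Path] = []
    for suffix, rc2 in (("fwd", False), ("rc", True)):
        lines = list(_SHEET_HEADER)
        for sample_id, idx1, idx2 in table.rows:
            i2 = reverse_complement(idx2) if rc2 else idx2
            lines.append(f"{sample_id},{idx1},{i2}")
        path = stem.parent / f"{stem.name}_{suffix}.csv"
        path.write_text("\n".join(lines) + "\n")
        out.append(path)
    return out


def read_sample_sheet(path) -> pd.DataFrame:
    """Parse the [Data] section of a sample sheet into a DataFrame."""
    lines = Path(path).read_text().splitlines()
    try:
        start = lines.index("[Data]") + 1
    except ValueError:
        raise ValueError(f"{path} has no [Data] section") from None
    header = lines[start].split(",")
    rows = [ln.split(",") for ln in lines[start + 1 :] if ln.strip()]
    return pd.DataFrame(rows, columns=header)


def validate_run(result: RunResult) -> None:
    """End-to-end audit of a finished run.

    Re-checks every invariant the pipeline promises: each selected index
    passes every per-sequence filter and the self-priming screen; pairwise
    edit distances within each role (across all plates) meet the
    threshold; all plate quartets are color balanced; no index is reused;
    sample-sheet uniqueness holds.  Raises PipelineError on any violation.
    """
    cfg = result.config
    templates = cfg.templates or load_templates()
    role_sets = {
        "i5": [idx for p in result.plates_i5 for idx in p.indexes_row_major()],
        "i7": [idx for p in result.plates_i7 for idx in p.indexes_row_major()],
    }
    seen: set[str] = set()
    for role, indexes in role_sets.items():
        for idx in indexes:
            if idx in seen:
                raise PipelineError(f"index {idx} used more than once in this run")
            seen.add(idx)
            if cfg.filters.forbid_leading_g and not index_pool.passes_leading_g(idx):
                raise PipelineError(f"{role} index {idx} starts with G")
            if not index_pool.passes_gc(idx, cfg.filters.gc_min, cfg.filters.gc_max):
                raise PipelineError(f"{role} index {idx} fails GC filter")
            if not index_pool.passes_repeats(idx, cfg.filters.max_repeat_units):
                raise PipelineError(f"{role} index {idx} fails repeat filter")
            if not _passes_selfprime_both_roles(idx, templates, cfg.filters):
                raise PipelineError(f"{role} index {idx} fails self-priming screen")
        d = min_pairwise_distance(indexes)
        if d < cfg.distances.min_dist_internal:
            raise PipelineError(
                f"{role} set: minimum pairwise edit distance {d} < "
                f"{cfg.distances.min_dist_internal}"
            )
    for plates in (result.plates_i5, result.plates_i7):
        for plate in plates:
            audit_plate(plate)
    for p5, p7 in zip(result.plates_i5, result.plates_i7):
        table = pair_for_demux(p5, p7, mode=UNIQUE_DUAL)
        idx1 = [r[1] for r in table.rows]
        idx2 = [r[2] for r in table.rows]
        if len(set(idx1)) != len(idx1) or len(set(idx2)) != len(idx2):
            raise PipelineError(f"plate {p5.plate_id}: sample-sheet indexes not unique")
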