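# Methods

## Problem and pipeline

`dualindex` designs sets of dual-index PCR primers for pooled sequencing
libraries. A run proceeds through fixed stages:

1. **Candidate generation.** For index length k ≤ 9 all 4^k k-mers are
   enumerated (lexicographic, so the stage is deterministic without a
   seed). For k > 9 a pool of `pool_size` (default 5000) distinct k-mers is
   drawn without replacement from the seeded generator; 5000 candidates are
   ample for filling several plates at these lengths while keeping the
   pairwise-distance work bounded.
2. **Per-sequence filters.** Leading G, GC content, and simple-repeat
   rules, detailed below. The three predicates are independent per
   sequence, so the survivor set is invariant to their order (a property
   the test suite asserts).
3. **Existing-set exclusion (optional).** Candidates within Levenshtein
   distance < `min_dist_existing` (default 3) of any index the user already
   uses are removed, so old and new plates can be pooled. Existing indexes
   may differ in length from the candidates; edit distance handles that.
4. **Self-priming screen.** Evaluated on the fully assembled primer for
   *both* roles; an index must be clean in every context it could be used
   in.
5. **Distance selection.** Greedy selection of `n_plates × 96` indexes per
   role with pairwise edit distance ≥ `min_dist_internal` (default 3).
6. **Plate arrangement.** Each plate of 96 is laid out so all 24 aligned
   row quartets are color balanced.
7. **Assembly and output.** Indexes are embedded in their constant flanks,
   order sheets and sample sheets are written, and a post-run validator
   re-checks every invariant end to end.

## Filter definitions and thresholds

**Leading G** (`forbid_leading_g`, default on). On two-channel Illumina
chemistry G is dark; an index read opening with dark cycles can fail
intensity registration in low-plex pools. The rule is evaluated in
*index-read orientation* — the sequence the sequencer reports — not in the
physical orientation of the inserted segment; the primer template owns that
mapping, so the filter stays orientation-agnostic.

**GC content** (`gc_min=0.25`, `gc_max=0.75`, fractions). Boundaries are
removal-inclusive: an index at exactly 25% or 75% GC is removed.

**Simple repeats** (`max_repeat_units=2`). An index is removed if any
single base occurs more than `max_repeat_units` times consecutively (so
`AAA` fails) or any 2-nt unit occurs more than `max_repeat_units` times
consecutively (so `ATATAT` fails). Counting *units* rather than
"additional copies" is the stricter of the two natural readings of "more
than two repeats"; the threshold is configurable for users who want the
laxer one. Tri-nucleotide and longer units are deliberately not screened.

**Distance thresholds.** "Within 3" is implemented as *distance < 3
removes*: a pair at exactly distance 3 is acceptable. The same strict-
inequality convention is used by the self-priming screen (Hamming < 3
rejects), which keeps the two screens consistent. Distance 3 tolerates any
single index error (substitution, insertion, or deletion) with guaranteed
unambiguous assignment.

**Self-priming** (`selfprime_window=8`, `selfprime_min_hamming=3`). The
probe is the reverse complement of the primer's 3′-terminal 8 bases. Every
8-nt window of the assembled primer that overlaps the index span by at
least one base is compared to the probe; Hamming distance < 3 at any window
rejects the index. Only windows touching the index are scanned because the
flanks are constant: if a flank-only window were self-complementary the
template itself would be unusable, and no index choice could change that.
This is a pure sequence-identity screen; no thermodynamic (nearest-
neighbor ΔG) model is attempted.

## Per-role selection

The i5 and i7 sets are selected as two *disjoint* greedy passes over one
shuffled candidate pool, each internally separated by
`min_dist_internal` across all plates of the run. No cross-role distance is
enforced: index 1 and index 2 arrive in separate sequencer reads and are
never compared to each other during demultiplexing, so constraining them
jointly would only shrink capacity. At k = 8 this matters — the maximal
greedy mutually-distant set under the default filters caps out near 400
indexes, enough for three plates per role (2 × 288) only because the roles
are independent.

Greedy selection scans the shuffled pool once and accepts a candidate iff
it is far enough from everything accepted so far. It makes no optimality
claim (this is deliberate; maximum-clique constructions are out of scope),
but every returned set is re-verified pairwise before being used. The
shuffle avoids the lexicographic clustering an in-order scan of the
enumerated pool would produce.

## Color balancing

The two-channel signal model is A → {ch1, ch2}, C → {ch1}, T → {ch2},
G → {} (dark). A group is *balanced* when at every index position the union
of channels over the group contains both ch1 and ch2 — this both guarantees
signal in each channel and excludes all-dark cycles. Four-channel
instruments need none of this; the rule is applied unconditionally but is a
two-channel concern.

Balance is enforced on the aligned, non-overlapping quartets of each row
(columns 1–4, 5–8, 9–12), filled row-major A→H, so users can pool as few as
four consecutive wells at quartet granularity without re-checking balance.
Arrangement is greedy with bounded backtracking: quartets are filled one at
a time from a seeded shuffle of the plate's 96 indexes, searching triples
plus an exhaustive fourth member; a dead end (bounded at 8000 candidate
visits per quartet) reshuffles and restarts, up to 200 restarts. With
filter-grade indexes a handful of restarts suffices; the post-hoc audit
re-checks every emitted quartet regardless.

## Primer assembly and orientation

A primer is `flank_5prime + inserted_segment + flank_3prime`. Two distinct
orientation concerns are kept separate by design:

- the **template** records how the sequencer's index read relates to the
  inserted segment (`as-inserted` or `reverse-complement`). With the
  default Illumina TruSeq architecture the i7 (index 1) read is the reverse
  complement of the insert, and the i5 (index 2) read on forward-strand
  workflow instruments equals the insert. Index sequences are stored in
  read orientation everywhere, so sheets never re-derive orientation.
- the **sample-sheet writer** handles the instrument-level variant: some
  machines read index 2 in the reverse complement direction, so both a
  forward and an index2-reverse-complemented sheet are always emitted.

The default flanks are the standard published Illumina TruSeq dual-index
primer constants (P5 grafting + i5 + TruSeq read-1 binding site; P7
grafting + i7 + read-2 binding site), shipped as YAML package data rather
than hard-coded so any constant regions — other platforms, custom
amplicons — can be substituted. The default 3′ annealing flanks have a Tm
of about 65 °C with NEB Q5 polymerase; Tm is a documented property of those
constants, not a computed quantity, and no melting-temperature calculator
is included.

Order sheets carry a single phosphorothioate bond between the last two 3′
bases, written in the IDT `*` inter-base convention, to protect primers
from 3′→5′ exonuclease proofreading degradation. The mark exists only in
the order sheet; screening and round-tripping always use the unannotated
sequence.

## Determinism and numerical choices

Every source of randomness (k > 9 sampling, selection shuffle, per-plate
arrangement seeds) derives from the single run seed (default 0), so
identical configurations produce byte-identical output files — including
the sample sheets, whose [Header] deliberately contains no timestamp.
Per-plate arrangement seeds are drawn from a `random.Random(seed)` stream
in a fixed order. Ties never arise: candidate order is either lexicographic
(enumeration) or a seeded permutation.

Degenerate inputs fail loudly: k < 4 is rejected (too short to hold useful
edit distance), empty flanks are rejected (the self-priming screen would be
meaningless), selection shortfalls name the stage and counts, and an
arrangement dead end after all restarts suggests supplying a larger
surplus.

## What the tests show, and limits

The suite cross-checks each primitive against an independent brute-force
oracle (quadratic-DP edit distance; exhaustive per-rule filters over all
65,536 8-mers; an exhaustive self-priming window enumerator; a separate
channel-union balance checker) and audits full pipeline runs end to end.
The default problem size used throughout — 8-nt indexes, three 96-well
plates per role — is the pipeline's own default configuration.

All guarantees are sequence-level. Passing runs say nothing about
synthesis quality, annealing thermodynamics beyond the Hamming screen, or
index performance on a real flow cell; the screens encode established
design rules, not wet-lab validation. The greedy selector is not maximal,
selection capacity at k = 8 with defaults is a few hundred indexes per
role, and 384-well plates and single-index kits are unsupported (a
single-index run is just an i7 plate whose i5 outputs are ignored).
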