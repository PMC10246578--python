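# dualindex

Design color-balanced dual-index PCR primer plates for multiplexed
sequencing libraries.

Multiplexing many samples into one sequencing run requires appending a
unique DNA barcode (index) to each sample. Buying indexed primers as part
of commercial kits is expensive at scale; designing your own is cheap but
error-prone, because a usable index set must simultaneously

- be **mutually distinguishable**: every pair of indexes within a role must
  be far apart in Levenshtein (edit) distance, so sequencing errors —
  including the insertions and deletions that plain Hamming distance misses
  — cannot turn one index into another;
- avoid **sequence pathologies**: a leading G (dark base on two-channel
  Illumina chemistry), extreme GC content, and homopolymer or dinucleotide
  repeats associated with synthesis errors;
- avoid **self-priming**: the 3′ end of the assembled primer must not anneal
  to any window covering its own index;
- be **color balanced**: on two-channel instruments (A lights both channels,
  C one, T the other, G neither), every pooled subset must produce signal in
  both channels at every index cycle.

`dualindex` generates candidate k-mers (exhaustively for k ≤ 9, a seeded
random pool of 5000 for longer indexes), applies the filter cascade,
optionally excludes indexes near an existing set, greedily selects two
disjoint sets (one per primer role, i5 and i7) with pairwise edit distance
≥ 3 across *all* plates of a run, arranges each plate so that every aligned
group of four wells along a row is color balanced on its own, embeds each
index into its constant primer context (Illumina TruSeq by default,
arbitrary flanks supported), and writes order-ready CSVs (with the 3′
phosphorothioate mark in IDT `*` syntax) plus bcl2fastq-style
demultiplexing sample sheets in both index-2 orientations.

By default sample sheets use **unique dual indexing**: well n of the i7
plate is paired with well n of the i5 plate, so either index alone
identifies the sample and index-hopped reads are detectable. Combinatorial
pairing (96 × 96 = 9216 samples per plate pair) is available as an option.

## Worked example

Generate one plate of 8-nt TruSeq index primers:

```sh
$ dualindex generate -p 1 --seed 7 -o my_run
wrote 5 files to my_run
  generated: 65536
  removed_leading_g: 16384
  removed_gc_content: 18944
  removed_repeats: 18904
  after_sequence_filters: 27138
  after_existing_exclusion: 27138
  after_selfprime_screen: 18884
  selected_per_role: 96
  plates_per_role: 1
```

All 65,536 8-mers are enumerated; 16,384 start with G, 18,944 have GC
content ≤ 25% or ≥ 75%, and 18,904 contain a >2-unit homopolymer or
dinucleotide repeat (a candidate can fail several rules at once), leaving
27,138. No existing index set was given, so that stage is a no-op. The
self-priming screen against both assembled primer contexts leaves 18,884
candidates, from which 96 mutually edit-distant indexes are selected per
role and arranged on one color-balanced plate each.

The order sheet is ready to paste into an oligo order form — note the
phosphorothioate bond (`*`) protecting the last 3′ linkage:

```
$ head -3 my_run/P1_i7_order.csv
Well Position,Name,Sequence
A1,P1_i7_A1,CAAGCAGAAGACGGCATACGAGATTCTTGGCAGTGACTGGAGTTCAGACGTGTGCTCTTCCGATC*T
A2,P1_i7_A2,CAAGCAGAAGACGGCATACGAGATAACATGCTGTGACTGGAGTTCAGACGTGTGCTCTTCCGATC*T
```

The matching sample sheet carries the index-read sequences (the i7 read is
the reverse complement of the segment inserted in the primer — compare
`TGCCAAGA` with the `TCTTGGCA` insert above):

```
$ sed -n 1,8p my_run/P1_samplesheet_fwd.csv
[Header]
IEMFileVersion,4
Workflow,GenerateFASTQ

[Data]
Sample_ID,index,index2
Sample_A1,TGCCAAGA,TCGCCAAT
Sample_A2,AGCATGTT,TGCTGTAT
```

`P1_samplesheet_rc.csv` is identical except that the `index2` column is
reverse complemented, for instruments that read index 2 in that direction.

Audit any previous run, or re-emit sample sheets from order CSVs:

```sh
dualindex validate my_run
dualindex samplesheet my_run/P1_i5_order.csv my_run/P1_i7_order.csv -o my_sheets
```

The same functionality is available as a library — see
`dualindex.run_pipeline`, `dualindex.RunConfig` and the per-stage functions
re-exported from the package root.

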