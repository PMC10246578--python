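# Standard Illumina TruSeq dual-index PCR primer constants.
#
# i5: P5 grafting sequence + i5 index + TruSeq read-1 primer binding site.
#     On forward-strand-workflow instruments the index-2 read equals the
#     inserted segment.
# i7: P7 grafting sequence + i7 index + TruSeq read-2 primer binding site.
#     The index-1 read is always the reverse complement of the inserted
#     segment.
i5:
  flank_5prime: AATGATACGGCGACCACCGAGATCTACAC
  flank_3prime: ACACTCTTTCCCTACACGACGCTCTTCCGATCT
  index_read_orientation: as-inserted
i7:
  flank_5prime: CAAGCAGAAGACGGCATACGAGAT
  flank_3prime: GTGACTGGAGTTCAGACGTGTGCTCTTCCGATCT
  index_read_orientation: reverse-complement
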