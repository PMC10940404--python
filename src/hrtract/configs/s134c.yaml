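# Hemizygous male locus: single mutant X-linked haplotype, S134C (c.401C>G).
# The homology region spans Intron 2 -> 3' UTR; region_length (3509 bp) plus
# the two linker insertions (28 + 33 bp) gives the 3570 bp editing element.
# Marker positions are plausible placeholders consistent with the locus
# anatomy (Intron-2 SNP within the first 100 bp, L1 in Intron 2, L2 in
# Intron 3, mutation in Exon 4, reporter junction immediately downstream of
# Exon 4); all inference is relative to marker order, not absolute distance.
# The "venus" allele is a short synthetic stand-in for the T2A-Venus
# junction; amplicon size bias is modeled via reporter_amplicon_dropout.
name: s134c
region_length: 3509
haplotypes: [mut]
flank: 150
anchor_5prime: -60
anchor_3prime: 3560
mutation_marker: s134c
l2_marker: L2
reporter_marker: venus
sequence_seed: 20407
gc_content: 0.45
markers:
  - {id: i2_snp, kind: substitution, position: 95, role: snp,
     vector: T, genomic: {mut: C}}
  - {id: L1, kind: insertion, position: 320, role: linker,
     vector: GGTACCTAGGCTTAAGTCGACGCATGCA}
  - {id: L2, kind: insertion, position: 1630, role: linker,
     vector: TTAATTAACCGCGGTACGTAGCTAGCGGCCGCT}
  - {id: s134c, kind: substitution, position: 2050, role: mutation,
     vector: C, genomic: {mut: G}}
  - {id: venus, kind: insertion, position: 2710, role: reporter,
     vector: GAGGGCAGAGGAAGTCTTCTAACATGCGGTGACGTGGAGGAGAATCCCGGCCCTATGGTG}
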