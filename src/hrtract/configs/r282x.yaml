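# Heterozygous female locus, R282X (c.844C>T, CGA->TGA) in Exon 4.
# Both haplotypes carry the same genomic SNP alleles (C in Intron 2, T in
# Intron 3) which differ from the vector (T and C respectively), plus a
# silent serine codon S423 (genome AGT on both alleles, vector AGC) near the
# end of Exon 4.  Positions are placeholders consistent with the locus
# anatomy; see s134c.yaml.
name: r282x
region_length: 3509
haplotypes: [WT, mut]
flank: 150
anchor_5prime: -60
anchor_3prime: 3560
mutation_marker: r282x
l2_marker: L2
reporter_marker: venus
sequence_seed: 28210
gc_content: 0.45
markers:
  - {id: i2_snp, kind: substitution, position: 95, role: snp,
     vector: T, genomic: {WT: C, mut: C}}
  - {id: L1, kind: insertion, position: 320, role: linker,
     vector: GGTACCTAGGCTTAAGTCGACGCATGCA}
  - {id: i3_snp, kind: substitution, position: 1250, role: snp,
     vector: C, genomic: {WT: T, mut: T}}
  - {id: L2, kind: insertion, position: 1630, role: linker,
     vector: TTAATTAACCGCGGTACGTAGCTAGCGGCCGCT}
  - {id: r282x, kind: substitution, position: 2350, role: mutation,
     vector: CGA, genomic: {WT: CGA, mut: TGA}}
  - {id: s423, kind: substitution, position: 2680, role: silent,
     vector: AGC, genomic: {WT: AGT, mut: AGT}}
  - {id: venus, kind: insertion, position: 2710, role: reporter,
     vector: GAGGGCAGAGGAAGTCTTCTAACATGCGGTGACGTGGAGGAGAATCCCGGCCCTATGGTG}
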