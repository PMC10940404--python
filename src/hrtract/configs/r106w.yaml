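# Heterozygous female locus, R106W (c.316C>T, CGG->TGG) in Exon 3.
# Two haplotypes: WT carries R106 (CGG), mut carries W106 (TGG).  The
# Intron-3 SNP is shared between the vector and the mutant haplotype (both
# C) while the WT haplotype carries T, so a C call there is attributable to
# vector-or-mut, not to a unique template.  Positions are placeholders
# consistent with the locus anatomy; see s134c.yaml.
name: r106w
region_length: 3509
haplotypes: [WT, mut]
flank: 150
anchor_5prime: -60
anchor_3prime: 3560
mutation_marker: r106w
l2_marker: L2
reporter_marker: venus
sequence_seed: 10611
gc_content: 0.45
markers:
  - {id: i2_snp, kind: substitution, position: 95, role: snp,
     vector: T, genomic: {WT: C, mut: C}}
  - {id: L1, kind: insertion, position: 320, role: linker,
     vector: GGTACCTAGGCTTAAGTCGACGCATGCA}
  - {id: r106w, kind: substitution, position: 700, role: mutation,
     vector: CGG, genomic: {WT: CGG, mut: TGG}}
  - {id: i3_snp, kind: substitution, position: 1250, role: snp,
     vector: C, genomic: {WT: T, mut: C}}
  - {id: L2, kind: insertion, position: 1630, role: linker,
     vector: TTAATTAACCGCGGTACGTAGCTAGCGGCCGCT}
  - {id: venus, kind: insertion, position: 2710, role: reporter,
     vector: GAGGGCAGAGGAAGTCTTCTAACATGCGGTGACGTGGAGGAGAATCCCGGCCCTATGGTG}
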