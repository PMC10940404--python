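# Published 5' TI outcome classes for the heterozygous R106W locus.
# The Intron-3 C is shared between the vector and the mutant haplotype, so
# outcomes carrying it do not resolve the HR template.
# Outcomes 1, 3 and 4 carry the wild-type R106 codon (together 71%).
locus: r106w
assay: five_prime
outcomes:
  - name: outcome1
    fraction: 0.35
    calls: {i2_snp: C, L1: absent, r106w: CGG, i3_snp: C, L2: present}
  - name: outcome2
    fraction: 0.29
    calls: {i2_snp: C, L1: absent, r106w: TGG, i3_snp: C, L2: present}
  - name: outcome3
    fraction: 0.18
    calls: {i2_snp: C, L1: present, r106w: CGG, i3_snp: C, L2: present}
  - name: outcome4
    fraction: 0.18
    calls: {i2_snp: T, L1: present, r106w: CGG, i3_snp: C, L2: present}
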