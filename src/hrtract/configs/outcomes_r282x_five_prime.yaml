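# Published 5' TI outcome classes for the heterozygous R282X locus.
# Both haplotypes share the genomic SNP alleles, so the template is never
# resolved at the 5' end.
# B1: all vector markers -> x5 within the first ~100 bp (before the
#     Intron-2 SNP); B4: only L2 -> x5 between the Intron-3 SNP and L2.
locus: r282x
assay: five_prime
outcomes:
  - name: B1
    fraction: 0.36
    calls: {i2_snp: T, L1: present, i3_snp: C, L2: present}
  - name: B2
    fraction: 0.14
    calls: {i2_snp: C, L1: present, i3_snp: C, L2: present}
  - name: B3
    fraction: 0.07
    calls: {i2_snp: C, L1: absent, i3_snp: C, L2: present}
  - name: B4
    fraction: 0.43
    calls: {i2_snp: C, L1: absent, i3_snp: T, L2: present}
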