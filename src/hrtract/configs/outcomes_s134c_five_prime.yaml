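# Published 5' TI outcome classes for the hemizygous S134C locus.
# B1: L2 inserted but L1 absent -> x5 between L1 and L2.
# B2: both linkers inserted -> x5 between the Intron-2 SNP and L1.
# All clones carried the genomic C at the Intron-2 SNP.
locus: s134c
assay: five_prime
outcomes:
  - name: B1
    fraction: 0.85
    calls: {i2_snp: C, L1: absent, L2: present}
  - name: B2
    fraction: 0.15
    calls: {i2_snp: C, L1: present, L2: present}
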