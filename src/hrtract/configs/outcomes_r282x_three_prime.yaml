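# Published 3' TI outcome classes for the heterozygous R282X locus.
# Both classes retain the genomic AGT at the silent S423 codon and lack
# the reporter, placing x3 between L2/R282X and S423.
# C1: wild-type R282 codon (template unresolvable); C2: mutant codon
# retained -> x3 upstream of the mutation.
locus: r282x
assay: three_prime
outcomes:
  - name: C1
    fraction: 0.78
    calls: {L2: present, r282x: CGA, s423: AGT, venus: absent}
  - name: C2
    fraction: 0.22
    calls: {L2: present, r282x: TGA, s423: AGT, venus: absent}
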