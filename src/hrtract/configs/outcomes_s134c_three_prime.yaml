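# Published 3' TI outcome classes for the hemizygous S134C locus.
# Reporter-containing amplicons were excluded from sequencing, so the
# reporter is absent in both classes.
# C1: wild-type C at the mutation site -> corrected (x3 downstream of it).
# C2: mutant G retained -> x3 between L2 and the mutation site.
locus: s134c
assay: three_prime
outcomes:
  - name: C1
    fraction: 0.44
    calls: {L2: present, s134c: C, venus: absent}
  - name: C2
    fraction: 0.56
    calls: {L2: present, s134c: G, venus: absent}
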