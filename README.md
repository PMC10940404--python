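# hrtract

Crossover-interval mapping for nuclease-free homologous-recombination (HR)
genome editing assayed by targeted-integration (TI) amplicons.

## The problem

AAV-delivered, nuclease-free HR editing replaces a chromosomal segment with
a donor ("editing vector") that is fully homologous to the target except at
a handful of engineered markers: substitution SNPs, short intronic linker
insertions (L1, L2), a promoterless reporter cassette at the end of the
coding region, and — on the chromosome — the pathogenic mutation to be
corrected. Each editing event is a single contiguous conversion tract
delimited by a 5′ crossover `x5` and a 3′ crossover `x3`. The junctions are
unobservable; what Sanger sequencing of TI amplicons shows is, for each
clone, which markers were incorporated. From that pattern the crossovers
can be bounded between flanking informative markers, and the mutation is
corrected exactly when the tract straddles it (`x5 < m < x3`).

`hrtract` turns this style of manual amplicon reasoning — developed for
MECP2 editing in Rett-syndrome patient cells (hemizygous S134C, heterozygous
R106W and R282X loci) — into a reusable, tested pipeline:

- **locus model** (`hrtract.locus`): homology region, ordered markers,
  per-haplotype alleles, vector; concrete sequence construction.
- **forward simulator** (`hrtract.simulate`): samples template haplotype and
  crossover pairs, applies the tract, emits Sanger-like TI-amplicon FASTA
  plus a ground-truth table. Detection mirrors the assay: one primer outside
  the homology arms, one inside linker L2, so only L2-positive alleles
  amplify, and reporter-containing 3′ amplicons drop out (configurable).
- **genotyper** (`hrtract.genotype`): calls each marker in a read by
  flanking-context matching; calls are `vector`, `genomic:<haplotypes>`,
  `shared` (vector allele equals a genomic allele — attributable to
  neither), or `missing` (never guessed).
- **crossover inference** (`hrtract.inference`): inverts the forward model —
  minimal feasible `x5`/`x3` intervals per candidate template, correction
  and reporter status, canonical outcome-class signature, exhaustive class
  enumeration with witness events, and a brute-force grid oracle.
- **statistics** (`hrtract.stats`): outcome-class tables with Wilson CIs,
  closed-form class probabilities under a crossover model, goodness of fit,
  reporter-ascertainment estimation, crossover-model selection.

## The model

With `F` the per-junction CDF of a crossover position on the homology
region `[0, L]` (uniform by default: crossovers occur throughout the
homology region), the pair `(x5, x3)` is the order statistic of two iid
draws. Key quantities:

- correction probability of a mutation at coordinate `m`:
  `p_correct(m) = 2 F(m) (1 − F(m))` — maximal at the center, zero at the
  homology ends;
- detection probability (L2 at coordinate `c`): `2 F(c) (1 − F(c))`;
- reporter ascertainment, for the reporter junction at `r > c`:
  `P(reporter | detected) = (1 − F(r)) / (1 − F(c)) < 1` — reporter
  expression strictly under-represents editing;
- each outcome class is a product of marker-bounded segments, so its
  probability is `2 F(seg5) F(seg3)` summed over templates, conditioned on
  detection.

## Worked example

Aggregate the published R106W 5′ outcome classes (encoded with the shipped
`r106w` locus fixture) at their printed fractions:

```sh
hrtract report --locus r106w \
    --outcomes src/hrtract/configs/outcomes_r106w_five_prime.yaml \
    -o r106w_classes.tsv
```

prints to stderr:

```
conditioning: detected (L2 in tract)
corrected fraction: 0.7100
TV(observed, uniform)=0.1686 (fractions only; no test)
```

i.e. 71% of detected recombination events carry the wild-type R106 codon
(outcomes 1, 3 and 4), 29% retained the mutation because the 5′ crossover
landed downstream of it; with fractions but no clone counts only divergence
from the uniform-model prediction is reported, no test.

A full synthetic round trip on the hemizygous S134C locus:

```sh
hrtract simulate --locus s134c -n 200 --seed 1 --editing-efficiency 1.0 -o demo
hrtract genotype --locus s134c --fasta demo/reads_five_prime.fasta \
    --assay five_prime -o demo/patterns.tsv
hrtract infer --locus s134c --patterns demo/patterns.tsv -o demo/inference.tsv
hrtract report --locus s134c --patterns demo/patterns.tsv -o demo/classes.tsv
```

```
simulated 200 clones (101 detected); wrote reads + truth to demo
genotyped 101 reads -> demo/patterns.tsv
inferred 101 clones (0 inconsistent) -> demo/inference.tsv
conditioning: detected (L2 in tract)
corrected fraction: 0.0000
X2=3.927 df=2 p=0.14
```

Of 200 fully-edited clones, 101 captured L2 and amplified. The three
observed 5′ classes (L1 absent 88%, both linkers 9%, all markers vector 3%)
match the uniform-model prediction (80%/14%/6%, Pearson p = 0.14); the
corrected fraction is 0 *for this 5′ table* because the S134C mutation lies
downstream of L2 and is only visible to the 3′ assay. Each inferred clone
carries its feasible crossover intervals in marker-order space, e.g.
`x5 ∈ (L1, L2)` for the L1-absent class.

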