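# Methods

## Forward model

An editing locus is a homology region of `L` bases shared between the
vector's editing moiety and one (hemizygous) or two (heterozygous)
chromosomal haplotypes, annotated with ordered markers. Coordinates are
0-based and half-open; junction coordinates place a substitution occupying
bases `[q, q+k)` at `q + 0.5` and an insertion before base `p` at `p`, so
with real-valued crossovers "marker inside the tract" is the strict
inequality `x5 < coord < x3` and ties never arise.

Each edited allele results from exactly one contiguous conversion tract:
markers inside `(x5, x3)` carry the vector allele, markers outside carry
the template haplotype's allele, and non-marker sequence is unchanged
(the donor is otherwise fully homologous). Discontinuous or patchy gene
conversion is not modeled; this two-junction abstraction is the
interpretive model the amplicon patterns are read under, and the package
does not attempt to distinguish crossover from non-crossover resolution
mechanisms. Crossovers are restricted to the homology region, editing is
monoallelic per clone by default (a biallelic flag samples one event per
haplotype), and each detected clone yields one clean full-length amplicon —
Sanger-sequenced plasmid clones, not reads with quality profiles.

The crossover pair is the order statistic of two iid draws from a
per-junction distribution with CDF `F` on `[0, L]`. The default is uniform
(`F(x) = x/L`), reflecting the observation that crossovers occur throughout
the region of homology; a Beta family (`BetaCrossoverModel(a, b)`, with
`end_biased` = Beta(½, ½) as a named U-shaped alternative) and a
duck-typed density hook are provided for sensitivity analyses. For disjoint
ordered segments `A < B`, `P(x5 ∈ A, x3 ∈ B) = 2 F(A) F(B)`; because
detection forces `x5 < c_L2 < x3`, all feasible regions used in class
probabilities factor this way, which is what makes the closed forms exact.

## Detection and ascertainment

TI amplification pairs a chromosome-specific primer outside the homology
arms with a primer inside linker L2, so only alleles whose tract captured
L2 amplify; unedited alleles are invisible. Every reported fraction is
therefore conditional, and the conditioning hierarchy is explicit:
(i) detected (L2 in tract); (ii) for the 3′ assay, optionally
reporter-excluded, mirroring the laboratory exclusion of oversized
reporter-containing amplicons. The simulator implements (ii) as a dropout
probability (default 1.0). The shipped reporter allele is a short
**synthetic** stand-in for the reporter-cassette junction; amplicon-size
bias is modeled parametrically by the dropout, not by sequence length.

Reporter ascertainment follows from the same geometry: the reporter
junction at `r` downstream of L2 is captured with probability
`(1 − F(r))/(1 − F(c_L2)) < 1` among detected clones, so reporter-based
editing estimates are a strict lower bound on editing. The estimator in
`ascertainment_report` works on simulated genomes (truth), making it
independent of amplicon dropout by construction. Note that detection alone
does not imply reporter capture even when the reporter sits at or upstream
of L2, because insertion additionally requires `x5 < r`; the package
therefore reports both the unconditional ratio P̂(reporter)/P̂(edited) and
the detected-clone fraction rather than asserting a degenerate ratio of 1.

## Inverse model

Given a pattern of calls from an L2-anchored amplicon, each candidate
template `h` contributes constraints: `vector` calls place the marker
inside the tract, `genomic:h` calls outside, `shared` calls (vector allele
equal to `h`'s allele) and `missing` calls constrain nothing — shared
calls are deliberately never used to tighten intervals, mirroring the
refusal to resolve the HR template when sequence outcomes are identical
for both alleles. Missing calls widen intervals rather than invalidating a
clone. Since `x5 < c_L2 < x3`, upstream markers bound only `x5` and
downstream markers only `x3`, so each template's feasible set is a product
of two open intervals whose bounds are named markers or region boundaries
(marker-order space); base-pair bounds are attached from configured
coordinates, which are placeholders — the published material fixes marker
order but not base-pair offsets, so no inference depends on absolute
distances. A pattern with no feasible `(template, x5, x3)` is returned as
an explicit inconsistent result, never an exception.

Correction status: `corrected` iff the observed allele at the mutation
site is the wild-type (vector) allele *and* the mutation is informative on
at least one candidate template (some candidate actually carried the
mutant allele); `not_corrected` iff the mutant allele is observed;
`indeterminate` when the site is missing or uncovered or no candidate
carries the mutation. This makes ambiguous heterozygous outcomes (e.g. a
wild-type codon reachable by editing either allele) count as wild-type
outcomes, which is how the published corrected percentages are tallied.

Outcome classes are canonical signatures: the ordered calls at informative
markers within the assay span. `enumerate_possible_classes` closes the case
analysis — every (template, 5′-segment, 3′-segment) triple yields a witness
event — and the independent brute-force oracle pushes every pair from a
1-bp grid through the forward rule. Grid points sit at `k + 0.25` and
`k + 0.75`, so any interval with integer or half-integer endpoints contains
exactly twice its length in points and uniform-model grid probabilities are
exact, not approximate; oracle runs use order-preserving rescaled loci
(`LocusMap.rescaled(1000)`) to keep enumeration cheap.

## Genotyping

Markers are located by exact-first, then ≤1-mismatch, matching of 15-nt
flanking genomic contexts (both configurable); the intervening bases are
classified against the configured alleles, and anything else is `missing` —
the inference layer only ever consumes defensible calls. Insertions at
amplicon edges (L2 starts the 3′ read and ends the 5′ read) are anchored on
the insert sequence plus the single available context, accepted only for
long (≥8 nt) inserts where the match is unambiguous. A full-alignment
fallback is deliberately not implemented: clone Sanger sequences are
near-perfect, and context matching keeps calls exactly testable.

## Synthetic data vs real data

The generator emulates the structure of the deposited clone sequences:
contiguous amplicons spanning the 5′ anchor→L2 or L2→3′ anchor, one
definite allele per covered marker, guaranteed L2 (primer anchoring), and
depleted reporter-containing 3′ amplicons. It does not emulate
chromatograms, heterozygous peak mixtures, indels or vector-ITR capture
(none were reported in the data this models), PCR chimeras, or
culture-level clone relatedness. Passing round-trip tests therefore show
that the inference logic is exact under the stated tract model and
error-free Sanger-grade reads — not that the genotyper is robust to messy
traces, nor that real crossovers are uniform.

Defaults are the study conditions: uniform crossover placement; editing
efficiency 0.1 (the order observed by reporter flow cytometry in the
modeled experiments, 3.8–12.1%); substitution error rate 0 (clone
sequences; monotone missing-call degradation is property-tested at 0.02
and 0.08); reporter dropout 1.0. Published percentages come without clone
denominators, so cohort sizes are free parameters: round-trip analyses use
1,000 clones per locus with efficiency 1.0 (modeling the TI-selected pool,
where only edited alleles are informative), model selection uses 100
cohorts of 500, and Monte-Carlo checks use 1e5 draws — sizes at which
binomial error is far below the effects being checked.

## Locus fixtures

Three shipped configs mirror the analyzed loci with marker order exactly as
drawn and placeholder coordinates: `s134c` (hemizygous; Intron-2 SNP, L1,
L2, C→G mutation, reporter), `r106w` (heterozygous; the Intron-3 C shared
by vector and mutant allele creates template ambiguity), `r282x`
(heterozygous; both haplotypes share genomic SNP alleles, plus a silent
S423 codon distinguishing vector from genome downstream of the mutation).
The homology span is 3,509 bp so that span + L1 (28 bp) + L2 (33 bp)
equals the 3,570 bp editing element; flanking anchor sites model the
chromosome-specific primers. A user may supply an explicit scaffold
sequence instead of the seeded random one (configurable GC content) —
the analysis depends only on marker order and alleles, not genomic context.

## Numerical choices

- Wilson intervals for class fractions (small counts), via statsmodels.
- Supplied-fraction tables must sum to 1 within 1e-3 (printed percentages
  round); internally fractions are renormalized and must re-sum within 1e-9.
- Goodness of fit: with counts, multinomial log-likelihood and Pearson X²
  over the predicted class set (zero observed cells contribute zero to the
  log-likelihood); with fractions only, KL and total-variation divergences
  and an explicit no-test flag.
- Model selection compares multinomial log-likelihoods on truth-level class
  counts; classes unseen under a model contribute −∞, which can never favor
  a model that assigns them zero mass.
- Crossover sampling is continuous, so junction/marker coordinate ties have
  probability zero; the single degenerate guard resamples equal draws.
- Seeds: cohort generation from `SimConfig.seed`; per-assay error and
  dropout streams from `(seed, assay-tag)` so 5′ and 3′ emissions are
  independent but reproducible; identical seed + config gives
  byte-identical FASTA and truth tables.

## Known limitations

- Interval minimality and class-probability exactness hold under the
  one-tract model; real events with template switching or patchy
  conversion would surface as "inconsistent pattern" results.
- The genotyper assumes markers are separated by more than one context
  length (true of the shipped fixtures); overlapping marker contexts would
  need the (unimplemented) alignment fallback.
- Heterozygous template ambiguity is irreducible from single-allele
  amplicons; the package reports candidate sets and per-template intervals
  rather than guessing.
- The 5′ and 3′ assays are treated as independent samples of events; if
  the same clones underlie both, joint per-clone tract reconstruction
  would be possible but is not attempted.
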