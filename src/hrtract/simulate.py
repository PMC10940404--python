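"""Forward model of nuclease-free HR editing and TI-amplicon read simulation.

Each edited allele is produced by exactly one contiguous conversion tract
delimited by a 5' crossover ``x5`` and a 3' crossover ``x3`` with
``0 <= x5 < x3 <= L``: markers strictly inside ``(x5, x3)`` carry the
vector allele, markers outside carry the template haplotype's genomic
allele, and non-marker sequence is unchanged (the vector is otherwise fully
homologous).  Detection mirrors the targeted-integration (TI) PCR: one
chromosome-specific primer outside the homology arms and one primer inside
linker L2, so only alleles whose tract captured L2 ever yield an amplicon,
and (by default) reporter-cassette-containing 3' amplicons drop out, the
way oversized T2A-Venus amplicons fail to amplify efficiently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy import stats as _sps

from .locus import INSERTION, LocusMap, Marker, _apply_alleles

__all__ = [
    "CrossoverModel",
    "UniformCrossoverModel",
    "BetaCrossoverModel",
    "get_crossover_model",
    "DegenerateDensityError",
    "CrossoverEvent",
    "SimConfig",
    "Cohort",
    "sample_event",
    "apply_event",
    "true_alleles",
    "simulate_cohort",
    "emit_amplicons",
    "write_fasta",
    "FIVE_PRIME",
    "THREE_PRIME",
    "ASSAYS",
]

FIVE_PRIME = "five_prime"
THREE_PRIME = "three_prime"
ASSAYS = (FIVE_PRIME, THREE_PRIME)

_NUC = "ACGT"


class DegenerateDensityError(ValueError):
    """Raised when a crossover density places zero mass on the region."""


class CrossoverModel:
    """Distribution of one crossover junction on ``[0, L]``.

    A crossover *pair* is the order statistic of two independent draws, so
    for disjoint intervals ``A < B``,
    ``P(x5 in A, x3 in B) = 2 P(X in A) P(X in B)``.  Subclasses (or any
    duck-typed replacement, the pluggable density hook) must provide
    ``cdf`` and ``sample_points``.
    """

    name = "abstract"

    def cdf(self, x, L):  # pragma: no cover - interface
        raise NotImplementedError

    def pdf(self, x, L):  # pragma: no cover - interface
        raise NotImplementedError

    def sample_points(self, rng, L, n):  # pragma: no cover - interface
        raise NotImplementedError

    def interval_prob(self, lo: float, hi: float, L: float) -> float:
        return float(self.cdf(hi, L) - self.cdf(lo, L))

    def pair_prob(self, seg5: tuple[float, float], seg3: tuple[float, float], L: float) -> float:
        """Mass of {x5 in seg5, x3 in seg3} for disjoint seg5 < seg3."""
        if seg5[1] > seg3[0] + 1e-12:
            raise ValueError("pair_prob requires disjoint ordered segments")
        return 2.0 * self.interval_prob(*seg5, L) * self.interval_prob(*seg3, L)

    def sample_pair(self, rng: np.random.Generator, L: float) -> tuple[float, float]:
        a, b = self.sample_points(rng, L, 2)
        while a == b:  # zero-measure guard
            a, b = self.sample_points(rng, L, 2)
        return (a, b) if a < b else (b, a)

    def validate(self, L: float) -> None:
        if not self.interval_prob(0.0, L, L) > 0.0:
            raise DegenerateDensityError(
                f"crossover model {self.name!r} has zero mass on (0, {L})"
            )


class UniformCrossoverModel(CrossoverModel):
    """Crossovers fall uniformly throughout the region of homology."""

    name = "uniform"

    def cdf(self, x, L):
        return np.clip(np.asarray(x, dtype=float) / L, 0.0, 1.0)

    def pdf(self, x, L):
        x = np.asarray(x, dtype=float)
        return np.where((x >= 0) & (x <= L), 1.0 / L, 0.0)

    def sample_points(self, rng, L, n):
        return rng.uniform(0.0, L, size=n)


class BetaCrossoverModel(CrossoverModel):
    """Beta-distributed junction position scaled to the region.

    ``a = b = 1`` recovers the uniform model; ``a = b = 0.5`` is a U-shaped,
    end-biased alternative concentrating crossovers near the homology ends.
    """

    def __init__(self, a: float, b: float):
        self.a, self.b = float(a), float(b)
        self.name = f"beta({self.a:g},{self.b:g})"

    def cdf(self, x, L):
        return _sps.beta.cdf(np.asarray(x, dtype=float) / L, self.a, self.b)

    def pdf(self, x, L):
        return _sps.beta.pdf(np.asarray(x, dtype=float) / L, self.a, self.b) / L

    def sample_points(self, rng, L, n):
        return L * rng.beta(self.a, self.b, size=n)


_NAMED_MODELS = {
    "uniform": UniformCrossoverModel,
    "end_biased": lambda: BetaCrossoverModel(0.5, 0.5),
}


def get_crossover_model(spec) -> CrossoverModel:
    """Resolve a model spec: name, ``('beta', a, b)`` tuple, or instance."""
    if isinstance(spec, CrossoverModel):
        return spec
    if isinstance(spec, str):
        try:
            return _NAMED_MODELS[spec]()
        except KeyError:
            raise ValueError(
                f"unknown crossover model {spec!r}; known: {sorted(_NAMED_MODELS)}"
            ) from None
    if isinstance(spec, (tuple, list)) and spec and spec[0] == "beta":
        return BetaCrossoverModel(spec[1], spec[2])
    if hasattr(spec, "cdf") and hasattr(spec, "sample_points"):
        return spec  # user-supplied density hook
    raise ValueError(f"cannot interpret crossover model spec {spec!r}")


# ---------------------------------------------------------------------------
# Events
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CrossoverEvent:
    """Ground truth for one clone: template haplotype and tract junctions."""

    clone_id: str
    template: str
    x5: float
    x3: float
    edited: bool = True

    def __post_init__(self):
        if self.edited and not (0.0 <= self.x5 < self.x3):
            raise ValueError(f"{self.clone_id}: invalid tract ({self.x5}, {self.x3})")

    def covers(self, coord: float) -> bool:
        return self.edited and self.x5 < coord < self.x3


@dataclass
class SimConfig:
    """Simulation parameters.

    Defaults describe the study conditions the package emulates: uniform
    crossover placement across the homology region, error-free Sanger-grade
    clone sequences, certain exclusion of reporter-containing 3' amplicons,
    monoallelic editing, and an editing efficiency of the order seen by
    flow cytometry (~10% of transduced cells).
    """

    n_clones: int = 100
    editing_efficiency: float = 0.1
    template_probabilities: dict[str, float] | None = None  # default uniform
    crossover_model: object = "uniform"
    substitution_error_rate: float = 0.0
    reporter_amplicon_dropout: float = 1.0
    biallelic: bool = False
    seed: int = 0

    def validate(self, locus: LocusMap) -> None:
        if self.n_clones <= 0:
            raise ValueError("n_clones must be positive")
        for name in ("editing_efficiency", "substitution_error_rate",
                     "reporter_amplicon_dropout"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        probs = self.template_probs(locus)
        if abs(sum(probs.values()) - 1.0) > 1e-9 or any(p < 0 for p in probs.values()):
            raise ValueError("template_probabilities must be a distribution")
        get_crossover_model(self.crossover_model).validate(locus.region_length)

    def template_probs(self, locus: LocusMap) -> dict[str, float]:
        if self.template_probabilities is None:
            n = len(locus.haplotype_ids)
            return {h: 1.0 / n for h in locus.haplotype_ids}
        return {h: float(self.template_probabilities[h]) for h in locus.haplotype_ids}


def sample_event(locus: LocusMap, cfg: SimConfig, rng: np.random.Generator,
                 clone_id: str = "clone") -> CrossoverEvent:
    """Draw one clone's editing outcome.

    With probability ``editing_efficiency`` the clone is edited: a template
    haplotype is drawn from ``template_probabilities`` and ``(x5, x3)`` from
    the configured joint density restricted to ``0 <= x5 < x3 <= L``.
    """
    model = get_crossover_model(cfg.crossover_model)
    model.validate(locus.region_length)
    if rng.random() >= cfg.editing_efficiency:
        return CrossoverEvent(clone_id, template="", x5=np.nan, x3=np.nan, edited=False)
    probs = cfg.template_probs(locus)
    haps = list(locus.haplotype_ids)
    template = haps[rng.choice(len(haps), p=[probs[h] for h in haps])]
    x5, x3 = model.sample_pair(rng, locus.region_length)
    return CrossoverEvent(clone_id, template=template, x5=x5, x3=x3)


def true_alleles(locus: LocusMap, event: CrossoverEvent) -> dict[str, str]:
    """Per-marker allele carried by the edited allele under the tract model."""
    if not event.edited:
        raise ValueError("unedited event has no single-allele truth")
    return {
        m.id: (m.vector_allele if event.covers(m.coord)
               else m.genomic_alleles[event.template])
        for m in locus.markers
    }


def apply_event(locus: LocusMap, event: CrossoverEvent) -> tuple[str, dict[str, str]]:
    """Edited genomic sequence (homology region only) and true marker alleles."""
    alleles = true_alleles(locus, event)
    seq = _apply_alleles(locus, lambda m: alleles[m.id])
    return seq, alleles


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    """A simulated panel of clones with ground truth.

    ``truth`` has one row per clone (per edited allele when biallelic) with
    the tract junctions, per-marker true alleles and derived statuses:
    ``detected`` (L2 captured, hence TI-amplifiable), ``reporter_inserted``,
    ``mutation_wildtype`` (edited allele carries the wild-type base at the
    mutation site) and ``corrected`` (a mutant template whose tract
    straddled the mutation -- the flanking rule).
    """

    locus: LocusMap
    config: SimConfig
    events: list[CrossoverEvent]
    genomes: dict[str, str] = field(repr=False)
    truth: pd.DataFrame = field(repr=False)


def _truth_row(locus: LocusMap, event: CrossoverEvent) -> dict:
    mut = locus.mutation_marker
    rep = locus.reporter_marker
    row = {
        "clone_id": event.clone_id,
        "edited": event.edited,
        "template": event.template,
        "x5": event.x5,
        "x3": event.x3,
    }
    if event.edited:
        alleles = true_alleles(locus, event)
        row["detected"] = event.covers(locus.l2_marker.coord)
        row["reporter_inserted"] = bool(rep) and event.covers(rep.coord)
        row["mutation_wildtype"] = alleles[mut.id] == mut.vector_allele
        row["corrected"] = mut.informative_for(event.template) and event.covers(mut.coord)
        for m in locus.markers:
            row[f"allele_{m.id}"] = alleles[m.id]
    else:
        row.update(detected=False, reporter_inserted=False,
                   mutation_wildtype=False, corrected=False)
        for m in locus.markers:
            row[f"allele_{m.id}"] = ""
    return row


def simulate_cohort(locus: LocusMap, cfg: SimConfig) -> Cohort:
    """Generate ``n_clones`` clones; reproducible for a fixed seed."""
    cfg.validate(locus)
    rng = np.random.default_rng(cfg.seed)
    width = max(4, len(str(cfg.n_clones - 1)))
    events: list[CrossoverEvent] = []
    genomes: dict[str, str] = {}
    rows = []
    for i in range(cfg.n_clones):
        base_id = f"clone{i:0{width}d}"
        if cfg.biallelic:
            for h in locus.haplotype_ids:
                per_allele = SimConfig(**{**cfg.__dict__,
                                          "template_probabilities": {x: float(x == h)
                                                                     for x in locus.haplotype_ids}})
                ev = sample_event(locus, per_allele, rng, clone_id=f"{base_id}/{h}")
                events.append(ev)
                rows.append(_truth_row(locus, ev))
                if ev.edited:
                    genomes[ev.clone_id], _ = apply_event(locus, ev)
        else:
            ev = sample_event(locus, cfg, rng, clone_id=base_id)
            events.append(ev)
            rows.append(_truth_row(locus, ev))
            if ev.edited:
                genomes[ev.clone_id], _ = apply_event(locus, ev)
    truth = pd.DataFrame(rows)
    return Cohort(locus=locus, config=cfg, events=events, genomes=genomes, truth=truth)


# ---------------------------------------------------------------------------
# TI amplicons
# ---------------------------------------------------------------------------

def _inserted_offset(locus: LocusMap, alleles: dict[str, str], coord: float) -> int:
    """Total inserted length upstream of ``coord`` in the edited sequence."""
    off = 0
    for m in locus.markers:
        if m.kind == INSERTION and m.coord < coord and alleles[m.id]:
            off += len(alleles[m.id])
    return off


def _inject_errors(read: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0.0 or not read:
        return read
    arr = np.frombuffer(read.encode(), dtype=np.uint8).copy()
    hits = np.flatnonzero(rng.random(arr.size) < rate)
    for i in hits:
        choices = [c for c in _NUC if ord(c) != arr[i]]
        arr[i] = ord(choices[rng.integers(len(choices))])
    return arr.tobytes().decode()


def emit_amplicons(locus: LocusMap, cohort: Cohort, assay: str) -> list[SeqRecord]:
    """TI-amplicon reads for one assay; Sanger-like, one read per detected clone.

    Only clones whose edited allele captured L2 amplify.  The 5' amplicon
    runs from the 5' chromosomal anchor to the end of the L2 insertion; the
    3' amplicon from the start of L2 to the 3' anchor.  Reporter-containing
    3' amplicons are dropped with probability ``reporter_amplicon_dropout``.
    Truth rows for undetected and dropped clones remain in ``cohort.truth``.
    """
    if assay not in ASSAYS:
        raise ValueError(f"unknown assay {assay!r}")
    cfg = cohort.config
    l2 = locus.l2_marker
    rep = locus.reporter_marker
    if assay == THREE_PRIME and locus.anchor_3prime <= locus.region_length:
        raise ValueError("locus has no 3' anchor outside the homology region")
    if assay == FIVE_PRIME and locus.anchor_5prime >= 0:
        raise ValueError("locus has no 5' anchor outside the homology region")
    rng = np.random.default_rng([cfg.seed, 7 if assay == FIVE_PRIME else 11])
    pad = len(locus.left_flank)
    records: list[SeqRecord] = []
    for ev in cohort.events:
        if not (ev.edited and ev.covers(l2.coord)):
            continue
        alleles = true_alleles(locus, ev)
        full = locus.left_flank + cohort.genomes[ev.clone_id] + locus.right_flank
        l2_start = pad + l2.position + _inserted_offset(locus, alleles, l2.coord)
        if assay == FIVE_PRIME:
            read = full[pad + locus.anchor_5prime : l2_start + len(l2.vector_allele)]
        else:
            if rep is not None and ev.covers(rep.coord):
                if rng.random() < cfg.reporter_amplicon_dropout:
                    continue
            end = pad + locus.anchor_3prime + _inserted_offset(
                locus, alleles, locus.region_length + 0.5)
            read = full[l2_start:end]
        read = _inject_errors(read, cfg.substitution_error_rate, rng)
        records.append(SeqRecord(Seq(read), id=f"{ev.clone_id}|{assay}", description=""))
    return records


def write_fasta(records, path) -> None:
    SeqIO.write(records, str(path), "fasta")
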