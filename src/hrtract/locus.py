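"""Editing-locus model: homology region, markers, haplotypes, vector.

The locus is a genomic homology region of ``region_length`` bases shared
between an editing vector and one or two chromosomal haplotypes.  Markers are
the positions where the vector and/or the haplotypes differ: substitution
SNPs, vector-only insertions (intronic linkers, the reporter-cassette
junction) and the pathogenic mutation itself.  All coordinates are 0-based
and half-open over the genomic region:

* a substitution occupying bases ``[q, q+k)`` has junction coordinate
  ``q + 0.5``;
* an insertion placed between bases ``p-1`` and ``p`` has junction
  coordinate ``p`` (an integer).

Crossover junctions are real-valued points in ``[0, L]``, so "marker lies
inside the conversion tract" is the strict inequality ``x5 < coord < x3``
with no ties.
"""

from __future__ import annotations

import hashlib
import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

__all__ = [
    "Marker",
    "LocusMap",
    "VectorModel",
    "LocusValidationError",
    "DuplicateMarkerIdError",
    "UnorderedMarkersError",
    "MissingMutationError",
    "InsertionAlleleError",
    "AlleleLengthError",
    "load_locus",
    "load_locus_file",
    "builtin_locus",
    "builtin_locus_names",
    "build_sequences",
    "extract_allele",
    "random_sequence",
]

_NUCS = np.frombuffer(b"ACGT", dtype="S1")

SUBSTITUTION = "substitution"
INSERTION = "insertion"

ROLES = {"snp", "linker", "mutation", "reporter", "silent"}


class LocusValidationError(ValueError):
    """Base class for locus configuration problems."""


class DuplicateMarkerIdError(LocusValidationError):
    pass


class UnorderedMarkersError(LocusValidationError):
    pass


class MissingMutationError(LocusValidationError):
    pass


class InsertionAlleleError(LocusValidationError):
    pass


class AlleleLengthError(LocusValidationError):
    pass


def random_sequence(length: int, seed: int, gc_content: float = 0.5) -> str:
    """Seeded random nucleotide scaffold with the requested GC fraction."""
    rng = np.random.default_rng(seed)
    p_gc = gc_content / 2.0
    p_at = (1.0 - gc_content) / 2.0
    draws = rng.choice(_NUCS, size=length, p=[p_at, p_gc, p_gc, p_at])
    return draws.tobytes().decode("ascii")


@dataclass(frozen=True)
class Marker:
    """One position where vector and genome may differ.

    ``position`` is the 0-based base index: for a substitution the first
    replaced base, for an insertion the base before which the vector
    sequence is inserted.
    """

    id: str
    kind: str  # substitution | insertion
    position: int
    vector_allele: str
    genomic_alleles: dict[str, str]  # haplotype id -> allele ('' for insertions)
    role: str = "snp"

    @property
    def coord(self) -> float:
        """Junction coordinate used for tract-membership tests."""
        return self.position + 0.5 if self.kind == SUBSTITUTION else float(self.position)

    @property
    def length(self) -> int:
        """Footprint on the genomic scaffold (0 for insertions)."""
        return len(self.vector_allele) if self.kind == SUBSTITUTION else 0

    def informative_for(self, haplotype: str) -> bool:
        """True when the vector allele differs from this haplotype's allele."""
        return self.vector_allele != self.genomic_alleles[haplotype]

    def informative_for_any(self, haplotypes) -> bool:
        return any(self.informative_for(h) for h in haplotypes)


@dataclass(frozen=True)
class LocusMap:
    """Validated description of the editing locus.

    ``scaffold`` is the genomic reference sequence of the homology region
    before haplotype alleles are applied; haplotypes differ from it only at
    substitution markers.  ``left_flank``/``right_flank`` are chromosomal
    sequence outside the homology region where the chromosome-specific TI
    primers anneal (``anchor_5prime < 0``, ``anchor_3prime > region_length``,
    both within the flanks).
    """

    name: str
    region_length: int
    haplotype_ids: tuple[str, ...]
    markers: tuple[Marker, ...]
    mutation_marker_id: str
    l2_marker_id: str
    reporter_marker_id: str | None
    anchor_5prime: int
    anchor_3prime: int
    scaffold: str
    left_flank: str
    right_flank: str
    source_text: str = field(default="", repr=False, compare=False)

    # -- lookups ---------------------------------------------------------
    def marker(self, marker_id: str) -> Marker:
        for m in self.markers:
            if m.id == marker_id:
                return m
        raise KeyError(marker_id)

    @property
    def mutation_marker(self) -> Marker:
        return self.marker(self.mutation_marker_id)

    @property
    def l2_marker(self) -> Marker:
        return self.marker(self.l2_marker_id)

    @property
    def reporter_marker(self) -> Marker | None:
        return self.marker(self.reporter_marker_id) if self.reporter_marker_id else None

    def assay_markers(self, assay: str) -> tuple[Marker, ...]:
        """Markers covered by the 5' or 3' TI amplicon (L2 included in both)."""
        c_l2 = self.l2_marker.coord
        if assay == "five_prime":
            return tuple(m for m in self.markers if self.anchor_5prime < m.coord <= c_l2)
        if assay == "three_prime":
            return tuple(m for m in self.markers if c_l2 <= m.coord < self.anchor_3prime)
        raise ValueError(f"unknown assay {assay!r}; expected five_prime or three_prime")

    def config_hash(self) -> str:
        payload = self.source_text or repr(self)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    # -- derived loci ----------------------------------------------------
    def rescaled(self, new_length: int, seed: int = 0) -> "LocusMap":
        """Order-preserving copy with marker positions scaled to ``new_length``.

        Used by the grid-enumeration oracles, which run on a reduced region
        so exhaustive (x5, x3) enumeration stays cheap.  Marker order, kinds,
        roles and alleles are preserved; only positions (and the scaffold,
        regenerated from ``seed``) change.
        """
        factor = new_length / self.region_length
        positions = []
        for m in self.markers:
            p = int(round(m.position * factor))
            p = max(1, min(new_length - max(1, m.length) - 1, p))
            positions.append(p)
        # enforce strict ordering and flank separation after rounding
        for i in range(1, len(positions)):
            gap = max(1, self.markers[i - 1].length + 1)
            if positions[i] <= positions[i - 1] + gap:
                positions[i] = positions[i - 1] + gap + 1
        markers = tuple(replace(m, position=p) for m, p in zip(self.markers, positions))
        flank = len(self.left_flank)
        return LocusMap(
            name=f"{self.name}_L{new_length}",
            region_length=new_length,
            haplotype_ids=self.haplotype_ids,
            markers=markers,
            mutation_marker_id=self.mutation_marker_id,
            l2_marker_id=self.l2_marker_id,
            reporter_marker_id=self.reporter_marker_id,
            anchor_5prime=max(self.anchor_5prime, -flank),
            anchor_3prime=new_length + min(self.anchor_3prime - self.region_length, flank),
            scaffold=random_sequence(new_length, seed + 11, 0.5),
            left_flank=self.left_flank,
            right_flank=self.right_flank,
        )


@dataclass(frozen=True)
class VectorModel:
    """The vector's homology moiety plus opaque ITR placeholders."""

    homology_sequence: str
    itr_5prime: str = "<ITR>"
    itr_3prime: str = "<ITR>"

    @property
    def length(self) -> int:
        return len(self.homology_sequence)


# ---------------------------------------------------------------------------
# Loading and validation
# ---------------------------------------------------------------------------

def _validate(locus: LocusMap) -> LocusMap:
    L = locus.region_length
    seen: set[str] = set()
    prev_coord = -np.inf
    prev_end = -np.inf
    for m in locus.markers:
        if m.id in seen:
            raise DuplicateMarkerIdError(f"duplicate marker id {m.id!r}")
        seen.add(m.id)
        if not (0 < m.coord < L):
            raise LocusValidationError(
                f"marker {m.id!r}: coord {m.coord} outside (0, {L})"
            )
        if m.coord <= prev_coord:
            raise UnorderedMarkersError(
                f"marker {m.id!r}: coord {m.coord} not strictly after {prev_coord}"
            )
        if m.position < prev_end:
            raise UnorderedMarkersError(
                f"marker {m.id!r} overlaps the footprint of the previous marker"
            )
        prev_coord = m.coord
        prev_end = m.position + m.length
        if m.kind == INSERTION:
            if any(a != "" for a in m.genomic_alleles.values()):
                raise InsertionAlleleError(
                    f"insertion marker {m.id!r} must have empty genomic alleles"
                )
            if not m.vector_allele:
                raise InsertionAlleleError(
                    f"insertion marker {m.id!r} has an empty vector allele"
                )
        elif m.kind == SUBSTITUTION:
            k = len(m.vector_allele)
            if k == 0 or any(len(a) != k for a in m.genomic_alleles.values()):
                raise AlleleLengthError(
                    f"substitution marker {m.id!r}: alleles must be non-empty "
                    "and of equal length across haplotypes and vector"
                )
        else:
            raise LocusValidationError(f"marker {m.id!r}: unknown kind {m.kind!r}")
        if m.role not in ROLES:
            raise LocusValidationError(f"marker {m.id!r}: unknown role {m.role!r}")
        missing = set(locus.haplotype_ids) - set(m.genomic_alleles)
        if missing:
            raise LocusValidationError(
                f"marker {m.id!r}: no genomic allele for haplotype(s) {sorted(missing)}"
            )

    mutation = [m for m in locus.markers if m.role == "mutation"]
    if len(mutation) != 1:
        raise MissingMutationError(
            f"locus {locus.name!r}: exactly one marker must have role='mutation' "
            f"(found {len(mutation)})"
        )
    if mutation[0].id != locus.mutation_marker_id:
        raise MissingMutationError(
            f"mutation_marker_id {locus.mutation_marker_id!r} does not match the "
            f"marker with role='mutation' ({mutation[0].id!r})"
        )
    mut = mutation[0]
    if not any(mut.informative_for(h) for h in locus.haplotype_ids):
        raise LocusValidationError(
            f"mutation marker {mut.id!r}: no haplotype carries a mutant allele"
        )

    reporters = [m for m in locus.markers if m.role == "reporter"]
    if len(reporters) > 1:
        raise LocusValidationError("at most one marker may have role='reporter'")
    if reporters and reporters[0].coord <= mut.coord:
        raise LocusValidationError(
            f"reporter marker {reporters[0].id!r} must lie downstream of the "
            f"mutation marker {mut.id!r}"
        )

    l2 = locus.marker(locus.l2_marker_id)
    if l2.kind != INSERTION:
        raise LocusValidationError(f"L2 anchor marker {l2.id!r} must be an insertion")
    if len(locus.scaffold) != L:
        raise LocusValidationError(
            f"scaffold length {len(locus.scaffold)} != region_length {L}"
        )
    if not (-len(locus.left_flank) <= locus.anchor_5prime < 0):
        raise LocusValidationError("anchor_5prime must lie in the left flank (< 0)")
    if not (L < locus.anchor_3prime <= L + len(locus.right_flank)):
        raise LocusValidationError("anchor_3prime must lie in the right flank (> L)")
    return locus


def load_locus(config_text: str, name: str | None = None) -> LocusMap:
    """Parse a structured-text (YAML) locus configuration and validate it.

    Schema (all coordinates in genomic bases of the homology region)::

        name: s134c
        region_length: 3509
        haplotypes: [mut]
        flank: 150                 # chromosomal padding on each side
        anchor_5prime: -60         # chromosome-specific 5' primer site
        anchor_3prime: 3560        # chromosome-specific 3' primer site
        mutation_marker: s134c
        l2_marker: L2
        reporter_marker: venus     # optional
        sequence_seed: 20407       # scaffold generator seed
        gc_content: 0.45
        markers:                   # strictly ordered by coordinate
          - {id: i2_snp, kind: substitution, position: 95, role: snp,
             vector: T, genomic: {mut: C}}
          - {id: L1, kind: insertion, position: 320, role: linker,
             vector: GGTACCTAGGCTTAAGTCGACGCATGCA}
          ...

    A haplotype scaffold may alternatively be supplied explicitly under
    ``scaffold:`` (uppercase ACGT) instead of being generated from
    ``sequence_seed``.
    """
    cfg = yaml.safe_load(config_text)
    if not isinstance(cfg, dict):
        raise LocusValidationError("locus config must be a mapping")
    for key in ("region_length", "haplotypes", "markers", "mutation_marker", "l2_marker"):
        if key not in cfg:
            raise LocusValidationError(f"locus config missing required field {key!r}")

    L = int(cfg["region_length"])
    haplotypes = tuple(str(h) for h in cfg["haplotypes"])
    flank = int(cfg.get("flank", 150))
    seed = int(cfg.get("sequence_seed", 0))
    gc = float(cfg.get("gc_content", 0.5))

    markers = []
    for raw in cfg["markers"]:
        kind = raw["kind"]
        genomic = raw.get("genomic", {})
        if kind == INSERTION:
            # genomic alleles default to empty but are not silently dropped:
            # a config that claims a genomic insertion allele must fail validation
            alleles = {h: str(genomic.get(h, "")).upper() for h in haplotypes}
        else:
            alleles = {str(h): str(a).upper() for h, a in genomic.items()}
        markers.append(
            Marker(
                id=str(raw["id"]),
                kind=kind,
                position=int(raw["position"]),
                vector_allele=str(raw["vector"]).upper(),
                genomic_alleles=alleles,
                role=raw.get("role", "snp"),
            )
        )

    scaffold = cfg.get("scaffold")
    if scaffold is None:
        scaffold = random_sequence(L, seed, gc)
        # imprint each substitution marker's reference state: use the first
        # haplotype's allele so the scaffold is a real haplotype backbone
        chars = list(scaffold)
        for m in markers:
            if m.kind == SUBSTITUTION:
                ref = m.genomic_alleles.get(haplotypes[0], m.vector_allele)
                chars[m.position : m.position + m.length] = list(ref)
        scaffold = "".join(chars)
    scaffold = str(scaffold).upper()

    locus = LocusMap(
        name=str(cfg.get("name", name or "locus")),
        region_length=L,
        haplotype_ids=haplotypes,
        markers=tuple(markers),
        mutation_marker_id=str(cfg["mutation_marker"]),
        l2_marker_id=str(cfg["l2_marker"]),
        reporter_marker_id=(str(cfg["reporter_marker"]) if cfg.get("reporter_marker") else None),
        anchor_5prime=int(cfg.get("anchor_5prime", -min(60, flank))),
        anchor_3prime=int(cfg.get("anchor_3prime", L + min(60, flank))),
        scaffold=scaffold,
        left_flank=random_sequence(flank, seed + 1, gc),
        right_flank=random_sequence(flank, seed + 2, gc),
        source_text=config_text,
    )
    return _validate(locus)


def load_locus_file(path) -> LocusMap:
    with open(path) as fh:
        return load_locus(fh.read())


def builtin_locus_names() -> list[str]:
    root = importlib.resources.files("hrtract") / "configs"
    return sorted(p.name[:-5] for p in root.iterdir() if p.name.endswith(".yaml"))


def builtin_locus(name: str) -> LocusMap:
    """Load one of the shipped locus fixtures (``s134c``, ``r106w``, ``r282x``)."""
    res = importlib.resources.files("hrtract") / "configs" / f"{name.lower()}.yaml"
    try:
        text = res.read_text()
    except FileNotFoundError:
        raise KeyError(
            f"no built-in locus {name!r}; available: {builtin_locus_names()}"
        ) from None
    return load_locus(text, name=name)


# ---------------------------------------------------------------------------
# Sequence construction
# ---------------------------------------------------------------------------

def _apply_alleles(locus: LocusMap, allele_of) -> str:
    """Scaffold with ``allele_of(marker)`` applied at every marker.

    Substitutions are replaced in place; insertion alleles (when non-empty)
    are inserted before their position.  Applied right-to-left so earlier
    coordinates are unaffected by downstream insertions.
    """
    seq = locus.scaffold
    for m in reversed(locus.markers):
        a = allele_of(m)
        if m.kind == SUBSTITUTION:
            if len(a) != m.length:
                raise AlleleLengthError(
                    f"marker {m.id!r}: allele {a!r} does not match footprint "
                    f"length {m.length}"
                )
            seq = seq[: m.position] + a + seq[m.position + m.length :]
        else:
            seq = seq[: m.position] + a + seq[m.position :]
    return seq


def build_sequences(locus: LocusMap) -> tuple[dict[str, str], str]:
    """Concrete per-haplotype genomic sequences and the vector homology moiety.

    Deterministic: the haplotype sequence is the scaffold with that
    haplotype's substitution alleles; the vector sequence additionally
    carries every vector allele, so its length is ``region_length`` plus the
    summed insertion lengths.
    """
    genomes = {
        h: _apply_alleles(locus, lambda m, h=h: m.genomic_alleles[h])
        for h in locus.haplotype_ids
    }
    vector = _apply_alleles(locus, lambda m: m.vector_allele)
    return genomes, vector


def build_vector(locus: LocusMap) -> VectorModel:
    _, vec = build_sequences(locus)
    return VectorModel(homology_sequence=vec)


def extract_allele(seq: str, locus: LocusMap, marker_id: str, *, vector: bool) -> str:
    """Read a marker's allele back out of a built sequence (round-trip check).

    For the vector sequence (``vector=True``) positions are shifted by the
    cumulative length of upstream insertions.
    """
    m = locus.marker(marker_id)
    offset = 0
    if vector:
        for other in locus.markers:
            if other.kind == INSERTION and other.coord < m.coord:
                offset += len(other.vector_allele)
    pos = m.position + offset
    if m.kind == SUBSTITUTION:
        return seq[pos : pos + m.length]
    length = len(m.vector_allele) if vector else 0
    return seq[pos : pos + length]
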