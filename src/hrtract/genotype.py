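"""Marker calling on TI-amplicon reads.

Each marker is located in a read by exact (or one-mismatch) matching of its
fixed-length flanking genomic context, and the intervening bases are
classified against the configured alleles:

``vector``
    the observed allele equals the vector allele and no genomic allele;
``genomic``
    it equals one or more haplotypes' genomic alleles but not the vector's;
``shared``
    it equals both the vector allele and at least one genomic allele, so it
    cannot be attributed to either template -- such calls constrain nothing;
``missing``
    the site could not be located, or the observed bases match no
    configured allele (never guessed).

Sanger clone sequences are near-perfect, so light context matching suffices
and keeps calls exactly testable; no pairwise alignment is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

from .locus import INSERTION, SUBSTITUTION, LocusMap, Marker

__all__ = [
    "Call",
    "MarkerPattern",
    "call_markers",
    "batch_genotype",
    "classify_allele",
    "pattern_from_truth",
    "patterns_to_table",
    "patterns_from_table",
]

log = logging.getLogger(__name__)

VECTOR = "vector"
GENOMIC = "genomic"
SHARED = "shared"
MISSING = "missing"


@dataclass(frozen=True)
class Call:
    """One marker's classified state in one read."""

    kind: str  # vector | genomic | shared | missing
    haplotypes: frozenset[str] = frozenset()  # genomic/shared: matching haplotypes
    allele: str = ""  # raw observed allele ('' for absent insertions)

    def __str__(self) -> str:
        if self.kind in (GENOMIC, SHARED) and self.haplotypes:
            return f"{self.kind}:{'+'.join(sorted(self.haplotypes))}"
        return self.kind


@dataclass
class MarkerPattern:
    """Observed allele calls at every marker covered by one amplicon."""

    clone_id: str
    assay: str
    calls: dict[str, Call]
    diagnostics: list[str] = field(default_factory=list)

    def call(self, marker_id: str) -> Call:
        return self.calls[marker_id]

    @property
    def missing_fraction(self) -> float:
        if not self.calls:
            return 0.0
        return sum(c.kind == MISSING for c in self.calls.values()) / len(self.calls)


def classify_allele(marker: Marker, allele: str) -> Call:
    """Classify an observed allele string against the marker's alleles."""
    matches_vector = allele == marker.vector_allele
    haps = frozenset(h for h, a in marker.genomic_alleles.items() if allele == a)
    if matches_vector and haps:
        return Call(SHARED, haps, allele)
    if matches_vector:
        return Call(VECTOR, frozenset(), allele)
    if haps:
        return Call(GENOMIC, haps, allele)
    return Call(MISSING, frozenset(), allele)


def pattern_from_truth(locus: LocusMap, alleles: dict[str, str], assay: str,
                       clone_id: str = "truth") -> MarkerPattern:
    """The error-free pattern a read with these true alleles would yield."""
    calls = {m.id: classify_allele(m, alleles[m.id]) for m in locus.assay_markers(assay)}
    return MarkerPattern(clone_id=clone_id, assay=assay, calls=calls)


def pattern_from_calls(locus: LocusMap, assay: str, calls: dict[str, str],
                       clone_id: str = "encoded") -> MarkerPattern:
    """Encode a described outcome as a MarkerPattern.

    ``calls`` maps marker id to an observed allele string, or for insertion
    markers the words ``present``/``absent`` (equivalently ``+``/``-``).
    Markers covered by the assay but not mentioned are recorded as missing.
    """
    out: dict[str, Call] = {}
    for m in locus.assay_markers(assay):
        if m.id not in calls:
            out[m.id] = Call(MISSING)
            continue
        raw = str(calls[m.id])
        if m.kind == INSERTION:
            if raw.lower() in ("present", "+", "inserted"):
                allele = m.vector_allele
            elif raw.lower() in ("absent", "-"):
                allele = ""
            else:
                allele = raw.upper()
        else:
            allele = raw.upper()
        out[m.id] = classify_allele(m, allele)
    unknown = set(calls) - set(out)
    if unknown:
        raise KeyError(
            f"calls given for markers outside the {assay} span: {sorted(unknown)}"
        )
    return MarkerPattern(clone_id=clone_id, assay=assay, calls=out)


# ---------------------------------------------------------------------------
# Read-level calling
# ---------------------------------------------------------------------------

def _find_approx(read: str, read_bytes: np.ndarray, pat: str, max_mismatch: int) -> int:
    """Leftmost occurrence of ``pat`` with at most ``max_mismatch`` mismatches."""
    i = read.find(pat)
    if i >= 0 or max_mismatch == 0:
        return i
    k = len(pat)
    if k == 0 or k > read_bytes.size:
        return -1
    windows = np.lib.stride_tricks.sliding_window_view(read_bytes, k)
    pat_b = np.frombuffer(pat.encode(), dtype=np.uint8)
    mism = (windows != pat_b).sum(axis=1)
    hits = np.flatnonzero(mism <= max_mismatch)
    return int(hits[0]) if hits.size else -1


def _matches(a: str, b: str, max_mismatch: int) -> bool:
    if len(a) != len(b):
        return False
    if a == b:
        return True
    return sum(x != y for x, y in zip(a, b)) <= max_mismatch


def _marker_contexts(locus: LocusMap, marker: Marker, context: int) -> tuple[str, str]:
    ext = locus.left_flank + locus.scaffold + locus.right_flank
    pad = len(locus.left_flank)
    up = ext[pad + marker.position - context : pad + marker.position]
    down_start = pad + marker.position + marker.length
    down = ext[down_start : down_start + context]
    return up, down


def _candidate_alleles(marker: Marker) -> list[str]:
    seen: list[str] = []
    for a in [marker.vector_allele, *marker.genomic_alleles.values()]:
        if a not in seen:
            seen.append(a)
    # longest first so a present insertion is preferred over the vacuous
    # empty-allele match that its own prefix would otherwise produce
    return sorted(seen, key=len, reverse=True)


def _call_one(read: str, read_bytes: np.ndarray, locus: LocusMap, marker: Marker,
              context: int, max_mismatch: int, diagnostics: list[str]) -> Call:
    up, down = _marker_contexts(locus, marker, context)
    i = _find_approx(read, read_bytes, up, max_mismatch)
    if i < 0:
        # amplicon edges: an insertion can begin a read (3' assay starts at
        # L2) so its upstream context is absent -- anchor on the insert plus
        # its downstream context instead
        if marker.kind == INSERTION:
            j = _find_approx(read, read_bytes, down, max_mismatch)
            ins = marker.vector_allele
            if j >= len(ins) and _matches(read[j - len(ins) : j], ins, 1):
                return classify_allele(marker, ins)
        diagnostics.append(f"{marker.id}: flanking context not found")
        return Call(MISSING)

    start = i + len(up)
    matched: list[str] = []
    observed = ""
    for allele in _candidate_alleles(marker):
        seg = read[start : start + len(allele)]
        if not observed and len(allele) == marker.length and seg:
            observed = seg  # raw bases at the located site, kept for diagnostics
        allele_mm = 1 if len(allele) >= 8 else 0
        if not _matches(seg, allele, allele_mm):
            continue
        tail = read[start + len(allele) : start + len(allele) + len(down)]
        if len(tail) == len(down):
            if _matches(tail, down, max_mismatch):
                matched.append(allele)
        elif down.startswith(tail) and len(allele) >= 8:
            # read truncates inside the downstream context (5' assay ends at
            # the end of L2); accept only for long, unambiguous insert alleles
            matched.append(allele)
        if matched:
            break
    if matched:
        return classify_allele(marker, matched[0])

    j_down = read.find(down)
    if 0 <= j_down < i:
        diagnostics.append(f"{marker.id}: flanks found in conflicting order")
        return Call(MISSING)
    if observed:
        # site located but allele matches nothing configured: never guess
        diagnostics.append(f"{marker.id}: unrecognized allele {observed!r}")
        return Call(MISSING, allele=observed)
    diagnostics.append(f"{marker.id}: downstream context not found")
    return Call(MISSING)


def call_markers(read: str, locus: LocusMap, assay: str, clone_id: str = "read",
                 *, context: int = 15, max_mismatch: int = 1) -> MarkerPattern:
    """Call every marker covered by the given assay's amplicon in one read."""
    markers = locus.assay_markers(assay)
    diagnostics: list[str] = []
    read = str(read).upper()
    if not read:
        log.warning("%s: empty read; all markers missing", clone_id)
        return MarkerPattern(clone_id, assay,
                             {m.id: Call(MISSING) for m in markers},
                             ["empty read"])
    read_bytes = np.frombuffer(read.encode(), dtype=np.uint8)
    calls = {
        m.id: _call_one(read, read_bytes, locus, m, context, max_mismatch, diagnostics)
        for m in markers
    }
    return MarkerPattern(clone_id, assay, calls, diagnostics)


def batch_genotype(fasta, locus: LocusMap, assay: str,
                   *, context: int = 15, max_mismatch: int = 1) -> list[MarkerPattern]:
    """Genotype every record of a (multi-)FASTA; order-stable, one pattern per read.

    Records whose sequence contains characters outside IUPAC nucleotides are
    reported and yield all-missing patterns rather than aborting the batch.
    """
    try:
        records = list(SeqIO.parse(str(fasta), "fasta"))
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read FASTA {fasta!r}: {exc}") from exc
    patterns = []
    for rec in records:
        clone_id = rec.id.split("|")[0]
        seq = str(rec.seq).upper()
        if not seq or set(seq) - set("ACGTN"):
            log.warning("record %s: corrupted or empty sequence; skipped calls", rec.id)
            patterns.append(
                MarkerPattern(clone_id, assay,
                              {m.id: Call(MISSING) for m in locus.assay_markers(assay)},
                              [f"corrupted record {rec.id}"])
            )
            continue
        patterns.append(call_markers(seq, locus, assay, clone_id,
                                     context=context, max_mismatch=max_mismatch))
    n_calls = sum(len(p.calls) for p in patterns)
    n_missing = sum(sum(c.kind == MISSING for c in p.calls.values()) for p in patterns)
    log.info("genotyped %d reads (%s): %.2f%% missing calls",
             len(patterns), assay, 100.0 * n_missing / n_calls if n_calls else 0.0)
    return patterns


# ---------------------------------------------------------------------------
# Tabular round-trip
# ---------------------------------------------------------------------------

def patterns_to_table(patterns: list[MarkerPattern]):
    """Long-form pattern table (clone_id, assay, marker, call, haplotypes, allele)."""
    import pandas as pd

    rows = [
        {"clone_id": p.clone_id, "assay": p.assay, "marker": mid,
         "call": c.kind, "haplotypes": "+".join(sorted(c.haplotypes)),
         "allele": c.allele}
        for p in patterns
        for mid, c in p.calls.items()
    ]
    return pd.DataFrame(rows, columns=["clone_id", "assay", "marker",
                                       "call", "haplotypes", "allele"])


def patterns_from_table(table) -> list[MarkerPattern]:
    patterns = []
    for (clone_id, assay), grp in table.groupby(["clone_id", "assay"], sort=False):
        calls = {}
        for row in grp.itertuples():
            haps = frozenset(str(row.haplotypes).split("+")) if isinstance(row.haplotypes, str) and row.haplotypes else frozenset()
            allele = row.allele if isinstance(row.allele, str) else ""
            calls[row.marker] = Call(row.call, haps, allele)
        patterns.append(MarkerPattern(str(clone_id), str(assay), calls))
    return patterns
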