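"""Inverse model: from observed marker patterns to feasible crossover intervals.

Given an L2-anchored amplicon's marker calls, every candidate template
haplotype ``h`` admits a set of tract junction pairs ``(x5, x3)`` whose
forward image reproduces each non-missing call: markers called ``vector``
must lie inside the tract, markers called ``genomic`` for ``h`` must lie
outside, ``shared`` and ``missing`` calls constrain nothing.  Because
amplification itself requires L2 inside the tract (``x5 < c_L2 < x3``),
markers upstream of L2 only bound ``x5`` and markers downstream only bound
``x3``, so each template's feasible set is a product of two open intervals.
The reported intervals are minimal: every feasible sub-segment adjacent to
a bound is realizable (certified by the enumeration oracle).

Intervals are expressed in marker-order space -- each bound is a named
marker or region boundary -- with base-pair coordinates attached from the
configured marker positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotype import (GENOMIC, MISSING, SHARED, VECTOR, Call, MarkerPattern,
                       pattern_from_truth)
from .locus import INSERTION, LocusMap, Marker
from .simulate import CrossoverEvent, UniformCrossoverModel, get_crossover_model

__all__ = [
    "Interval",
    "InferenceResult",
    "infer",
    "classify",
    "signature_of",
    "ClassCertificate",
    "enumerate_possible_classes",
    "grid_signature_probs",
    "grid_correction_probability",
    "results_to_table",
]

CORRECTED = "corrected"
NOT_CORRECTED = "not_corrected"
INDETERMINATE = "indeterminate"
INSERTED = "inserted"
ABSENT = "absent"

REGION_START = "region_start"
REGION_END = "region_end"


@dataclass(frozen=True)
class Interval:
    """Open interval with named bounds in marker-order space."""

    lo: float
    hi: float
    lo_name: str
    hi_name: str

    def contains(self, x: float) -> bool:
        return self.lo < x < self.hi

    @property
    def empty(self) -> bool:
        return not self.lo < self.hi

    def __str__(self) -> str:
        return f"({self.lo_name}, {self.hi_name})"


@dataclass
class InferenceResult:
    """Feasible crossover intervals and statuses for one amplicon pattern."""

    clone_id: str
    assay: str
    consistent: bool
    template_candidates: tuple[str, ...]
    x5_interval: Interval | None
    x3_interval: Interval | None
    per_template: dict[str, tuple[Interval, Interval]]
    correction_status: str
    reporter_status: str
    class_signature: str
    pattern: MarkerPattern = field(repr=False, default=None)
    edited: bool = True


def _per_template_bounds(pattern: MarkerPattern, locus: LocusMap,
                         template: str) -> tuple[Interval, Interval] | None:
    """Feasible (x5, x3) interval pair under one template, or None."""
    l2 = locus.l2_marker
    lo5, lo5_name = 0.0, REGION_START
    hi5, hi5_name = l2.coord, l2.id
    lo3, lo3_name = l2.coord, l2.id
    hi3, hi3_name = float(locus.region_length), REGION_END

    for m in locus.assay_markers(pattern.assay):
        if m.id == l2.id or m.id not in pattern.calls:
            continue
        call = pattern.calls[m.id]
        if call.kind == MISSING:
            continue
        if call.kind == SHARED and template in call.haplotypes:
            continue  # vector allele equals this template's allele: no constraint
        if call.kind in (VECTOR, SHARED):
            inside = True
        elif call.kind == GENOMIC:
            if template not in call.haplotypes:
                return None  # observed allele unreachable from this template
            inside = False
        else:  # pragma: no cover - exhaustive kinds
            continue
        upstream = m.coord < l2.coord
        if inside:
            if upstream and m.coord < hi5:
                hi5, hi5_name = m.coord, m.id
            elif not upstream and m.coord > lo3:
                lo3, lo3_name = m.coord, m.id
        else:
            if upstream and m.coord > lo5:
                lo5, lo5_name = m.coord, m.id
            elif not upstream and m.coord < hi3:
                hi3, hi3_name = m.coord, m.id

    i5 = Interval(lo5, hi5, lo5_name, hi5_name)
    i3 = Interval(lo3, hi3, lo3_name, hi3_name)
    if i5.empty or i3.empty:
        return None
    return i5, i3


def _envelope(intervals: list[Interval]) -> Interval:
    lo = min(intervals, key=lambda i: i.lo)
    hi = max(intervals, key=lambda i: i.hi)
    return Interval(lo.lo, hi.hi, lo.lo_name, hi.hi_name)


def _correction_status(pattern: MarkerPattern, locus: LocusMap,
                       candidates: tuple[str, ...]) -> str:
    mut = locus.mutation_marker
    if mut.id not in pattern.calls or not candidates:
        return INDETERMINATE
    call = pattern.calls[mut.id]
    if call.kind == MISSING:
        return INDETERMINATE
    if call.kind in (VECTOR, SHARED):
        # observed wild-type base; a correction only if some candidate
        # template actually carried the mutant allele there
        if any(mut.informative_for(h) for h in candidates):
            return CORRECTED
        return INDETERMINATE
    return NOT_CORRECTED


def _reporter_status(pattern: MarkerPattern, locus: LocusMap) -> str:
    rep = locus.reporter_marker
    if rep is None or rep.id not in pattern.calls:
        return INDETERMINATE
    kind = pattern.calls[rep.id].kind
    if kind == VECTOR:
        return INSERTED
    if kind == GENOMIC:
        return ABSENT
    return INDETERMINATE


def signature_of(pattern: MarkerPattern, locus: LocusMap) -> str:
    """Canonical outcome-class signature: ordered calls at informative markers.

    Insertions are rendered ``+``/``-`` (present/absent), substitutions by
    the observed allele, missing calls as ``?``.  Two patterns share a
    signature exactly when their informative calls -- hence their feasible
    (template, x5, x3) sets -- coincide.
    """
    parts = []
    for m in locus.assay_markers(pattern.assay):
        if not m.informative_for_any(locus.haplotype_ids):
            continue
        call = pattern.calls.get(m.id, Call(MISSING))
        if call.kind == MISSING and not call.allele:
            sym = "?"
        elif m.kind == INSERTION:
            sym = "+" if call.kind == VECTOR else "-"
        else:
            sym = call.allele or "?"
        parts.append(f"{m.id}={sym}")
    return "|".join(parts)


def infer(pattern: MarkerPattern, locus: LocusMap) -> InferenceResult:
    """Localize the 5'/3' crossovers compatible with one amplicon pattern."""
    l2 = locus.l2_marker
    sig = signature_of(pattern, locus)
    l2_call = pattern.calls.get(l2.id, Call(MISSING))
    if l2_call.kind == GENOMIC:
        # an L2-anchored amplicon cannot lack L2: flag, don't crash
        return InferenceResult(
            pattern.clone_id, pattern.assay, consistent=False,
            template_candidates=(), x5_interval=None, x3_interval=None,
            per_template={}, correction_status=INDETERMINATE,
            reporter_status=INDETERMINATE, class_signature=sig, pattern=pattern)

    per_template: dict[str, tuple[Interval, Interval]] = {}
    for h in locus.haplotype_ids:
        bounds = _per_template_bounds(pattern, locus, h)
        if bounds is not None:
            per_template[h] = bounds
    if not per_template:
        return InferenceResult(
            pattern.clone_id, pattern.assay, consistent=False,
            template_candidates=(), x5_interval=None, x3_interval=None,
            per_template={}, correction_status=INDETERMINATE,
            reporter_status=INDETERMINATE, class_signature=sig, pattern=pattern)

    candidates = tuple(h for h in locus.haplotype_ids if h in per_template)
    x5 = _envelope([b[0] for b in per_template.values()])
    x3 = _envelope([b[1] for b in per_template.values()])
    return InferenceResult(
        clone_id=pattern.clone_id,
        assay=pattern.assay,
        consistent=True,
        template_candidates=candidates,
        x5_interval=x5,
        x3_interval=x3,
        per_template=per_template,
        correction_status=_correction_status(pattern, locus, candidates),
        reporter_status=_reporter_status(pattern, locus),
        class_signature=sig,
        pattern=pattern,
    )


def classify(result: InferenceResult, locus: LocusMap) -> str:
    """Canonical class signature of a (consistent) inference result."""
    return signature_of(result.pattern, locus)


# ---------------------------------------------------------------------------
# Exhaustive class enumeration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassCertificate:
    """A reachable outcome class with a witness event proving feasibility."""

    signature: str
    witness: CrossoverEvent


def _segments(bounds: list[float]) -> list[tuple[float, float]]:
    b = sorted(set(bounds))
    return [(b[i], b[i + 1]) for i in range(len(b) - 1)]


def assay_segments(locus: LocusMap, assay: str) -> tuple[list[tuple[float, float]],
                                                         list[tuple[float, float]]]:
    """Feasible-region segmentation induced by assay-covered marker coords.

    Returns (5' segments upstream of L2, 3' segments downstream of L2);
    every (template, segment-pair) choice yields one constant signature.
    """
    c_l2 = locus.l2_marker.coord
    span = locus.assay_markers(assay)
    up = [0.0, c_l2] + [m.coord for m in span if m.coord < c_l2]
    down = [c_l2, float(locus.region_length)] + [m.coord for m in span if m.coord > c_l2]
    return _segments(up), _segments(down)


def enumerate_possible_classes(locus: LocusMap, assay: str) -> list[ClassCertificate]:
    """All signatures reachable by some (template, x5, x3), with witnesses."""
    from .simulate import true_alleles

    segs5, segs3 = assay_segments(locus, assay)
    seen: dict[str, ClassCertificate] = {}
    for h in locus.haplotype_ids:
        for a5, b5 in segs5:
            for a3, b3 in segs3:
                ev = CrossoverEvent("witness", h, (a5 + b5) / 2, (a3 + b3) / 2)
                pattern = pattern_from_truth(locus, true_alleles(locus, ev), assay)
                sig = signature_of(pattern, locus)
                if sig not in seen:
                    seen[sig] = ClassCertificate(sig, ev)
    return list(seen.values())


# ---------------------------------------------------------------------------
# Brute-force grid oracle
# ---------------------------------------------------------------------------

def _grid_points(L: int) -> np.ndarray:
    """Two off-lattice points per base (k+0.25, k+0.75).

    Marker coordinates are integers or half-integers, so every feasible
    segment contains exactly ``2 * length`` grid points and grid counts are
    exact for the uniform model.
    """
    k = np.arange(L, dtype=float)
    return np.sort(np.concatenate([k + 0.25, k + 0.75]))


def grid_signature_probs(locus: LocusMap, assay: str, *, model="uniform",
                         template_probs: dict[str, float] | None = None,
                         exclude_reporter: bool = False) -> dict[str, float]:
    """Class probabilities by exhaustive enumeration of (x5, x3) grid pairs.

    Conditions on detection (L2 inside the tract) and optionally on
    reporter exclusion, mirroring the 3' assay.  Independent of the
    closed-form interval-geometry computation: every grid pair is pushed
    through the forward tract rule marker by marker.
    """
    from .simulate import true_alleles

    model = get_crossover_model(model)
    L = locus.region_length
    c_l2 = locus.l2_marker.coord
    if template_probs is None:
        template_probs = {h: 1.0 / len(locus.haplotype_ids) for h in locus.haplotype_ids}

    pts = _grid_points(L)
    x5 = pts[pts < c_l2]
    x3 = pts[pts > c_l2]
    if exclude_reporter:
        rep = locus.reporter_marker
        if rep is not None:
            x3 = x3[x3 < rep.coord]
    w5 = model.pdf(x5, L)
    w3 = model.pdf(x3, L)
    span = locus.assay_markers(assay)
    markers = [m for m in span if m.id != locus.l2_marker_id]

    masses: dict[str, float] = {}
    for h in locus.haplotype_ids:
        # encode each pair's in-tract profile, then translate codes to signatures
        code5 = np.zeros(x5.size, dtype=np.int64)
        code3 = np.zeros(x3.size, dtype=np.int64)
        for k, m in enumerate(markers):
            if m.coord < c_l2:
                code5 |= (x5 < m.coord).astype(np.int64) << k
            else:
                code3 |= (x3 > m.coord).astype(np.int64) << k
        pair_code = code5[:, None] | code3[None, :]
        pair_w = w5[:, None] * w3[None, :]
        codes, inverse = np.unique(pair_code.ravel(), return_inverse=True)
        sums = np.bincount(inverse, weights=pair_w.ravel())
        for code, s in zip(codes, sums):
            alleles = {}
            for k, m in enumerate(markers):
                inside = bool(code >> k & 1)
                alleles[m.id] = m.vector_allele if inside else m.genomic_alleles[h]
            alleles[locus.l2_marker_id] = locus.l2_marker.vector_allele
            for m in locus.markers:
                alleles.setdefault(m.id, m.genomic_alleles[h])
            sig = signature_of(pattern_from_truth(locus, alleles, assay), locus)
            masses[sig] = masses.get(sig, 0.0) + template_probs[h] * float(s)
    total = sum(masses.values())
    return {sig: v / total for sig, v in masses.items()}


def grid_correction_probability(L: int, m: float, *, conditional_on: float | None = None) -> float:
    """P(x5 < m < x3) by grid-pair counting, optionally given detection.

    ``conditional_on`` is the L2 coordinate; when given, the probability is
    conditioned on ``x5 < conditional_on < x3``.
    """
    pts = _grid_points(L)
    if conditional_on is None:
        n_left = int((pts < m).sum())
        n_right = int((pts > m).sum())
        total = pts.size * (pts.size - 1) // 2
        return n_left * n_right / total
    c = conditional_on
    x5 = pts[pts < c]
    x3 = pts[pts > c]
    straddle = (x5[:, None] < m) & (m < x3[None, :])
    return float(straddle.sum()) / (x5.size * x3.size)


def results_to_table(results: list[InferenceResult]):
    """Per-clone inference table (tab-separated friendly)."""
    import pandas as pd

    rows = []
    for r in results:
        rows.append({
            "clone_id": r.clone_id,
            "assay": r.assay,
            "consistent": r.consistent,
            "templates": "+".join(r.template_candidates),
            "x5_lo": r.x5_interval.lo if r.x5_interval else np.nan,
            "x5_hi": r.x5_interval.hi if r.x5_interval else np.nan,
            "x5_bounds": str(r.x5_interval) if r.x5_interval else "",
            "x3_lo": r.x3_interval.lo if r.x3_interval else np.nan,
            "x3_hi": r.x3_interval.hi if r.x3_interval else np.nan,
            "x3_bounds": str(r.x3_interval) if r.x3_interval else "",
            "correction_status": r.correction_status,
            "reporter_status": r.reporter_status,
            "class_signature": r.class_signature,
        })
    return pd.DataFrame(rows)
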