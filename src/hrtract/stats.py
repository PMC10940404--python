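"""Outcome-class tables, model-predicted class probabilities, ascertainment.

Every reported fraction names its conditioning explicitly.  The TI assay
only sees alleles whose tract captured L2 ("detected"), and the 3' assay
can additionally exclude reporter-containing amplicons, so class
frequencies here are always fractions of detected recombination events --
the same conditioning the printed outcome tables use.

Under a crossover model with per-junction CDF ``F``, the crossover pair is
the order statistic of two iid draws, so for the mutation at coordinate
``m`` the unconditional correction probability (tract straddles ``m``) is

    p_correct(m) = 2 F(m) (1 - F(m))

which for the uniform model is ``2 (m/L)(1 - m/L)``: zero at the homology
ends and maximal (1/2) at the center.  Likewise the reporter junction at
``r > c_L2`` is captured with conditional probability
``P(x3 > r | detected) = (1 - F(r)) / (1 - F(c_L2)) < 1``, which is why
reporter-based editing estimates under-represent true editing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _sps
from statsmodels.stats.proportion import proportion_confint

from .genotype import pattern_from_truth
from .inference import (CORRECTED, InferenceResult, assay_segments,
                        signature_of)
from .locus import LocusMap
from .simulate import CrossoverEvent, get_crossover_model, true_alleles

__all__ = [
    "OutcomeClassTable",
    "ModelPrediction",
    "GoodnessOfFit",
    "AscertainmentReport",
    "aggregate",
    "predict_class_probs",
    "compare_observed_to_model",
    "ascertainment_report",
    "model_selection_replicates",
    "OutcomeFixture",
    "load_outcome_fixture",
    "plot_correction_probability",
]

_FRACTION_TOL = 1e-6


@dataclass
class OutcomeClassTable:
    """Per-class counts/fractions with Wilson CIs and correction statuses."""

    table: pd.DataFrame = field(repr=False)
    corrected_fraction: float
    n: int | None  # total detected clones (None when fractions were supplied)
    conditioning: str = "detected (L2 in tract)"

    def fraction_of(self, signature: str) -> float:
        row = self.table.loc[self.table.signature == signature]
        if row.empty:
            raise KeyError(signature)
        return float(row.fraction.iloc[0])


def aggregate(results: list[InferenceResult],
              fractions: dict[str, float] | None = None,
              conditioning: str = "detected (L2 in tract)") -> OutcomeClassTable:
    """Collapse per-clone inferences into an outcome-class table.

    With ``fractions`` (signature -> fraction, as printed outcome tables
    supply) the results provide each class's correction status and the
    fractions are taken as given -- no counts, hence no confidence
    intervals.  Otherwise classes are counted and Wilson intervals attached
    (Wilson rather than Wald: clone counts are small).
    """
    results = [r for r in results if r.consistent]
    if not results:
        raise ValueError("no consistent inference results to aggregate")

    status: dict[str, str] = {}
    for r in results:
        prev = status.setdefault(r.class_signature, r.correction_status)
        if prev != r.correction_status:
            raise ValueError(
                f"class {r.class_signature!r} has conflicting correction statuses "
                f"({prev!r} vs {r.correction_status!r})"
            )

    if fractions is not None:
        total = sum(fractions.values())
        if abs(total - 1.0) > 1e-3:
            raise ValueError(f"supplied fractions sum to {total:g}, not 1")
        unknown = set(fractions) - set(status)
        if unknown:
            raise ValueError(f"fractions supplied for unseen classes: {sorted(unknown)}")
        rows = [{
            "signature": sig,
            "count": np.nan,
            "fraction": frac / total,
            "ci_low": np.nan,
            "ci_high": np.nan,
            "correction_status": status[sig],
        } for sig, frac in fractions.items()]
        n = None
    else:
        counts = pd.Series([r.class_signature for r in results]).value_counts()
        n = int(counts.sum())
        rows = []
        for sig, c in counts.items():
            lo, hi = proportion_confint(int(c), n, alpha=0.05, method="wilson")
            rows.append({
                "signature": sig,
                "count": int(c),
                "fraction": c / n,
                "ci_low": float(lo),
                "ci_high": float(hi),
                "correction_status": status[sig],
            })

    table = pd.DataFrame(rows).sort_values("fraction", ascending=False,
                                           kind="stable").reset_index(drop=True)
    assert abs(table.fraction.sum() - 1.0) < 1e-9
    corrected = float(table.loc[table.correction_status == CORRECTED, "fraction"].sum())
    return OutcomeClassTable(table=table, corrected_fraction=corrected,
                             n=n, conditioning=conditioning)


# ---------------------------------------------------------------------------
# Model predictions
# ---------------------------------------------------------------------------

@dataclass
class ModelPrediction:
    """Closed-form class probabilities under a crossover model.

    ``class_probs`` are conditional on detection (and optionally on
    reporter exclusion); ``p_detect`` is the probability an edited allele is
    detectable at all; ``reporter_fraction`` is P(reporter inserted |
    detected), the ascertainment factor by which reporter-based editing
    estimates undercount true editing.
    """

    locus_name: str
    assay: str
    model_name: str
    class_probs: dict[str, float]
    p_detect: float
    reporter_fraction: float | None
    conditioning: str
    _model: object = field(repr=False, default=None)
    _L: float = field(repr=False, default=0.0)
    _c_l2: float = field(repr=False, default=0.0)

    def correction_probability(self, m: float, *, conditional_on_detection: bool = False) -> float:
        """P(tract straddles coordinate m), i.e. P(x5 < m < x3)."""
        F = lambda x: float(self._model.cdf(x, self._L))
        if not conditional_on_detection:
            return 2.0 * F(m) * (1.0 - F(m))
        c = self._c_l2
        if m == c:
            return 1.0
        if m < c:
            return F(m) / F(c)
        return (1.0 - F(m)) / (1.0 - F(c))


def predict_class_probs(locus: LocusMap, assay: str, model="uniform",
                        template_probs: dict[str, float] | None = None,
                        exclude_reporter: bool = False) -> ModelPrediction:
    """Probability of each enumerable outcome class, conditional on detection.

    Closed form by interval geometry: the assay's marker coordinates cut
    the region into segments; each (template, 5'-segment, 3'-segment)
    triple maps to one signature with mass
    ``P(template) * 2 F(seg5) F(seg3)``.  Cross-checked against the
    brute-force grid enumeration oracle in the test suite.
    """
    mdl = get_crossover_model(model)
    mdl.validate(locus.region_length)
    L = float(locus.region_length)
    if template_probs is None:
        template_probs = {h: 1.0 / len(locus.haplotype_ids) for h in locus.haplotype_ids}
    rep = locus.reporter_marker

    segs5, segs3 = assay_segments(locus, assay)
    if rep is not None:
        # refine the 3' segmentation at the reporter junction so reporter
        # capture is constant within each segment (the 5' assay span does
        # not otherwise cut there)
        refined = []
        for a, b in segs3:
            if a < rep.coord < b:
                refined += [(a, rep.coord), (rep.coord, b)]
            else:
                refined.append((a, b))
        segs3 = refined
    masses: dict[str, float] = {}
    reporter_mass = 0.0
    total = 0.0
    kept = 0.0
    for h in locus.haplotype_ids:
        for s5 in segs5:
            for s3 in segs3:
                mass = template_probs[h] * mdl.pair_prob(s5, s3, L)
                if mass <= 0.0:
                    continue
                total += mass
                reporter_in = rep is not None and s3[0] >= rep.coord
                if reporter_in:
                    reporter_mass += mass
                if exclude_reporter and reporter_in:
                    continue
                kept += mass
                ev = CrossoverEvent("pred", h, sum(s5) / 2, sum(s3) / 2)
                sig = signature_of(pattern_from_truth(locus, true_alleles(locus, ev), assay), locus)
                masses[sig] = masses.get(sig, 0.0) + mass
    if kept <= 0.0:
        raise ValueError("zero detection probability under this model/conditioning")
    probs = {sig: v / kept for sig, v in masses.items()}
    conditioning = "detected (L2 in tract)"
    if exclude_reporter:
        conditioning += " + reporter-containing amplicons excluded"
    return ModelPrediction(
        locus_name=locus.name, assay=assay, model_name=mdl.name,
        class_probs=probs, p_detect=float(total),
        reporter_fraction=(reporter_mass / total if rep is not None else None),
        conditioning=conditioning,
        _model=mdl, _L=L, _c_l2=locus.l2_marker.coord,
    )


# ---------------------------------------------------------------------------
# Goodness of fit
# ---------------------------------------------------------------------------

@dataclass
class GoodnessOfFit:
    """Observed-vs-predicted class comparison.

    When the table carries counts, a multinomial log-likelihood and Pearson
    chi-square test are computed; with supplied fractions only divergence
    measures are reported and ``tested`` is False (no denominators, no
    test -- printed outcome tables give percentages without clone counts).
    """

    log_likelihood: float
    chi2: float | None
    df: int | None
    p_value: float | None
    kl_divergence: float
    total_variation: float
    tested: bool


def compare_observed_to_model(table: OutcomeClassTable,
                              prediction: ModelPrediction) -> GoodnessOfFit:
    probs = prediction.class_probs
    obs = table.table
    unmatched = sorted(set(obs.signature) - set(probs))
    if unmatched:
        raise ValueError(
            "observed classes absent from the model prediction: "
            + ", ".join(unmatched)
        )
    p = np.array([probs[s] for s in obs.signature], dtype=float)
    f = obs.fraction.to_numpy(dtype=float)

    # divergences over the union of classes (predicted-only classes have
    # observed mass zero and contribute only to total variation)
    extra = sum(v for s, v in probs.items() if s not in set(obs.signature))
    tv = 0.5 * (np.abs(f - p).sum() + extra)
    with np.errstate(divide="ignore"):
        kl = float(np.where(f > 0, f * np.log(np.where(f > 0, f / p, 1.0)), 0.0).sum())

    if table.n is None:
        ll = float(np.where(f > 0, f * np.log(p), 0.0).sum())
        return GoodnessOfFit(ll, None, None, None, kl, tv, tested=False)

    counts = obs["count"].to_numpy(dtype=float)
    ll = float(np.where(counts > 0, counts * np.log(p), 0.0).sum())
    n = table.n
    all_sigs = list(probs)
    e = np.array([probs[s] * n for s in all_sigs])
    o = np.array([float(obs.loc[obs.signature == s, "count"].sum()) for s in all_sigs])
    mask = e > 0
    chi2 = float(((o[mask] - e[mask]) ** 2 / e[mask]).sum())
    df = int(mask.sum()) - 1
    p_value = float(_sps.chi2.sf(chi2, df)) if df > 0 else np.nan
    return GoodnessOfFit(ll, chi2, df, p_value, kl, tv, tested=True)


# ---------------------------------------------------------------------------
# Reporter ascertainment
# ---------------------------------------------------------------------------

@dataclass
class AscertainmentReport:
    """How far reporter positivity undercounts true editing in a cohort.

    Computed from simulated genomes (truth), not amplicons, so amplicon
    dropout does not affect it.  ``ratio`` is P̂(reporter)/P̂(edited) with a
    Wilson CI; ``ratio_detected`` conditions on TI detectability instead.
    """

    n_clones: int
    n_edited: int
    n_detected: int
    n_reporter: int
    ratio: float
    ci_low: float
    ci_high: float
    ratio_detected: float
    defined: bool

    def __str__(self) -> str:
        if not self.defined:
            return "ascertainment undefined: no edited clones"
        return (f"reporter-positive {self.n_reporter}/{self.n_edited} edited "
                f"(ratio {self.ratio:.3f}, 95% CI {self.ci_low:.3f}-{self.ci_high:.3f}; "
                f"{self.ratio_detected:.3f} of detected)")


def ascertainment_report(truth: pd.DataFrame) -> AscertainmentReport:
    """Ratio of reporter-positive to truly-edited clones in a simulated cohort."""
    n = len(truth)
    edited = truth[truth.edited]
    n_edited = len(edited)
    if n_edited == 0:
        return AscertainmentReport(n, 0, 0, 0, float("nan"), float("nan"),
                                   float("nan"), float("nan"), defined=False)
    n_rep = int(edited.reporter_inserted.sum())
    n_det = int(edited.detected.sum())
    lo, hi = proportion_confint(n_rep, n_edited, alpha=0.05, method="wilson")
    n_rep_det = int((edited.reporter_inserted & edited.detected).sum())
    ratio_det = n_rep_det / n_det if n_det else float("nan")
    return AscertainmentReport(n, n_edited, n_det, n_rep,
                               n_rep / n_edited, float(lo), float(hi),
                               ratio_det, defined=True)


def model_selection_replicates(locus: LocusMap, *, assay: str = "five_prime",
                               n_cohorts: int = 100, cohort_size: int = 500,
                               seed: int = 0, true_model="uniform",
                               alt_model="end_biased") -> dict:
    """Parameter-recovery check: can class counts identify the crossover model?

    Simulates ``n_cohorts`` cohorts of edited clones under ``true_model``,
    tallies detected outcome-class counts (truth-level patterns: model
    identification concerns class frequencies, not read calling), and asks
    how often the multinomial log-likelihood prefers the true model over
    the alternative.
    """
    from .simulate import SimConfig, sample_event

    pred_true = predict_class_probs(locus, assay, model=true_model)
    pred_alt = predict_class_probs(locus, assay, model=alt_model)

    def loglik(counts: dict[str, int], probs: dict[str, float]) -> float:
        ll = 0.0
        for sig, c in counts.items():
            p = probs.get(sig, 0.0)
            ll += c * (np.log(p) if p > 0 else -np.inf)
        return ll

    cfg = SimConfig(n_clones=cohort_size, editing_efficiency=1.0,
                    crossover_model=true_model, seed=seed)
    c_l2 = locus.l2_marker.coord
    n_prefer = 0
    for rep in range(n_cohorts):
        rng = np.random.default_rng([seed, rep])
        counts: dict[str, int] = {}
        for i in range(cohort_size):
            ev = sample_event(locus, cfg, rng, clone_id=f"c{i}")
            if not ev.covers(c_l2):
                continue
            sig = signature_of(
                pattern_from_truth(locus, true_alleles(locus, ev), assay), locus)
            counts[sig] = counts.get(sig, 0) + 1
        if loglik(counts, pred_true.class_probs) > loglik(counts, pred_alt.class_probs):
            n_prefer += 1
    return {"n_cohorts": n_cohorts, "cohort_size": cohort_size,
            "n_prefer_true": n_prefer, "fraction_prefer_true": n_prefer / n_cohorts,
            "true_model": pred_true.model_name, "alt_model": pred_alt.model_name}


@dataclass
class OutcomeFixture:
    """A published outcome-class table: named patterns with their fractions."""

    locus_name: str
    assay: str
    names: list[str]
    patterns: list  # MarkerPattern per outcome
    fractions: list[float]

    def analyze(self, locus: LocusMap) -> tuple[dict[str, InferenceResult],
                                                OutcomeClassTable]:
        """Run crossover inference on each encoded outcome and aggregate
        at the supplied fractions."""
        from .inference import infer

        results = {name: infer(p, locus)
                   for name, p in zip(self.names, self.patterns)}
        frac = {r.class_signature: f
                for r, f in zip(results.values(), self.fractions)}
        table = aggregate(list(results.values()), fractions=frac)
        return results, table


def load_outcome_fixture(source, locus: LocusMap | None = None) -> OutcomeFixture:
    """Load a published outcome table (YAML path, text, or built-in name).

    Built-in names follow ``outcomes_<locus>_<assay>`` (e.g.
    ``outcomes_r106w_five_prime``); the matching built-in locus is used to
    encode the patterns unless ``locus`` is given.
    """
    import importlib.resources

    import yaml

    from .genotype import pattern_from_calls
    from .locus import builtin_locus

    if isinstance(source, str) and "\n" not in source and not source.endswith((".yaml", ".yml")):
        res = importlib.resources.files("hrtract") / "configs" / f"{source}.yaml"
        text = res.read_text()
    elif isinstance(source, str) and "\n" in source:
        text = source
    else:
        with open(source) as fh:
            text = fh.read()
    spec = yaml.safe_load(text)
    if locus is None:
        locus = builtin_locus(spec["locus"])
    assay = spec["assay"]
    names, patterns, fractions = [], [], []
    for out in spec["outcomes"]:
        names.append(str(out["name"]))
        fractions.append(float(out["fraction"]))
        patterns.append(pattern_from_calls(locus, assay, out["calls"],
                                           clone_id=str(out["name"])))
    return OutcomeFixture(locus.name, assay, names, patterns, fractions)


def plot_correction_probability(locus: LocusMap, model="uniform", path=None, ax=None):
    """Optional plot of p_correct(m) across the homology region."""
    import matplotlib
    if path is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pred = predict_class_probs(locus, "three_prime", model=model)
    m = np.linspace(0, locus.region_length, 400)
    y = [pred.correction_probability(x) for x in m]
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3.5))
    ax.plot(m, y, label=f"p_correct, {pred.model_name}")
    ax.axvline(locus.mutation_marker.coord, ls="--", color="grey",
               label=f"mutation ({locus.mutation_marker_id})")
    ax.set_xlabel("coordinate in homology region (bp)")
    ax.set_ylabel("P(tract straddles m)")
    ax.legend(frameon=False)
    if path is not None:
        ax.figure.savefig(path, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
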