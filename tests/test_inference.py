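"""Crossover inference: worked outcome examples, enumeration, minimality."""

import pytest

from hrtract import (CrossoverEvent, SimConfig, emit_amplicons,
                     enumerate_possible_classes, grid_signature_probs, infer,
                     call_markers, classify, load_locus, pattern_from_calls,
                     pattern_from_truth, signature_of, simulate_cohort,
                     true_alleles)
from hrtract.inference import CORRECTED, INDETERMINATE, NOT_CORRECTED


def _encode(locus, assay, calls):
    return infer(pattern_from_calls(locus, assay, calls), locus)


class TestWorkedExamples:
    """Each published outcome pattern maps to its stated crossover interval."""

    def test_s134c_5p_l1_absent_puts_x5_between_l1_and_l2(self, s134c):
        r = _encode(s134c, "five_prime",
                    {"i2_snp": "C", "L1": "absent", "L2": "present"})
        assert (r.x5_interval.lo_name, r.x5_interval.hi_name) == ("L1", "L2")

    def test_s134c_5p_both_linkers_puts_x5_between_snp_and_l1(self, s134c):
        r = _encode(s134c, "five_prime",
                    {"i2_snp": "C", "L1": "present", "L2": "present"})
        assert (r.x5_interval.lo_name, r.x5_interval.hi_name) == ("i2_snp", "L1")

    def test_s134c_3p_mutant_retained_puts_x3_upstream_of_mutation(self, s134c):
        r = _encode(s134c, "three_prime",
                    {"L2": "present", "s134c": "G", "venus": "absent"})
        assert (r.x3_interval.lo_name, r.x3_interval.hi_name) == ("L2", "s134c")
        assert r.correction_status == NOT_CORRECTED

    def test_r282x_5p_all_vector_puts_x5_before_intron2_snp(self, r282x):
        r = _encode(r282x, "five_prime",
                    {"i2_snp": "T", "L1": "present", "i3_snp": "C", "L2": "present"})
        assert (r.x5_interval.lo_name, r.x5_interval.hi_name) == ("region_start", "i2_snp")
        assert set(r.template_candidates) == {"WT", "mut"}

    def test_r282x_5p_only_l2_puts_x5_between_intron3_snp_and_l2(self, r282x):
        r = _encode(r282x, "five_prime",
                    {"i2_snp": "C", "L1": "absent", "i3_snp": "T", "L2": "present"})
        assert (r.x5_interval.lo_name, r.x5_interval.hi_name) == ("i3_snp", "L2")

    def test_r106w_outcome1_is_template_ambiguous_with_differing_intervals(self, r106w):
        r = _encode(r106w, "five_prime",
                    {"i2_snp": "C", "L1": "absent", "r106w": "CGG",
                     "i3_snp": "C", "L2": "present"})
        assert set(r.template_candidates) == {"WT", "mut"}
        i5_wt, _ = r.per_template["WT"]
        i5_mut, _ = r.per_template["mut"]
        # WT template: x5 between L1 and the Intron-3 SNP (C is vector there);
        # mutant template: x5 between L1 and the mutation (its correction)
        assert (i5_wt.lo_name, i5_wt.hi_name) == ("L1", "i3_snp")
        assert (i5_mut.lo_name, i5_mut.hi_name) == ("L1", "r106w")
        assert r.correction_status == CORRECTED

    def test_r106w_outcome2_mutant_allele_edited_but_uncorrected(self, r106w):
        r = _encode(r106w, "five_prime",
                    {"i2_snp": "C", "L1": "absent", "r106w": "TGG",
                     "i3_snp": "C", "L2": "present"})
        assert r.template_candidates == ("mut",)
        assert (r.x5_interval.lo_name, r.x5_interval.hi_name) == ("r106w", "L2")
        assert r.correction_status == NOT_CORRECTED

    def test_maximal_ignorance_pattern(self, s134c):
        r = _encode(s134c, "five_prime", {"L2": "present"})
        assert (r.x5_interval.lo_name, r.x5_interval.hi_name) == ("region_start", "L2")
        assert (r.x3_interval.lo_name, r.x3_interval.hi_name) == ("L2", "region_end")
        assert r.correction_status == INDETERMINATE
        assert r.reporter_status == INDETERMINATE

    def test_inconsistent_pattern_flagged_not_crashed(self, s134c):
        # vector Intron-2 SNP (tract reaches before it) but L1 absent: no
        # contiguous tract explains this
        r = _encode(s134c, "five_prime",
                    {"i2_snp": "T", "L1": "absent", "L2": "present"})
        assert not r.consistent
        assert r.template_candidates == ()

    def test_intervals_never_cross(self, all_loci):
        for locus in all_loci.values():
            cfg = SimConfig(n_clones=200, editing_efficiency=1.0, seed=31,
                            reporter_amplicon_dropout=0.0)
            cohort = simulate_cohort(locus, cfg)
            for assay in ("five_prime", "three_prime"):
                for rec in emit_amplicons(locus, cohort, assay):
                    r = infer(call_markers(str(rec.seq), locus, assay,
                                           rec.id.split("|")[0]), locus)
                    assert r.consistent
                    assert r.x5_interval.hi <= r.x3_interval.lo


class TestClassify:
    def test_s134c_5p_has_exactly_two_observed_classes(self, s134c):
        sigs = {
            _encode(s134c, "five_prime", c).class_signature
            for c in ({"i2_snp": "C", "L1": "absent", "L2": "present"},
                      {"i2_snp": "C", "L1": "present", "L2": "present"})
        }
        assert len(sigs) == 2

    def test_r106w_5p_has_exactly_four_observed_classes(self, r106w):
        calls = [
            {"i2_snp": "C", "L1": "absent", "r106w": "CGG", "i3_snp": "C", "L2": "present"},
            {"i2_snp": "C", "L1": "absent", "r106w": "TGG", "i3_snp": "C", "L2": "present"},
            {"i2_snp": "C", "L1": "present", "r106w": "CGG", "i3_snp": "C", "L2": "present"},
            {"i2_snp": "T", "L1": "present", "r106w": "CGG", "i3_snp": "C", "L2": "present"},
        ]
        sigs = {_encode(r106w, "five_prime", c).class_signature for c in calls}
        assert len(sigs) == 4

    def test_identical_calls_identical_signature(self, s134c):
        c = {"i2_snp": "C", "L1": "absent", "L2": "present"}
        a = _encode(s134c, "five_prime", c)
        b = _encode(s134c, "five_prime", dict(c))
        assert classify(a, s134c) == classify(b, s134c)


class TestEnumeration:
    def test_s134c_5p_reachable_classes_include_observed_plus_upstream(self, s134c):
        certs = enumerate_possible_classes(s134c, "five_prime")
        sigs = {c.signature for c in certs}
        observed = {
            _encode(s134c, "five_prime",
                    {"i2_snp": "C", "L1": "absent", "L2": "present"}).class_signature,
            _encode(s134c, "five_prime",
                    {"i2_snp": "C", "L1": "present", "L2": "present"}).class_signature,
        }
        unobserved = _encode(s134c, "five_prime",
                             {"i2_snp": "T", "L1": "present", "L2": "present"}
                             ).class_signature
        assert observed <= sigs
        assert unobserved in sigs  # feasible though never observed
        assert len(sigs) == 3

    def test_r106w_5p_enumeration_contains_all_four_observed(self, r106w):
        sigs = {c.signature for c in enumerate_possible_classes(r106w, "five_prime")}
        for calls in (
            {"i2_snp": "C", "L1": "absent", "r106w": "CGG", "i3_snp": "C", "L2": "present"},
            {"i2_snp": "C", "L1": "absent", "r106w": "TGG", "i3_snp": "C", "L2": "present"},
            {"i2_snp": "C", "L1": "present", "r106w": "CGG", "i3_snp": "C", "L2": "present"},
            {"i2_snp": "T", "L1": "present", "r106w": "CGG", "i3_snp": "C", "L2": "present"},
        ):
            assert _encode(r106w, "five_prime", calls).class_signature in sigs

    def test_locus_with_only_l2_informative_has_one_class(self):
        cfg = """
name: l2only
region_length: 2000
haplotypes: [h]
mutation_marker: m
l2_marker: L2
markers:
  - {id: L2, kind: insertion, position: 600, role: linker, vector: TTAATTAACC}
  - {id: m, kind: substitution, position: 1500, role: mutation,
     vector: A, genomic: {h: G}}
"""
        locus = load_locus(cfg)
        assert len(enumerate_possible_classes(locus, "five_prime")) == 1

    def test_witness_events_reproduce_their_signature(self, all_loci):
        for locus in all_loci.values():
            for assay in ("five_prime", "three_prime"):
                for cert in enumerate_possible_classes(locus, assay):
                    ev = cert.witness
                    p = pattern_from_truth(locus, true_alleles(locus, ev), assay)
                    assert signature_of(p, locus) == cert.signature

    def test_enumeration_matches_grid_oracle_signatures(self, all_loci):
        for locus in all_loci.values():
            small = locus.rescaled(400)
            for assay in ("five_prime", "three_prime"):
                enum_sigs = {c.signature
                             for c in enumerate_possible_classes(small, assay)}
                grid_sigs = set(grid_signature_probs(small, assay))
                assert enum_sigs == grid_sigs


class TestMinimality:
    EPS = 0.2

    def test_interval_bounds_are_tight(self, all_loci):
        """Just inside either bound the signature is reproduced; just outside
        a marker-named bound it is not (the intervals cannot shrink)."""
        for locus in all_loci.values():
            for assay in ("five_prime", "three_prime"):
                for cert in enumerate_possible_classes(locus, assay):
                    ev = cert.witness
                    p = pattern_from_truth(locus, true_alleles(locus, ev), assay)
                    r = infer(p, locus)
                    assert r.consistent and ev.template in r.per_template
                    i5, i3 = r.per_template[ev.template]
                    assert i5.contains(ev.x5) and i3.contains(ev.x3)
                    for x5, x3, should_match in [
                        (i5.lo + self.EPS, ev.x3, True),
                        (i5.hi - self.EPS, ev.x3, True),
                        (ev.x5, i3.lo + self.EPS, True),
                        (ev.x5, i3.hi - self.EPS, True),
                        (i5.lo - self.EPS, ev.x3, i5.lo_name == "region_start"),
                        (ev.x5, i3.hi + self.EPS, i3.hi_name == "region_end"),
                    ]:
                        if not 0 <= x5 < x3 <= locus.region_length:
                            continue
                        probe = CrossoverEvent("probe", ev.template, x5, x3)
                        sig = signature_of(
                            pattern_from_truth(locus, true_alleles(locus, probe),
                                               assay), locus)
                        assert (sig == cert.signature) == should_match, (
                            locus.name, assay, cert.signature, (x5, x3))
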