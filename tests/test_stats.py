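"""Aggregation, model predictions, goodness of fit, ascertainment."""

import numpy as np
import pytest

from hrtract import (SimConfig, aggregate, ascertainment_report,
                     compare_observed_to_model, enumerate_possible_classes,
                     grid_correction_probability, infer, load_outcome_fixture,
                     model_selection_replicates, pattern_from_truth,
                     predict_class_probs, sample_event, simulate_cohort,
                     true_alleles)
from hrtract.inference import CORRECTED


def _class_results(locus, assay):
    """One representative inference result per enumerable class."""
    return [infer(pattern_from_truth(locus, true_alleles(locus, c.witness), assay),
                  locus)
            for c in enumerate_possible_classes(locus, assay)]


class TestAggregate:
    def test_r106w_supplied_fractions_give_71_percent_corrected(self, r106w):
        fixture = load_outcome_fixture("outcomes_r106w_five_prime")
        _, table = fixture.analyze(r106w)
        assert table.corrected_fraction == pytest.approx(0.71, abs=1e-12)
        assert table.n is None  # fractions supplied: no counts, no CIs

    def test_s134c_3p_supplied_fractions_give_44_percent_corrected(self, s134c):
        _, table = load_outcome_fixture("outcomes_s134c_three_prime").analyze(s134c)
        assert table.corrected_fraction == pytest.approx(0.44, abs=1e-12)

    def test_single_class_counts(self, s134c):
        r = _class_results(s134c, "five_prime")[0]
        table = aggregate([r] * 10)
        row = table.table.iloc[0]
        assert row.fraction == 1.0 and row["count"] == 10
        assert 0.0 < row.ci_low < 1.0 and row.ci_high <= 1.0

    def test_counted_aggregation_invariants(self, r106w):
        cfg = SimConfig(n_clones=300, editing_efficiency=1.0, seed=41)
        rng = np.random.default_rng(41)
        results = []
        for i in range(300):
            ev = sample_event(r106w, cfg, rng, clone_id=f"c{i}")
            if ev.covers(r106w.l2_marker.coord):
                results.append(infer(pattern_from_truth(
                    r106w, true_alleles(r106w, ev), "five_prime"), r106w))
        table = aggregate(results)
        assert table.table.fraction.sum() == pytest.approx(1.0)
        assert table.n == len(results)
        for row in table.table.itertuples():
            assert row.ci_low <= row.fraction <= row.ci_high
        assert 0.0 <= table.corrected_fraction <= 1.0

    def test_empty_and_bad_fraction_inputs_raise(self, s134c):
        with pytest.raises(ValueError, match="no consistent"):
            aggregate([])
        r = _class_results(s134c, "five_prime")[0]
        with pytest.raises(ValueError, match="sum"):
            aggregate([r], fractions={r.class_signature: 0.5})


class TestModelPrediction:
    def test_correction_probability_closed_form_and_boundaries(self, all_loci):
        for locus in all_loci.values():
            L = locus.region_length
            pred = predict_class_probs(locus, "three_prime")
            assert pred.correction_probability(0.0) == 0.0
            assert pred.correction_probability(float(L)) == 0.0
            assert pred.correction_probability(L / 2) == pytest.approx(0.5)
            for m in (0.1 * L, 0.37 * L, 0.8 * L):
                assert pred.correction_probability(m) == pytest.approx(
                    2 * (m / L) * (1 - m / L))
                # the center is the maximum
                assert pred.correction_probability(m) < 0.5

    def test_class_probabilities_sum_to_one(self, all_loci):
        for locus in all_loci.values():
            for assay in ("five_prime", "three_prime"):
                pred = predict_class_probs(locus, assay, exclude_reporter=True)
                assert sum(pred.class_probs.values()) == pytest.approx(1.0)

    def test_reporter_fraction_strictly_below_one_and_matches_grid(self, s134c):
        """The reporter junction lies downstream of L2, so among detected
        clones it is captured strictly less than always: reporter-based
        editing estimates under-represent editing."""
        small = s134c.rescaled(1000)
        pred = predict_class_probs(small, "three_prime")
        assert pred.reporter_fraction < 1.0
        oracle = grid_correction_probability(
            small.region_length, small.marker("venus").coord,
            conditional_on=small.l2_marker.coord)
        assert pred.reporter_fraction == pytest.approx(oracle, abs=1e-9)

    def test_oracle_equivalence_total_variation(self, all_loci):
        from hrtract import grid_signature_probs

        for locus in all_loci.values():
            small = locus.rescaled(1000)
            for assay in ("five_prime", "three_prime"):
                pred = predict_class_probs(small, assay)
                grid = grid_signature_probs(small, assay)
                sigs = set(pred.class_probs) | set(grid)
                tv = 0.5 * sum(abs(pred.class_probs.get(s, 0) - grid.get(s, 0))
                               for s in sigs)
                assert tv <= 1e-3


class TestGoodnessOfFit:
    def test_null_simulation_chi2_in_central_99(self, r106w):
        pred = predict_class_probs(r106w, "five_prime")
        cfg = SimConfig(n_clones=1, editing_efficiency=1.0, seed=0)
        rng = np.random.default_rng(97)
        results = []
        while len(results) < 500:
            ev = sample_event(r106w, cfg, rng, clone_id=f"c{len(results)}")
            if ev.covers(r106w.l2_marker.coord):
                results.append(infer(pattern_from_truth(
                    r106w, true_alleles(r106w, ev), "five_prime"), r106w))
        gof = compare_observed_to_model(aggregate(results), pred)
        assert gof.tested
        assert 0.005 < gof.p_value < 0.995

    def test_observed_equal_predicted_has_zero_divergence(self, s134c):
        pred = predict_class_probs(s134c, "five_prime")
        results = _class_results(s134c, "five_prime")
        table = aggregate(results, fractions=dict(pred.class_probs))
        gof = compare_observed_to_model(table, pred)
        assert not gof.tested  # fractions only: descriptive, no test
        assert gof.total_variation == pytest.approx(0.0, abs=1e-12)
        assert gof.kl_divergence == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_all_mass_one_class_is_finite(self, s134c):
        pred = predict_class_probs(s134c, "five_prime")
        results = _class_results(s134c, "five_prime")
        sig = results[0].class_signature
        table = aggregate(results[:1], fractions={sig: 1.0})
        gof = compare_observed_to_model(table, pred)
        assert np.isfinite(gof.log_likelihood)
        assert gof.total_variation == pytest.approx(1.0 - pred.class_probs[sig])

    def test_class_mismatch_lists_unmatched(self, s134c, r282x):
        pred = predict_class_probs(s134c, "five_prime")
        results = _class_results(r282x, "five_prime")
        with pytest.raises(ValueError, match="absent from the model"):
            compare_observed_to_model(aggregate(results * 3), pred)


class TestAscertainment:
    def test_ratio_bounded_and_matches_grid_oracle(self, s134c):
        cfg = SimConfig(n_clones=4000, editing_efficiency=1.0, seed=53)
        truth = simulate_cohort(s134c, cfg).truth
        rep = ascertainment_report(truth)
        assert rep.defined and rep.ratio <= 1.0
        oracle = grid_correction_probability(s134c.region_length,
                                             s134c.marker("venus").coord)
        se = np.sqrt(oracle * (1 - oracle) / rep.n_edited)
        assert abs(rep.ratio - oracle) < 4 * se
        assert rep.ci_low <= rep.ratio <= rep.ci_high

    def test_dropout_does_not_affect_truth_level_ratio(self, s134c):
        base = dict(n_clones=500, editing_efficiency=1.0, seed=57)
        t0 = simulate_cohort(s134c, SimConfig(reporter_amplicon_dropout=0.0, **base)).truth
        t1 = simulate_cohort(s134c, SimConfig(reporter_amplicon_dropout=1.0, **base)).truth
        assert ascertainment_report(t0).ratio == ascertainment_report(t1).ratio

    def test_undefined_without_edited_clones(self, s134c):
        truth = simulate_cohort(
            s134c, SimConfig(n_clones=20, editing_efficiency=0.0, seed=1)).truth
        rep = ascertainment_report(truth)
        assert not rep.defined
        assert "undefined" in str(rep)


class TestModelSelection:
    def test_uniform_preferred_over_end_biased(self, r106w):
        res = model_selection_replicates(r106w, n_cohorts=20, cohort_size=500,
                                         seed=61)
        assert res["n_prefer_true"] >= 19


def test_correction_probability_plot_smoke(s134c, tmp_path):
    pytest.importorskip("matplotlib")
    from hrtract.stats import plot_correction_probability

    out = tmp_path / "p_correct.png"
    plot_correction_probability(s134c, path=out)
    assert out.stat().st_size > 0
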