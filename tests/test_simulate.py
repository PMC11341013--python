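"""Generator contracts: determinism, planted truth, depth censoring."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from chscreen import (
    CohortSpec,
    apply_depth_censoring,
    detection_probability,
    make_variant_catalog,
    simulate_matched_discovery_cohort,
    simulate_screening_cohorts,
)
from chscreen.simulate import (
    IMMUNE_CELL_TYPES,
    PROTEIN_ALTERING,
    VafParams,
    expected_criterion_flags,
)


class TestMakeVariantCatalog:
    def test_panel_size_is_exact(self):
        catalog, truth = make_variant_catalog(500, 98, seed=7)
        planted = [e for e in catalog if e.true_class == "ch_pathogenic"]
        assert len(planted) == 98
        assert sorted(e.variant_id for e in planted) == truth.panel

    def test_empty_panel(self):
        catalog, truth = make_variant_catalog(10, 0, seed=1)
        assert not any(e.true_class == "ch_pathogenic" for e in catalog)
        assert truth.panel == []

    def test_deterministic_for_fixed_seed(self):
        a, ta = make_variant_catalog(80, 9, seed=42)
        b, tb = make_variant_catalog(80, 9, seed=42)
        assert a == b
        assert ta.beta_true == tb.beta_true

    def test_criterion_flags_match_true_class(self, small_catalog):
        """Brute-force recomputation of the four criterion predicates."""
        catalog, _ = small_catalog
        for e in catalog:
            flags = expected_criterion_flags(e)
            if e.true_class == "ch_pathogenic":
                assert all(flags.values()), e
            elif e.true_class == "ch_passenger":
                assert not all(flags.values()), e

    def test_each_criterion_has_an_individual_failer(self):
        catalog, _ = make_variant_catalog(60, 6, seed=5)
        passengers = [e for e in catalog if e.true_class == "ch_passenger"]
        for criterion in ("tumor_freq", "population_freq", "expression", "damaging"):
            sole = [
                e
                for e in passengers
                if not expected_criterion_flags(e)[criterion]
                and all(v for k, v in expected_criterion_flags(e).items() if k != criterion)
            ]
            assert sole, f"no passenger fails only {criterion}"

    def test_truth_log_odds_match_prevalences(self):
        _, truth = make_variant_catalog(50, 5, seed=3)
        for vid in truth.panel:
            pc, pn = truth.prevalence_cancer[vid], truth.prevalence_noncancer[vid]
            lor = np.log(pc / (1 - pc)) - np.log(pn / (1 - pn))
            assert truth.beta_true[vid] == pytest.approx(lor, abs=1e-9)

    @pytest.mark.parametrize(
        "n_variants,panel_size",
        [(5, 2), (50, -1), (20, 19), (10, 10)],
    )
    def test_invalid_arguments(self, n_variants, panel_size):
        with pytest.raises(ValueError):
            make_variant_catalog(n_variants, panel_size, seed=0)


class TestDiscoveryCohort:
    def test_deterministic(self, small_catalog):
        catalog, _ = small_catalog
        a = simulate_matched_discovery_cohort(catalog, 50, seed=9)
        b = simulate_matched_discovery_cohort(catalog, 50, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_vaf_ranges_by_class(self, small_discovery):
        calls, catalog, _ = small_discovery
        cls = {e.variant_id: e.true_class for e in catalog}
        grp = calls.assign(cls=calls["variant_id"].map(cls))
        germ = grp[grp["cls"] == "germline_common"]
        assert ((germ["vaf_blood"] > 0.3) & (germ["vaf_blood"] < 0.7)).all()
        ch = grp[grp["cls"].str.startswith("ch_")]
        assert ((ch["vaf_blood"] > 0.02) & (ch["vaf_blood"] < 0.25)).all()
        assert ((ch["vaf_tumor"] > 0.02) & (ch["vaf_tumor"] < 0.25)).all()
        som = grp[grp["cls"] == "somatic_private"]
        assert (som["vaf_blood"] < 0.01).all()
        assert ((som["vaf_tumor"] >= 0.05) & (som["vaf_tumor"] <= 0.40)).all()

    def test_carriage_frequency_matches_binomial(self, small_discovery):
        """Empirical carriage within 3 binomial SEs of the generating rate."""
        calls, catalog, _ = small_discovery
        n = 200
        counts = calls.groupby("variant_id")["sample_id"].nunique()
        for e in catalog:
            p = e.carriage_prob
            se = np.sqrt(p * (1 - p) / n)
            assert counts.get(e.variant_id, 0) / n == pytest.approx(p, abs=3 * se + 1e-9)

    def test_degenerate_params_yield_germline_band_only(self, small_catalog):
        catalog, _ = small_catalog
        params = VafParams(ch_lo=0.5, ch_hi=0.5)
        calls = simulate_matched_discovery_cohort(catalog, 30, params=params, seed=2)
        ch_ids = {e.variant_id for e in catalog if e.true_class.startswith("ch_")}
        ch_calls = calls[calls["variant_id"].isin(ch_ids)]
        assert (ch_calls["vaf_blood"] == 0.5).all()

    def test_errors(self, small_catalog):
        catalog, _ = small_catalog
        with pytest.raises(ValueError):
            simulate_matched_discovery_cohort([], 10, seed=0)
        with pytest.raises(ValueError):
            simulate_matched_discovery_cohort(catalog, 0, seed=0)


class TestScreeningCohorts:
    def test_row_count_matches_cohort_spec(self, small_catalog):
        _, truth = small_catalog
        spec = [("a", 10, "cancer"), ("b", 25, "non_cancer"), ("c", 5, "cancer")]
        prof = simulate_screening_cohorts(truth, spec, seed=0)
        assert len(prof) == 40
        assert set(prof["cohort_id"]) == {"a", "b", "c"}
        assert prof.loc[prof["cohort_id"] == "a", "label"].eq(1).all()
        assert prof.loc[prof["cohort_id"] == "b", "label"].eq(0).all()

    def test_carriage_tracks_label_conditional_prevalence(self, small_catalog):
        _, truth = small_catalog
        n = 4000
        prof = simulate_screening_cohorts(
            truth, [("ca", n, "cancer"), ("co", n, "non_cancer")], seed=1
        )
        for vid in truth.panel:
            for label, prev_map in (
                (1, truth.prevalence_cancer), (0, truth.prevalence_noncancer)
            ):
                p = prev_map[vid]
                frac = (prof.loc[prof["label"] == label, vid] > 0).mean()
                se = np.sqrt(p * (1 - p) / n)
                assert frac == pytest.approx(p, abs=4 * se)

    def test_null_mutation_shows_no_label_difference(self, small_catalog):
        _, truth = small_catalog
        import copy

        t = copy.deepcopy(truth)
        vid = t.panel[0]
        t.prevalence_cancer[vid] = t.prevalence_noncancer[vid] = 0.2
        n = 2000
        prof = simulate_screening_cohorts(
            t, [("ca", n, "cancer"), ("co", n, "non_cancer")], seed=4
        )
        f1 = (prof.loc[prof["label"] == 1, vid] > 0).mean()
        f0 = (prof.loc[prof["label"] == 0, vid] > 0).mean()
        pooled_se = np.sqrt(2 * 0.2 * 0.8 / n)
        assert abs(f1 - f0) < 3 * pooled_se

    def test_unknown_label_rejected(self, small_catalog):
        _, truth = small_catalog
        with pytest.raises(ValueError, match="label"):
            simulate_screening_cohorts(truth, [("a", 5, "mixed")], seed=0)

    def test_single_feature_bayes_accuracy(self):
        """With one informative mutation, the optimal single-feature rule
        (predict cancer iff carrier) attains its analytic accuracy."""
        catalog, truth = make_variant_catalog(10, 1, seed=8)
        import copy

        t = copy.deepcopy(truth)
        vid = t.panel[0]
        t.prevalence_cancer[vid] = 0.9
        t.prevalence_noncancer[vid] = 0.1
        n = 1000
        prof = simulate_screening_cohorts(
            t, [("ca", n, "cancer"), ("co", n, "non_cancer")], seed=6
        )
        pred = (prof[vid] > 0).astype(int)
        acc = (pred == prof["label"]).mean()
        # analytic Bayes accuracy: 0.5*P(carrier|cancer) + 0.5*P(not|non-cancer)
        assert acc == pytest.approx(0.9, abs=3 * np.sqrt(0.9 * 0.1 / (2 * n)))


class TestDepthCensoring:
    def test_exact_binomial_tail(self):
        """Detection probability equals the explicit binomial tail sum."""
        for vaf, depth, k in [(0.04, 36, 3), (0.03, 457, 3), (0.25, 36, 3), (0.1, 95, 5)]:
            brute = sum(
                sps.binom.pmf(j, depth, vaf) for j in range(k, depth + 1)
            )
            assert detection_probability(vaf, depth, k) == pytest.approx(brute, abs=1e-12)

    def test_absent_mutation_stays_absent(self, small_catalog):
        _, truth = small_catalog
        prof = simulate_screening_cohorts(truth, [("a", 50, "cancer")], seed=2)
        vid = truth.panel[0]
        prof[vid] = 0.0
        censored = apply_depth_censoring(prof, {"a": 36}, seed=3)
        assert (censored[vid] == 0).all()

    def test_observed_vaf_is_alt_over_depth(self, small_catalog):
        _, truth = small_catalog
        prof = simulate_screening_cohorts(truth, [("a", 100, "cancer")], seed=5)
        censored = apply_depth_censoring(prof, {"a": 50}, min_alt_reads=3, seed=5)
        vals = censored[truth.panel].to_numpy()
        assert np.allclose(vals * 50, np.round(vals * 50), atol=1e-9)
        assert (vals <= 1).all()
        # censoring never creates a mutation absent in truth
        assert ((prof[truth.panel].to_numpy() == 0) <= (vals == 0)).all()

    def test_low_depth_loses_more_low_vaf_calls(self, small_catalog):
        """Cohorts at 36x lose far more VAF-3% mutations than cohorts at 457x."""
        _, truth = small_catalog
        n = 400
        vid = truth.panel[0]
        base = simulate_screening_cohorts(
            truth, [("lo", n, "cancer"), ("hi", n, "cancer")], seed=7
        )
        base[truth.panel] = 0.0
        base[vid] = 0.03
        censored = apply_depth_censoring(base, {"lo": 36, "hi": 457}, 3, seed=8)
        det_lo = (censored.loc[censored["cohort_id"] == "lo", vid] > 0).mean()
        det_hi = (censored.loc[censored["cohort_id"] == "hi", vid] > 0).mean()
        assert det_hi > det_lo
        assert det_hi > 0.99 and det_lo < 0.5

    def test_detection_monotone_in_depth_and_vaf(self):
        depths = [20, 36, 95, 197, 457]
        vafs = [0.01, 0.03, 0.05, 0.1, 0.25]
        for v in vafs:
            probs = [detection_probability(v, d, 3) for d in depths]
            assert probs == sorted(probs)
        for d in depths:
            probs = [detection_probability(v, d, 3) for v in vafs]
            assert probs == sorted(probs)

    def test_errors(self, small_catalog):
        _, truth = small_catalog
        prof = simulate_screening_cohorts(truth, [("a", 5, "cancer")], seed=0)
        with pytest.raises(ValueError):
            apply_depth_censoring(prof, {"a": 0}, seed=0)
        with pytest.raises(ValueError):
            apply_depth_censoring(prof, {"a": 36}, min_alt_reads=0, seed=0)
        with pytest.raises(ValueError):
            apply_depth_censoring(prof, {}, seed=0)
        with pytest.raises(ValueError):
            detection_probability(0.1, -1)

    def test_deterministic(self, small_catalog):
        _, truth = small_catalog
        prof = simulate_screening_cohorts(truth, [("a", 50, "cancer")], seed=1)
        a = apply_depth_censoring(prof, {"a": 36}, seed=9)
        b = apply_depth_censoring(prof, {"a": 36}, seed=9)
        pd.testing.assert_frame_equal(a, b)
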