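"""Early/late decomposition: centring identities, sign recovery, term importance,
sex and species comparisons."""

import numpy as np
import pandas as pd
import pytest

from reproage import decompose as dc
from reproage import records as rec
from reproage.simulate import (
    SimulationConfig,
    simulate_paired_population,
    simulate_population,
    truth_recovery_report,
)


def _annotated(cfg):
    df, truth = simulate_population(cfg)
    hist = rec.build_histories(df, int(df["season"].max()))
    return rec.derive_covariates(df, hist), truth


class TestSplit:
    def test_partition_at_cutoff(self, wa_annotated):
        ann, _ = wa_annotated
        early, late = dc.split_at_threshold(ann, 18)
        assert early["age"].max() <= 18
        assert late["age"].min() >= 19
        assert len(early) + len(late) == len(ann)

    def test_override_map_wins(self, wa_annotated):
        ann, _ = wa_annotated
        early, _ = dc.split_at_threshold(ann, 14, overrides={("WA", "F"): 18})
        f = early[early["sex"] == "F"]
        m = early[early["sex"] == "M"]
        assert f["age"].max() <= 18 and f["age"].max() > 14
        assert m["age"].max() <= 14

    def test_empty_side_errors(self, wa_annotated):
        ann, _ = wa_annotated
        with pytest.raises(ValueError, match="late"):
            dc.split_at_threshold(ann, int(ann["age"].max()))


class TestEarlyModel:
    def test_signs_and_importance_with_known_truth(self, wa_annotated):
        ann, _ = wa_annotated
        early, _ = dc.split_at_threshold(ann, 20)
        res = dc.fit_early_model(early, species="WA", sex=None)
        est = res.estimates
        # improvement with experience (generative early slope +0.15/yr)
        assert est["years_since_first"][0] > 0
        assert est["years_since_first"][2] > 2
        # strong simulated first-attempt penalty (-0.8)
        assert est["is_first_attempt"][0] < 0
        assert est["is_first_attempt"][2] > 2

    def test_covers_generating_slope(self, wa_annotated):
        ann, _ = wa_annotated
        early, _ = dc.split_at_threshold(ann, 20)
        res = dc.fit_early_model(early)
        b, se, _ = res.estimates["years_since_first"]
        assert b - 2.5 * se < 0.15 < b + 2.5 * se

    def test_centring_shift_invariance(self, wa_annotated):
        """Adding a constant to every age and age_first leaves the
        within-individual terms untouched."""
        ann, _ = wa_annotated
        early, _ = dc.split_at_threshold(ann, 20)
        res = dc.fit_early_model(early, importance=False)
        shifted = early.copy()
        shifted["age"] = shifted["age"] + 7
        shifted["age_first"] = shifted["age_first"] + 7
        res2 = dc.fit_early_model(shifted, importance=False)
        assert res2.estimates["years_since_first"][0] == pytest.approx(
            res.estimates["years_since_first"][0], abs=1e-5
        )
        assert res2.estimates["is_first_attempt"][0] == pytest.approx(
            res.estimates["is_first_attempt"][0], abs=1e-5
        )

    def test_record_order_invariance(self, wa_annotated):
        ann, _ = wa_annotated
        early, _ = dc.split_at_threshold(ann, 20)
        res = dc.fit_early_model(early, importance=False)
        perm = early.sample(frac=1.0, random_state=1).reset_index(drop=True)
        res2 = dc.fit_early_model(perm, importance=False)
        for t in res.estimates:
            assert res2.estimates[t][0] == pytest.approx(res.estimates[t][0], abs=1e-6)

    def test_requires_known_recruits(self, wa_annotated):
        ann, _ = wa_annotated
        early, _ = dc.split_at_threshold(ann, 20)
        none = early.assign(known_recruit=0)
        with pytest.raises(ValueError, match="known recruits"):
            dc.fit_early_model(none)


class TestLateModel:
    def test_senescence_disappearance_terminal_signs(self, wa_annotated):
        ann, _ = wa_annotated
        _, late = dc.split_at_threshold(ann, 20)
        res = dc.fit_late_model(late)
        est = res.estimates
        assert est["years_before_death"][0] > 0  # decline approaching death
        assert est["age_last"][0] < 0  # good breeders die younger (cost < 0)
        assert est["is_last_attempt"][0] > 0  # terminal boost (+0.7)

    def test_constant_column_dropped_not_fitted(self, wa_annotated):
        ann, _ = wa_annotated
        _, late = dc.split_at_threshold(ann, 20)
        same = late[late["presumed_dead"] == 1].copy()
        same["age_last"] = 30
        res = dc.fit_late_model(same, importance=False)
        assert "age_last" in res.dropped
        assert "age_last" not in res.estimates

    def test_robustness_terms_join_but_keep_headline(self, wa_annotated):
        ann, _ = wa_annotated
        _, late = dc.split_at_threshold(ann, 20)
        res = dc.fit_late_model(
            late,
            robustness=("partner_change", "years_since_last", "previous_outcome",
                        "years_since_last_x_previous_outcome"),
            importance=False,
        )
        for t in dc.LATE_TERMS:
            assert t in res.estimates
        assert "partner_change" in res.estimates
        assert "years_since_last_x_previous_outcome" in res.estimates

    def test_unknown_robustness_term_rejected(self, wa_annotated):
        ann, _ = wa_annotated
        _, late = dc.split_at_threshold(ann, 20)
        with pytest.raises(ValueError, match="robustness"):
            dc.fit_late_model(late, robustness=("bad_term",))


class TestTermImportance:
    def test_accessor_matches_estimates(self, wa_annotated):
        ann, _ = wa_annotated
        early, _ = dc.split_at_threshold(ann, 20)
        res = dc.fit_early_model(early)
        assert dc.term_importance(res, "years_since_first") == res.estimates["years_since_first"][2]
        with pytest.raises(KeyError):
            dc.term_importance(res, "not_a_term")

    def test_null_term_importance_near_minus_two(self):
        """A covariate with no true effect costs ~2 AIC on average; averaged
        over replicates the removal dAIC should sit near -2 (between -2 and 0)."""
        rng = np.random.default_rng(8)
        deltas = []
        for r in range(6):
            cfg = SimulationConfig(
                seed=int(rng.integers(2**31)), species_profile="annual",
                n_individuals=400, early_slope=0.0, late_slope=0.0,
                first_attempt_effect=0.0, terminal_effect=0.0, cost_coefficient=0.0,
                defer_prob_after_success=0.1, defer_prob_after_failure=0.1,
            )
            ann, _ = _annotated(cfg)
            early, _ = dc.split_at_threshold(ann, 20)
            res = dc.fit_early_model(early)
            deltas.append(res.estimates["age_first"][2])
        mean_delta = np.mean(deltas)
        assert -2.2 < mean_delta < 0.5


class TestTruthRecovery:
    def test_report_covers_and_signs(self, wa_annotated, wa_population):
        cfg, _, truth = wa_population
        ann, _ = wa_annotated
        early, late = dc.split_at_threshold(ann, 20)
        er = dc.fit_early_model(early, importance=False)
        lr = dc.fit_late_model(late, importance=False)
        rep = truth_recovery_report(truth, cfg, [er, lr])
        assert set(rep["term"]) >= {"years_since_first", "is_first_attempt",
                                    "years_before_death", "is_last_attempt", "age_last"}
        age_last_row = rep[rep["term"] == "age_last"].iloc[0]
        assert age_last_row["ci_covers"]  # estimated sign equals sign of the cost

    def test_slope_bias_across_replicates(self):
        """Early slope, late decline and terminal effect recovered with
        modest bias under an outcome-independent (annual) schedule."""
        rng = np.random.default_rng(55)
        est = {"years_since_first": [], "years_before_death": [], "is_last_attempt": []}
        for r in range(8):
            cfg = SimulationConfig(
                seed=int(rng.integers(2**31)), species_profile="annual",
                n_individuals=1000, defer_prob_after_success=0.1,
                defer_prob_after_failure=0.1, baseline_survival=0.91,
            )
            ann, _ = _annotated(cfg)
            early, late = dc.split_at_threshold(ann, cfg.threshold_age)
            er = dc.fit_early_model(early, importance=False)
            lr = dc.fit_late_model(late, importance=False)
            est["years_since_first"].append(er.estimates["years_since_first"][0])
            est["years_before_death"].append(lr.estimates["years_before_death"][0])
            est["is_last_attempt"].append(lr.estimates["is_last_attempt"][0])
        truth = {"years_since_first": 0.15, "years_before_death": 0.10, "is_last_attempt": 0.7}
        for term, vals in est.items():
            bias = np.mean(vals) - truth[term]
            assert abs(bias) < 0.25 * abs(truth[term]) + 1e-9, (term, np.mean(vals))


@pytest.fixture(scope="module")
def female_driven():
    return simulate_paired_population(
        n_pairs=400, seed=9, male_slopes=(0.0, 0.0), female_slopes=(0.12, -0.08),
        age_correlation=0.7,
    )


class TestSexComparison:
    def test_female_effect_detected_under_correlated_ages(self, female_driven):
        out = dc.compare_sex_ages(female_driven, threshold_male=18, threshold_female=18)
        assert out["more_variation"] == "female"
        assert out["delta_aic_drop"]["female"] > out["delta_aic_drop"]["male"]
        # two useless male parameters: dropping them costs about nothing
        assert out["delta_aic_drop"]["male"] < 2.0

    def test_symmetric_dependence_is_balanced(self):
        sym = simulate_paired_population(
            n_pairs=400, seed=10, male_slopes=(0.08, -0.05), female_slopes=(0.08, -0.05),
        )
        out = dc.compare_sex_ages(sym, threshold_male=18, threshold_female=18)
        assert abs(out["delta_aic_drop"]["male"] - out["delta_aic_drop"]["female"]) < 10

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing column"):
            dc.compare_sex_ages(pd.DataFrame({"pair_id": []}), 18, 18)


class TestSpeciesInteractions:
    def _three_species(self, seed, bba_early_slope):
        frames = []
        rng = np.random.default_rng(seed)
        for prof, sp_slope in (
            ("annual", bba_early_slope),
            ("biennial_short", 0.15),
            ("biennial_yearlong", 0.15),
        ):
            from reproage.simulate import species_profile_defaults

            cfg = species_profile_defaults(prof)
            cfg.seed = int(rng.integers(2**31))
            cfg.n_individuals = 350
            cfg.early_slope = sp_slope
            df, _ = simulate_population(cfg)
            frames.append(df)
        df = pd.concat(frames, ignore_index=True)
        hist = rec.build_histories(df, int(df["season"].max()))
        return rec.derive_covariates(df, hist)

    def test_heterogeneous_improvement_detected(self):
        ann = self._three_species(3, bba_early_slope=0.30)
        early, _ = dc.split_at_threshold(ann, 20)
        early = early[early["known_recruit"] == 1]
        rep = dc.species_interaction_model(early, "early")
        block = rep[rep["term"] == "years_since_first"]["block_delta_aic"].iloc[0]
        assert block > 2

    def test_identically_parameterised_species_show_no_interaction(self):
        """Three populations with the same generative setup (only the species
        label differs): every interaction block should be dispensable."""
        rng = np.random.default_rng(14)
        frames = []
        for label in ("BBA", "GHA", "WA"):
            cfg = SimulationConfig(
                seed=int(rng.integers(2**31)), species_profile="annual", species=label,
                n_individuals=350, defer_prob_after_success=0.1,
                defer_prob_after_failure=0.1,
            )
            frames.append(simulate_population(cfg)[0])
        df = pd.concat(frames, ignore_index=True)
        hist = rec.build_histories(df, int(df["season"].max()))
        ann = rec.derive_covariates(df, hist)
        early, _ = dc.split_at_threshold(ann, 20)
        rep = dc.species_interaction_model(early, "early")
        assert (rep.groupby("term")["block_delta_aic"].first() < 4).all()

    def test_requires_multiple_species(self, wa_annotated):
        ann, _ = wa_annotated
        with pytest.raises(ValueError, match="two species"):
            dc.species_interaction_model(ann, "early", reference="WA")
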