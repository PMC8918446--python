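import pytest

from primed2.scoring_engine import (
    DICHOTOMOUS_ITEMS,
    ITEM_IDS,
    ScoringConfig,
    TimingEpoch,
    classify_epoch,
    score_agent,
    score_item,
    shows_benefit,
    summary_total,
)
from primed2.synthetic_data import generate_dossier, random_profile_spec

from conftest import make_dossier, make_experiment, make_outcome, make_study
from oracles import naive_welch_p


class TestClassifyEpoch:
    @pytest.mark.parametrize("model, occlusion, start, expected", [
        ("transient", 90.0, -10.0, TimingEpoch.PRE_ONSET),
        ("transient", 60.0, 0.0, TimingEpoch.PRE_ONSET),  # concurrent = pre-onset
        ("transient", 60.0, 30.0, TimingEpoch.INTRA_ISCHEMIA_TRANSIENT),
        ("transient", 60.0, 75.0, TimingEpoch.POST_REPERFUSION),
        ("transient", 60.0, 60.0, TimingEpoch.POST_REPERFUSION),  # at reperfusion
        ("permanent", None, 120.0, TimingEpoch.POST_ONSET_PERMANENT),
        ("permanent", None, -5.0, TimingEpoch.PRE_ONSET),
    ])
    def test_epoch_assignment(self, model, occlusion, start, expected):
        study = make_study(model=model, occlusion=occlusion)
        assert classify_epoch(make_experiment(start=start), study) is expected


class TestShowsBenefit:
    def test_large_effect_welch_significant(self, config):
        outcome = make_outcome(mean_t=30, mean_c=50, sd=10, n=10)
        assert naive_welch_p(10, 30, 10, 10, 50, 10) < 0.001
        assert shows_benefit(outcome, config)

    def test_identical_arms_no_benefit(self, config):
        assert not shows_benefit(make_outcome(mean_t=50, mean_c=50), config)

    def test_reported_p_gates_large_d(self, config):
        outcome = make_outcome(mean_t=35, mean_c=50, sd=10, reported_p=0.30)
        assert not shows_benefit(outcome, config)

    def test_reported_p_preferred_over_welch(self, config):
        # Welch p would be tiny, but the reported p rules
        outcome = make_outcome(mean_t=30, mean_c=50, sd=10, reported_p=0.9)
        assert not shows_benefit(outcome, config)

    def test_small_d_fails_even_when_significant(self, config):
        outcome = make_outcome(mean_t=49, mean_c=50, sd=10, reported_p=0.001)
        assert not shows_benefit(outcome, config)


def _benefit_exp(start, route="intravenous", **kw):
    return make_experiment(start=start, route=route,
                           outcomes=[make_outcome()], **kw)


class TestItems:
    def test_two_epochs_scores_two(self):
        dossier = make_dossier(
            make_study("a", experiments=[_benefit_exp(-5.0)]),
            make_study("b", experiments=[_benefit_exp(90.0)]),
        )
        assert score_item(dossier, "time_epochs").score == 2

    def test_single_epoch_scores_one(self):
        dossier = make_dossier(make_study(experiments=[_benefit_exp(30.0)]))
        item = score_item(dossier, "time_epochs")
        assert item.score == 1
        assert "intra_ischemia_transient" in item.rationale

    def test_no_benefit_epochs_scores_zero(self):
        dossier = make_dossier(make_study(experiments=[make_experiment(
            outcomes=[make_outcome(mean_t=50, mean_c=50)])]))
        assert score_item(dossier, "time_epochs").score == 0

    def test_feasible_window_at_60_min(self):
        dossier = make_dossier(make_study(experiments=[_benefit_exp(60.0)]))
        assert score_item(dossier, "feasible_window").score == 2

    def test_window_boundary_is_inclusive(self):
        dossier = make_dossier(make_study(experiments=[_benefit_exp(45.0)]))
        assert score_item(dossier, "feasible_window").score == 2

    def test_pre_onset_only_window_scores_zero(self):
        dossier = make_dossier(make_study(experiments=[_benefit_exp(0.0)]))
        assert score_item(dossier, "feasible_window").score == 0

    def test_male_only_benefit_sex_zero(self):
        dossier = make_dossier(make_study(sex="male"))
        assert score_item(dossier, "sex").score == 0

    def test_both_sexes_via_two_single_sex_studies(self):
        dossier = make_dossier(make_study("m", sex="male"),
                               make_study("f", sex="female"))
        assert score_item(dossier, "sex").score == 2

    def test_unreported_sex_never_counts_as_both(self):
        dossier = make_dossier(make_study(sex="unreported"))
        assert score_item(dossier, "sex").score == 0

    def test_age_hierarchy(self):
        aged = make_dossier(make_study("a", age_class="aged"),
                            make_study("b", age_class="juvenile"))
        assert score_item(aged, "age").score == 2
        adult = make_dossier(make_study(age_class="young_adult"))
        assert score_item(adult, "age").score == 1
        young = make_dossier(make_study(age_class="juvenile"))
        assert score_item(young, "age").score == 0

    def test_species_counts(self):
        two = make_dossier(make_study("a", species="rat"),
                           make_study("b", species="mouse"))
        assert score_item(two, "species").score == 2
        one = make_dossier(make_study(species="rat"))
        assert score_item(one, "species").score == 1

    def test_comorbidity_counts(self):
        none = make_dossier(make_study(comorbidity="none"))
        assert score_item(none, "comorbidities").score == 0
        one = make_dossier(make_study(comorbidity="hypertension"))
        assert score_item(one, "comorbidities").score == 1
        two = make_dossier(make_study("a", comorbidity="hypertension"),
                           make_study("b", comorbidity="diabetes"))
        assert score_item(two, "comorbidities").score == 2

    def test_replication_needs_two_labs(self):
        one = make_dossier(make_study("a", lab_id="x"),
                           make_study("b", lab_id="x"))
        assert score_item(one, "replication").score == 0
        two = make_dossier(make_study("a", lab_id="x"),
                           make_study("b", lab_id="y"))
        assert score_item(two, "replication").score == 2

    def test_route_feasibility_map(self):
        iv = make_dossier(make_study(experiments=[_benefit_exp(90.0)]))
        assert score_item(iv, "route").score == 2
        icv = make_dossier(make_study(experiments=[
            _benefit_exp(90.0, route="intracerebroventricular")]))
        assert score_item(icv, "route").score == 0

    def test_no_behavioral_outcomes_scores_zero(self):
        dossier = make_dossier()
        item = score_item(dossier, "behavioral")
        assert item.score == 0
        assert "no behavioral" in item.rationale

    @pytest.mark.parametrize("d, expected", [(1.2, 2), (0.55, 1), (0.3, 0)])
    def test_infarct_magnitude_banding(self, d, expected):
        outcome = make_outcome(mean_t=50 - d * 10, mean_c=50, reported_p=0.001)
        dossier = make_dossier(make_study(experiments=[
            make_experiment(outcomes=[outcome])]))
        assert score_item(dossier, "infarct_magnitude").score == expected

    def test_small_scores_one_config_variant(self):
        outcome = make_outcome(mean_t=47, mean_c=50, reported_p=0.001)
        dossier = make_dossier(make_study(experiments=[
            make_experiment(outcomes=[outcome])]))
        lenient = ScoringConfig(magnitude_small_scores_one=True)
        assert score_item(dossier, "infarct_magnitude", lenient).score == 1

    def _dose_dossier(self, ds):
        exps = [make_experiment(
            experiment_id=f"d{i}", dose_value=10.0 * (i + 1), dose_unit="mg/kg",
            outcomes=[make_outcome(mean_t=50 - d * 10, mean_c=50,
                                   reported_p=0.001)])
            for i, d in enumerate(ds)]
        return make_dossier(make_study(experiments=exps))

    def test_dose_response_ladder(self):
        assert score_item(self._dose_dossier([0.5]), "dose_response").score == 0
        assert score_item(self._dose_dossier([0.5, 0.8]), "dose_response").score == 1
        assert score_item(self._dose_dossier([0.5, 0.8, 1.0]),
                          "dose_response").score == 2

    def test_dose_response_nonmonotone_zero(self):
        assert score_item(self._dose_dossier([0.5, 1.0, 0.8]),
                          "dose_response").score == 0

    def test_dose_response_ties_count_as_monotone(self):
        assert score_item(self._dose_dossier([0.5, 0.5, 0.5]),
                          "dose_response").score == 2

    def test_unknown_item_lists_roster(self):
        with pytest.raises(KeyError, match="age"):
            score_item(make_dossier(), "bogus_item")


class TestScoreAgent:
    def test_no_benefit_floor(self):
        dossier = make_dossier(make_study(experiments=[make_experiment(
            outcomes=[make_outcome(mean_t=50, mean_c=50)])]))
        profile = score_agent(dossier)
        assert profile.total == 0
        assert all(item.score == 0 for item in profile.items)

    def test_total_is_sum_of_items(self):
        for seed in range(10):
            profile = score_agent(generate_dossier(random_profile_spec(seed)))
            assert profile.total == sum(i.score for i in profile.items)
            assert 0 <= profile.total <= 22
            assert summary_total(profile) == profile.total

    def test_deterministic(self):
        dossier = generate_dossier(random_profile_spec(5))
        first = score_agent(dossier).model_dump_json()
        second = score_agent(dossier).model_dump_json()
        assert first == second

    def test_eleven_distinct_items(self):
        profile = score_agent(make_dossier())
        assert sorted(i.item_id for i in profile.items) == sorted(ITEM_IDS)

    def test_monotone_under_added_benefit_study(self):
        # a new strongly-beneficial dose-free study never lowers items 1-8/11
        exempt = {"infarct_magnitude", "behavioral"}
        extra = make_study(
            "extra", lab_id="lab_new", species="nonhuman_primate",
            age_class="aged", sex="both", comorbidity="hypertension",
            experiments=[_benefit_exp(90.0)])
        for seed in range(20):
            dossier = generate_dossier(random_profile_spec(seed))
            before = score_agent(dossier)
            grown = dossier.model_copy(deep=True)
            grown.studies.append(extra)
            after = score_agent(grown)
            for item_id in ITEM_IDS:
                if item_id not in exempt:
                    assert after.score_of(item_id) >= before.score_of(item_id)

    def test_dichotomous_items_never_one(self):
        for seed in range(30):
            profile = score_agent(generate_dossier(random_profile_spec(seed)))
            for item in profile.items:
                if item.item_id in DICHOTOMOUS_ITEMS:
                    assert item.score in (0, 2)


class TestConfig:
    def test_boundaries_must_increase(self):
        with pytest.raises(ValueError):
            ScoringConfig(effect_boundaries=(0.4, 0.4, 0.7))

    def test_alpha_open_interval(self):
        with pytest.raises(ValueError):
            ScoringConfig(benefit_alpha=1.0)

    def test_from_yaml_partial_keys(self, tmp_path):
        path = tmp_path / "config.yaml"
        path.write_text("feasible_window_min: 60\n")
        config = ScoringConfig.from_yaml(path)
        assert config.feasible_window_min == 60.0
        assert config.benefit_alpha == 0.05  # untouched default
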