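"""Cohort generator: task rules, determinism, ranges, truth bookkeeping."""

import numpy as np
import pandas as pd
import pytest

from ncptkit.binning import K_BINS, assign_bins
from ncptkit.registry import UnknownSubtestError
from ncptkit.simulate import (CohortConfig, make_reference, sample_cohort,
                              simulate_cohort, simulate_scores_fast,
                              simulate_subtest)


class TestSubtestRules:
    def test_matrices_perfect_agent_scores_17(self):
        trials, score = simulate_subtest(0.0, 31, seed=1, p_override=1.0)
        assert score == 17 and len(trials) == 17

    def test_matrices_hopeless_agent_stops_after_three_straight_misses(self):
        trials, score = simulate_subtest(0.0, 31, seed=1, p_override=0.0)
        assert score == 0 and len(trials) == 3

    def test_grammar_floor_of_zero(self):
        _, score = simulate_subtest(0.0, 30, seed=2, p_override=0.0)
        assert score == 0.0

    @pytest.mark.parametrize("sid,target", [(32, 10), (26, 5)])
    def test_gonogo_stops_at_target_correct_go_trials(self, sid, target):
        trials, score = simulate_subtest(0.0, sid, seed=3, p_override=1.0)
        go_correct = [t for t in trials if t.stimulus["type"] == "go" and t.correct]
        assert len(go_correct) == target          # stops exactly at the target
        assert trials[-1].stimulus["type"] == "go" and trials[-1].correct
        assert score == pytest.approx(
            1000 * np.mean([t.rt for t in go_correct]))
        assert 0 < score < 1500                   # mean correct-go RT within the cap

    def test_gonogo_three_errors_fails_and_retries_to_missing(self):
        trials, score = simulate_subtest(0.0, 32, seed=4, p_override=0.0)
        assert score is None
        # three attempts, each ended by its third incorrect response
        assert sum(not t.correct for t in trials) == 9

    def test_posner_cued_fraction_near_60_percent(self):
        rng = np.random.default_rng(5)
        cued = total = 0
        for _ in range(200):
            trials, score = simulate_subtest(0.0, 52, rng=rng)
            assert len(trials) == 100 and 0 <= score <= 100
            cued += sum(t.stimulus["cued"] for t in trials)
            total += len(trials)
        se = np.sqrt(0.6 * 0.4 / total)
        assert abs(cued / total - 0.60) < 3 * se

    def test_span_score_is_max_span_with_a_correct_trial(self):
        trials, score = simulate_subtest(0.0, 28, seed=6, p_override=1.0)
        spans = [t.stimulus["span"] for t in trials]
        assert spans[0] == 3
        assert spans == sorted(spans)
        assert score == max(spans)

    def test_span_v2_scores_total_correct(self):
        trials, score = simulate_subtest(0.0, 43, seed=7, p_override=1.0)
        assert score == len(trials)

    def test_unknown_subtest_raises(self):
        with pytest.raises(UnknownSubtestError):
            simulate_subtest(0.0, 99, seed=0)

    @pytest.mark.parametrize("sid,lo,hi", [
        (27, 0, 12), (31, 0, 17), (52, 0, 100), (54, 0, 40),
        (55, 0, 50), (51, 0, 25), (36, 0, 12), (37, 0, 12),
    ])
    def test_score_ranges(self, sid, lo, hi, rng):
        for _ in range(25):
            _, score = simulate_subtest(float(rng.normal()), sid, rng=rng)
            assert lo <= score <= hi

    def test_timed_scores_are_positive_times(self, rng):
        for sid in (39, 40):
            trials, score = simulate_subtest(0.0, sid, rng=rng)
            assert score == pytest.approx(sum(t.rt for t in trials))
            assert score > 0

    def test_higher_ability_scores_better(self):
        """Stochastic monotonicity: more able agents score higher on counts
        and finish the trails faster."""
        rng = np.random.default_rng(8)
        n = 5000
        lo = [simulate_subtest(-1.0, 31, rng=rng)[1] for _ in range(n)]
        hi = [simulate_subtest(+1.0, 31, rng=rng)[1] for _ in range(n)]
        assert np.mean(hi) > np.mean(lo) + 1.0
        lo_t = [simulate_subtest(-1.0, 39, rng=rng)[1] for _ in range(n // 2)]
        hi_t = [simulate_subtest(+1.0, 39, rng=rng)[1] for _ in range(n // 2)]
        assert np.mean(hi_t) < np.mean(lo_t)


class TestCohortSampling:
    def test_single_participant(self):
        profiles = sample_cohort(CohortConfig(n=1), 0)
        assert len(profiles) == 1

    def test_concentrated_composition(self):
        comp = np.zeros(K_BINS)
        comp[7] = 1.0  # ages 40-49, college bin
        cfg = CohortConfig(n=50, composition=comp, p_education_missing=0,
                           p_education_other=0)
        profiles = sample_cohort(cfg, 1)
        ks = assign_bins([p.age for p in profiles],
                         [p.education_level for p in profiles])
        assert (ks == 7).all()

    def test_same_seed_same_cohort(self):
        a = sample_cohort(CohortConfig(n=40), 11)
        b = sample_cohort(CohortConfig(n=40), 11)
        assert a == b

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(n=0).validate()
        with pytest.raises(ValueError):
            CohortConfig(composition=np.zeros(K_BINS)).validate()
        with pytest.raises(ValueError):
            CohortConfig(pause_rate=1.5).validate()


class TestSimulateCohort:
    def test_no_contamination_excludes_nobody(self, clean_cohort):
        from ncptkit.preprocessing import run_filters

        kept, report = run_filters(list(clean_cohort.logs))
        assert len(kept) == len(clean_cohort.logs)
        assert all(v == 0 for v in report.counts.values())

    def test_battery60_emits_five_rows_per_complete_participant(self):
        cohort = simulate_cohort(CohortConfig(n=60, battery_id=60), 3)
        counts = cohort.scores.groupby("user_id").size()
        assert (counts == 5).all()
        order = cohort.scores.groupby("user_id", sort=False)[
            "specific_subtest_id"].apply(tuple)
        assert set(order) == {(54, 52, 53, 55, 51)}  # administration order

    def test_determinism_under_config_and_seed(self):
        cfg = CohortConfig(n=30, battery_id=60, pause_rate=0.1)
        a = simulate_cohort(cfg, 21)
        b = simulate_cohort(cfg, 21)
        pd.testing.assert_frame_equal(a.scores, b.scores)
        pd.testing.assert_frame_equal(a.truth, b.truth)
        assert [l.to_dict() for l in a.logs] == [l.to_dict() for l in b.logs]

    def test_time_of_day_is_floor_hour_of_run_start(self, clean_cohort):
        by_run = {log.test_run_id: log for log in clean_cohort.logs}
        for run_id, grp in clean_cohort.scores.groupby("test_run_id"):
            start = by_run[run_id].first_start
            assert set(grp["time_of_day"]) == {int((start % 86400) // 3600)}

    def test_entries_time_ordered_with_positive_durations(self, clean_cohort):
        for log in clean_cohort.logs:
            starts = [e.start_time for e in log.entries]
            assert starts == sorted(starts)
            assert all(e.end_time > e.start_time for e in log.entries)

    def test_pause_truth_set_recovered_exactly(self):
        from ncptkit.preprocessing import filter_pauses

        cfg = CohortConfig(n=300, battery_id=60, pause_rate=0.1)
        cohort = simulate_cohort(cfg, 42)
        _, report = filter_pauses(list(cohort.logs))
        injected = set(cohort.truth.loc[
            cohort.truth["violation"] == "pause", "user_id"])
        assert set(report.excluded["pause_gt_24h"]) == injected
        assert len(injected) > 0


class TestFastSimulator:
    def test_matches_released_schema_and_determinism(self):
        cfg = CohortConfig(n=500, battery_id=50)
        a, ta = simulate_scores_fast(cfg, 9)
        b, tb = simulate_scores_fast(cfg, 9)
        pd.testing.assert_frame_equal(a, b)
        pd.testing.assert_frame_equal(ta, tb)
        assert a.groupby("test_run_id").size().eq(8).all()

    def test_composition_matched_in_expectation(self):
        comp = np.zeros(K_BINS)
        comp[[2, 10]] = 0.5
        cfg = CohortConfig(n=4000, composition=comp, p_education_missing=0,
                           p_education_other=0)
        scores, _ = simulate_scores_fast(cfg, 13)
        per_user = scores.groupby("user_id").first()
        ks = assign_bins(per_user["age"], per_user["education_level"])
        frac = (ks == 2).mean()
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / 4000)

    def test_subtest_scores_positively_correlated(self, fast_cohort):
        scores, _ = fast_cohort
        wide = scores.pivot(index="test_run_id", columns="specific_subtest_id",
                            values="raw_score")
        from ncptkit.norming import orient_scores

        for sid in wide.columns:
            wide[sid] = orient_scores(np.full(len(wide), sid), wide[sid])
        corr = wide.corr().to_numpy()
        off = corr[~np.eye(len(corr), dtype=bool)]
        assert (off > 0).all()


class TestMakeReference:
    def test_uniform(self):
        ref = make_reference("uniform")
        assert np.allclose(ref.proportions, 1 / K_BINS)

    def test_match_cohort_equals_empirical_composition(self, fast_cohort):
        scores, _ = fast_cohort
        ref = make_reference("match_cohort", cohort=scores)
        per_user = scores.groupby("user_id").first()
        ks = assign_bins(per_user["age"], per_user["education_level"])
        ks = ks[ks >= 0]
        emp = np.bincount(ks, minlength=K_BINS) / ks.size
        assert np.allclose(ref.proportions, emp, atol=1e-12)

    def test_explicit_under_unit_mass_errors_or_renormalizes(self):
        vec = np.full(K_BINS, 0.9 / K_BINS)
        with pytest.raises(ValueError):
            make_reference("explicit", explicit=vec, strict=True)
        with pytest.warns(UserWarning, match="renormaliz"):
            ref = make_reference("explicit", explicit=vec, strict=False)
        assert ref.proportions.sum() == pytest.approx(1.0)

    def test_census_default_sums_to_one(self):
        assert make_reference("census").proportions.sum() == pytest.approx(1.0)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            make_reference("acs")
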