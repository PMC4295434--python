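"""Synthetic cohort generator: latent structure, trials, planted defects."""

import numpy as np
import pandas as pd
import pytest
import yaml
from scipy import stats

from tvasem.synthetic import (
    DEFAULT_LOADINGS,
    MEASURE_FACTORS,
    SyntheticCohortConfig,
    generate_battery_trials,
    generate_measure_table,
    generate_population,
    simulate_whole_report,
    write_cohort,
)
from tvasem.tva import TvaParams, score_distribution


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs,needle",
        [
            ({"n_participants": 2}, "n_participants"),
            ({"missing_rate": 1.5}, "missing_rate"),
            ({"trial_outlier_rate": -0.1}, "trial_outlier_rate"),
            ({"latent_resid_corr": 2.0}, "latent_resid_corr"),
            ({"age_range": (75.0, 60.0)}, "age_range"),
            ({"exposure_set_ms": ()}, "exposure_set_ms"),
            ({"measure_loadings": {"Nope": 0.5}}, "Nope"),
        ],
    )
    def test_invalid_config_names_the_parameter(self, kwargs, needle):
        cfg = SyntheticCohortConfig(**kwargs)
        with pytest.raises(ValueError, match=needle):
            cfg.validate()


class TestPopulation:
    def test_ages_respect_range_and_moments(self):
        cfg = SyntheticCohortConfig(n_participants=2000, seed=1)
        pop = generate_population(cfg)
        ages = np.array([p.age for p in pop])
        assert ages.min() >= 60 and ages.max() <= 75
        assert abs(ages.mean() - 67.8) < 0.3  # truncation pulls the mean slightly

    def test_null_age_effect_gives_null_correlation(self):
        cfg = SyntheticCohortConfig(
            n_participants=2000, beta_age_speed=0.0, beta_age_capacity=0.0, seed=2
        )
        pop = generate_population(cfg)
        ages = np.array([p.age for p in pop])
        speed = np.array([p.speed_latent for p in pop])
        assert abs(np.corrcoef(ages, speed)[0, 1]) < 3 / np.sqrt(len(pop))

    def test_default_age_effect_recovered_at_large_n(self):
        cfg = SyntheticCohortConfig(n_participants=5000, seed=3)
        pop = generate_population(cfg)
        ages = np.array([p.age for p in pop])
        speed = np.array([p.speed_latent for p in pop])
        assert np.corrcoef(ages, speed)[0, 1] == pytest.approx(-0.3, abs=0.04)

    def test_true_c_hits_natural_scale_targets(self):
        n = 5000
        cfg = SyntheticCohortConfig(n_participants=n, seed=4)
        pop = generate_population(cfg)
        c = np.array([p.true_C for p in pop])
        se_mean = 16.54 / np.sqrt(n)
        se_sd = 16.54 / np.sqrt(2 * n)
        assert abs(c.mean() - 43.21) < 3 * se_mean
        assert abs(c.std(ddof=1) - 16.54) < 3 * se_sd

    def test_parameter_invariants_hold(self):
        pop = generate_population(SyntheticCohortConfig(n_participants=500, seed=5))
        for p in pop:
            assert p.true_C > 0 and 0 < p.true_K <= 6 and p.true_t0 >= 0
            assert 0 <= p.true_laterality <= 1

    def test_deterministic_under_fixed_seed(self):
        cfg = SyntheticCohortConfig(n_participants=50, seed=6)
        a = generate_population(cfg)
        b = generate_population(cfg)
        assert all(
            (x.age, x.speed_latent, x.true_C, x.true_K, x.true_t0, x.true_laterality)
            == (y.age, y.speed_latent, y.true_C, y.true_K, y.true_t0, y.true_laterality)
            for x, y in zip(a, b)
        )


class TestWholeReportSimulation:
    def test_zero_effective_exposure_reports_nothing(self):
        p = TvaParams(60, 4, 20)
        trials = simulate_whole_report(p, [5], 50, seed=0)
        assert all(t.score == 0 for t in trials)

    def test_unbounded_capacity_and_speed_reports_everything(self):
        p = TvaParams(5000, 6, 0)
        trials = simulate_whole_report(p, [500], 50, seed=0)
        assert all(t.score == 6 for t in trials)

    def test_zero_score_probability_matches_closed_form(self):
        # p(item) = 1 - e^-1, so P(score 0) = e^-6
        p = TvaParams(60, 4.0, 10)
        n = 200_000
        trials = simulate_whole_report(p, [110], n, seed=1)
        p0 = np.mean([t.score == 0 for t in trials])
        target = np.exp(-6)
        assert abs(p0 - target) < 3 * np.sqrt(target * (1 - target) / n)

    def test_empirical_distribution_matches_score_distribution(self):
        params = TvaParams(43.21, 3.58, 21.9)
        n = 100_000
        trials = simulate_whole_report(params, [80], n, seed=2)
        counts = np.bincount([t.score for t in trials], minlength=7)
        probs = score_distribution(params, 80)
        keep = probs * n >= 5
        chi2 = np.sum((counts[keep] - n * probs[keep]) ** 2 / (n * probs[keep]))
        p = stats.chi2.sf(chi2, keep.sum() - 1)
        assert p > 0.01

    def test_reported_subset_of_displayed_and_sides(self):
        trials = simulate_whole_report(TvaParams(40, 3, 20), [80, 140], 30, seed=3, w=0.9)
        for t in trials:
            assert set(t.reported) <= set(t.displayed)
            assert len(set(t.displayed)) == 6
        # strong left bias: most correct reports from the left half
        left = sum(t.n_left_correct for t in trials)
        total = sum(t.score for t in trials)
        assert total > 0 and left / total > 0.7

    def test_empty_exposure_set_rejected(self):
        with pytest.raises(ValueError):
            simulate_whole_report(TvaParams(40, 3, 20), [], 10, seed=0)


class TestBatteryTrials:
    def test_random_responder_accuracy_near_guessing(self):
        cfg = SyntheticCohortConfig(
            n_participants=40, random_responder_rate=0.5, missing_rate=0.0, seed=7,
            trials_per_exposure=2,
        )
        pop = generate_population(cfg)
        tables = generate_battery_trials(pop, cfg)
        truth = tables["truth"].set_index("participant_id")
        acc = tables["dwm"].groupby("participant_id")["correct"].mean()
        rr = truth.index[truth["is_random_responder"]]
        assert len(rr) > 5
        # underlying rate is the 0.25 guessing level; observed trial means
        # scatter with binomial noise around it
        assert abs(acc[rr].mean() - 0.25) <= 0.08
        sd = np.sqrt(0.25 * 0.75 / 55)
        for pid in rr:
            assert abs(acc[pid] - 0.25) <= 4 * sd

    def test_no_outliers_when_rate_zero(self):
        cfg = SyntheticCohortConfig(
            n_participants=20, trial_outlier_rate=0.0, seed=8, trials_per_exposure=2
        )
        pop = generate_population(cfg)
        tables = generate_battery_trials(pop, cfg)
        assert tables["truth"]["n_planted_dwm_outliers"].sum() == 0
        assert not tables["dwm"]["planted_outlier"].any()

    def test_planted_outlier_count_is_binomial(self):
        cfg = SyntheticCohortConfig(seed=9, trials_per_exposure=2)
        pop = generate_population(cfg)
        tables = generate_battery_trials(pop, cfg)
        n_trials = len(tables["dwm"])
        expected = 0.03 * n_trials
        sd = np.sqrt(n_trials * 0.03 * 0.97)
        realized = int(tables["dwm"]["planted_outlier"].sum())
        assert abs(realized - expected) < 3 * sd
        # and against the nominal full-battery count 0.03 * 55 * 112
        nominal = 0.03 * 55 * 112
        assert abs(realized - nominal) < 3 * np.sqrt(nominal) + 0.05 * nominal

    def test_mcar_masks_whole_tests_jointly(self, small_config):
        pop = generate_population(small_config)
        tables = generate_battery_trials(pop, small_config)
        truth = tables["truth"].set_index("participant_id")
        dwm_pids = set(tables["dwm"]["participant_id"])
        for pid, row in truth.iterrows():
            masked = set(row["masked_tests"].split(";")) if row["masked_tests"] else set()
            assert (pid not in dwm_pids) == ("DWM" in masked)
        subj = tables["subject"].set_index("participant_id")
        memo_nan = subj["Memo_Time"].isna()
        miss_nan = subj["Memo_Misses"].isna()
        assert (memo_nan == miss_nan).all()

    def test_tables_bit_identical_under_fixed_seed(self, small_config):
        pop = generate_population(small_config)
        t1 = generate_battery_trials(pop, small_config)
        t2 = generate_battery_trials(generate_population(small_config), small_config)
        for k in t1:
            pd.testing.assert_frame_equal(t1[k], t2[k])


class TestMeasureTable:
    def test_same_factor_measures_correlate_after_sign_alignment(self):
        cfg = SyntheticCohortConfig(
            n_participants=3000, missing_rate=0.0, random_responder_rate=0.0, seed=10
        )
        pop = generate_population(cfg)
        tab = generate_measure_table(pop, cfg)
        for factor in ("speed", "capacity"):
            ms = [m for m, f in MEASURE_FACTORS.items() if f == factor]
            for i, a in enumerate(ms):
                for b in ms[i + 1 :]:
                    r = tab[a].corr(tab[b])
                    assert np.sign(DEFAULT_LOADINGS[a] * DEFAULT_LOADINGS[b]) * r > 0.1

    def test_missingness_rate_is_respected(self):
        cfg = SyntheticCohortConfig(n_participants=2000, missing_rate=0.2, seed=11)
        pop = generate_population(cfg)
        tab = generate_measure_table(pop, cfg)
        frac = tab["Memo_Time"].isna().mean()
        assert abs(frac - 0.2) < 3 * np.sqrt(0.2 * 0.8 / 2000)


def test_write_cohort_roundtrip(tmp_path, small_config):
    pop = generate_population(small_config)
    tables = generate_battery_trials(pop, small_config)
    write_cohort(tables, small_config, tmp_path)
    for name in ("dwm", "fm", "whole_report", "subject", "truth"):
        assert (tmp_path / f"{name}.csv").exists()
    cfg = yaml.safe_load((tmp_path / "config.yaml").read_text())
    assert cfg["n_participants"] == small_config.n_participants
    wr = pd.read_csv(tmp_path / "whole_report.csv")
    assert set(wr.columns) == {"participant_id", "exposure_ms", "displayed", "reported"}
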