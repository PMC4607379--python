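"""Daily score estimator: rolling prediction, correction by observed items,
variance/CI construction, flags, and agreement with brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from ema_phq9 import (
    CohortConfig,
    DEFAULT_DESIGN,
    DailyScoreEstimate,
    daily_item_means,
    day_variance_ci,
    estimate_cohort,
    estimate_day,
    flag_day,
    generate_cohort,
    naive_day,
    predict_item,
)
from ema_phq9.score_estimation import item_window_variance

from conftest import make_records, roster_of

Z95 = 1.959963984540054


# --- independent brute-force oracles (explicit loops, no shared code path) ---

def brute_predict(means_by_day, day, window=14, fallback=1.5):
    vals = []
    for d in range(max(1, day - window), day):
        if d in means_by_day:
            vals.append(means_by_day[d])
    if not vals:
        return fallback
    return sum(vals) / len(vals)


def brute_variance(means_by_day, day, window=14):
    vals = []
    for d in range(max(1, day - window), day):
        if d in means_by_day:
            vals.append(means_by_day[d])
    if len(vals) < 2:
        return 0.0
    mean = sum(vals) / len(vals)
    return sum((v - mean) ** 2 for v in vals) / (len(vals) - 1)


def random_history(gen, max_day=40):
    days = sorted(
        gen.choice(np.arange(1, max_day), size=gen.integers(0, 12), replace=False)
    )
    return {int(d): float(gen.uniform(0, 3)) for d in days}


class TestDailyItemMeans:
    def test_single_and_repeated_items(self):
        df = make_records(
            [("A", 4, "morning", 3, 2), ("A", 4, "evening", 3, 3),
             ("A", 4, "morning", 5, 1)]
        )
        out = daily_item_means(df)
        assert out[3] == (2.5, 2)
        assert out[5] == (1.0, 1)

    def test_empty_day(self):
        assert daily_item_means(make_records([]).head(0)) == {}

    def test_mixed_days_rejected(self):
        df = make_records([("A", 1, "morning", 1, 1), ("A", 2, "morning", 1, 1)])
        with pytest.raises(ValueError):
            daily_item_means(df)


class TestPredictItem:
    def test_constant_history(self):
        assert predict_item({d: 2.0 for d in range(1, 8)}, 8) == 2.0

    def test_mean_of_window_days(self):
        assert predict_item({5: 1.0, 6: 2.0, 7: 3.0}, 8) == pytest.approx(2.0)

    def test_no_history_returns_fallback(self):
        assert predict_item({}, 5, fallback=1.25) == 1.25

    def test_window_excludes_current_day_and_old_days(self):
        # day 20: window is days 6..19; day 5 and day 20 must not count
        hist = {5: 3.0, 10: 1.0, 20: 3.0}
        assert predict_item(hist, 20) == 1.0

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(200):
            hist = random_history(rng)
            day = int(rng.integers(1, 41))
            assert predict_item(hist, day) == pytest.approx(
                brute_predict(hist, day), abs=1e-12
            )
            assert item_window_variance(hist, day) == pytest.approx(
                brute_variance(hist, day), abs=1e-12
            )


class TestDayVarianceCI:
    def test_constant_histories_collapse_ci(self):
        hists = {i: {d: 1.0 for d in range(1, 10)} for i in range(1, 10)}
        var, lo, hi = day_variance_ci(hists, 10)
        assert var == 0.0
        assert lo == hi == pytest.approx(9.0)

    def test_single_varying_item(self):
        hists = {i: {1: 1.0, 2: 1.0} for i in range(1, 9)}
        hists[9] = {1: 0.0, 2: 2.0}
        var, lo, hi = day_variance_ci(hists, 3)
        assert var == pytest.approx(2.0)
        half = Z95 * np.sqrt(2.0)
        assert half == pytest.approx(2.7718, abs=1e-3)
        pred = 8 * 1.0 + 1.0
        assert lo == pytest.approx(pred - half)
        assert hi == pytest.approx(pred + half)

    def test_truncation_to_scale(self):
        hists = {i: {1: 0.0, 2: 3.0} for i in range(1, 10)}
        _, lo, hi = day_variance_ci(hists, 3)
        assert lo >= 0.0 and hi <= 27.0

    def test_bad_level_rejected(self):
        with pytest.raises(ValueError):
            day_variance_ci({1: {}}, 2, level=1.5)


class TestNaiveDay:
    def test_full_coverage_is_plain_sum(self):
        means = {i: (float(v), 1) for i, v in zip(range(1, 10), [3, 3, 2, 2, 2, 1, 1, 1, 0])}
        assert naive_day(means) == pytest.approx(15.0)

    def test_partial_coverage_is_upweighted(self):
        means = {1: (3.0, 1), 2: (3.0, 1), 3: (3.0, 1)}
        assert naive_day(means) == pytest.approx(27.0)

    def test_no_items_absent(self):
        assert naive_day({}) is None


class TestEstimateDay:
    def test_exact_recovery_with_full_day(self):
        values = [3, 3, 2, 2, 2, 1, 1, 1, 0]
        rows = [("A", d, "morning", 1 + (d % 9), 2) for d in range(1, 20)]
        rows += [("A", 20, "morning", i, v) for i, v in zip(range(1, 10), values)]
        est = estimate_day(make_records(rows), 20)
        assert est.estimate == pytest.approx(15.0, abs=1e-12)
        assert est.n_items_observed == 9

    def test_no_responses_estimate_equals_prediction(self):
        rows = [("A", d, "morning", i, 1) for d in range(1, 5) for i in range(1, 10)]
        est = estimate_day(make_records(rows), 6)
        assert est.n_items_observed == 0
        assert est.estimate == est.prediction

    def test_hand_arithmetic_partial_day(self):
        # constant history of 1s -> every prediction 1.0; observing items
        # 1..3 at 3 shifts the estimate by (3-1) per observed item
        rows = [("A", d, "morning", i, 1) for d in range(1, 10) for i in range(1, 10)]
        rows += [("A", 10, "morning", i, 3) for i in (1, 2, 3)]
        est = estimate_day(make_records(rows), 10)
        assert est.prediction == pytest.approx(9.0)
        assert est.estimate == pytest.approx(15.0)
        assert est.naive_estimate == pytest.approx(27.0)

    def test_invalid_day_rejected(self):
        with pytest.raises(ValueError):
            estimate_day(make_records([]), 0)

    def test_repeated_item_collapses_to_daily_mean(self):
        # item 1 answered 0 and 2 in two sessions: one difference term from
        # its daily mean 1.0, keeping the estimate within scale
        rows = [("A", d, "morning", i, 1) for d in range(1, 10) for i in range(1, 10)]
        rows += [("A", 10, "morning", 1, 0), ("A", 10, "evening", 1, 2)]
        est = estimate_day(make_records(rows), 10)
        assert est.prediction == pytest.approx(9.0)
        assert est.estimate == pytest.approx(9.0)  # mean 1.0 equals prediction
        assert est.n_items_observed == 1


class TestFlags:
    def _est(self, estimate, lo, hi):
        return DailyScoreEstimate(
            "A", 15, prediction=(lo + hi) / 2, estimate=estimate,
            naive_estimate=None, variance=1.0, ci_low=lo, ci_high=hi,
            n_items_observed=3,
        )

    @pytest.mark.parametrize(
        "estimate,expected",
        [(10.0, "none"), (14.1, "high"), (5.9, "low"), (14.0, "none"), (6.0, "none")],
    )
    def test_deviation_against_ci(self, estimate, expected):
        assert flag_day(self._est(estimate, 6.0, 14.0)).deviates == expected

    def test_suicidality_from_item9_threshold(self):
        base = [("A", 3, "morning", 1, 1)]
        flagged = flag_day(
            self._est(10, 6, 14),
            make_records(base + [("A", 3, "evening", 9, 2)]),
        )
        assert flagged.suicidality_flag
        unflagged = flag_day(
            self._est(10, 6, 14),
            make_records(base + [("A", 3, "evening", 9, 1)]),
        )
        assert not unflagged.suicidality_flag


class TestEstimateCohort:
    def test_study_layout_yields_387_rows(self, default_cohort):
        est = estimate_cohort(
            default_cohort.responses, roster=roster_of(default_cohort.config)
        )
        assert len(est) == 10 * 30 + 3 * 29 == 387
        key = est[["subject_id", "study_day"]]
        assert not key.duplicated().any()
        assert key.equals(key.sort_values(["subject_id", "study_day"],
                                          ignore_index=True))

    def test_empty_table_cold_start(self):
        empty = make_records([]).head(0)
        est = estimate_cohort(empty, roster={"A": 16})
        assert len(est) == 16
        assert np.allclose(est["prediction"], 13.5)  # 9 * scale midpoint
        assert est["burn_in"].iloc[:14].all()
        assert not est["burn_in"].iloc[14:].any()

    def test_scores_stay_on_scale(self, default_cohort):
        est = estimate_cohort(
            default_cohort.responses, roster=roster_of(default_cohort.config)
        )
        assert est["prediction"].between(0, 27).all()
        assert est["estimate"].between(0, 27).all()
        assert (est["variance"] >= 0).all()
        assert (est["ci_low"] <= est["prediction"] + 1e-12).all()
        assert (est["prediction"] <= est["ci_high"] + 1e-12).all()

    def test_exact_recovery_over_randomized_histories(self, rng):
        # whenever all 9 items are observed once, the estimate is the plain
        # PHQ-9 sum regardless of history
        for _ in range(50):
            day = int(rng.integers(1, 31))
            rows = []
            for d in range(1, day):
                for item in rng.choice(9, size=rng.integers(0, 4), replace=False):
                    rows.append(("A", d, "morning", int(item) + 1,
                                 int(rng.integers(0, 4))))
            values = rng.integers(0, 4, size=9)
            slots = ["morning", "afternoon", "evening"]
            for i, v in enumerate(values):
                rows.append(("A", day, slots[i % 3], i + 1, int(v)))
            est = estimate_day(make_records(rows), day)
            assert est.estimate == pytest.approx(float(values.sum()), abs=1e-12)

    def test_full_day_agreement_with_independent_recomputation(self, rng):
        # brute-force the whole per-day pipeline for one synthetic subject
        cohort = generate_cohort(CohortConfig(seed=3))
        sid = "S01"
        sub = cohort.responses[cohort.responses["subject_id"] == sid]
        est = estimate_cohort(sub, roster={sid: 30})
        # per-day per-item means via explicit loops
        means = {}
        for row in sub.itertuples():
            means.setdefault(row.item_id, {}).setdefault(row.study_day, []).append(
                row.canonical_value
            )
        hist = {
            item: {d: sum(v) / len(v) for d, v in by_day.items()}
            for item, by_day in means.items()
        }
        for day in range(1, 31):
            preds, var = {}, 0.0
            prior_cells = [
                v for by_day in hist.values() for d, v in by_day.items() if d < day
            ]
            for item in range(1, 10):
                by_day = hist.get(item, {})
                windowed = [v for d, v in by_day.items() if day - 14 <= d < day]
                if windowed:
                    preds[item] = sum(windowed) / len(windowed)
                else:
                    all_prior = [v for d, v in by_day.items() if d < day]
                    if all_prior:
                        preds[item] = sum(all_prior) / len(all_prior)
                    elif prior_cells:
                        preds[item] = sum(prior_cells) / len(prior_cells)
                    else:
                        preds[item] = 1.5
                var += brute_variance(by_day, day)
            prediction = sum(preds.values())
            estimate = sum(
                hist[i][day] if i in hist and day in hist[i] else preds[i]
                for i in range(1, 10)
            )
            row = est[est["study_day"] == day].iloc[0]
            assert row["prediction"] == pytest.approx(prediction, abs=1e-10)
            assert row["estimate"] == pytest.approx(estimate, abs=1e-10)
            assert row["variance"] == pytest.approx(var, abs=1e-10)

    def test_ci_covers_truth_in_stationary_regime(self):
        # with no day-to-day autocorrelation the 95% band around the
        # prediction covers the latent truth well above 80% of the time
        hits = total = 0
        for seed in range(5):
            cohort = generate_cohort(CohortConfig(seed=seed, ar_coefficient=0.0))
            est = estimate_cohort(
                cohort.responses, roster=roster_of(cohort.config)
            )
            merged = est.merge(
                cohort.truth[["subject_id", "study_day", "latent_total"]],
                on=["subject_id", "study_day"],
            )
            merged = merged[~merged["burn_in"]]
            inside = (merged["latent_total"] >= merged["ci_low"]) & (
                merged["latent_total"] <= merged["ci_high"]
            )
            hits += int(inside.sum())
            total += len(merged)
        assert total > 1000
        assert hits / total >= 0.80

    def test_estimator_beats_naive_on_partial_days(self):
        # smaller companion to the acceptance check: 3 seeds
        for seed in (0, 1, 2):
            cohort = generate_cohort(CohortConfig(seed=seed))
            est = estimate_cohort(
                cohort.responses, roster=roster_of(cohort.config)
            )
            merged = est.merge(
                cohort.truth[["subject_id", "study_day", "latent_total"]],
                on=["subject_id", "study_day"],
            )
            part = merged[merged["n_items_observed"].between(1, 8)]
            mse_est = ((part["estimate"] - part["latent_total"]) ** 2).mean()
            mse_naive = ((part["naive_estimate"] - part["latent_total"]) ** 2).mean()
            assert mse_est < mse_naive
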