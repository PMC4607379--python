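"""Daily PHQ-9 score estimation from planned-missingness EMA responses.

Because each session presents only 3 of the 9 items, a day rarely yields a
complete questionnaire.  The estimator works strictly within subject:

1. *Prediction.*  Each item's response for day *d* is predicted by the mean
   of that item's daily means over the trailing 14 days (days d-14 .. d-1),
   never using day *d* itself.  The predicted total is the sum of the nine
   per-item predictions.
2. *Estimate.*  The daily score estimate is the prediction plus the sum of
   differences between each observed item's daily mean and its prediction —
   equivalently, observed items replace their predictions.  When every item
   is answered exactly once in a day, the estimate reduces to the plain
   PHQ-9 sum.
3. *Uncertainty.*  Each item's variance is the sample variance of its daily
   means over the same trailing window; the predicted total's variance is the
   sum over all nine items, and the confidence interval is the prediction
   ± z * sqrt(variance), truncated to [0, 27].
4. *Flags.*  A day deviates (high/low) when the estimate leaves the CI, and
   carries a suicidality flag when any canonical response to item 9 that day
   reaches 2.

Within-day repeats of an item are collapsed to their daily mean and
contribute a single difference term; this keeps both the 0-27 range and the
exact-recovery property when an item is asked more than once per day.  Days
1..window_days use whatever shorter history exists (cold start) and are
marked ``burn_in``.  When an item has no window history at all the prediction
falls back, in order, to the subject's all-time prior mean for that item,
the subject's prior mean over all items, then the scale midpoint 1.5.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import norm

from .study_design import StudyDesign, DEFAULT_DESIGN

SCALE_MIDPOINT = 1.5

ESTIMATE_COLUMNS = [
    "subject_id",
    "study_day",
    "prediction",
    "estimate",
    "naive_estimate",
    "variance",
    "ci_low",
    "ci_high",
    "n_items_observed",
    "deviates",
    "suicidality_flag",
    "burn_in",
]


@dataclass
class ItemHistory:
    """Per-day observed mean canonical values of one item for one subject."""

    subject_id: str
    item_id: int
    daily_means: dict[int, float]


@dataclass
class DailyScoreEstimate:
    subject_id: str
    study_day: int
    prediction: float
    estimate: float
    naive_estimate: float | None
    variance: float
    ci_low: float
    ci_high: float
    n_items_observed: int
    deviates: str = "none"
    suicidality_flag: bool = False
    burn_in: bool = False


def daily_item_means(records: pd.DataFrame) -> dict[int, tuple[float, int]]:
    """Collapse one subject-day's canonical responses to per-item (mean, count)."""
    if len(records) == 0:
        return {}
    if records["subject_id"].nunique() > 1 or records["study_day"].nunique() > 1:
        raise ValueError("records must all belong to one subject-day")
    grouped = records.groupby("item_id")["canonical_value"]
    return {
        int(item): (float(vals.mean()), int(vals.size))
        for item, vals in grouped
    }


def predict_item(
    history: ItemHistory | Mapping[int, float],
    day: int,
    window_days: int = 14,
    fallback: float = SCALE_MIDPOINT,
) -> float:
    """Mean of the item's daily means over the trailing window before ``day``.

    Only days strictly before ``day`` (and at most ``window_days`` back) with
    observations contribute; with no such day the ``fallback`` is returned.
    """
    if day < 1:
        raise ValueError("day must be >= 1")
    means = history.daily_means if isinstance(history, ItemHistory) else history
    window = [
        means[d] for d in range(max(1, day - window_days), day) if d in means
    ]
    if not window:
        return float(fallback)
    return float(np.mean(window))


def item_window_variance(
    history: ItemHistory | Mapping[int, float], day: int, window_days: int = 14
) -> float:
    """Sample variance (ddof=1) of the item's window daily means; 0 if < 2 days."""
    means = history.daily_means if isinstance(history, ItemHistory) else history
    window = [
        means[d] for d in range(max(1, day - window_days), day) if d in means
    ]
    if len(window) < 2:
        return 0.0
    return float(np.var(window, ddof=1))


def day_variance_ci(
    histories: Mapping[int, Mapping[int, float]],
    day: int,
    window_days: int = 14,
    level: float = 0.95,
    fallback: float = SCALE_MIDPOINT,
) -> tuple[float, float, float]:
    """Variance of the predicted total and its CI, truncated to [0, 27].

    ``histories`` maps item id -> {day -> daily mean}.  The interval is
    centred on the predicted total (sum of per-item window means).
    """
    if not (0.0 < level < 1.0):
        raise ValueError("confidence level must lie in (0, 1)")
    prediction = sum(
        predict_item(h, day, window_days, fallback) for h in histories.values()
    )
    variance = sum(
        item_window_variance(h, day, window_days) for h in histories.values()
    )
    z = norm.ppf(0.5 + level / 2.0)
    half = z * float(np.sqrt(variance))
    return variance, max(0.0, prediction - half), min(27.0, prediction + half)


def naive_day(
    day_means: Mapping[int, tuple[float, int]], design: StudyDesign = DEFAULT_DESIGN
) -> float | None:
    """Missingness-weighted daily sum: (n_items/m) * sum of observed item means.

    Returns None when no item was observed that day.
    """
    m = len(day_means)
    if m == 0:
        return None
    total = sum(mean for mean, _ in day_means.values())
    return design.n_items / m * total


def flag_day(
    est: DailyScoreEstimate,
    day_records: pd.DataFrame | None = None,
    design: StudyDesign = DEFAULT_DESIGN,
) -> DailyScoreEstimate:
    """Set the deviation and suicidality flags on a populated estimate."""
    if est.estimate > est.ci_high:
        est.deviates = "high"
    elif est.estimate < est.ci_low:
        est.deviates = "low"
    else:
        est.deviates = "none"
    if day_records is not None and len(day_records):
        item9 = day_records[day_records["item_id"] == design.suicidality_item]
        est.suicidality_flag = bool(
            (item9["canonical_value"] >= design.suicidality_threshold).any()
        )
    return est


def _subject_matrices(
    sub: pd.DataFrame, n_days: int, design: StudyDesign
) -> tuple[np.ndarray, np.ndarray]:
    """(n_days x n_items) matrices of daily mean canonical values and suicidality
    day flags; NaN marks an unobserved item-day."""
    means = np.full((n_days + 1, design.n_items + 1), np.nan)  # 1-based indexing
    flags = np.zeros(n_days + 1, dtype=bool)
    g = sub.groupby(["study_day", "item_id"])["canonical_value"]
    for (day, item), vals in g:
        means[day, item] = vals.mean()
        if item == design.suicidality_item:
            flags[day] = bool((vals >= design.suicidality_threshold).any())
    return means, flags


def estimate_subject(
    sub: pd.DataFrame,
    n_days: int,
    design: StudyDesign = DEFAULT_DESIGN,
    window_days: int = 14,
    level: float = 0.95,
) -> list[DailyScoreEstimate]:
    """Daily estimates for one subject over days 1..n_days."""
    if not (0.0 < level < 1.0):
        raise ValueError("confidence level must lie in (0, 1)")
    sid = sub["subject_id"].iloc[0] if len(sub) else ""
    means, sflags = _subject_matrices(sub, n_days, design)
    z = norm.ppf(0.5 + level / 2.0)
    out = []
    for day in range(1, n_days + 1):
        lo_day = max(1, day - window_days)
        window = means[lo_day:day, 1:]          # rows strictly before `day`
        prior = means[1:day, 1:]                # all-time prior, for fallback
        win_n = (
            np.sum(~np.isnan(window), axis=0)
            if window.size
            else np.zeros(design.n_items, dtype=int)
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            win_mean = np.where(
                win_n > 0,
                np.nansum(window, axis=0) / np.maximum(win_n, 1)
                if window.size
                else np.nan,
                np.nan,
            )
        win_var = np.full(design.n_items, 0.0)
        enough = win_n >= 2
        if enough.any():
            centered = window[:, enough] - win_mean[enough]
            win_var[enough] = np.nansum(centered**2, axis=0) / (win_n[enough] - 1)
        prior_n = (
            np.sum(~np.isnan(prior), axis=0)
            if prior.size
            else np.zeros(design.n_items, dtype=int)
        )
        prior_item = np.where(
            prior_n > 0,
            (np.nansum(prior, axis=0) if prior.size else 0.0)
            / np.maximum(prior_n, 1),
            np.nan,
        )
        prior_all = (
            float(np.nansum(prior) / prior_n.sum()) if prior_n.sum() else np.nan
        )

        preds = win_mean.copy()
        missing = np.isnan(preds)
        preds[missing] = prior_item[missing]
        missing = np.isnan(preds)
        preds[missing] = prior_all if not np.isnan(prior_all) else SCALE_MIDPOINT

        today = means[day, 1:]
        observed = ~np.isnan(today)
        prediction = float(preds.sum())
        # observed items replace their predictions (equivalently: prediction
        # plus the sum of observed-minus-predicted differences)
        estimate = float(np.where(observed, today, preds).sum())
        m = int(observed.sum())
        naive = (
            float(design.n_items / m * today[observed].sum()) if m else None
        )
        variance = float(win_var.sum())
        half = z * float(np.sqrt(variance))
        est = DailyScoreEstimate(
            subject_id=sid,
            study_day=day,
            prediction=prediction,
            estimate=estimate,
            naive_estimate=naive,
            variance=variance,
            ci_low=max(0.0, prediction - half),
            ci_high=min(27.0, prediction + half),
            n_items_observed=m,
            suicidality_flag=bool(sflags[day]),
            burn_in=day <= window_days,
        )
        flag_day(est, day_records=None, design=design)
        out.append(est)
    return out


def estimate_day(
    records: pd.DataFrame,
    day: int,
    design: StudyDesign = DEFAULT_DESIGN,
    window_days: int = 14,
    level: float = 0.95,
) -> DailyScoreEstimate:
    """Estimate one subject-day from that subject's responses up to ``day``."""
    if day < 1:
        raise ValueError("day must be >= 1")
    sub = records[records["study_day"] <= day]
    return estimate_subject(sub, day, design, window_days, level)[-1]


def estimate_cohort(
    records: pd.DataFrame,
    design: StudyDesign = DEFAULT_DESIGN,
    window_days: int = 14,
    level: float = 0.95,
    roster: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """One DailyScoreEstimate row per subject per study day, sorted, no gaps.

    ``roster`` maps subject_id -> number of study days; inferred from the
    maximum observed day per subject when omitted.  Days with zero responses
    still yield a row (estimate = prediction).
    """
    if roster is None:
        roster = records.groupby("subject_id")["study_day"].max().to_dict()
    rows = []
    for sid in sorted(roster):
        sub = records[records["subject_id"] == sid]
        for est in estimate_subject(sub, int(roster[sid]), design, window_days, level):
            est.subject_id = sid
            rows.append(est.__dict__)
    df = pd.DataFrame(rows, columns=ESTIMATE_COLUMNS)
    return df.sort_values(["subject_id", "study_day"], ignore_index=True)
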