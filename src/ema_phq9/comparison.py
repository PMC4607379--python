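"""App-vs-clinic comparison of PHQ-9 scores.

Each subject contributes the mean of their daily app score estimates over the
study and the mean of their two clinic ("paper") administrations.  The
comparison reports the mean and SD of the per-subject app-minus-clinic
differences, the Pearson correlation of the per-subject means with a CI from
the variance-stabilizing (Fisher z) transform, and a cross-tabulation of
suicidal-ideation flags (app: any study day flagged; clinic: item 9 >= 2 on
either administration).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, pearsonr


@dataclass
class ComparisonResult:
    per_subject: pd.DataFrame          # subject_id, app_mean, clinic_mean
    mean_difference: float             # points, app - clinic
    sd_difference: float               # sample SD of per-subject differences
    pearson_r: float
    r_ci_low: float | None
    r_ci_high: float | None
    n_subjects: int
    suicidality_app: int = 0
    suicidality_clinic: int = 0

    def to_dict(self) -> dict:
        return {
            "n_subjects": self.n_subjects,
            "mean_difference": self.mean_difference,
            "sd_difference": self.sd_difference,
            "pearson_r": self.pearson_r,
            "r_ci_low": self.r_ci_low,
            "r_ci_high": self.r_ci_high,
            "suicidality_app": self.suicidality_app,
            "suicidality_clinic": self.suicidality_clinic,
            "per_subject": self.per_subject.to_dict(orient="records"),
        }


def fisher_r_ci(
    r: float, n: int, level: float = 0.95
) -> tuple[float | None, float | None]:
    """CI for a Pearson correlation via the variance-stabilizing transform.

    arctanh(r) +/- z * 1/sqrt(n-3), mapped back with tanh.  Unavailable
    (None, None) when n < 4.
    """
    if n < 4:
        return None, None
    if abs(r) >= 1.0:
        return float(r), float(r)  # degenerate: transform diverges
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(n - 3)
    q = norm.ppf(0.5 + level / 2.0)
    return float(np.tanh(z - q * se)), float(np.tanh(z + q * se))


def compare(
    estimates: pd.DataFrame,
    clinic: pd.DataFrame,
    quantity: str = "estimate",
    exclude_burn_in: bool = False,
    level: float = 0.95,
) -> ComparisonResult:
    """Compare per-subject mean app scores with mean clinic PHQ-9 totals.

    ``quantity`` selects the app-side daily column (``estimate`` by default;
    ``prediction`` or ``naive_estimate`` for sensitivity checks).  All study
    days enter the app mean unless ``exclude_burn_in``.
    """
    app = estimates
    if exclude_burn_in:
        app = app[~app["burn_in"]]
    app_means = app.groupby("subject_id")[quantity].mean()
    clinic_means = clinic.groupby("subject_id")["phq9_total"].mean()

    if set(app_means.index) != set(clinic_means.index):
        missing = set(app_means.index) ^ set(clinic_means.index)
        raise ValueError(f"mismatched subject sets: {sorted(missing)}")

    per_subject = pd.DataFrame(
        {
            "subject_id": sorted(app_means.index),
            "app_mean": app_means.sort_index().to_numpy(),
            "clinic_mean": clinic_means.sort_index().to_numpy(),
        }
    )
    diffs = per_subject["app_mean"] - per_subject["clinic_mean"]
    n = len(per_subject)
    if (
        per_subject["app_mean"].nunique() < 2
        or per_subject["clinic_mean"].nunique() < 2
    ):
        r, lo, hi = float("nan"), None, None  # correlation undefined
    else:
        r = float(
            pearsonr(per_subject["app_mean"], per_subject["clinic_mean"]).statistic
        )
        lo, hi = fisher_r_ci(r, n, level)
    return ComparisonResult(
        per_subject=per_subject,
        mean_difference=float(diffs.mean()),
        sd_difference=float(diffs.std(ddof=1)) if n > 1 else float("nan"),
        pearson_r=r,
        r_ci_low=lo,
        r_ci_high=hi,
        n_subjects=n,
    )


def suicidality_crosstab(
    estimates: pd.DataFrame, clinic: pd.DataFrame, clinic_threshold: int = 2
) -> dict[str, int]:
    """Counts of subjects flagged app-only / clinic-only / both / neither.

    App flag: any study day with suicidality_flag true.  Clinic flag: item 9
    at or above ``clinic_threshold`` on any administration (requires an
    ``item9`` column).
    """
    app_flag = estimates.groupby("subject_id")["suicidality_flag"].any()
    if "item9" in clinic.columns:
        clinic_flag = clinic.groupby("subject_id")["item9"].apply(
            lambda s: bool((s >= clinic_threshold).any())
        )
    else:
        clinic_flag = pd.Series(False, index=app_flag.index)
    subjects = sorted(set(app_flag.index) | set(clinic_flag.index))
    a = app_flag.reindex(subjects, fill_value=False)
    c = clinic_flag.reindex(subjects, fill_value=False)
    return {
        "app_only": int((a & ~c).sum()),
        "clinic_only": int((~a & c).sum()),
        "both": int((a & c).sum()),
        "neither": int((~a & ~c).sum()),
    }
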