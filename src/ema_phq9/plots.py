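"""Optional matplotlib figures: daily score band and app-vs-clinic scatter."""

from __future__ import annotations

from pathlib import Path

import pandas as pd


def plot_subject_trajectory(
    estimates: pd.DataFrame, subject_id: str, path: str | Path, window_days: int = 14
) -> None:
    """Daily prediction with CI band, estimates, and suicidality markers."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = estimates[estimates["subject_id"] == subject_id]
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.fill_between(
        sub["study_day"], sub["ci_low"], sub["ci_high"], alpha=0.25,
        label="95% CI", color="tab:blue",
    )
    ax.plot(sub["study_day"], sub["prediction"], label="prediction",
            color="tab:blue")
    ax.plot(sub["study_day"], sub["estimate"], "o-", ms=3, label="estimate",
            color="tab:orange")
    flagged = sub[sub["suicidality_flag"]]
    if len(flagged):
        ax.plot(flagged["study_day"], flagged["estimate"], "D", color="red",
                label="suicidal ideation", ms=6)
    ax.axvline(window_days + 0.5, color="gray", ls="--", lw=1)
    ax.set_xlabel("study day")
    ax.set_ylabel("PHQ-9 score")
    ax.set_ylim(-1, 28)
    ax.set_title(f"Daily PHQ-9 estimates, subject {subject_id}")
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_app_vs_clinic(per_subject: pd.DataFrame, path: str | Path) -> None:
    """Scatter of per-subject mean app vs clinic scores with the identity line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(per_subject["clinic_mean"], per_subject["app_mean"])
    lim = max(per_subject[["clinic_mean", "app_mean"]].max().max() + 2, 10)
    ax.plot([0, lim], [0, lim], color="gray", lw=1)
    ax.set_xlabel("mean clinic PHQ-9")
    ax.set_ylabel("mean app PHQ-9")
    ax.set_title("App vs clinic PHQ-9 by subject")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
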