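"""Adherence analysis: completion rates overall, by slot, subject, and day.

Also reproduces the design arithmetic of the original study layout (90
sessions per full-duration subject; 1161 scheduled cohort sessions) and runs
the time-of-day one-way ANOVA on per-subject slot completion rates.

Writes results/adherence/{overall,by_slot,by_subject,by_day,grid}.csv.
"""

import pandas as pd

from ema_phq9 import (
    adherence,
    per_subject_slot_rates,
    scheduled_sessions,
    slot_anova,
)

from _common import RESULTS, load_cohort_tables, roster_of, study_config


def main() -> None:
    responses, _, _ = load_cohort_tables()
    config = study_config()
    roster = roster_of(config)
    report = adherence(responses, roster=roster)

    out = RESULTS / "adherence"
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame([{
        "scheduled": report.overall.scheduled,
        "completed": report.overall.completed,
        "rate_pct": report.overall.rate,
    }]).to_csv(out / "overall.csv", index=False)
    report.by_slot.to_csv(out / "by_slot.csv", index=False)
    report.by_subject.to_csv(out / "by_subject.csv", index=False)
    report.by_day.to_csv(out / "by_day.csv", index=False)
    report.grid.to_csv(out / "grid.csv", index=False)

    print(f"design arithmetic: {scheduled_sessions({'solo': 30})} sessions "
          f"per 30-day subject; {scheduled_sessions(roster)} scheduled "
          "for the cohort")
    print(f"overall adherence: {report.overall.completed}/"
          f"{report.overall.scheduled} = {report.overall.rate:.2f}%")
    for row in report.by_slot.itertuples():
        print(f"  {row.slot}: {row.completed}/{row.scheduled} "
              f"= {row.rate_pct:.1f}%")
    f, p = slot_anova(per_subject_slot_rates(report))
    print(f"time-of-day ANOVA on per-subject slot rates: "
          f"F = {f:.2f}, p = {p:.4f}")


if __name__ == "__main__":
    main()
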