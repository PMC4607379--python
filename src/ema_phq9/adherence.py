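"""Adherence accounting: scheduled vs completed survey sessions.

A session is scheduled for every (subject, study day, slot) triple on the
roster and counted completed when at least one response record exists for it.
Rates are reported as percentages at cohort, slot, subject, and day
granularity, plus the full subject x slot x day grid.  The time-of-day
comparison is a one-way ANOVA across slots on per-subject slot-level rates,
with subjects as the replication unit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import f_oneway

from .study_design import StudyDesign, DEFAULT_DESIGN


@dataclass(frozen=True)
class AdherenceSummary:
    scheduled: int
    completed: int
    grouping: str = "overall"

    @property
    def rate(self) -> float:
        """Completion rate as a percentage."""
        return 100.0 * self.completed / self.scheduled


@dataclass
class AdherenceReport:
    overall: AdherenceSummary
    by_slot: pd.DataFrame
    by_subject: pd.DataFrame
    by_day: pd.DataFrame
    grid: pd.DataFrame


def adherence_rate_pct(completed: int, scheduled: int) -> float:
    return 100.0 * completed / scheduled


def scheduled_sessions(
    roster: Mapping[str, int], design: StudyDesign = DEFAULT_DESIGN
) -> int:
    """Total scheduled sessions: sum over subjects of days x sessions/day."""
    return sum(int(d) * design.sessions_per_day for d in roster.values())


def adherence(
    records: pd.DataFrame,
    design: StudyDesign = DEFAULT_DESIGN,
    roster: Mapping[str, int] | None = None,
) -> AdherenceReport:
    """Scheduled/completed counts and rates at every reporting granularity."""
    if roster is None:
        roster = records.groupby("subject_id")["study_day"].max().to_dict()
    roster = {sid: int(d) for sid, d in roster.items()}

    out_of_range = records[
        records.apply(
            lambda r: r["subject_id"] not in roster
            or not (1 <= r["study_day"] <= roster[r["subject_id"]]),
            axis=1,
        )
    ] if len(records) else records
    if len(out_of_range):
        first = out_of_range.iloc[0]
        raise ValueError(
            f"response outside roster range: subject {first['subject_id']} "
            f"day {first['study_day']}"
        )

    # full scheduled grid, marked completed where >=1 response exists
    grid_rows = [
        (sid, day, slot)
        for sid, n_days in roster.items()
        for day in range(1, n_days + 1)
        for slot in design.slot_names
    ]
    grid = pd.DataFrame(grid_rows, columns=["subject_id", "study_day", "slot"])
    done = (
        records[["subject_id", "study_day", "slot"]].drop_duplicates()
        if len(records)
        else pd.DataFrame(columns=["subject_id", "study_day", "slot"])
    )
    done = done.assign(completed=True)
    grid = grid.merge(done, how="left", on=["subject_id", "study_day", "slot"])
    grid["completed"] = grid["completed"].notna()

    def summarize(by: list[str]) -> pd.DataFrame:
        g = grid.groupby(by, sort=True)["completed"]
        df = g.agg(scheduled="size", completed="sum").reset_index()
        df["rate_pct"] = 100.0 * df["completed"] / df["scheduled"]
        return df

    overall = AdherenceSummary(
        scheduled=len(grid), completed=int(grid["completed"].sum())
    )
    by_slot = summarize(["slot"])
    by_slot["slot"] = pd.Categorical(
        by_slot["slot"], categories=design.slot_names, ordered=True
    )
    by_slot = by_slot.sort_values("slot", ignore_index=True)
    return AdherenceReport(
        overall=overall,
        by_slot=by_slot,
        by_subject=summarize(["subject_id"]),
        by_day=summarize(["study_day"]),
        grid=grid,
    )


def per_subject_slot_rates(report: AdherenceReport) -> pd.DataFrame:
    """Subject x slot completion-rate table feeding the time-of-day ANOVA."""
    g = report.grid.groupby(["subject_id", "slot"])["completed"].mean()
    return g.unstack("slot")


def slot_anova(rates: pd.DataFrame | np.ndarray) -> tuple[float, float]:
    """One-way ANOVA across slots on per-subject slot-level completion rates.

    ``rates`` is subjects x slots; returns (F, p).
    """
    arr = np.asarray(rates, dtype=float)
    if arr.ndim != 2 or arr.shape[1] < 2 or arr.shape[0] < 2:
        raise ValueError("need >= 2 slots and >= 2 subjects for the ANOVA")
    groups = [arr[:, j] for j in range(arr.shape[1])]
    if all(np.allclose(g, groups[0]) for g in groups) and all(
        np.allclose(g, g[0]) for g in groups
    ):
        return 0.0, 1.0  # identical cells: no variance anywhere
    f, p = f_oneway(*groups)
    return float(f), float(p)
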