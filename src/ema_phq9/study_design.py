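"""Survey schedule and item-sampling rules for the smartphone EMA design.

The design delivers three short survey sessions per day in fixed clock
windows (morning 10:00-12:00, afternoon 13:00-15:00, evening 17:00-19:00),
each presenting 3 of the 9 PHQ-9 items sampled uniformly without replacement
within the session and independently across sessions.  Prompts may be
reverse-worded; a reversed prompt's raw Likert answer must be reflected
(3 - raw) back onto the canonical 0-3 scale before any scoring.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Canonical column order of a response table.
RESPONSE_COLUMNS = [
    "subject_id",
    "study_day",
    "slot",
    "item_id",
    "polarity",
    "raw_value",
    "timestamp_iso8601",
]

POLARITIES = ("standard", "reversed")


class DesignError(ValueError):
    """A study design whose fields violate the design invariants."""


class ResponseValidationError(ValueError):
    """A response record or table that cannot be interpreted under a design."""


@dataclass(frozen=True)
class StudyDesign:
    """Parameters of the EMA survey schedule and item-sampling rule.

    Defaults reproduce the 9-item PHQ-9 design with 3 sessions/day,
    3 items/session, a 2-hour response window after each alert, and
    question 9 (suicidal ideation) flagged at a canonical score of 2 or 3.
    """

    n_items: int = 9
    items_per_session: int = 3
    sessions_per_day: int = 3
    slot_names: tuple[str, ...] = ("morning", "afternoon", "evening")
    slot_alert_windows: tuple[tuple[int, int], ...] = ((10, 12), (13, 15), (17, 19))
    response_window_hours: int = 2
    item_score_range: tuple[int, int] = (0, 3)
    suicidality_item: int = 9
    suicidality_threshold: int = 2

    def __post_init__(self) -> None:
        if not (1 <= self.items_per_session <= self.n_items):
            raise DesignError(
                f"items_per_session={self.items_per_session} must be in "
                f"1..n_items={self.n_items}"
            )
        if len(self.slot_names) != self.sessions_per_day:
            raise DesignError("slot_names must have one label per daily session")
        if len(self.slot_alert_windows) != self.sessions_per_day:
            raise DesignError("slot_alert_windows must have one window per session")
        prev_end = -1
        for start, end in self.slot_alert_windows:
            if not (0 <= start < end <= 24):
                raise DesignError(f"invalid clock window ({start}, {end})")
            if start < prev_end:
                raise DesignError("slot windows must be disjoint and ordered")
            prev_end = end
        lo, hi = self.item_score_range
        if lo >= hi:
            raise DesignError("item_score_range must be a nonempty interval")
        if not (1 <= self.suicidality_item <= self.n_items):
            raise DesignError("suicidality_item must be a valid item id")

    @property
    def item_ids(self) -> range:
        return range(1, self.n_items + 1)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "StudyDesign":
        raw = json.loads(text)
        for key in ("slot_names", "slot_alert_windows", "item_score_range"):
            if key in raw:
                raw[key] = tuple(
                    tuple(v) if isinstance(v, list) else v for v in raw[key]
                )
        return cls(**raw)


@dataclass
class ResponseRecord:
    """One item response: who, when, which item, and the raw Likert answer."""

    subject_id: str
    study_day: int
    slot: str
    item_id: int
    polarity: str
    raw_value: int
    canonical_value: int | None = None
    timestamp_iso8601: str = ""


DEFAULT_DESIGN = StudyDesign()


def sample_session_items(
    design: StudyDesign, rng_state: np.random.Generator
) -> np.ndarray:
    """Draw the item ids presented in one session.

    Items are sampled uniformly without replacement within the session, so a
    session shows ``items_per_session`` distinct items; successive calls are
    independent, so across a day some items may repeat and others never appear.
    """
    return rng_state.choice(
        np.arange(1, design.n_items + 1), size=design.items_per_session, replace=False
    )


def canonical_from_raw(raw_value: int, polarity: str, design: StudyDesign) -> int:
    lo, hi = design.item_score_range
    if polarity not in POLARITIES:
        raise ResponseValidationError(f"unknown polarity {polarity!r}")
    if not (lo <= raw_value <= hi):
        raise ResponseValidationError(
            f"raw_value {raw_value} outside item score range {lo}..{hi}"
        )
    return raw_value if polarity == "standard" else hi - raw_value


def canonicalize(record: ResponseRecord, design: StudyDesign) -> ResponseRecord:
    """Return the record with canonical_value set per the polarity rule.

    Standard prompts keep their raw value; reverse-worded prompts are
    reflected, canonical = hi - raw (3 - raw on the PHQ-9 scale).
    """
    try:
        canonical = canonical_from_raw(record.raw_value, record.polarity, design)
    except ResponseValidationError as exc:
        raise ResponseValidationError(f"{exc} in record {record!r}") from exc
    return dataclasses.replace(record, canonical_value=canonical)


def canonicalize_table(responses: pd.DataFrame, design: StudyDesign) -> pd.DataFrame:
    """Vectorised canonicalization: add a canonical_value column to a table."""
    lo, hi = design.item_score_range
    raw = responses["raw_value"].to_numpy()
    bad = (raw < lo) | (raw > hi)
    if bad.any():
        rows = responses.index[bad].tolist()[:5]
        raise ResponseValidationError(
            f"raw_value outside {lo}..{hi} at rows {rows}"
        )
    unknown = ~responses["polarity"].isin(POLARITIES)
    if unknown.any():
        rows = responses.index[unknown].tolist()[:5]
        raise ResponseValidationError(f"unknown polarity at rows {rows}")
    out = responses.copy()
    reversed_mask = (out["polarity"] == "reversed").to_numpy()
    out["canonical_value"] = np.where(reversed_mask, hi - raw, raw)
    return out


def validate_response_table(
    records: pd.DataFrame | Iterable[ResponseRecord], design: StudyDesign
) -> list[dict]:
    """Check a response table against the design; return a violation report.

    Each violation is a dict with a ``kind`` and a human-readable ``detail``.
    An empty list means the table is consistent with the design: no duplicate
    item within a session, at most items_per_session items per session,
    values within range, and only known slot labels and item ids.
    """
    df = _as_frame(records)
    report: list[dict] = []
    if df.empty:
        return report

    lo, hi = design.item_score_range
    bad_value = df[(df["raw_value"] < lo) | (df["raw_value"] > hi)]
    for _, row in bad_value.iterrows():
        report.append(
            {
                "kind": "value_out_of_range",
                "detail": f"subject {row.subject_id} day {row.study_day} "
                f"slot {row.slot} item {row.item_id}: raw_value {row.raw_value}",
            }
        )

    bad_item = df[(df["item_id"] < 1) | (df["item_id"] > design.n_items)]
    for _, row in bad_item.iterrows():
        report.append(
            {
                "kind": "unknown_item",
                "detail": f"subject {row.subject_id} day {row.study_day}: "
                f"item_id {row.item_id}",
            }
        )

    bad_slot = df[~df["slot"].isin(design.slot_names)]
    for _, row in bad_slot.iterrows():
        report.append(
            {
                "kind": "unknown_slot",
                "detail": f"subject {row.subject_id} day {row.study_day}: "
                f"slot {row.slot!r}",
            }
        )

    session_key = ["subject_id", "study_day", "slot"]
    dup = df.groupby(session_key + ["item_id"], sort=False).size()
    for key, count in dup[dup > 1].items():
        report.append(
            {
                "kind": "duplicate_item_in_session",
                "detail": f"session {key[:3]}: item {key[3]} answered {count} times",
            }
        )

    per_session = df.groupby(session_key, sort=False).size()
    for key, count in per_session[per_session > design.items_per_session].items():
        report.append(
            {
                "kind": "session_overfull",
                "detail": f"session {key}: {count} responses "
                f"(limit {design.items_per_session})",
            }
        )
    return report


def _as_frame(records: pd.DataFrame | Iterable[ResponseRecord]) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    rows = [dataclasses.asdict(r) for r in records]
    if not rows:
        return pd.DataFrame(columns=RESPONSE_COLUMNS)
    return pd.DataFrame(rows)
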