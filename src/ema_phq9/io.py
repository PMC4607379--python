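"""Readers/writers for the pipeline's CSV/JSON dialects.

All tables are comma-separated UTF-8 with a header row; study days are
1-based; timestamps are ISO-8601 strings.  Readers validate eagerly and
name the offending row and column in their error messages.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import pandas as pd

from .study_design import (
    RESPONSE_COLUMNS,
    POLARITIES,
    StudyDesign,
    DEFAULT_DESIGN,
    ResponseValidationError,
    canonicalize_table,
)


def read_design(path: str | Path | None) -> StudyDesign:
    if path is None:
        return DEFAULT_DESIGN
    return StudyDesign.from_json(Path(path).read_text(encoding="utf-8"))


def write_design(design: StudyDesign, path: str | Path) -> None:
    Path(path).write_text(design.to_json() + "\n", encoding="utf-8")


def read_responses(
    path: str | Path, design: StudyDesign = DEFAULT_DESIGN
) -> pd.DataFrame:
    """Read and canonicalize a response table; row numbers are 1-based data rows."""
    df = pd.read_csv(path, dtype={"subject_id": str, "slot": str, "polarity": str})
    missing = [c for c in RESPONSE_COLUMNS if c not in df.columns]
    if missing:
        raise ResponseValidationError(
            f"{path}: missing column(s) {', '.join(missing)}"
        )
    for col in ("study_day", "item_id", "raw_value"):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any() or df[col].isna().any():
            row = int((bad | df[col].isna()).idxmax()) + 2  # +1 header, +1 0-base
            raise ResponseValidationError(
                f"{path}: unparseable value in column {col!r}, file row {row}"
            )
        df[col] = converted.astype(int)
    lo, hi = design.item_score_range
    out = df[(df["raw_value"] < lo) | (df["raw_value"] > hi)]
    if len(out):
        row = int(out.index[0]) + 2
        raise ResponseValidationError(
            f"{path}: raw_value {out['raw_value'].iloc[0]} outside {lo}..{hi}, "
            f"file row {row} (column raw_value)"
        )
    bad_pol = df[~df["polarity"].isin(POLARITIES)]
    if len(bad_pol):
        row = int(bad_pol.index[0]) + 2
        raise ResponseValidationError(
            f"{path}: unknown polarity {bad_pol['polarity'].iloc[0]!r}, "
            f"file row {row} (column polarity)"
        )
    return canonicalize_table(df, design)


def write_responses(responses: pd.DataFrame, path: str | Path) -> None:
    responses[RESPONSE_COLUMNS].to_csv(path, index=False)


def read_roster(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, dtype={"subject_id": str})
    if "subject_id" not in df.columns or "days" not in df.columns:
        raise ResponseValidationError(f"{path}: roster needs subject_id,days columns")
    return dict(zip(df["subject_id"], df["days"].astype(int)))


def write_roster(roster: Mapping[str, int], path: str | Path) -> None:
    pd.DataFrame(
        {"subject_id": list(roster), "days": [int(v) for v in roster.values()]}
    ).to_csv(path, index=False)


def read_clinic(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"subject_id": str})
    needed = {"subject_id", "day", "phq9_total"}
    missing = needed - set(df.columns)
    if missing:
        raise ResponseValidationError(
            f"{path}: missing column(s) {', '.join(sorted(missing))}"
        )
    return df


def write_estimates(estimates: pd.DataFrame, path: str | Path) -> None:
    estimates.to_csv(path, index=False, float_format="%.6f")


def read_estimates(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"subject_id": str})


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2) + "\n", encoding="utf-8")
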