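"""Synthetic EMA cohorts with the statistical structure the pipeline assumes.

No raw patient data accompany the original study, so every downstream stage
is exercised against simulated cohorts.  The generative model is deliberately
minimal:

* a latent daily depression severity per subject follows a mean-reverting
  AR(1) process on the 0-27 total-score scale;
* each ordinal item response is the item's share of that day's latent total
  plus Gaussian momentary noise, rounded half-to-even and clamped to 0-3;
* session completion is Bernoulli with slot-specific probabilities shifted
  per subject on the logit scale;
* clinic ("paper") administrations apply the same response process to a
  bias-shifted latent, so the app-minus-clinic reporting gap is a recoverable
  parameter rather than an assertion.

Defaults mirror the study conditions: 13 subjects (ten followed 30 days,
three 29), 3 sessions/day with completion probabilities 0.755/0.842/0.755,
a baseline severity of 11.64 = 8.62 clinic baseline + 3.02 reporting bias,
and a 3.02-point clinic under-report.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .study_design import (
    RESPONSE_COLUMNS,
    StudyDesign,
    DEFAULT_DESIGN,
    sample_session_items,
)

_BASE_DATE = np.datetime64("2015-01-05")  # nominal study start; carried, unused


class ConfigError(ValueError):
    """A cohort configuration with invalid fields (all listed in the message)."""


@dataclass(frozen=True)
class CohortConfig:
    """All generator parameters: trajectory, response, adherence, bias, seed.

    ``latent_start_mean``/``latent_start_sd`` are on the total-score (0-27)
    scale and describe severity as reported to the app; the clinic baseline is
    lower by ``clinic_bias``.  ``item_loadings`` give each item's share of the
    latent total and must sum to 1.
    """

    n_subjects: int = 13
    days_per_subject: tuple[int, ...] = (30,) * 10 + (29,) * 3
    slot_adherence: tuple[float, ...] = (0.755, 0.842, 0.755)
    subject_adherence_sd: float = 0.5
    latent_start_mean: float = 11.64
    latent_start_sd: float = 4.56
    ar_coefficient: float = 0.8
    innovation_sd: float = 1.5
    item_loadings: tuple[float, ...] = (1 / 9,) * 9
    response_noise_sd: float = 0.5
    clinic_bias: float = 3.02
    reversed_fraction: float = 0.2
    seed: int = 0

    def validate(self, design: StudyDesign = DEFAULT_DESIGN) -> None:
        problems = []
        if self.n_subjects < 1:
            problems.append("n_subjects must be >= 1")
        if len(self.days_per_subject) != self.n_subjects:
            problems.append("days_per_subject must have one entry per subject")
        if any(d < 1 for d in self.days_per_subject):
            problems.append("days_per_subject entries must be >= 1")
        if len(self.slot_adherence) != design.sessions_per_day:
            problems.append("slot_adherence must have one probability per slot")
        if any(not (0.0 <= p <= 1.0) for p in self.slot_adherence):
            problems.append("slot_adherence probabilities must lie in [0, 1]")
        if not (0.0 <= self.reversed_fraction <= 1.0):
            problems.append("reversed_fraction must lie in [0, 1]")
        for name in ("subject_adherence_sd", "latent_start_sd", "innovation_sd",
                     "response_noise_sd"):
            if getattr(self, name) < 0:
                problems.append(f"{name} must be >= 0")
        if len(self.item_loadings) != design.n_items:
            problems.append("item_loadings must have one weight per item")
        elif any(w < 0 for w in self.item_loadings):
            problems.append("item_loadings must be nonnegative")
        elif abs(sum(self.item_loadings) - 1.0) > 1e-9:
            problems.append("item_loadings must sum to 1 (within 1e-9)")
        if problems:
            raise ConfigError("invalid CohortConfig: " + "; ".join(problems))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, raw: dict) -> "CohortConfig":
        raw = dict(raw)
        for key in ("days_per_subject", "slot_adherence", "item_loadings"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class SyntheticCohort:
    """A generated cohort: responses, ground truth, clinic scores, mask."""

    responses: pd.DataFrame
    truth: pd.DataFrame
    clinic_scores: pd.DataFrame
    adherence_mask: pd.DataFrame
    config: CohortConfig
    design: StudyDesign


def subject_ids(config: CohortConfig) -> list[str]:
    return [f"S{i + 1:02d}" for i in range(config.n_subjects)]


def simulate_latent_trajectories(
    config: CohortConfig, rng_state: np.random.Generator
) -> pd.DataFrame:
    """Mean-reverting AR(1) latent severity per subject-day, clamped to [0, 27].

    L(1) ~ Normal(latent_start_mean, latent_start_sd);
    L(d+1) = mean + ar_coefficient * (L(d) - mean) + Normal(0, innovation_sd).
    """
    rows = []
    mu = config.latent_start_mean
    for sid, n_days in zip(subject_ids(config), config.days_per_subject):
        level = float(
            np.clip(rng_state.normal(mu, config.latent_start_sd), 0.0, 27.0)
        )
        for day in range(1, n_days + 1):
            rows.append((sid, day, level))
            shock = rng_state.normal(0.0, config.innovation_sd)
            level = float(
                np.clip(mu + config.ar_coefficient * (level - mu) + shock, 0.0, 27.0)
            )
    return pd.DataFrame(rows, columns=["subject_id", "study_day", "latent_total"])


def simulate_item_response(
    latent_total: float,
    item_id: int,
    config: CohortConfig,
    rng_state: np.random.Generator,
) -> int:
    """One ordinal 0-3 response: loading share + noise, round half-to-even, clamp."""
    value = latent_total * config.item_loadings[item_id - 1]
    value += rng_state.normal(0.0, config.response_noise_sd)
    return int(np.clip(np.rint(value), 0, 3))


def simulate_adherence_mask(
    config: CohortConfig,
    rng_state: np.random.Generator,
    design: StudyDesign = DEFAULT_DESIGN,
) -> pd.DataFrame:
    """Bernoulli session completion with logit-scale subject offsets."""
    rows = []
    base_logit = np.array([logit(p) for p in config.slot_adherence])
    for sid, n_days in zip(subject_ids(config), config.days_per_subject):
        offset = rng_state.normal(0.0, config.subject_adherence_sd)
        probs = expit(base_logit + offset)
        for day in range(1, n_days + 1):
            for slot, p in zip(design.slot_names, probs):
                rows.append((sid, day, slot, bool(rng_state.random() < p)))
    return pd.DataFrame(
        rows, columns=["subject_id", "study_day", "slot", "completed"]
    )


def _session_timestamp(
    day: int, window: tuple[int, int], rng_state: np.random.Generator
) -> str:
    start_h, end_h = window
    minutes = int(rng_state.integers(0, (end_h - start_h) * 60))
    ts = (
        _BASE_DATE
        + np.timedelta64(day - 1, "D")
        + np.timedelta64(start_h * 60 + minutes, "m")
    )
    return np.datetime_as_string(ts, unit="s")


def generate_cohort(
    config: CohortConfig, design: StudyDesign = DEFAULT_DESIGN
) -> SyntheticCohort:
    """Generate a full synthetic cohort, reproducible from ``config.seed``.

    Responses exist only for completed sessions; each completed session carries
    exactly ``design.items_per_session`` records, items drawn by the design's
    sampling rule, each prompt reverse-worded with probability
    ``reversed_fraction``.  Clinic PHQ-9 totals (all 9 items, same response
    process) are produced for day 1 and each subject's final day from the
    latent severity minus ``clinic_bias``.
    """
    config.validate(design)
    rng = np.random.default_rng(config.seed)

    truth_long = simulate_latent_trajectories(config, rng)
    loadings = np.asarray(config.item_loadings)
    truth = truth_long.copy()
    for i in design.item_ids:
        truth[f"item_{i}"] = truth["latent_total"] * loadings[i - 1]

    mask = simulate_adherence_mask(config, rng, design)
    latent_lookup = {
        (r.subject_id, r.study_day): r.latent_total
        for r in truth_long.itertuples()
    }
    windows = dict(zip(design.slot_names, design.slot_alert_windows))
    lo, hi = design.item_score_range

    resp_rows = []
    for row in mask.itertuples():
        if not row.completed:
            continue
        latent = latent_lookup[(row.subject_id, row.study_day)]
        items = sample_session_items(design, rng)
        ts = _session_timestamp(row.study_day, windows[row.slot], rng)
        for item in items:
            canonical = simulate_item_response(latent, int(item), config, rng)
            reversed_prompt = rng.random() < config.reversed_fraction
            polarity = "reversed" if reversed_prompt else "standard"
            raw = hi - canonical if reversed_prompt else canonical
            resp_rows.append(
                (
                    row.subject_id,
                    row.study_day,
                    row.slot,
                    int(item),
                    polarity,
                    raw,
                    ts,
                    canonical,
                )
            )
    responses = pd.DataFrame(
        resp_rows, columns=RESPONSE_COLUMNS + ["canonical_value"]
    )

    clinic_rows = []
    for sid, n_days in zip(subject_ids(config), config.days_per_subject):
        for day in (1, n_days):
            latent = np.clip(
                latent_lookup[(sid, day)] - config.clinic_bias, 0.0, 27.0
            )
            item_scores = [
                simulate_item_response(float(latent), i, config, rng)
                for i in design.item_ids
            ]
            clinic_rows.append(
                (sid, day, int(sum(item_scores)),
                 int(item_scores[design.suicidality_item - 1]))
            )
    clinic = pd.DataFrame(
        clinic_rows, columns=["subject_id", "day", "phq9_total", "item9"]
    )

    return SyntheticCohort(
        responses=responses,
        truth=truth,
        clinic_scores=clinic,
        adherence_mask=mask,
        config=config,
        design=design,
    )
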