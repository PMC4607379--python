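"""Shared plumbing for the numbered analysis drivers."""

from pathlib import Path

import pandas as pd

from ema_phq9 import CohortConfig, generate_cohort
from ema_phq9.io import read_responses

COHORT_SEED = 2015
RESULTS = Path(__file__).resolve().parent.parent / "results"
COHORT_DIR = RESULTS / "cohort"


def study_config() -> CohortConfig:
    return CohortConfig(seed=COHORT_SEED)


def roster_of(config: CohortConfig) -> dict[str, int]:
    return {f"S{i + 1:02d}": d for i, d in enumerate(config.days_per_subject)}


def load_cohort_tables():
    """Responses/truth/clinic from results/cohort, regenerating if absent."""
    if not (COHORT_DIR / "responses.csv").exists():
        cohort = generate_cohort(study_config())
        return cohort.responses, cohort.truth, cohort.clinic_scores
    responses = read_responses(COHORT_DIR / "responses.csv")
    truth = pd.read_csv(COHORT_DIR / "truth.csv", dtype={"subject_id": str})
    clinic = pd.read_csv(COHORT_DIR / "clinic.csv", dtype={"subject_id": str})
    return responses, truth, clinic
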