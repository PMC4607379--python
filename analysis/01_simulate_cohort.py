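"""Generate the synthetic study cohort and write its tables.

Emulates the study conditions: 13 outpatients (ten followed for 30 days,
three for 29), three 3-item PHQ-9 survey sessions per day with slot
completion probabilities 0.755/0.842/0.755, latent daily severity following
a mean-reverting AR(1) around 11.64 points, and clinic administrations at
study start and end that under-report by 3.02 points.

Writes results/cohort/{responses,truth,clinic,mask,roster}.csv.
"""

from ema_phq9 import generate_cohort, validate_response_table
from ema_phq9.io import write_responses, write_roster

from _common import COHORT_DIR, roster_of, study_config


def main() -> None:
    config = study_config()
    cohort = generate_cohort(config)
    COHORT_DIR.mkdir(parents=True, exist_ok=True)
    write_responses(cohort.responses, COHORT_DIR / "responses.csv")
    cohort.truth.to_csv(COHORT_DIR / "truth.csv", index=False,
                        float_format="%.6f")
    cohort.clinic_scores.to_csv(COHORT_DIR / "clinic.csv", index=False)
    cohort.adherence_mask.to_csv(COHORT_DIR / "mask.csv", index=False)
    write_roster(roster_of(config), COHORT_DIR / "roster.csv")

    violations = validate_response_table(cohort.responses, cohort.design)
    completed = int(cohort.adherence_mask["completed"].sum())
    print(f"cohort seed {config.seed}: {config.n_subjects} subjects, "
          f"{sum(config.days_per_subject)} subject-days")
    print(f"completed sessions: {completed} of "
          f"{len(cohort.adherence_mask)} scheduled "
          f"({100 * completed / len(cohort.adherence_mask):.2f}%)")
    print(f"item responses: {len(cohort.responses)} "
          f"({(cohort.responses['polarity'] == 'reversed').mean():.1%} "
          f"reverse-worded)")
    print(f"design validation violations: {len(violations)}")
    print(f"tables written to {COHORT_DIR}")


if __name__ == "__main__":
    main()
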