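"""Published aggregate inputs of the TRAPID-AMI economic evaluation.

These are the study-level quantities the analysis runs on when
patient-level data are not available ("table mode"): zone counts and
diagnostic-category population shares, zone-level accuracy, pathway
timings, the multivariate log-normal LoS coefficient sets (used as the
ground truth of the synthetic cohort generator), and the per-country
share-weighted cost cells of the cost-consequence table.

Monetary values are 2016 price-year GBP (UK), EUR (DE) and CHF (CH);
each country's pipeline is self-contained — no cross-currency use.
"""

from __future__ import annotations

N_STUDY = 1282
ZONE_COUNTS = {"rule_in": 184, "rule_out": 813, "observation": 285}
ZONE_SHARES = {z: c / N_STUDY for z, c in ZONE_COUNTS.items()}
OBSERVATION_AMI_COUNT = 48

#: zone-group accuracy (sensitivity, specificity); the observation zone is
#: assumed to perform like ED standard of care.
ZONE_GROUP_ACCURACY = {
    "rule_in_out": (0.95, 0.95),
    "observation": (0.69, 0.98),
}
SOC_ACCURACY = (0.69, 0.98)

#: population diagnostic-category shares (fractions of all patients), as
#: published; within-group sums give the group's share of the population.
ALGORITHM_CATEGORY_SHARES = {
    "rule_in_out": {"TP": 0.1260, "FN": 0.0062, "TN": 0.6135, "FP": 0.0320},
    "observation": {"TP": 0.0261, "FN": 0.0117, "TN": 0.1816, "FP": 0.0029},
}
SOC_CATEGORY_SHARES = {"TP": 0.1173, "FN": 0.0527, "TN": 0.8168, "FP": 0.0132}

#: pathway timings (hours)
SECOND_DRAW_MEAN_H = 1.7
SECOND_DRAW_SE_H = 0.03
PROCESSING_TIME_H = 1.0  # analysis + discharge protocol; expert opinion, tested 1-3 h
SOC_MEAN_LOS_AMI_H = 5.33
SOC_MEAN_LOS_NONAMI_H = 6.63

#: annual UK suspected-AMI presentations used for the national projection
ANNUAL_SUSPECTED_AMI_UK = 573_916

#: multivariate log-normal LoS coefficients (log-hours), by ED working
#: diagnosis stratum; reference levels (site Detroit, age <=65, dyspnea no,
#: pain intensity 0, heart rate normal, CHF no) are 0 and omitted.  These
#: double as the synthetic generator's ground-truth model.
LOS_COEFFS_AMI = {
    "intercept": 1.7949,
    "site[Sydney]": 0.5209,
    "site[Brussels]": -0.0589,
    "site[Basel]": 0.5366,
    "site[Heidelberg]": 0.6571,
    "site[Nuremberg]": -0.1371,
    "site[Barcelona]": 1.2668,
    "site[Manchester]": 0.3381,
    "site[Milan]": 1.0565,
    "site[Padova]": -0.5153,
    "site[Stockholm]": -0.4207,
    "site[Baltimore]": 0.0726,
    "peak_hours": -0.0906,
    "dyspnea[yes]": -0.2858,
    "chf_history[yes]": -0.3443,
    "chf_history[unknown]": -1.4077,
}
LOS_COEFFS_NONAMI = {
    "intercept": 2.0077,
    "site[Sydney]": 0.7926,
    "site[Brussels]": 0.2363,
    "site[Basel]": 0.1970,
    "site[Heidelberg]": 0.0031,
    "site[Nuremberg]": -0.6486,
    "site[Barcelona]": 1.0026,
    "site[Manchester]": -0.2656,
    "site[Milan]": 0.6906,
    "site[Padova]": -0.0456,
    "site[Stockholm]": -0.6901,
    "site[Baltimore]": 0.0806,
    "age_category[65-75]": 0.0899,
    "age_category[>75]": 0.1646,
    "peak_hours": -0.0277,
    "dyspnea[yes]": 0.1532,
    "pain_intensity_positive[1]": -0.3053,
    "hr_category[above]": 0.0229,
    "hr_category[below]": 0.1253,
    "chf_history[yes]": 0.0024,
    "chf_history[unknown]": -0.3637,
}
#: generator sigma on the log-hour scale.  The published scale entries are
#: not interpretable as a log-normal sigma (they would imply astronomically
#: large mean stays); 0.6 gives realistic right-skewed ED stays with a
#: heavy-but-plausible tail.
LOS_SIGMA = 0.6

AMI_COVARIATES = ("site", "peak_hours", "dyspnea", "chf_history")
NONAMI_COVARIATES = (
    "site",
    "age_category",
    "peak_hours",
    "dyspnea",
    "pain_intensity_positive",
    "hr_category",
    "chf_history",
)

#: share-weighted cost cells per country ("share of cost by diagnosis
#: result"): each cell is the population share of the category multiplied
#: by the per-patient management cost, so an arm total is the plain sum of
#: its cells.  Periods: before/during/post ED plus the alternative-diagnosis
#: work-up bucket.
PERIODS = ("before_ed", "during_ed", "post_ed", "alt_dx")

COST_CELLS = {
    "UK": {
        "currency": "GBP",
        "algorithm": {
            "rule_in_out": {
                "TP": {"before_ed": 5, "during_ed": 218, "post_ed": 229, "alt_dx": 0, "total": 452},
                "FN": {"before_ed": 0, "during_ed": 12, "post_ed": 0, "alt_dx": 3, "total": 16},
                "TN": {"before_ed": 5, "during_ed": 1219, "post_ed": 32, "alt_dx": 156, "total": 1412},
                "FP": {"before_ed": 1, "during_ed": 55, "post_ed": 58, "alt_dx": 17, "total": 132},
            },
            "observation": {
                "TP": {"before_ed": 0, "during_ed": 85, "post_ed": 97, "alt_dx": 0, "total": 182},
                "FN": {"before_ed": 0, "during_ed": 39, "post_ed": 7, "alt_dx": 6, "total": 52},
                "TN": {"before_ed": 2, "during_ed": 60, "post_ed": 104, "alt_dx": 46, "total": 212},
                "FP": {"before_ed": 0, "during_ed": 10, "post_ed": 11, "alt_dx": 2, "total": 22},
            },
        },
        "soc": {
            "all": {
                "TP": {"before_ed": 5, "during_ed": 384, "post_ed": 434, "alt_dx": 0, "total": 823},
                "FN": {"before_ed": 1, "during_ed": 176, "post_ed": 30, "alt_dx": 26, "total": 232},
                "TN": {"before_ed": 9, "during_ed": 2723, "post_ed": 467, "alt_dx": 208, "total": 3406},
                "FP": {"before_ed": 1, "during_ed": 43, "post_ed": 49, "alt_dx": 7, "total": 100},
            },
        },
    },
    "DE": {
        "currency": "EUR",
        "algorithm": {
            "rule_in_out": {
                "TP": {"before_ed": 6, "during_ed": 92, "post_ed": 322, "alt_dx": 0, "total": 420},
                "FN": {"before_ed": 0, "during_ed": 1, "post_ed": 0, "alt_dx": 25, "total": 26},
                "TN": {"before_ed": 1, "during_ed": 99, "post_ed": 13, "alt_dx": 306, "total": 419},
                "FP": {"before_ed": 2, "during_ed": 23, "post_ed": 82, "alt_dx": 38, "total": 145},
            },
            "observation": {
                "TP": {"before_ed": 0, "during_ed": 28, "post_ed": 134, "alt_dx": 0, "total": 162},
                "FN": {"before_ed": 0, "during_ed": 4, "post_ed": 9, "alt_dx": 47, "total": 60},
                "TN": {"before_ed": 1, "during_ed": 20, "post_ed": 139, "alt_dx": 91, "total": 251},
                "FP": {"before_ed": 0, "during_ed": 3, "post_ed": 15, "alt_dx": 3, "total": 22},
            },
        },
        "soc": {
            "all": {
                "TP": {"before_ed": 6, "during_ed": 125, "post_ed": 602, "alt_dx": 0, "total": 733},
                "FN": {"before_ed": 0, "during_ed": 18, "post_ed": 40, "alt_dx": 211, "total": 269},
                "TN": {"before_ed": 4, "during_ed": 275, "post_ed": 625, "alt_dx": 407, "total": 1312},
                "FP": {"before_ed": 1, "during_ed": 14, "post_ed": 68, "alt_dx": 16, "total": 98},
            },
        },
    },
    "CH": {
        "currency": "CHF",
        "algorithm": {
            "rule_in_out": {
                "TP": {"before_ed": 13, "during_ed": 601, "post_ed": 1198, "alt_dx": 0, "total": 1813},
                "FN": {"before_ed": 0, "during_ed": 28, "post_ed": 1, "alt_dx": 96, "total": 125},
                "TN": {"before_ed": 3, "during_ed": 2756, "post_ed": 72, "alt_dx": 1329, "total": 4160},
                "FP": {"before_ed": 3, "during_ed": 153, "post_ed": 304, "alt_dx": 149, "total": 609},
            },
            "observation": {
                "TP": {"before_ed": 1, "during_ed": 211, "post_ed": 368, "alt_dx": 0, "total": 579},
                "FN": {"before_ed": 0, "during_ed": 90, "post_ed": 30, "alt_dx": 181, "total": 301},
                "TN": {"before_ed": 4, "during_ed": 142, "post_ed": 462, "alt_dx": 393, "total": 1002},
                "FP": {"before_ed": 0, "during_ed": 24, "post_ed": 41, "alt_dx": 14, "total": 79},
            },
        },
        "soc": {
            "all": {
                "TP": {"before_ed": 13, "during_ed": 947, "post_ed": 1654, "alt_dx": 0, "total": 2614},
                "FN": {"before_ed": 1, "during_ed": 405, "post_ed": 134, "alt_dx": 814, "total": 1354},
                "TN": {"before_ed": 16, "during_ed": 6285, "post_ed": 2080, "alt_dx": 1770, "total": 10151},
                "FP": {"before_ed": 1, "during_ed": 107, "post_ed": 186, "alt_dx": 62, "total": 356},
            },
        },
    },
}

COUNTRIES = tuple(COST_CELLS)
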