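"""Published summary statistics of the two-observer porcine strain study.

These tables hold the printed summary numbers of the 10-pig CMR
feature-tracking study this package models: per-state global strain
means +/- SD for each observer, the inter- and intra-observer agreement
summaries (bias +/- SD of differences, limits of agreement, ICC), and the
sample-size inputs (pooled difference SDs and the f-factor).  They calibrate
the synthetic-data preset and serve as fixed inputs to the sample-size
calculation; per-animal raw data were never published, so none of these
numbers can be recomputed from data — they are design constants here.

All strain quantities are in percent (strain points).
"""

from __future__ import annotations

import pandas as pd

#: f(alpha, P) factor of the sample-size relation for alpha = 0.05, power = 0.80.
F_FACTOR = 10.5

#: Nominal detectable relative changes (percent, used as strain points).
DELTAS = (5.0, 10.0, 15.0)

#: Planning dropout rate suggested for prospective designs.
DROPOUT_RATE = 0.25

#: Pooled SD of between-measurement differences per component (sample-size input).
SAMPLE_SIZE_SIGMA = {"GLS": 4.9, "GCS": 7.4, "GRS": 17.9}

#: Inter-observer mean difference per component at baseline (sample-size table).
SAMPLE_SIZE_MEAN_DIFF = {"GLS": -1.1, "GCS": -2.3, "GRS": 21.7}

#: Published required-n cells (component, delta) -> animals; None where not printed.
SAMPLE_SIZE_CELLS = {
    ("GLS", 5.0): 20, ("GLS", 10.0): 5, ("GLS", 15.0): 2,
    ("GCS", 5.0): 45, ("GCS", 10.0): 11, ("GCS", 15.0): 5,
    ("GRS", 5.0): None, ("GRS", 10.0): 68, ("GRS", 15.0): 30,
}

# Global strain summaries, mean +/- SD over the 10 animals.
# "first"/"second" are observer 1 and observer 2 (inter-observer level);
# "repeat" is observer 1's second analysis session (intra-observer level).
_STRAIN_SUMMARY_ROWS = [
    # state, label, first_mean, first_sd, second_mean, second_sd, repeat_mean, repeat_sd
    ("BL",  "GLS", -26.1,  5, -25.1,  4, -23.3,  4),
    ("BL",  "GCS", -32.7,  8, -30.4,  6, -31.0,  8),
    ("BL",  "GRS",  73.3,  9,  51.5, 17,  71.7, 19),
    ("Dob", "GLS", -45.1, 11, -40.6,  7, -45.6,  9),
    ("Dob", "GCS", -55.1, 12, -54.7, 10, -53.3, 11),
    ("Dob", "GRS", 103.0, 20, 101.8, 14,  87.9, 36),
    ("Ver", "GLS", -20.8,  6, -17.3,  5, -16.5,  3),
    ("Ver", "GCS", -18.6,  4, -21.0,  6, -16.9,  5),
    ("Ver", "GRS",  53.9, 10,  29.1,  9,  30.3, 13),
]

STRAIN_SUMMARY = pd.DataFrame(
    _STRAIN_SUMMARY_ROWS,
    columns=[
        "state", "label",
        "first_mean", "first_sd",
        "second_mean", "second_sd",
        "repeat_mean", "repeat_sd",
    ],
)

# Agreement summaries: bias (observer1 - observer2, or session1 - session2),
# SD of differences, 95% limits of agreement and the reported ICC.
_AGREEMENT_ROWS = [
    # comparison, label, state, mean_diff, sd_diff, loa_lower, loa_upper, icc
    ("inter_observer", "GLS", "BL",   -1.0,  3.0,  -6.9,  4.8,  0.88),
    ("inter_observer", "GLS", "Dob",  -4.5, 10.0, -24.1, 15.1,  0.60),
    ("inter_observer", "GLS", "Ver",   3.5,  4.2,  -4.7, 11.7,  0.79),
    ("inter_observer", "GCS", "BL",   -2.2,  7.6, -17.2, 12.6,  0.66),
    ("inter_observer", "GCS", "Dob",  -0.4, 11.5, -23.0, 22.2,  0.51),
    ("inter_observer", "GCS", "Ver",   2.4,  3.4,  -4.3,  9.2,  0.61),
    ("inter_observer", "GRS", "BL",   21.7, 11.6,  -0.9, 44.5,  0.80),
    ("inter_observer", "GRS", "Dob",   1.2, 29.6, -56.9, 59.3, -1.60),
    ("inter_observer", "GRS", "Ver",  24.7, 12.6,   0.1, 49.4,  0.24),
    ("intra_observer", "GLS", "BL",    2.8,  2.9,  -2.8,  8.5,  0.81),
    ("intra_observer", "GLS", "Dob",  -0.4,  7.3, -14.8, 14.0,  0.87),
    ("intra_observer", "GLS", "Ver",   4.3,  4.3,  -4.1, 12.7,  0.75),
    ("intra_observer", "GCS", "BL",    1.7,  1.5,  -1.3,  4.7,  0.98),
    ("intra_observer", "GCS", "Dob",   1.8,  3.4,  -4.8,  8.4,  0.97),
    ("intra_observer", "GCS", "Ver",   1.6,  1.4,  -1.1,  4.4,  0.95),
    ("intra_observer", "GRS", "BL",   -1.5, 12.7, -26.4, 23.3,  0.79),
    ("intra_observer", "GRS", "Dob", -15.1, 31.1, -76.0, 45.8,  0.62),
    ("intra_observer", "GRS", "Ver", -23.6, 15.7, -54.4,  7.2,  0.14),
]

AGREEMENT_SUMMARY = pd.DataFrame(
    _AGREEMENT_ROWS,
    columns=[
        "comparison", "label", "state",
        "mean_diff", "sd_diff", "loa_lower", "loa_upper", "icc",
    ],
)
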