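"""Published clinical validation summaries shipped as reference data.

The framework was originally validated on a confidential 12-lead abdominal
ECG cohort; the per-fold and per-subject summary figures from that
validation are public and are embedded here so the package's summary
arithmetic (fold averages, cohort mean +/- SD, gestational-age and
maternal-condition strata) can be recomputed and checked without access to
the underlying recordings.

``cohort_table()`` returns one row per subject: maternal health status
("normal" / "none" = no condition recorded, "exists" = a maternal condition
was present), gestational age in weeks, fetal weight in grams, maternal age
in years, body-mass index in kg/m^2, and the leave-one-subject-out test
accuracy in percent.  Missing entries are NaN.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["FOLD_ACCURACY_PCT", "FOLD_F1", "cohort_table"]

# Five-fold subject-dependent cross-validation summary (percent / fraction).
FOLD_ACCURACY_PCT = (92.5, 93.4, 93.5, 93.2, 92.6)
FOLD_F1 = (0.96, 0.97, 0.97, 0.96, 0.96)

# subject, status, gestational_age_weeks, fetal_weight_g, maternal_age_years,
# bmi_kg_m2, loso_accuracy_pct
_COHORT_ROWS = [
    (1, "normal", 20.6, 393, 33, 32.4, 93.8),
    (2, "exists", 39.3, 2835, 35, 21.0, 90.2),
    (3, "normal", 20.1, 355, 31, 23.9, 88.5),
    (4, "exists", 26.2, 937, 32, 15.8, 88.7),
    (5, "exists", 33.4, 1854, 28, 33.0, 68.5),
    (6, "exists", 30.0, 1310, 22, 24.1, 92.9),
    (7, "exists", 26.3, 1023, 24, 25.9, 92.9),
    (8, "normal", 24.0, 757, 31, 24.2, 93.8),
    (9, "exists", 29.2, 1239, 35, 21.0, 89.4),
    (10, "exists", 38.3, 2267, 35, 21.3, 94.4),
    (11, "none", 35.1, np.nan, 36, np.nan, 97.0),
    (12, "exists", 39.2, 2892, 45, 35.6, 86.9),
    (13, "none", 39.3, 3138, 30, 26.2, 94.1),
    (14, "normal", 35.4, 2462, 41, 21.7, 90.5),
    (15, "normal", 25.3, 916, 38, 20.0, 84.3),
    (16, "none", 35.1, 2281, 32, 21.9, 97.1),
    (17, "exists", 26.0, 919, 32, 26.9, 86.4),
    (18, "exists", 29.0, 1314, 34, 21.5, 94.1),
    (19, "exists", 24.3, 809, 29, 24.7, 77.7),
    (20, "normal", 27.2, 1019, 22, 23.1, 86.8),
    (21, "normal", 29.2, 1150, 22, 23.8, 84.2),
    (22, "exists", 29.4, 1445, 41, 20.4, 86.5),
    (23, "exists", 34.0, 2252, 34, 22.5, 85.0),
    (24, "exists", 28.5, 1383, 29, 25.6, 90.4),
    (25, "exists", 30.6, 1481, 33, 20.9, 95.0),
    (26, "exists", 31.6, np.nan, 25, 20.1, 81.0),
]

_COLUMNS = ["subject", "status", "gestational_age_weeks", "fetal_weight_g",
            "maternal_age_years", "bmi_kg_m2", "accuracy_pct"]


def cohort_table() -> pd.DataFrame:
    """26-subject demographics + leave-one-subject-out accuracy table."""
    return pd.DataFrame(_COHORT_ROWS, columns=_COLUMNS)
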