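"""Small bundled study tables used in worked examples and sanity checks.

These are printed summary tables from the 18-participant smart-bed
validation study that motivated this package: the demographic roster and
the fold-level validation accuracy of its five-fold subject-blocked
cross-validation.  They let the agreement and summary machinery be
exercised against published-scale numbers without any raw recordings.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["participant_roster", "fold_accuracy_table"]

_ROSTER = [
    # id, gender, age (years), height (m), weight (kg)
    ("S01", "Male", 41, 1.75, 112.7),
    ("S02", "Female", 37, 1.55, 68.7),
    ("S03", "Male", 45, 1.83, 117.7),
    ("S04", "Female", 39, 1.72, 68.2),
    ("S05", "Male", 42, 1.95, 92.9),
    ("S06", "Female", 42, 1.61, 61.9),
    ("S07", "Male", 43, 1.76, 87.8),
    ("S08", "Male", 31, 1.86, 99.6),
    ("S09", "Female", 49, 1.57, 81.8),
    ("S10", "Female", 49, 1.60, 79.0),
    ("S11", "Male", 51, 1.76, 85.5),
    ("S12", "Female", 45, 1.60, 79.0),
    ("S13", "Female", 57, 1.55, 81.8),
    ("S14", "Male", 41, 1.75, 81.8),
    ("S15", "Male", 57, 1.79, 102.7),
    ("S16", "Female", 42, 1.59, 84.9),
    ("S17", "Male", 50, 1.76, 91.7),
    ("S18", "Female", 40, 1.73, 88.5),
]

_FOLD_ACCURACY = [
    # fold, bias (degC), lower LoA (degC), upper LoA (degC), R2
    (1, -0.01, -0.76, 0.73, 0.88),
    (2, 0.01, -0.77, 0.79, 0.89),
    (3, -0.01, -0.96, 0.94, 0.83),
    (4, 0.00, -0.82, 0.83, 0.87),
    (5, 0.00, -0.65, 0.65, 0.90),
]


def participant_roster() -> pd.DataFrame:
    """The 18-participant demographic roster (gender, age, height, weight)."""
    return pd.DataFrame(_ROSTER, columns=["subject_id", "gender", "age",
                                          "height_m", "weight_kg"])


def fold_accuracy_table() -> pd.DataFrame:
    """Fold-level validation accuracy of the study's five-fold
    subject-blocked cross-validation (bias, limits of agreement, R²)."""
    return pd.DataFrame(_FOLD_ACCURACY,
                        columns=["fold", "bias", "lower_loa", "upper_loa", "r2"])
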