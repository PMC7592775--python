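"""Published study values shipped as package data.

These are the printed summary numbers of the original 34-subject clinical
study: the per-subject correlation/lag table, the cohort-level feature means,
the refined regression coefficients, and the clinical classification counts.
They serve as fixed inputs for reproducing the study's aggregate statistics
and for prediction with the published model on new feature vectors.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "PUBLISHED_COEFFICIENTS",
    "PUBLISHED_INTERCEPT",
    "PUBLISHED_PREDICTORS",
    "COHORT_MEAN_FEATURES",
    "COHORT_MEAN_CVP",
    "NORMAL_RANGE_MMHG",
    "NORMAL_RANGE_CMH2O",
    "CLASSIFICATION_COUNTS",
    "subject_correlation_table",
]

#: Refined linear model: mean CVP (cmH2O) from mean IJV-CSA (cm^2) and the
#: CSA autocorrelation r-values at the listed sample lags.
PUBLISHED_INTERCEPT = -10.014
PUBLISHED_COEFFICIENTS = {
    "csa_mean": 2.836,
    "lag40": -32.469,
    "lag80": -22.015,
    "lag100": -7.590,
    "lag120": -18.417,
    "lag140": -14.016,
    "lag180": -23.054,
    "lag220": -11.470,
    "lag240": -5.513,
    "lag280": -8.478,
    "lag320": -7.059,
}
PUBLISHED_PREDICTORS = tuple(PUBLISHED_COEFFICIENTS)

#: Cohort means of the IJV-CSA features (mean CSA in cm^2; ACF r-values).
COHORT_MEAN_FEATURES = {
    "csa_mean": 0.984,
    "lag0": 1.000,
    "lag20": 0.384,
    "lag40": -0.163,
    "lag60": -0.321,
    "lag80": -0.290,
    "lag100": -0.051,
    "lag120": 0.033,
    "lag140": -0.039,
    "lag160": -0.097,
    "lag180": -0.114,
    "lag200": -0.034,
    "lag220": 0.031,
    "lag240": 0.102,
    "lag260": 0.101,
    "lag280": 0.050,
    "lag300": 0.017,
    "lag320": 0.007,
    "lag340": 0.000,
    "lag360": -0.018,
}

#: Cohort mean of the measured mean CVP, cmH2O.
COHORT_MEAN_CVP = 5.998

#: Clinical normal range for mean CVP.
NORMAL_RANGE_MMHG = (2.0, 8.0)
NORMAL_RANGE_CMH2O = (2.72, 10.88)

#: Per-class (correct, total) classification outcome of the published model.
CLASSIFICATION_COUNTS = {"normal": (26, 27), "high": (0, 1), "low": (3, 6)}

# Per-subject correlations and lag times between the measured CVP and
# IJV-CSA signals: (subject_id, measured r, ACF-curve r, incremental lag
# in samples, sampling interval s, lag time s).
_SUBJECT_ROWS = [
    (1, 0.877, 0.992, -4, 0.009, -0.035),
    (4, -0.286, 0.956, -37, 0.007, -0.261),
    (5, 0.501, 0.947, -12, 0.008, -0.094),
    (8, -0.004, 0.561, -55, 0.009, -0.478),
    (10, 0.205, 0.659, -13, 0.010, -0.130),
    (15, -0.003, 0.528, -88, 0.009, -0.759),
    (18, -0.204, 0.680, -34, 0.008, -0.262),
    (19, -0.013, 0.821, -29, 0.006, -0.170),
    (20, -0.239, 0.550, -53, 0.009, -0.491),
    (23, -0.388, 0.509, -31, 0.007, -0.220),
    (24, -0.284, 0.229, -69, 0.010, -0.690),
    (25, -0.196, 0.789, -17, 0.010, -0.165),
    (28, 0.682, 0.929, -1, 0.008, -0.008),
    (30, 0.062, 0.224, -35, 0.004, -0.134),
    (31, -0.052, 0.679, -41, 0.004, -0.161),
    (34, 0.096, 0.771, -17, 0.007, -0.120),
    (38, -0.592, 0.826, -30, 0.009, -0.278),
    (39, -0.366, 0.787, -37, 0.012, -0.430),
    (40, -0.075, 0.732, -28, 0.008, -0.219),
    (42, -0.150, 0.927, -44, 0.004, -0.173),
    (44, -0.408, 0.855, -40, 0.006, -0.245),
    (46, 0.018, 0.339, -22, 0.008, -0.171),
    (47, -0.686, 0.930, -32, 0.013, -0.400),
    (48, -0.102, 0.969, -17, 0.016, -0.270),
    (49, -0.149, 0.729, -45, 0.010, -0.455),
    (50, -0.354, 0.870, -34, 0.008, -0.283),
    (51, 0.677, 0.926, -17, 0.005, -0.077),
    (52, 0.115, 0.916, -51, 0.004, -0.179),
    (53, -0.112, 0.584, -52, 0.003, -0.156),
    (54, 0.481, 0.957, -18, 0.006, -0.112),
    (55, 0.342, 0.726, -7, 0.003, -0.024),
    (56, 0.219, 0.803, -31, 0.005, -0.150),
    (57, -0.059, 0.583, -42, 0.003, -0.119),
    (58, -0.175, 0.373, -64, 0.004, -0.262),
]


def subject_correlation_table() -> pd.DataFrame:
    """The 34-subject correlation/lag table as a DataFrame."""
    return pd.DataFrame(
        _SUBJECT_ROWS,
        columns=["subject_id", "measured_r", "acf_r", "incremental_lag", "dt", "lag_time"],
    )
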