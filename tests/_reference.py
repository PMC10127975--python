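"""Published reference values used as test inputs.

COHORT_AICC_DELTAS: corrected-AIC criterion differences for a 19-patient
head-and-neck cohort, six models per patient (columns: exponential,
fractional exponential, logistic, fractional logistic, exponential-linear,
fractional exponential-linear), printed to 2 decimal places.  These are
*inputs* for arithmetic checks of the selection machinery, not fixtures a
model must reproduce.
"""

import numpy as np

MODEL_COLUMNS = (
    "exp", "fr_exp", "log", "fr_log", "explin", "fr_explin",
)

COHORT_AICC_DELTAS = np.array([
    [0.00, 5.60, 1.43, 7.03, 5.60, 14.93],   # patient 1
    [0.84, 2.03, 0.00, 1.70, 4.98, 10.66],   # patient 2
    [3.79, 3.95, 0.00, 5.60, 1.73, 10.99],   # patient 3
    [0.00, 7.00, 0.83, 7.83, 7.00, 21.00],   # patient 4
    [0.00, 5.60, 1.33, 6.93, 5.60, 14.93],   # patient 5
    [0.00, 5.60, 1.86, 7.46, 5.60, 14.93],   # patient 6
    [0.00, 5.60, 4.42, 10.02, 5.60, 14.93],  # patient 7
    [0.00, 5.60, 1.54, 7.14, 5.60, 14.93],   # patient 8
    [0.00, 7.00, 4.41, 11.41, 7.00, 21.00],  # patient 9
    [0.00, 4.80, 2.07, 6.87, 4.80, 12.00],   # patient 10
    [0.00, 5.60, 0.15, 5.75, 5.51, 14.84],   # patient 11
    [0.00, 5.60, 0.37, 5.97, 5.60, 14.93],   # patient 12
    [0.00, 5.60, 0.76, 6.36, 5.60, 14.93],   # patient 13
    [0.50, 0.00, 14.07, 19.67, 2.82, 9.33],  # patient 14
    [0.00, 5.60, 3.91, 9.51, 5.65, 14.98],   # patient 15
    [0.00, 5.60, 2.12, 7.72, 5.60, 14.93],   # patient 16
    [0.14, 5.74, 0.00, 5.60, 5.46, 14.80],   # patient 17
    [0.00, 5.60, 0.54, 6.14, 5.60, 14.93],   # patient 18
    [0.00, 4.80, 1.98, 6.78, 4.80, 12.00],   # patient 19
])

# Fitted-parameter counts of the six model variants, in column order.
MODEL_N_PARAMS = (2, 3, 2, 3, 3, 4)

# Reference single-patient fitted values (exponential and
# exponential-linear fits of the same series).
PATIENT5_EXP_A = 0.0118
PATIENT5_EXP_ALPHA = 0.0222
PATIENT5_EXPLIN_LAMBDA0 = 0.0118
PATIENT5_EXPLIN_LAMBDA1 = 0.5007

# Published cohort-summary values for the fractional exponential-linear
# column (mean criterion difference, tie-averaged rank tally).
FR_EXPLIN_MEAN_DELTA = 14.53
FR_EXPLIN_RANK_TALLY = 112.0

# Published logistic-model Akaike weight for the patient-4 delta row.
PATIENT4_LOGISTIC_WEIGHT = 0.37924

# Published tie-averaged ranking of the patient-5 delta row.
PATIENT5_RANKING = (1.0, 3.5, 2.0, 5.0, 3.5, 6.0)
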