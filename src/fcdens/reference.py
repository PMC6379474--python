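"""Published reference values for worked examples and consistency checks.

These constants are the printed group-level summary statistics of a
resting-state connectivity-density study of alcohol dependence (24 male
patients, 24 male healthy controls).  Raw imaging data for that study were
never deposited, so the numbers serve two purposes only: worked examples of
the summary-statistic routines (two-sample t from group means, ROC-table
summaries, correlation p-values), and internal-consistency checks of the
formulas — not as a reproduction of the imaging analysis.
"""

from __future__ import annotations

import pandas as pd

# Group demographics and clinical scores, mean and sd per group (n = 24 each).
DEMOGRAPHICS = pd.DataFrame(
    [
        # variable,             patient mean, sd,   control mean, sd
        ("age_years",            47.83, 6.93, 47.67, 6.99),
        ("education_years",       9.67, 3.09,  8.33, 3.21),
        ("audit_score",          24.08, 5.69,  2.63, 0.97),
    ],
    columns=["variable", "patient_mean", "patient_sd", "control_mean", "control_sd"],
)

N_PER_GROUP = 24

# Region-level in-sample ROC results for the corrected group-difference
# clusters (map kind: long- or short-range degree).  Sensitivity and
# specificity in percent; cutoffs on the mean-scaled map value.
ROC_TABLE = pd.DataFrame(
    [
        ("R_cerebellum_posterior_lobe", "long",  0.806, 70.8, 79.2,  0.3530),
        ("L_superior_temporal_gyrus",   "short", 0.830, 87.5, 70.8, -0.7980),
        ("R_fusiform_gyrus",            "short", 0.833, 79.2, 75.0, -0.6405),
        ("L_lentiform_nucleus",         "short", 0.844, 83.3, 75.0, -0.0515),
        ("L_lingual_gyrus",             "short", 0.832, 91.7, 62.5,  0.2195),
        ("R_middle_occipital_gyrus",    "short", 0.826, 70.8, 87.5,  0.8400),
        ("R_medial_frontal_gyrus",      "short", 0.878, 66.7, 95.8, -0.2770),
        ("L_precentral_gyrus",          "short", 0.851, 91.7, 83.3, -0.1730),
        ("R_cingulate_gyrus",           "short", 0.806, 79.2, 79.2,  0.5365),
    ],
    columns=["region", "map", "auc", "sensitivity_pct", "specificity_pct", "cutoff"],
)

# Combined visual-pathway score (fusiform + lingual + middle occipital).
COMBINED_ROC = {
    "auc": 0.943,
    "sensitivity_pct": 91.7,
    "specificity_pct": 91.7,
    "cutoff": 0.4629,
}

# Reported Pearson correlations in the patient group (n = 24).
CORRELATIONS = pd.DataFrame(
    [
        ("years_of_drinking", "R_cerebellum_posterior_lobe", -0.513, 0.010),
        ("SADQ",              "L_lingual_gyrus",              0.412, 0.045),
        ("SADQ",              "audit_score",                  0.630, 0.001),
        ("SADQ",              "R_medial_frontal_gyrus",       0.367, 0.077),
    ],
    columns=["variable", "against", "r", "p"],
)

# Cluster-correction convention the study used: two-tailed voxel p < 0.01,
# cluster-level alpha 0.05, contiguous volume >= 1080 mm^3 on a 3 mm grid.
CLUSTER_MIN_VOLUME_MM3 = 1080.0
VOXEL_SIZE_MM = 3.0
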