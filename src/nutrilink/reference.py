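"""Published summary statistics from the 2019/20 Rwanda DHS analysis of
co-occurring child undernutrition and anemia.

These constants are the printed summary tables of that analysis — sample
size, outcome frequencies, the joint 2x2 distribution of anemia and
undernutrition, the eigenstructure of the three anthropometric z-scores, and
selected covariate frequencies.  They serve as worked-example inputs and as
fixed points the package's arithmetic can be checked against; the underlying
child-level microdata are access-restricted and are not distributed here
(the synthetic generator in :mod:`nutrilink.synthdata` emulates them).
"""

from __future__ import annotations

import numpy as np

#: weighted number of children in the analysis sample
N_CHILDREN = 3206

#: outcome frequencies: (count coded 0, count coded 1)
ANEMIA_COUNTS = {"not_anemic": 1724, "anemic": 1482}
UNDERNUTRITION_COUNTS = {"nourished": 2548, "undernourished": 658}

#: joint 2x2 weighted counts of (anemia, undernutrition):
#: keys are (y_anemia, y_undernutrition)
JOINT_COUNTS = {(1, 1): 371, (1, 0): 1111, (0, 1): 280, (0, 0): 1444}

#: printed pairwise correlations of the anthropometric z-scores
ZSCORE_CORRELATIONS = {("haz", "waz"): 0.42, ("haz", "whz"): 0.44, ("waz", "whz"): 0.62}

#: the same correlations as a matrix in (haz, waz, whz) order
ZSCORE_CORR_MATRIX = np.array(
    [
        [1.00, 0.42, 0.44],
        [0.42, 1.00, 0.62],
        [0.44, 0.62, 1.00],
    ]
)

#: printed eigenvalues of the z-score correlation matrix and PC1 loadings
EIGENVALUES = np.array([1.995, 0.631, 0.375])
PC1_LOADINGS = np.array([0.521, 0.600, 0.608])

#: the single association odds ratio between anemia and undernutrition,
#: as printed (computed from 3-dp rounded joint probabilities)
ASSOCIATION_OR = 1.729

#: covariate level frequencies (counts), a subset of the published
#: frequency table used as generator defaults; the first level of each
#: covariate is its modelling reference category
COVARIATE_COUNTS = {
    "residence": {"rural": 2662, "urban": 544},
    "water_source": {"not_improved": 2054, "improved": 1152},
    "mother_anemia": {"not_anemic": 2827, "anemic": 379},
    "twin": {"single": 3116, "multiple": 90},
    "child_age": {"infant": 667, "12_59_months": 2539},
    "sex": {"male": 1640, "female": 1566},
    "birth_size": {"small": 532, "average": 1668, "large": 1006},
}

#: anemia-by-twin-status cross-tabulation (not anemic, anemic) per row
TWIN_ANEMIA_TABLE = np.array([[1778, 1338], [37, 53]])
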