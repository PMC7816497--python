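"""Published summary statistics for the registry cohort of 1,594 surgically
resected primary retroperitoneal tumors (SEER, diagnoses 2004-2016).

The patient-level registry extract is not redistributable; what *is* public
are the cohort's printed summary rates, reproduced here to one decimal as
published.  They serve two purposes: as inputs to the worked examples
(conditional-survival ratios and standardized differences computed from
printed actual rates) and as calibration anchors for the synthetic
generator's defaults.  Keys are years since resection.
"""

from __future__ import annotations

COHORT_SIZE = 1594
DEATHS = 693
CANCER_SPECIFIC_DEATHS = 523
#: share of deaths attributed to the index cancer
CANCER_SPECIFIC_DEATH_FRACTION = 0.755

#: Actual (unconditional) overall survival, percent.
ACTUAL_OS_PERCENT = {1: 89.8, 3: 71.8, 4: 65.5, 5: 60.8, 6: 56.0, 8: 48.2}

#: Actual cancer-specific survival, percent.
ACTUAL_CSS_PERCENT = {1: 91.9, 3: 77.1, 4: 71.8, 5: 67.8, 6: 63.7, 8: 58.2}

#: Whole-cohort 3-year conditional rates by years already survived.
COS3_OVERALL_PERCENT = {0: 71.8, 1: 72.9, 2: 76.5, 3: 77.9, 4: 79.6, 5: 79.3}
CCSS3_OVERALL_PERCENT = {0: 77.1, 1: 78.1, 2: 81.3, 3: 82.7, 4: 84.9, 5: 85.8}

#: Subgroup 3-year conditional rates used in the worked comparisons.
COS3_BY_GRADE_PERCENT = {
    "I": {0: 90.5, 1: 87.7, 2: 87.1, 3: 89.1, 4: 85.4, 5: 90.0},
    "III": {0: 53.8, 1: 58.5, 2: 66.2, 3: 68.0, 4: 71.5, 5: 78.9},
}
CCSS3_BY_CHEMOTHERAPY_PERCENT = {
    "no": {0: 80.6, 1: 81.3, 2: 83.8, 3: 84.5, 4: 86.5, 5: 86.7},
    "yes": {0: 56.2, 1: 58.0, 2: 64.1, 3: 68.6, 4: 72.2, 5: 77.7},
}
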