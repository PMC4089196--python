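"""Score a tiny hand-written diary into daily RTSS / TRMS / CSMS values.

RTSS sums six 0-3 symptom grades (0-18); TRMS adds 1/2/3/5 points per
rescue-medication class used; CSMS = RTSS + TRMS is the daily severity
outcome every downstream analysis correlates against.
"""

import pandas as pd

from pollencorr import score_diary, cohort_mean_csms_series

diary = pd.DataFrame(
    [
        # patient, date, sneeze, runny, itchy nose, congestion, tearing, itchy eyes, meds...
        ("P1", "2009-06-01", 1, 2, 0, 3, 0, 1, 0, 1, 0, 0),
        ("P1", "2009-06-02", 3, 3, 3, 3, 3, 3, 0, 1, 1, 0),
        ("P2", "2009-06-01", 1, 1, 1, 1, 1, 1, 0, 0, 0, 0),
        ("P2", "2009-06-02", 0, 0, 0, 0, 0, 0, 0, 0, 0, 0),
    ],
    columns=[
        "patient_id", "date",
        "sneezing", "runny_nose", "itchy_nose", "nasal_congestion", "tearing", "itchy_eyes",
        "med_chromone", "med_antihistamine", "med_corticosteroid", "med_leukotriene",
    ],
)

scores = score_diary(diary)
print(scores.to_string(index=False))
# P1 on Jun 2: all symptoms maximal (RTSS 18) plus antihistamine (2) and
# nasal corticosteroid (3) -> TRMS 5, CSMS 23.

mean, count = cohort_mean_csms_series(scores)
print("\nCohort daily mean CSMS (both patients):")
print(pd.DataFrame({"mean_csms": mean, "n_patients": count}).to_string())
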