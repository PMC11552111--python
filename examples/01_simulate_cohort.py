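"""Simulate a 38-patient end-of-therapy PET/CT cohort and summarise it.

Covariates, true IMS levels and proportional-hazards survival outcomes are
drawn from one master seed; the printed table shows the IMS distribution and
the group-wise event counts the downstream analyses operate on.
"""

import numpy as np

from imscore import (records_to_dataframe, simulate_covariates,
                     simulate_outcomes, simulate_true_scores)

records = simulate_covariates(38, seed=2024, cohort="PET_CT")
records = simulate_true_scores(records, seed=2024)
records = simulate_outcomes(records, seed=2024)
df = records_to_dataframe(records)

print("IMS level counts:", np.bincount(df["true_ims"], minlength=6)[1:])
for label, sub in df.groupby(df["true_ims"] >= 4):
    name = "IMS 4-5" if label else "IMS 1-3"
    print(f"{name}: n={len(sub)}, PFS events={int(sub.pfs_event.sum())}, "
          f"median observed PFS={sub.pfs_time.median():.0f} days")
# Patients scored 4-5 progress far sooner than 1-3 (generating HR ~ 9),
# mirroring the prognostic separation the score is designed to capture.
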