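"""Kaplan-Meier, log-rank and Cox analysis of a simulated cohort.

Reproduces the analysis pattern used for score validation: stratify PFS by
the IMS 1-3 vs 4-5 dichotomy, test the separation, and estimate the hazard
ratio with a Wald interval.
"""

import numpy as np

from imscore import (cox_fit, km_estimate, logrank_test, records_to_dataframe,
                     simulate_covariates, simulate_outcomes, simulate_true_scores)

records = simulate_outcomes(
    simulate_true_scores(simulate_covariates(200, seed=5), seed=5), seed=5)
df = records_to_dataframe(records)
group = np.where(df["true_ims"] >= 4, "IMS 4-5", "IMS 1-3")

for label in ("IMS 1-3", "IMS 4-5"):
    sub = df[group == label]
    est = km_estimate(sub["pfs_time"], sub["pfs_event"])
    med = "not reached" if est.median is None else f"{est.median:.0f} days"
    print(f"{label}: n={est.n}, events={est.n_events}, median PFS {med}")

lr = logrank_test(df["pfs_time"], df["pfs_event"], group)
print(f"log-rank chi2={lr.chi2:.1f} (df={lr.df}), p={lr.p:.2e}")

fit = cox_fit(df["pfs_time"].to_numpy(), df["pfs_event"].to_numpy(),
              (df["true_ims"] >= 4).astype(float).to_numpy(),
              names=["ims_4-5"])
eff = fit.effect("ims_4-5")
print(f"Cox HR {eff.hr:.2f} (95% CI {eff.ci_low:.2f}-{eff.ci_high:.2f})")
# The estimated hazard ratio recovers the generating value (~9) within
# sampling error; the log-rank p-value reflects the same group separation.
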