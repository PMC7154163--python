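"""The 2-df score splitting statistic vs the classical logrank.

Simulates a cohort in which the two groups have the same cure fraction but
different event dynamics (alpha = 0, beta != 0) - crossing hazards - and
compares the two splitting criteria on the same data.
"""

import numpy as np
from scipy.stats import chi2

import cureforest as cf
from cureforest.splitting import null_estimates, score_split_statistic

spec = cf.SignalSpec(
    covariates=[cf.CovariateEffect("w", "binary", alpha=0.0, beta=1.0)],
    theta0=0.7, censor_horizon=3.0)
cohort = cf.generate_cure_cohort(400, spec, seed=42)
w = cohort.data["w"].to_numpy()
print(f"Cohort: n={cohort.n}, events={int(cohort.event.sum())}, "
      f"group sizes {int((w == 0).sum())}/{int((w == 1).sum())}")

ne = null_estimates(cohort.time, cohort.event)
print(f"Null plug-ins: theta0_hat={ne.theta0_hat:.3f} "
      f"(estimated mean clone count; cure fraction ~ {np.exp(-ne.theta0_hat):.3f})")

res = score_split_statistic(cohort.time, cohort.event, w, ne)
lr = cf.logrank_statistic(cohort.time, cohort.event, w)
print(f"\nScore statistic: U=({res.u[0]:+.3f}, {res.u[1]:+.3f}) "
      f"chi2={res.statistic:.2f} on {res.df_used} df "
      f"(p={chi2.sf(res.statistic, res.df_used):.4f})")
print(f"Logrank:         chi2={lr:.2f} on 1 df (p={chi2.sf(lr, 1):.4f})")
print("\nThe beta component reweights the logrank residuals by 1 - H0_hat(t),")
print("which changes sign over follow-up and picks up the crossing-hazard")
print("pattern a dynamics-only effect produces; the plain logrank, integrating")
print("early excess against late deficit, largely cancels it out.")
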