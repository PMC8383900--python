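"""Generate a calibrated synthetic cohort and rerun the association analysis.

Draws n=3074 subjects whose FTD is linearly driven by age, sex, BMI,
axial length, parapapillary atrophy and subfoveal choroidal thickness
(SFCT), then fits the stepwise multivariate model and the stratified
summaries an epidemiological study would report.
"""

import numpy as np

import fundtess as ft
from fundtess.cohort import PREDICTORS

cohort = ft.generate_cohort(3074, seed=1)
print(f"n = {len(cohort)}, mean FTD = {cohort['ftd'].mean():.3f} "
      f"+- {cohort['ftd'].std():.3f}")
print(f"age-FTD Pearson r = "
      f"{np.corrcoef(cohort['age'], cohort['ftd'])[0, 1]:.3f}")

report = ft.multivariate_stepwise(cohort, list(PREDICTORS))
print(f"\nmultivariate model R = {report.model_r:.3f}")
print(report.terms[["beta", "vif", "p"]].round(4))
# beta: standardized coefficient (association strength per SD);
# vif: variance inflation factor (collinearity; < 3 here by design).

strata = ft.stratified_summaries(cohort)
print("\nFTD by age decade:")
print(strata["age_groups"].round(3))
print(f"ANOVA F = {strata['age_anova']['F']:.1f}, "
      f"p = {strata['age_anova']['p']:.2e}")
print("\nFTD by refraction class (myopia: SE < -0.25 D):")
print(strata["refraction"].round(3))
# the myopia row's r is the within-stratum correlation between spherical
# equivalent and FTD: more myopic eyes show denser tessellation.
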