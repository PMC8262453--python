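"""Cluster-wise z-transform of the tempo measure, then a multiple regression
on age, arousal, long-term stress, and musical experience.

The z-transform puts all tempo clusters on a common scale so faster/slower-
than-cluster tendencies can be predicted across modes.  Writes
results/regression.csv.
"""

import numpy as np
import pandas as pd
from _common import RESULTS, SEED, cleaned_records, load_cohort

from tempoclust.inference import clusterwise_z, fit_regression
from tempoclust.mixture import fit_em

ds = load_cohort()
kept, _, _ = cleaned_records(ds)
iti = np.array([r.summary.mean_iti for r in kept])
cv = np.array([r.summary.cv for r in kept])
model = fit_em(np.column_stack([iti, cv]), K=6, family="EEI", seed=SEED)

z = clusterwise_z(iti, model.assignments)
predictors = {
    k: np.array([getattr(r, k) for r in kept], dtype=float)
    for k in ("age", "arousal", "pss4", "musical_experience")
}
res = fit_regression(z, predictors, standardize=True)

print(
    f"model: F({res.df_model},{res.df_resid}) = {res.F:.2f}, "
    f"p = {res.p_model:.4f}, R^2 = {res.r_squared:.4f}"
)
rows = [
    {"predictor": k, "beta_std": res.coefficients[k], "p": res.p_values[k]}
    for k in predictors
]
for r in rows:
    print(f"  {r['predictor']:<20} beta = {r['beta_std']:+.4f}  p = {r['p']:.4f}")
pd.DataFrame(rows).to_csv(RESULTS / "regression.csv", index=False)
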