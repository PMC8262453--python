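"""Subharmonic structure: are cluster tempi multiples of one base period?

Evaluates the published six cluster means against T = 251 ms with
multipliers {1,2,3,4,5,7}, then estimates the base period from the fitted
cluster means of the simulated cohort on a 200-300 ms grid.  Writes
results/harmonics.json.
"""

import json

import pandas as pd
from _common import RESULTS

from tempoclust.harmonics import estimate_base_period, harmonic_fit

published = [265, 525, 754, 997, 1314, 1757]
fit = harmonic_fit(published, T=251, allowed_n=(1, 2, 3, 4, 5, 7))
print(
    f"published cluster means vs n*251 ms: deviations {fit.deviations_ms} ms, "
    f"MAD {fit.mad_ms} ms (range {fit.dev_min:.0f}-{fit.dev_max:.0f} ms)"
)
T_star, fit_star = estimate_base_period(published, allowed_n=(1, 2, 3, 4, 5, 7))
print(f"grid-estimated base period: {T_star:.1f} ms (MAD {fit_star.mad:.1f} ms)")

out = {"published": fit.as_dict(), "estimated_base_period_ms": T_star}
desc_path = RESULTS / "cluster_descriptives.csv"
if desc_path.exists():
    fitted_means = pd.read_csv(desc_path)["mean_iti_ms"].dropna().tolist()
    T_fit, fit_fitted = estimate_base_period(fitted_means, allowed_n=(1, 2, 3, 4, 5, 7))
    print(
        f"fitted simulated clusters: base period {T_fit:.1f} ms, "
        f"MAD {fit_fitted.mad:.1f} ms"
    )
    out["simulated"] = {"estimated_base_period_ms": T_fit, "fit": fit_fitted.as_dict()}
(RESULTS / "harmonics.json").write_text(json.dumps(out, indent=1))
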