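"""Generate the study cohort: 3,600 synthetic participants with tempo modes
at multiples of 251 ms, covariate effects, and planted contamination.

Writes participants.csv / trials.csv / ground_truth.json under results/cohort.
"""

from _common import COHORT_DIR, SEED

from tempoclust.io import write_dataset, write_ground_truth
from tempoclust.simulate import SimConfig, simulate_cohort

cfg = SimConfig(
    n_participants=3600,
    seed=SEED,
    repeat_rate=0.03,
    fast_rate=0.01,
    age_outlier_rate=0.008,
    invalid_rate=0.004,
    bad_country_rate=0.001,
)
ds, truth = simulate_cohort(cfg)
COHORT_DIR.mkdir(parents=True, exist_ok=True)
write_dataset(ds, COHORT_DIR / "participants.csv", COHORT_DIR / "trials.csv")
write_ground_truth(truth, COHORT_DIR / "ground_truth.json")

print(f"wrote {len(ds.participants)} participants to {COHORT_DIR}")
print(f"planted contamination: {truth.planted_counts}")
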