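"""Trial acceptance and the cohort cleaning cascade.

Applies the online acceptance rule (CV <= 0.1, >= 8 taps) to every trial and
then the five-stage cleaning cascade; writes the per-stage audit to
results/filter_audit.csv and checks it against the planted contamination.
"""

import json

import pandas as pd
from _common import COHORT_DIR, RESULTS, cleaned_records, load_cohort

ds = load_cohort()
kept, audit, _ = cleaned_records(ds)

table = pd.DataFrame(audit.as_rows())
table.to_csv(RESULTS / "filter_audit.csv", index=False)
print(table.to_string(index=False))

truth = json.loads((COHORT_DIR / "ground_truth.json").read_text())
planted = truth["planted_counts"]
removed = {
    "repeat": audit.removed_by("REPEAT"),
    "fast": audit.removed_by("FAST_ITI"),
    "age_outlier": audit.removed_by("AGE_OUTLIER"),
    "invalid": audit.removed_by("INVALID_RECORD"),
    "bad_country": audit.removed_by("COUNTRY"),
}
print(f"\nkept {audit.n_final} of {audit.n_initial} participants")
for kind, n_removed in removed.items():
    flag = "OK" if n_removed == planted[kind] else "MISMATCH"
    print(f"  {kind:<12} removed {n_removed:>3}  planted {planted[kind]:>3}  {flag}")
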