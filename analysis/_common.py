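"""Shared paths and cohort loading for the numbered analysis drivers."""

from pathlib import Path

RESULTS = Path(__file__).resolve().parent.parent / "results"
COHORT_DIR = RESULTS / "cohort"
SEED = 1


def load_cohort():
    """Load the cohort written by 01_simulate_cohort.py (run it first)."""
    from tempoclust.io import read_dataset

    if not (COHORT_DIR / "participants.csv").exists():
        raise SystemExit("run analysis/01_simulate_cohort.py first")
    ds, log = read_dataset(COHORT_DIR / "participants.csv", COHORT_DIR / "trials.csv")
    return ds


def cleaned_records(ds, seed=SEED):
    from tempoclust.datatypes import PipelineConfig
    from tempoclust.pipeline import join_accepted_trials
    from tempoclust.preprocess import clean_cohort

    cfg = PipelineConfig(seed=seed)
    kept, audit = clean_cohort(join_accepted_trials(ds, cfg), cfg)
    return kept, audit, cfg
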