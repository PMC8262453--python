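"""Trial summaries, acceptance rule, and the cohort cleaning cascade."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tempoclust.datatypes import ParticipantRecord, PipelineConfig, TrialSummary
from tempoclust.preprocess import (
    REASON_AGE_OUTLIER,
    REASON_COUNTRY,
    REASON_FAST_ITI,
    REASON_INVALID,
    REASON_REPEAT,
    age_fences,
    clean_cohort,
    compute_itis,
    evenness_score,
    summarize_trial,
)


@pytest.mark.parametrize(
    "timestamps,expected",
    [
        ([0, 500, 1000, 1500], [500, 500, 500]),
        ([0, 400, 900, 1500], [400, 500, 600]),
        ([0, 100], [100]),
    ],
)
def test_compute_itis_successive_differences(timestamps, expected):
    np.testing.assert_allclose(compute_itis(timestamps), expected)


@pytest.mark.parametrize("bad", [[0], [], [0, 100, 100], [100, 50]])
def test_compute_itis_rejects_invalid_input(bad):
    with pytest.raises(ValueError):
        compute_itis(bad)


def test_summary_hand_arithmetic():
    # 4 taps, ITIs 400/500/600: mean 500, sample SD 100, CV 0.2 -> both rules fail
    s = summarize_trial([400, 500, 600])
    assert s.mean_iti == 500
    assert s.median_iti == 500
    assert s.sd_iti == pytest.approx(100.0)
    assert s.cv == pytest.approx(0.2)
    assert s.n_taps == 4
    assert not s.accepted


def test_summary_boundaries():
    # exactly 8 taps with zero variability: accepted, evenness 100
    s = summarize_trial([500.0] * 7)
    assert s.n_taps == 8
    assert s.cv == 0.0
    assert s.evenness_pct == 100.0
    assert s.accepted
    # CV exactly at the threshold is accepted (inclusive read of the rule)
    itis = np.array([450.0, 550.0] * 4)
    s2 = summarize_trial(itis, cv_max=summarize_trial(itis).cv)
    assert s2.accepted


@settings(max_examples=50, deadline=None)
@given(st.floats(0.0, 1.0), st.floats(0.0, 1.0))
def test_evenness_strictly_decreasing_in_cv(cv1, cv2):
    # strict decrease asserted only for float-distinguishable CV gaps
    if cv1 + 1e-9 < cv2:
        assert evenness_score(cv1) > evenness_score(cv2)
    elif cv1 == cv2:
        assert evenness_score(cv1) == evenness_score(cv2)


def _record(pid, age=30.0, mean_iti=500.0, repeat=False, country="Germany", arousal=3, date=""):
    return ParticipantRecord(
        participant_id=pid,
        age=age,
        country=country,
        arousal=arousal,
        musical_experience=2,
        pss4=5,
        repeat_flag=repeat,
        local_date=date,
        summary=TrialSummary(mean_iti, mean_iti, mean_iti * 0.05, 0.05, 30, 95.0, True),
    )


def test_clean_cohort_duplicate_and_fast_iti():
    records = [_record(f"P{i}") for i in range(8)]
    records.append(_record("P0", date="2021-06-02"))  # second attempt, same id
    records.append(_record("P9", mean_iti=95.0))
    kept, audit = clean_cohort(records)
    assert len(kept) == 8
    assert audit.removed_by(REASON_REPEAT) == 1
    assert audit.removed_by(REASON_FAST_ITI) == 1
    # conservation at every stage
    for prev, nxt in zip(audit.stages, audit.stages[1:]):
        assert prev.n_after == nxt.n_before
        assert nxt.n_after == nxt.n_before - nxt.n_removed


def test_mean_iti_exactly_100_is_kept():
    records = [_record(f"P{i}") for i in range(6)]
    records.append(_record("PX", mean_iti=100.0))
    kept, audit = clean_cohort(records)
    assert any(r.participant_id == "PX" for r in kept)
    assert audit.removed_by(REASON_FAST_ITI) == 0


def test_country_sanity_and_invalid_record():
    records = [_record(f"P{i}") for i in range(6)]
    records.append(_record("PA", country="Antarctica"))
    records.append(_record("PB", arousal=None))
    kept, audit = clean_cohort(records)
    assert audit.removed_by(REASON_COUNTRY) == 1
    assert audit.removed_by(REASON_INVALID) == 1
    assert len(kept) == 6


def test_planted_contamination_counts_match_audit(small_cohort):
    ds, truth = small_cohort
    cfg = PipelineConfig(seed=11)
    from tempoclust.pipeline import join_accepted_trials

    kept, audit = clean_cohort(join_accepted_trials(ds, cfg), cfg)
    assert audit.removed_by(REASON_INVALID) == truth.planted_counts["invalid"]
    assert audit.removed_by(REASON_REPEAT) == truth.planted_counts["repeat"]
    assert audit.removed_by(REASON_FAST_ITI) == truth.planted_counts["fast"]
    assert audit.removed_by(REASON_AGE_OUTLIER) == truth.planted_counts["age_outlier"]


def test_clean_cohort_idempotent_and_age_fence(cleaned_points):
    kept, _, _ = cleaned_points
    kept2, audit2 = clean_cohort(kept)
    assert [r.participant_id for r in kept2] == [r.participant_id for r in kept]
    assert audit2.n_final == len(kept)
    lo, hi = age_fences([r.age for r in kept])
    assert all(lo <= r.age <= hi for r in kept2)


def test_empty_cohort_rejected():
    with pytest.raises(ValueError):
        clean_cohort([])
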