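"""Core record types shared by every pipeline stage.

A cohort is a :class:`Dataset`: one :class:`ParticipantRecord` per respondent
plus the raw :class:`TapTrial` logs keyed by participant id.  Trial-level
statistics live in :class:`TrialSummary`; every cohort-cleaning decision is
recorded in a :class:`FilterAudit`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

#: Covariance families searched by default (mclust-style codes).
DEFAULT_FAMILIES = ("EII", "VII", "EEI", "VEI", "EVI", "VVI", "EEE", "VVV")

#: Multiplier preset used for the subharmonic fit of cluster tempi.
PAPER_MULTIPLIERS = (1, 2, 3, 4, 5, 7)
FULL_MULTIPLIERS = (1, 2, 3, 4, 5, 6, 7)


@dataclass
class TapTrial:
    """One finger-tapping trial: raw tap times plus execution context."""

    participant_id: str
    timestamps: np.ndarray  # ms since trial start, strictly increasing
    local_hour: int  # 0-23, local clock hour of execution
    local_date: str = ""
    device_category: str = "keyboard/mouse"
    os_category: str = "other"
    browser_category: str = "other"
    attempt_index: int = 1

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)

    def validate(self) -> None:
        ts = self.timestamps
        if ts.size and (np.any(np.diff(ts) <= 0) or ts[0] < 0):
            raise ValueError(
                f"trial {self.participant_id}: timestamps must be "
                "non-negative and strictly increasing"
            )
        if not 0 <= int(self.local_hour) <= 23:
            raise ValueError(
                f"trial {self.participant_id}: local_hour {self.local_hour} "
                "outside [0, 23]"
            )


@dataclass
class TrialSummary:
    """Derived ITI statistics and the acceptance verdict for one trial.

    ``accepted`` is true iff ``cv <= cv_max`` and ``n_taps >= min_taps`` (the
    online task's automatic repeat rule).  ``evenness_pct`` is the consistency
    feedback shown to the participant, anchored so that CV = 0 maps to 100%.
    """

    mean_iti: float
    median_iti: float
    sd_iti: float
    cv: float
    n_taps: int
    evenness_pct: float
    accepted: bool


@dataclass
class ParticipantRecord:
    """Demographics and questionnaire scores, joined with the accepted trial."""

    participant_id: str
    age: Optional[float]
    gender: str = "unspecified"
    country: str = ""
    city_size_category: str = ""
    arousal: Optional[int] = None  # 1 = very calm .. 5 = very excited
    musical_experience: Optional[int] = None  # 1 = never .. 6 = professional
    pss4: Optional[int] = None  # perceived stress, 0-16
    work_hours: Optional[float] = None
    repeat_flag: bool = False
    n_attempts: int = 1
    local_hour: Optional[int] = None  # populated on join with the trial
    local_date: str = ""
    summary: Optional[TrialSummary] = None

    def scales_valid(self) -> bool:
        """True when every required field is present and within its scale."""
        if self.age is None or not math.isfinite(self.age):
            return False
        if self.arousal is None or not 1 <= self.arousal <= 5:
            return False
        if self.musical_experience is None or not 1 <= self.musical_experience <= 6:
            return False
        if self.pss4 is None or not 0 <= self.pss4 <= 16:
            return False
        return True


@dataclass
class Dataset:
    """A cohort: participant table + tap logs + a free-text source label."""

    participants: list[ParticipantRecord]
    trials: list[TapTrial]
    provenance: str = ""

    def validate(self) -> None:
        ids = [p.participant_id for p in self.participants]
        if len(set(ids)) != len(ids):
            raise ValueError("participant ids are not unique")
        known = set(ids)
        for t in self.trials:
            if t.participant_id not in known:
                raise ValueError(
                    f"trial references unknown participant {t.participant_id!r}"
                )
            t.validate()

    def trials_for(self, participant_id: str) -> list[TapTrial]:
        return [t for t in self.trials if t.participant_id == participant_id]


@dataclass(frozen=True)
class FilterStage:
    stage_name: str
    n_before: int
    n_removed: int
    n_after: int
    reason_code: str

    def __post_init__(self) -> None:
        if self.n_after != self.n_before - self.n_removed:
            raise ValueError(
                f"stage {self.stage_name}: {self.n_before} - {self.n_removed} "
                f"!= {self.n_after}"
            )


@dataclass
class FilterAudit:
    """Ordered per-stage record of the cohort cleaning cascade."""

    stages: list[FilterStage] = field(default_factory=list)

    def add(self, stage_name: str, n_before: int, n_removed: int, reason_code: str) -> None:
        stage = FilterStage(stage_name, n_before, n_removed, n_before - n_removed, reason_code)
        if self.stages and self.stages[-1].n_after != n_before:
            raise ValueError(
                f"audit chain broken at {stage_name}: previous n_after "
                f"{self.stages[-1].n_after} != n_before {n_before}"
            )
        self.stages.append(stage)

    def removed_by(self, reason_code: str) -> int:
        return sum(s.n_removed for s in self.stages if s.reason_code == reason_code)

    @property
    def n_initial(self) -> int:
        return self.stages[0].n_before if self.stages else 0

    @property
    def n_final(self) -> int:
        return self.stages[-1].n_after if self.stages else 0

    def as_rows(self) -> list[dict]:
        return [
            {
                "stage": s.stage_name,
                "n_before": s.n_before,
                "n_removed": s.n_removed,
                "n_after": s.n_after,
                "reason_code": s.reason_code,
            }
            for s in self.stages
        ]


@dataclass
class PipelineConfig:
    """Tunable thresholds of the full analysis pipeline.

    Defaults reproduce the study conditions: trials accepted when the
    coefficient of variation of ITIs is at most ``cv_max`` (inclusive) and at
    least ``min_taps`` taps were made; participants dropped when their mean
    ITI is strictly below ``min_mean_iti`` (100 ms, the motoric lower limit
    of finger tapping); ages fenced at ``iqr_factor`` interquartile ranges;
    mixtures searched up to ``k_max`` components.
    """

    cv_max: float = 0.1
    min_taps: int = 8
    min_mean_iti: float = 100.0
    iqr_factor: float = 1.5
    k_max: int = 9
    covariance_families: Sequence[str] = DEFAULT_FAMILIES
    seed: int = 0
    hour_resolution: str = "integer hour"
    invalid_countries: Sequence[str] = ("Antarctica",)
    base_period: float = 251.0
    harmonic_multipliers: Sequence[int] = PAPER_MULTIPLIERS
    standardize_features: bool = False  # optional sensitivity switch

    def __post_init__(self) -> None:
        if self.cv_max <= 0:
            raise ValueError("cv_max must be positive")
        if self.min_taps < 2:
            raise ValueError("min_taps must be at least 2")
        if self.k_max < 1:
            raise ValueError("k_max must be at least 1")

    def with_overrides(self, **kwargs) -> "PipelineConfig":
        return replace(self, **{k: v for k, v in kwargs.items() if v is not None})
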