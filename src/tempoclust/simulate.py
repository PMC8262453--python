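"""Synthetic tapping cohorts with known ground truth.

The generator emulates the statistical structure the analysis assumes:

* a multimodal spontaneous-tempo distribution with modes at integer
  multiples of a ~251 ms base period, cluster weights matching the observed
  cluster sizes, and shared within-mode spread (the spherical equal-volume
  mixture geometry);
* per-trial tapping noise with a participant-specific coefficient of
  variation below 0.1, over 15-second trials;
* covariate effects: older participants tilt toward slower modes, a
  sinusoidal time-of-day modulation of mean ITI (slowest in the early
  morning), and a within-cluster arousal effect on the z scale;
* configurable contamination — repeat participations, mean ITIs below the
  100 ms motoric limit, implausible ages, structurally invalid rows, and an
  implausible country — planted in disjoint participants so audit counts
  are exact.

Latent mean ITIs are floored at 123 ms (the slowest cohort's observed
minimum) so that uncontaminated participants can never trip the <100 ms
filter.  Ground truth (latent mode, latent tempo, contamination flags) is
emitted alongside the cohort and never read by the pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from tempoclust.datatypes import Dataset, ParticipantRecord, TapTrial
from tempoclust.preprocess import summarize_timestamps

#: Observed cluster sizes used as default mode weights.
TABLE_COUNTS = (223, 1184, 925, 852, 283, 109)

_AROUSAL_P = (0.22, 0.45, 0.25, 0.06, 0.02)  # mean 2.21, like the cohort
_MUSIC_P = (0.50, 0.20, 0.12, 0.08, 0.06, 0.04)  # mean ~2.1, mostly novices
_COUNTRIES = ("China", "Germany", "France", "United States", "India", "Brazil")
_COUNTRY_P = (0.812, 0.05, 0.04, 0.04, 0.03, 0.028)
_DEVICES = ("keyboard/mouse", "touchscreen")
_OSES = ("Windows", "macOS", "Android", "iOS", "Linux")
_BROWSERS = ("Chrome", "Safari", "Firefox", "Edge", "Other")


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults reproduce the cohort the analysis targets: 3,600 participants,
    six tempo modes at n*251 ms for n in {1,2,3,4,5,7} with weights
    proportional to the observed cluster sizes, 60 ms within-mode spread,
    15 s trials, and small covariate effects (age tilt of mode odds, a
    10 ms circadian sinusoid slowest around 05:00, arousal beta -0.05 on
    the within-cluster z scale).  Contamination rates default to zero.
    """

    n_participants: int = 3600
    base_period: float = 251.0
    mode_multipliers: Sequence[int] = (1, 2, 3, 4, 5, 7)
    mode_weights: Sequence[float] = TABLE_COUNTS
    within_mode_sd: float = 60.0
    cv_range: tuple[float, float] = (0.02, 0.09)
    cv_mean: float = 0.055
    cv_sd: float = 0.015
    trial_duration: float = 15000.0
    min_iti_floor: float = 123.0
    age_mean: float = 27.6
    age_sd: float = 7.6
    age_range: tuple[float, float] = (12.0, 45.0)
    age_slowing_effect: float = 0.25  # mode log-odds shift per decade per mode step
    circadian_amplitude: float = 10.0  # ms
    circadian_acrophase: float = 5.0  # local hour of slowest tempo
    arousal_effect_beta: float = -0.05  # standardized within-cluster effect
    hour_concentration: float = 0.8  # von Mises kappa of the hour distribution
    hour_peak: float = 15.0  # afternoon peak of participation
    repeat_rate: float = 0.0
    fast_rate: float = 0.0  # mean ITI < 100 ms contamination
    age_outlier_rate: float = 0.0
    invalid_rate: float = 0.0
    bad_country_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        w = np.asarray(self.mode_weights, dtype=float)
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("mode_weights must be non-negative with positive sum")
        if len(self.mode_multipliers) != w.size:
            raise ValueError("mode_multipliers and mode_weights lengths differ")
        lo, hi = self.cv_range
        if not 0 < lo < hi:
            raise ValueError("cv_range must satisfy 0 < lo < hi")
        slowest = max(self.mode_multipliers) * self.base_period
        if self.trial_duration / slowest < 7:
            import warnings

            warnings.warn(
                "slowest mode may not reach the minimum tap count within "
                "the trial duration; expect trial rejections",
                stacklevel=2,
            )

    @property
    def normalized_weights(self) -> np.ndarray:
        w = np.asarray(self.mode_weights, dtype=float)
        return w / w.sum()


@dataclass
class GroundTruth:
    """Latent state emitted beside the cohort; never read by the pipeline."""

    modes: dict = field(default_factory=dict)  # participant_id -> multiplier n
    latent_iti: dict = field(default_factory=dict)  # participant_id -> ms
    contamination: dict = field(default_factory=dict)  # participant_id -> type
    planted_counts: dict = field(default_factory=dict)  # type -> count
    config: SimConfig | None = None

    def as_dict(self) -> dict:
        return {
            "modes": self.modes,
            "latent_iti": self.latent_iti,
            "contamination": self.contamination,
            "planted_counts": self.planted_counts,
        }


def _truncated_normal(rng, mean, sd, lo, hi, size=None):
    out = rng.normal(mean, sd, size=size)
    bad = (out < lo) | (out > hi)
    while np.any(bad):
        out = np.where(bad, rng.normal(mean, sd, size=size), out)
        bad = (out < lo) | (out > hi)
    return out


def _sample_hour(rng, cfg: SimConfig) -> int:
    ang = rng.vonmises(2 * np.pi * cfg.hour_peak / 24.0 - np.pi, cfg.hour_concentration)
    hour = int(np.floor(((ang + np.pi) % (2 * np.pi)) / (2 * np.pi) * 24.0))
    return min(hour, 23)


def _mode_probs(cfg: SimConfig, age: float) -> np.ndarray:
    """Age-tilted mode probabilities: older -> higher odds of slower modes."""
    base = np.log(cfg.normalized_weights)
    idx = np.arange(len(cfg.mode_multipliers), dtype=float)
    idx -= idx.mean()
    tilt = cfg.age_slowing_effect * (age - cfg.age_mean) / 10.0
    logits = base + tilt * idx
    p = np.exp(logits - logits.max())
    return p / p.sum()


def _circadian_shift(cfg: SimConfig, hour: int) -> float:
    """Additive mean-ITI shift, maximal (slowest) at the acrophase hour."""
    return cfg.circadian_amplitude * math.cos(
        2 * math.pi * (hour - cfg.circadian_acrophase) / 24.0
    )


def _tap_train(rng, mean_iti: float, cv: float, duration: float) -> np.ndarray:
    """Cumulate noisy ITIs from t=0 until the trial duration elapses."""
    sd = cv * mean_iti
    ts = np.array([0.0])
    while ts[-1] <= duration:
        batch = int(duration / mean_iti) + 8
        itis = np.maximum(rng.normal(mean_iti, sd, size=batch), 1.0)
        ts = np.concatenate([ts, ts[-1] + np.cumsum(itis)])
    return ts[ts <= duration]


def _arousal_moments() -> tuple[float, float]:
    p = np.asarray(_AROUSAL_P)
    vals = np.arange(1, 6, dtype=float)
    mu = float(p @ vals)
    sd = float(np.sqrt(p @ (vals - mu) ** 2))
    return mu, sd


def simulate_cohort(config: SimConfig | None = None) -> tuple[Dataset, GroundTruth]:
    """Generate a full synthetic cohort plus its ground truth.

    Fully reproducible from ``config.seed``.  Contaminated participants are
    drawn as disjoint sets, so planted counts equal the cleaning cascade's
    per-stage removals exactly.
    """
    cfg = config or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_participants
    multipliers = np.asarray(cfg.mode_multipliers)
    a_mu, a_sd = _arousal_moments()

    # disjoint contamination assignment
    kinds = ("repeat", "fast", "age_outlier", "invalid", "bad_country")
    rates = (
        cfg.repeat_rate,
        cfg.fast_rate,
        cfg.age_outlier_rate,
        cfg.invalid_rate,
        cfg.bad_country_rate,
    )
    counts = [int(round(r * n)) for r in rates]
    if sum(counts) > n:
        raise ValueError("contamination rates sum above 1")
    perm = rng.permutation(n)
    contamination: dict[int, str] = {}
    pos = 0
    for kind, c in zip(kinds, counts):
        for idx in perm[pos : pos + c]:
            contamination[int(idx)] = kind
        pos += c

    participants: list[ParticipantRecord] = []
    trials: list[TapTrial] = []
    truth = GroundTruth(planted_counts=dict(zip(kinds, counts)), config=cfg)

    for i in range(n):
        pid = f"P{i:05d}"
        kind = contamination.get(i)
        age = float(np.round(_truncated_normal(rng, cfg.age_mean, cfg.age_sd, *cfg.age_range)))
        arousal = int(rng.choice(5, p=_AROUSAL_P)) + 1
        music = int(rng.choice(6, p=_MUSIC_P)) + 1
        pss4 = int(rng.binomial(16, 0.35))
        work_hours = float(rng.choice([20, 30, 40, 45, 50, 60], p=[0.1, 0.15, 0.3, 0.2, 0.15, 0.1]))
        country = str(rng.choice(_COUNTRIES, p=_COUNTRY_P))
        city = str(rng.choice(["<100k", "100k-1M", ">1M"], p=[0.2, 0.3, 0.5]))
        hour = _sample_hour(rng, cfg)
        date = f"2021-{int(rng.integers(1, 13)):02d}-{int(rng.integers(1, 29)):02d}"
        device = str(rng.choice(_DEVICES, p=[0.55, 0.45]))
        os_cat = str(rng.choice(_OSES, p=[0.4, 0.15, 0.25, 0.15, 0.05]))
        browser = str(rng.choice(_BROWSERS, p=[0.55, 0.15, 0.12, 0.1, 0.08]))

        # latent tempo
        mode_n = int(rng.choice(multipliers, p=_mode_probs(cfg, age)))
        z_arousal = (arousal - a_mu) / a_sd
        beta = cfg.arousal_effect_beta
        resid_scale = math.sqrt(max(1.0 - beta**2, 0.0))
        while True:
            latent = (
                mode_n * cfg.base_period
                + cfg.within_mode_sd * (beta * z_arousal + resid_scale * rng.normal())
                + _circadian_shift(cfg, hour)
            )
            if latent >= cfg.min_iti_floor:
                break
        cv = float(_truncated_normal(rng, cfg.cv_mean, cfg.cv_sd, *cfg.cv_range))

        if kind == "fast":
            latent = float(rng.uniform(60.0, 90.0))
        elif kind == "age_outlier":
            age = float(rng.choice([1, 2, 3, 85, 90, 95, 99]))

        # draw trials until one passes the online acceptance rule
        attempt = 0
        while True:
            attempt += 1
            ts = _tap_train(rng, latent, cv, cfg.trial_duration)
            summary = summarize_timestamps(ts) if ts.size >= 2 else None
            if summary is not None and summary.accepted:
                break
            if attempt >= 10:
                break

        record = ParticipantRecord(
            participant_id=pid,
            age=age,
            gender=str(rng.choice(["male", "female", "other"], p=[0.64, 0.35, 0.01])),
            country="Antarctica" if kind == "bad_country" else country,
            city_size_category=city,
            arousal=None if kind == "invalid" else arousal,
            musical_experience=music,
            pss4=pss4,
            work_hours=work_hours,
            repeat_flag=kind == "repeat",
            n_attempts=attempt,
            local_hour=hour,
            local_date=date,
        )
        trial = TapTrial(
            participant_id=pid,
            timestamps=ts,
            local_hour=hour,
            local_date=date,
            device_category=device,
            os_category=os_cat,
            browser_category=browser,
            attempt_index=attempt,
        )
        participants.append(record)
        trials.append(trial)
        truth.modes[pid] = mode_n
        truth.latent_iti[pid] = float(latent)
        if kind is not None:
            truth.contamination[pid] = kind

    ds = Dataset(
        participants=participants,
        trials=trials,
        provenance=f"tempoclust simulate_cohort seed={cfg.seed}",
    )
    return ds, truth


def simulate_null_cohort(config: SimConfig | None = None) -> tuple[Dataset, GroundTruth]:
    """As :func:`simulate_cohort` with every covariate effect set to zero.

    Used for type-I-error calibration of the downstream tests.
    """
    cfg = config or SimConfig()
    cfg = replace(
        cfg,
        age_slowing_effect=0.0,
        circadian_amplitude=0.0,
        arousal_effect_beta=0.0,
    )
    return simulate_cohort(cfg)
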