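"""Reading and writing cohorts as CSV or JSON.

CSV dialect: UTF-8 with header, comma separator, one row per trial with the
tap timestamps serialized as one semicolon-joined field.  A cohort is a
participant table plus a trial table; JSON stores both in a single document.
Rows whose required fields cannot be parsed are dropped and counted in the
:class:`ReadLog`; an *empty* value for a nullable field (e.g. a missing
arousal rating) is preserved as missing so the cleaning cascade can count it.
External deposits with different column names can be adapted with a
column-mapping dict instead of editing files.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from tempoclust.datatypes import Dataset, ParticipantRecord, TapTrial

PARTICIPANT_REQUIRED = ("participant_id", "age", "arousal", "musical_experience", "pss4", "repeat_flag")
TRIAL_REQUIRED = ("participant_id", "timestamps", "local_hour")


@dataclass
class ReadLog:
    participant_rows_dropped: int = 0
    trial_rows_dropped: int = 0
    messages: list[str] = field(default_factory=list)

    @property
    def total_dropped(self) -> int:
        return self.participant_rows_dropped + self.trial_rows_dropped


def _parse_float(value: str, allow_missing: bool = True):
    s = str(value).strip()
    if s == "" or s.lower() in ("nan", "none"):
        if allow_missing:
            return None
        raise ValueError("missing")
    return float(s)


def _parse_int(value: str, allow_missing: bool = True):
    f = _parse_float(value, allow_missing)
    return None if f is None else int(round(f))


def _parse_bool(value) -> bool:
    return str(value).strip().lower() in ("true", "1", "yes")


def _check_columns(df: pd.DataFrame, required, path) -> None:
    for col in required:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")


def _read_table(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty file") from exc
    return df


def _participant_from_row(row: dict) -> ParticipantRecord:
    return ParticipantRecord(
        participant_id=str(row["participant_id"]),
        age=_parse_float(row.get("age", "")),
        gender=str(row.get("gender", "") or "unspecified"),
        country=str(row.get("country", "")),
        city_size_category=str(row.get("city_size_category", "")),
        arousal=_parse_int(row.get("arousal", "")),
        musical_experience=_parse_int(row.get("musical_experience", "")),
        pss4=_parse_int(row.get("pss4", "")),
        work_hours=_parse_float(row.get("work_hours", "")),
        repeat_flag=_parse_bool(row.get("repeat_flag", "")),
        n_attempts=_parse_int(row.get("n_attempts", "")) or 1,
        local_hour=_parse_int(row.get("local_hour", "")),
        local_date=str(row.get("local_date", "")),
    )


def _trial_from_row(row: dict) -> TapTrial:
    raw = str(row["timestamps"]).strip()
    if raw == "":
        raise ValueError("empty timestamps")
    ts = np.asarray([float(tok) for tok in raw.split(";")], dtype=float)
    hour = _parse_int(row.get("local_hour", ""), allow_missing=False)
    trial = TapTrial(
        participant_id=str(row["participant_id"]),
        timestamps=ts,
        local_hour=hour,
        local_date=str(row.get("local_date", "")),
        device_category=str(row.get("device_category", "") or "keyboard/mouse"),
        os_category=str(row.get("os_category", "") or "other"),
        browser_category=str(row.get("browser_category", "") or "other"),
        attempt_index=_parse_int(row.get("attempt_index", "")) or 1,
    )
    trial.validate()
    return trial


def read_dataset(
    participants_path,
    trials_path=None,
    format: str = "csv",
    column_map: dict | None = None,
) -> tuple[Dataset, ReadLog]:
    """Load a cohort; returns the dataset and a log of dropped rows.

    ``format="csv"`` expects the participant and trial tables as two files;
    ``format="json"`` reads a single document from ``participants_path``.
    ``column_map`` renames external column names onto the canonical ones,
    e.g. ``{"subject": "participant_id"}``.
    """
    log = ReadLog()
    if format == "json":
        with open(participants_path, encoding="utf-8") as fh:
            doc = json.load(fh)
        p_rows = doc.get("participants", [])
        t_rows = doc.get("trials", [])
        provenance = doc.get("provenance", str(participants_path))
        if not p_rows and not t_rows:
            raise ValueError(f"{participants_path}: empty file")
        pdf = pd.DataFrame(p_rows, dtype=str) if p_rows else pd.DataFrame(columns=PARTICIPANT_REQUIRED)
        tdf = pd.DataFrame(
            [{**r, "timestamps": ";".join(str(x) for x in r.get("timestamps", []))} for r in t_rows],
            dtype=str,
        ) if t_rows else pd.DataFrame(columns=TRIAL_REQUIRED)
    elif format == "csv":
        if trials_path is None:
            raise ValueError("csv format needs both a participants and a trials file")
        pdf = _read_table(participants_path)
        tdf = _read_table(trials_path)
        provenance = f"{participants_path}+{trials_path}"
    else:
        raise ValueError(f"unknown format {format!r}")

    if column_map:
        pdf = pdf.rename(columns=column_map)
        tdf = tdf.rename(columns=column_map)
    _check_columns(pdf, PARTICIPANT_REQUIRED, participants_path)
    _check_columns(tdf, TRIAL_REQUIRED, trials_path or participants_path)

    participants = []
    for _, row in pdf.iterrows():
        try:
            participants.append(_participant_from_row(row.to_dict()))
        except (ValueError, TypeError) as exc:
            log.participant_rows_dropped += 1
            log.messages.append(f"participant row dropped: {exc}")
    trials = []
    for _, row in tdf.iterrows():
        try:
            trials.append(_trial_from_row(row.to_dict()))
        except (ValueError, TypeError) as exc:
            log.trial_rows_dropped += 1
            log.messages.append(f"trial row dropped: {exc}")
    return Dataset(participants=participants, trials=trials, provenance=provenance), log


def _participant_row(p: ParticipantRecord) -> dict:
    def fmt(v):
        return "" if v is None else v

    return {
        "participant_id": p.participant_id,
        "age": fmt(p.age),
        "gender": p.gender,
        "country": p.country,
        "city_size_category": p.city_size_category,
        "arousal": fmt(p.arousal),
        "musical_experience": fmt(p.musical_experience),
        "pss4": fmt(p.pss4),
        "work_hours": fmt(p.work_hours),
        "repeat_flag": p.repeat_flag,
        "n_attempts": p.n_attempts,
        "local_hour": fmt(p.local_hour),
        "local_date": p.local_date,
    }


def _trial_row(t: TapTrial, join_timestamps: bool = True) -> dict:
    row = {
        "participant_id": t.participant_id,
        "timestamps": ";".join(repr(float(x)) for x in t.timestamps)
        if join_timestamps
        else [float(x) for x in t.timestamps],
        "local_hour": t.local_hour,
        "local_date": t.local_date,
        "device_category": t.device_category,
        "os_category": t.os_category,
        "browser_category": t.browser_category,
        "attempt_index": t.attempt_index,
    }
    return row


def write_dataset(
    dataset: Dataset,
    participants_path,
    trials_path=None,
    format: str = "csv",
) -> None:
    """Write a cohort; lossless round-trip with :func:`read_dataset`."""
    if format == "json":
        doc = {
            "provenance": dataset.provenance,
            "participants": [_participant_row(p) for p in dataset.participants],
            "trials": [_trial_row(t, join_timestamps=False) for t in dataset.trials],
        }
        Path(participants_path).write_text(
            json.dumps(doc, indent=1, sort_keys=True, default=_json_default),
            encoding="utf-8",
        )
        return
    if format != "csv":
        raise ValueError(f"unknown format {format!r}")
    if trials_path is None:
        raise ValueError("csv format needs both a participants and a trials path")
    pdf = pd.DataFrame([_participant_row(p) for p in dataset.participants])
    tdf = pd.DataFrame([_trial_row(t) for t in dataset.trials])
    if pdf.empty:
        pdf = pd.DataFrame(columns=list(_participant_row(_EMPTY_P).keys()))
    if tdf.empty:
        tdf = pd.DataFrame(columns=list(_trial_row(_EMPTY_T).keys()))
    pdf.to_csv(participants_path, index=False, encoding="utf-8")
    tdf.to_csv(trials_path, index=False, encoding="utf-8")


def write_ground_truth(truth, path) -> None:
    doc = truth.as_dict()
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True), encoding="utf-8")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if hasattr(obj, "__dict__"):
        return asdict(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


_EMPTY_P = ParticipantRecord(participant_id="", age=None)
_EMPTY_T = TapTrial(participant_id="", timestamps=np.array([]), local_hour=0)
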