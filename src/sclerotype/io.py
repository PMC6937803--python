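"""Delimited-text readers and writers for EHR extract tables.

Four CSV tables: labels (defines the subject universe; optional
demographic columns), diagnoses, labs, notes.  All UTF-8 with a
mandatory header row.  Dates are ISO 8601 (YYYY-MM-DD) by default;
a MM/DD/YYYY fallback can be enabled per run because de-identified
extracts are inconsistent about date dialects.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .model import (
    ChartLabel,
    ChartStatus,
    ClinicalNote,
    CodeSystem,
    Cohort,
    Demographics,
    DiagnosisEvent,
    LabResult,
    NoteSetting,
)
from .features import parse_titer

log = logging.getLogger(__name__)

LABEL_COLUMNS = ["subject_id", "status"]
DIAGNOSIS_COLUMNS = ["subject_id", "code", "system", "date"]
LAB_COLUMNS = ["subject_id", "test", "result", "date"]
NOTE_COLUMNS = ["subject_id", "date", "setting", "text"]


@dataclass(frozen=True)
class ParseConfig:
    """Reader options.

    ``date_fallback_mdy`` additionally accepts MM/DD/YYYY when the ISO
    parse fails.  Rows whose date parses under neither dialect are
    dropped with a logged count.
    """

    date_fallback_mdy: bool = False


def _parse_date(raw: str, config: ParseConfig) -> dt.date | None:
    raw = str(raw).strip()
    try:
        return dt.date.fromisoformat(raw)
    except ValueError:
        pass
    if config.date_fallback_mdy:
        try:
            return dt.datetime.strptime(raw, "%m/%d/%Y").date()
        except ValueError:
            pass
    return None


def _read_table(path: str | Path, required: list[str], what: str) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{what} file {path} is missing required column(s): {missing}")
    return df


def read_cohort(
    labels_path: str | Path,
    diagnoses_path: str | Path | None = None,
    labs_path: str | Path | None = None,
    notes_path: str | Path | None = None,
    config: ParseConfig = ParseConfig(),
) -> Cohort:
    """Read a cohort from delimited files.

    The labels file defines the subject universe; any event, lab or note
    row whose subject is absent from it is a hard error.  Duplicate
    subjects in the labels file are a hard error.
    """
    ldf = _read_table(labels_path, LABEL_COLUMNS, "labels")
    dupes = ldf["subject_id"][ldf["subject_id"].duplicated()].unique().tolist()
    if dupes:
        raise ValueError(f"duplicate subject_id in label file: {dupes}")
    labels = {
        r.subject_id: ChartLabel(r.subject_id, ChartStatus(r.status)) for r in ldf.itertuples()
    }
    demographics: dict[str, Demographics] = {}
    if {"age", "sex", "race"} & set(ldf.columns):
        for r in ldf.itertuples():
            demographics[r.subject_id] = Demographics(
                subject_id=r.subject_id,
                age=float(r.age) if getattr(r, "age", "") not in ("", None) else None,
                sex=getattr(r, "sex", None) or None,
                race=getattr(r, "race", None) or None,
            )

    events: dict[str, list[DiagnosisEvent]] = {}
    labs: dict[str, list[LabResult]] = {}
    notes: dict[str, list[ClinicalNote]] = {}

    def _check_subjects(df: pd.DataFrame, what: str) -> None:
        orphans = sorted(set(df["subject_id"]) - set(labels))
        if orphans:
            raise ValueError(f"{what} file references subjects not in the label file: {orphans}")

    if diagnoses_path is not None:
        ddf = _read_table(diagnoses_path, DIAGNOSIS_COLUMNS, "diagnoses")
        _check_subjects(ddf, "diagnoses")
        bad_dates = 0
        for r in ddf.itertuples():
            date = _parse_date(r.date, config)
            if date is None:
                bad_dates += 1
                continue
            events.setdefault(r.subject_id, []).append(
                DiagnosisEvent(r.subject_id, r.code, CodeSystem(r.system), date)
            )
        if bad_dates:
            log.warning("diagnoses: dropped %d row(s) with unparseable dates", bad_dates)

    if labs_path is not None:
        bdf = _read_table(labs_path, LAB_COLUMNS, "labs")
        _check_subjects(bdf, "labs")
        bad_dates = 0
        for r in bdf.itertuples():
            date = _parse_date(r.date, config)
            if date is None:
                bad_dates += 1
                continue
            parsed = parse_titer(r.result)
            labs.setdefault(r.subject_id, []).append(
                LabResult(
                    subject_id=r.subject_id,
                    test=r.test,
                    raw=r.result,
                    titer=parsed.value if parsed is not None else None,
                    bound=parsed.bound if parsed is not None else "exact",
                    date=date,
                )
            )
        if bad_dates:
            log.warning("labs: dropped %d row(s) with unparseable dates", bad_dates)

    if notes_path is not None:
        ndf = _read_table(notes_path, NOTE_COLUMNS, "notes")
        _check_subjects(ndf, "notes")
        bad_dates = 0
        for r in ndf.itertuples():
            date = _parse_date(r.date, config)
            if date is None:
                bad_dates += 1
                continue
            setting = NoteSetting(r.setting) if r.setting else NoteSetting.OUTPATIENT
            notes.setdefault(r.subject_id, []).append(
                ClinicalNote(r.subject_id, date, setting, r.text)
            )
        if bad_dates:
            log.warning("notes: dropped %d row(s) with unparseable dates", bad_dates)

    return Cohort(labels=labels, events=events, labs=labs, notes=notes, demographics=demographics)


def write_cohort(cohort: Cohort, out_dir: str | Path) -> dict[str, Path]:
    """Write the four CSV tables; returns the paths keyed by table name."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "labels": out / "labels.csv",
        "diagnoses": out / "diagnoses.csv",
        "labs": out / "labs.csv",
        "notes": out / "notes.csv",
    }

    lrows = []
    for sid, lab in cohort.labels.items():
        row = {"subject_id": sid, "status": lab.status.value}
        demo = cohort.demographics.get(sid)
        if cohort.demographics:
            row["age"] = "" if demo is None or demo.age is None else repr(demo.age)
            row["sex"] = "" if demo is None or demo.sex is None else demo.sex
            row["race"] = "" if demo is None or demo.race is None else demo.race
        lrows.append(row)
    label_cols = LABEL_COLUMNS + (["age", "sex", "race"] if cohort.demographics else [])
    pd.DataFrame(lrows, columns=label_cols).to_csv(paths["labels"], index=False)

    pd.DataFrame(
        [
            {"subject_id": e.subject_id, "code": e.code, "system": e.system.value,
             "date": e.date.isoformat()}
            for evs in cohort.events.values()
            for e in evs
        ],
        columns=DIAGNOSIS_COLUMNS,
    ).to_csv(paths["diagnoses"], index=False)

    pd.DataFrame(
        [
            {"subject_id": lr.subject_id, "test": lr.test, "result": lr.raw,
             "date": lr.date.isoformat()}
            for ls in cohort.labs.values()
            for lr in ls
        ],
        columns=LAB_COLUMNS,
    ).to_csv(paths["labs"], index=False)

    pd.DataFrame(
        [
            {"subject_id": n.subject_id, "date": n.date.isoformat(),
             "setting": n.setting.value, "text": n.text}
            for ns in cohort.notes.values()
            for n in ns
        ],
        columns=NOTE_COLUMNS,
    ).to_csv(paths["notes"], index=False)

    return paths
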