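"""Domain types for a de-identified structured EHR extract.

The unit of analysis is a *subject*: an opaque identifier carrying a
chart-review label plus collections of diagnosis-code events, antinuclear
antibody (ANA) lab results, and dated clinical notes.  Chart-review labels
use a four-way taxonomy (case / not a case / uncertain / missing
documentation) which a :class:`LabelPolicy` collapses into the binary
analysis classes actually used for metric computation.
"""

from __future__ import annotations

import datetime as dt
import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping


class CodeSystem(str, enum.Enum):
    ICD9 = "ICD9"
    ICD10CM = "ICD10CM"


class ChartStatus(str, enum.Enum):
    """Chart-review verdict for a subject."""

    CASE = "case"
    NOT_CASE = "not_case"
    UNCERTAIN = "uncertain"
    MISSING = "missing"


class AnalysisClass(str, enum.Enum):
    """Resolved binary class (plus exclusion) used for evaluation."""

    CASE = "case"
    NON_CASE = "non_case"
    EXCLUDED = "excluded"


class NoteSetting(str, enum.Enum):
    INPATIENT = "inpatient"
    OUTPATIENT = "outpatient"


def normalize_code(code: str) -> str:
    """Uppercase and strip a billing code, keeping any dot."""
    out = code.strip().upper()
    if not out:
        raise ValueError("diagnosis code is empty after normalization")
    return out


def strip_dot(code: str) -> str:
    return code.replace(".", "")


@dataclass(frozen=True)
class DiagnosisEvent:
    """One billing-code occurrence on a calendar date."""

    subject_id: str
    code: str
    system: CodeSystem
    date: dt.date

    def __post_init__(self) -> None:
        object.__setattr__(self, "code", normalize_code(self.code))
        object.__setattr__(self, "system", CodeSystem(self.system))


@dataclass(frozen=True)
class LabResult:
    """One ANA result.

    ``titer`` is the parsed ratio denominator (80 for "1:80"), ``None``
    when the raw string could not be parsed.  ``bound`` records prefix
    semantics: "exact", "lower" (">=1:1280" — true value at least this)
    or "upper" ("<1:80" — true value strictly below this).  The raw
    string is always retained.
    """

    subject_id: str
    test: str
    raw: str
    titer: float | None
    bound: str
    date: dt.date

    def __post_init__(self) -> None:
        if self.titer is not None and self.titer <= 0:
            raise ValueError(f"titer denominator must be positive, got {self.titer}")
        if self.bound not in ("exact", "lower", "upper"):
            raise ValueError(f"unknown bound kind {self.bound!r}")


@dataclass(frozen=True)
class ClinicalNote:
    subject_id: str
    date: dt.date
    setting: NoteSetting
    text: str


@dataclass(frozen=True)
class ChartLabel:
    subject_id: str
    status: ChartStatus

    def __post_init__(self) -> None:
        object.__setattr__(self, "status", ChartStatus(self.status))


@dataclass(frozen=True)
class Demographics:
    subject_id: str
    age: float | None = None
    sex: str | None = None
    race: str | None = None


@dataclass
class Cohort:
    """Per-subject collections keyed by subject_id.

    The label table defines the subject universe: every event, lab and
    note must belong to a labeled subject.
    """

    labels: dict[str, ChartLabel]
    events: dict[str, list[DiagnosisEvent]] = field(default_factory=dict)
    labs: dict[str, list[LabResult]] = field(default_factory=dict)
    notes: dict[str, list[ClinicalNote]] = field(default_factory=dict)
    demographics: dict[str, Demographics] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, table in (("events", self.events), ("labs", self.labs), ("notes", self.notes)):
            orphans = sorted(set(table) - set(self.labels))
            if orphans:
                raise ValueError(
                    f"{name} reference subjects absent from the label file: {orphans}"
                )
        for sid in self.labels:
            self.events.setdefault(sid, [])
            self.labs.setdefault(sid, [])
            self.notes.setdefault(sid, [])

    @property
    def subject_ids(self) -> list[str]:
        return list(self.labels)

    def __len__(self) -> int:
        return len(self.labels)

    def subset(self, subject_ids: Iterable[str]) -> "Cohort":
        keep = [s for s in subject_ids if s in self.labels]
        return Cohort(
            labels={s: self.labels[s] for s in keep},
            events={s: list(self.events.get(s, [])) for s in keep},
            labs={s: list(self.labs.get(s, [])) for s in keep},
            notes={s: list(self.notes.get(s, [])) for s in keep},
            demographics={s: self.demographics[s] for s in keep if s in self.demographics},
        )


@dataclass(frozen=True)
class LabelPolicy:
    """Maps the four chart statuses to analysis classes.

    The default counts uncertain diagnoses as non-cases and drops
    subjects with missing documentation from every analysis.
    """

    uncertain: AnalysisClass = AnalysisClass.NON_CASE
    missing: AnalysisClass = AnalysisClass.EXCLUDED


#: Uncertain verdicts count as non-cases; missing charts are excluded.
DEFAULT_POLICY = LabelPolicy()


def resolve_label(status: ChartStatus, policy: LabelPolicy = DEFAULT_POLICY) -> AnalysisClass:
    status = ChartStatus(status)
    if status is ChartStatus.CASE:
        return AnalysisClass.CASE
    if status is ChartStatus.NOT_CASE:
        return AnalysisClass.NON_CASE
    if status is ChartStatus.UNCERTAIN:
        return policy.uncertain
    return policy.missing


def resolve_labels(
    labels: Mapping[str, ChartLabel], policy: LabelPolicy = DEFAULT_POLICY
) -> dict[str, AnalysisClass]:
    return {sid: resolve_label(lab.status, policy) for sid, lab in labels.items()}
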