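"""Declarative rule-based phenotyping algorithms.

An :class:`AlgorithmSpec` is a code-count predicate (per code system, or
across both) optionally conjoined with ANA positivity and/or a Raynaud's
keyword clause.  The published grid comprises eight families at count
thresholds 1–4:

====================================  ==========================================
family                                predicate
====================================  ==========================================
ICD-9 only                            icd9_days >= k
ICD-10 only                           icd10_days >= k
ICD-9 or ICD-10                       icd9_days >= k  OR  icd10_days >= k
ICD-9 AND ANA                         icd9 count AND ana positive
ICD-10 AND ANA                        icd10 count AND ana positive
ICD-9 AND RP                          icd9 count AND rp keyword
ICD-9 AND (ANA OR RP)                 icd9 count AND (ana positive OR rp)
ICD-9 AND ANA AND RP                  icd9 count AND ana AND rp
====================================  ==========================================

An ICD-10 AND RP family is deliberately absent: too few ICD-10-era
subjects carried note data for it to be evaluable in the source cohort.

Complete-case eligibility: a subject must have complete data for every
component an algorithm tests — any algorithm touching ICD-10 counts
requires at least one ICD-10-CM code of any condition (an ICD-10-era
record), and any algorithm touching ANA requires the test to have been
performed.  Ineligible subjects appear in neither the numerator nor the
denominator of any metric.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .features import CodeMatcher, FeatureVector, SLE_MATCHER
from .model import Cohort

CODE_LOGICS = ("icd9_only", "icd10_only", "icd9_or_icd10")
ANA_CLAUSES = ("absent", "and")
RP_CLAUSES = ("absent", "and", "or_with_ana")
COUNT_MODES = ("either", "sum")


@dataclass(frozen=True)
class AlgorithmSpec:
    """One rule: count thresholds plus AND/OR clauses.

    ``count_mode`` applies only to ``icd9_or_icd10`` logic: "either"
    flags a subject when either system's distinct-day count meets its
    threshold (the default reading — the two code systems cover
    alternative eras); "sum" applies the ICD-9 threshold to the summed
    distinct-day count.
    """

    name: str
    code_logic: str
    icd9_min: int | None = None
    icd10_min: int | None = None
    ana_clause: str = "absent"
    rp_clause: str = "absent"
    count_mode: str = "either"

    def __post_init__(self) -> None:
        if self.code_logic not in CODE_LOGICS:
            raise ValueError(f"unknown code_logic {self.code_logic!r}")
        if self.ana_clause not in ANA_CLAUSES:
            raise ValueError(f"unknown ana_clause {self.ana_clause!r}")
        if self.rp_clause not in RP_CLAUSES:
            raise ValueError(f"unknown rp_clause {self.rp_clause!r}")
        if self.count_mode not in COUNT_MODES:
            raise ValueError(f"unknown count_mode {self.count_mode!r}")
        if self.icd9_min is None and self.icd10_min is None:
            raise ValueError("at least one count threshold is required")
        for thr in (self.icd9_min, self.icd10_min):
            if thr is not None and thr < 1:
                raise ValueError("count thresholds must be >= 1")
        if self.code_logic in ("icd9_only", "icd9_or_icd10") and self.icd9_min is None:
            raise ValueError(f"{self.code_logic} requires icd9_min")
        if self.code_logic == "icd10_only" and self.icd10_min is None:
            raise ValueError("icd10_only requires icd10_min")

    # -- component usage -------------------------------------------------
    @property
    def uses_icd10(self) -> bool:
        return self.code_logic in ("icd10_only", "icd9_or_icd10")

    @property
    def uses_ana(self) -> bool:
        return self.ana_clause == "and" or self.rp_clause == "or_with_ana"

    @property
    def uses_rp(self) -> bool:
        return self.rp_clause != "absent"

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "AlgorithmSpec":
        return cls(**d)


def specs_to_json(specs: Sequence[AlgorithmSpec], path: str | Path) -> None:
    Path(path).write_text(json.dumps([s.to_dict() for s in specs], indent=1))


def specs_from_json(path: str | Path) -> list[AlgorithmSpec]:
    return [AlgorithmSpec.from_dict(d) for d in json.loads(Path(path).read_text())]


def published_grid(count_mode: str = "either") -> list[AlgorithmSpec]:
    """The 32 published rule algorithms: 8 families x thresholds 1-4."""
    grid: list[AlgorithmSpec] = []
    for k in range(1, 5):
        grid.append(AlgorithmSpec(f">={k} ICD-9", "icd9_only", icd9_min=k))
    for k in range(1, 5):
        grid.append(AlgorithmSpec(f">={k} ICD-10", "icd10_only", icd10_min=k))
    for k in range(1, 5):
        grid.append(
            AlgorithmSpec(
                f">={k} ICD-9 or ICD-10", "icd9_or_icd10",
                icd9_min=k, icd10_min=k, count_mode=count_mode,
            )
        )
    for k in range(1, 5):
        grid.append(AlgorithmSpec(f">={k} ICD-9 AND ANA", "icd9_only", icd9_min=k, ana_clause="and"))
    for k in range(1, 5):
        grid.append(
            AlgorithmSpec(f">={k} ICD-10 AND ANA", "icd10_only", icd10_min=k, ana_clause="and")
        )
    for k in range(1, 5):
        grid.append(AlgorithmSpec(f">={k} ICD-9 AND RP", "icd9_only", icd9_min=k, rp_clause="and"))
    for k in range(1, 5):
        grid.append(
            AlgorithmSpec(
                f">={k} ICD-9 AND (ANA OR RP)", "icd9_only", icd9_min=k, rp_clause="or_with_ana"
            )
        )
    for k in range(1, 5):
        grid.append(
            AlgorithmSpec(
                f">={k} ICD-9 AND ANA AND RP", "icd9_only",
                icd9_min=k, ana_clause="and", rp_clause="and",
            )
        )
    return grid


def is_eligible(fv: FeatureVector, spec: AlgorithmSpec) -> tuple[bool, str | None]:
    """Complete-case eligibility; returns (eligible, reason-if-not)."""
    if spec.uses_icd10 and not fv.any_icd10:
        return False, "no ICD-10 era data"
    if spec.uses_ana and fv.ana == "missing":
        return False, "ANA never performed"
    return True, None


def _count_predicate(fv: FeatureVector, spec: AlgorithmSpec) -> bool:
    if spec.code_logic == "icd9_only":
        return fv.icd9_ssc_days >= spec.icd9_min
    if spec.code_logic == "icd10_only":
        return fv.icd10_ssc_days >= spec.icd10_min
    if spec.count_mode == "sum":
        return fv.icd9_ssc_days + fv.icd10_ssc_days >= spec.icd9_min
    return fv.icd9_ssc_days >= spec.icd9_min or fv.icd10_ssc_days >= (
        spec.icd10_min if spec.icd10_min is not None else spec.icd9_min
    )


def apply_algorithm(fv: FeatureVector, spec: AlgorithmSpec) -> bool:
    """Whether an (eligible) subject is flagged by the rule."""
    ok, reason = is_eligible(fv, spec)
    if not ok:
        raise ValueError(f"subject {fv.subject_id} ineligible for {spec.name!r}: {reason}")
    if not _count_predicate(fv, spec):
        return False
    if spec.rp_clause == "or_with_ana":
        return fv.ana == "positive" or fv.rp_keyword
    if spec.ana_clause == "and" and fv.ana != "positive":
        return False
    if spec.rp_clause == "and" and not fv.rp_keyword:
        return False
    return True


def flagged_set(features: Mapping[str, FeatureVector], spec: AlgorithmSpec) -> set[str]:
    """Subjects flagged by ``spec`` among those eligible for it."""
    return {
        sid for sid, fv in features.items() if is_eligible(fv, spec)[0] and apply_algorithm(fv, spec)
    }


def first_code_date(
    events: Iterable, matcher: CodeMatcher
) -> dt.date | None:
    dates = [e.date for e in events if matcher.matches(e)]
    return min(dates) if dates else None


def stratify_by_first_code_date(
    cohort: Cohort,
    features: Mapping[str, FeatureVector],
    spec: AlgorithmSpec,
    breakpoints: Sequence[int],
    matcher: CodeMatcher | None = None,
) -> dict[tuple[int, int], set[str]]:
    """Apply ``spec`` within strata of first matching-code date.

    Subjects are partitioned into half-open calendar-year intervals
    [b_i, b_{i+1}) by the date of their first matching code; the final
    breakpoint is an exclusive upper edge.  Subjects with no matching
    code, or whose first code falls outside [b_0, b_last), are in no
    stratum.
    """
    if list(breakpoints) != sorted(breakpoints) or len(breakpoints) < 2:
        raise ValueError("breakpoints must be a sorted list of >= 2 years")
    if matcher is None:
        matcher = CodeMatcher()
    intervals = list(zip(breakpoints[:-1], breakpoints[1:]))
    out: dict[tuple[int, int], set[str]] = {iv: set() for iv in intervals}
    for sid, fv in features.items():
        first = first_code_date(cohort.events.get(sid, []), matcher)
        if first is None:
            continue
        for lo, hi in intervals:
            if lo <= first.year < hi:
                if is_eligible(fv, spec)[0] and apply_algorithm(fv, spec):
                    out[(lo, hi)].add(sid)
                break
    return out


def exclude_by_code(cohort: Cohort, exclusion: CodeMatcher = SLE_MATCHER) -> Cohort:
    """Drop subjects carrying >=1 code matching ``exclusion`` in either system.

    Default exclusion is systemic lupus erythematosus (ICD-9 710.0,
    ICD-10-CM M32*), the most common alternative diagnosis among
    code-positive non-cases.
    """
    keep = [
        sid
        for sid in cohort.labels
        if not any(exclusion.matches(e) for e in cohort.events.get(sid, []))
    ]
    return cohort.subset(keep)
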