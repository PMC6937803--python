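"""Per-subject feature extraction.

The four phenotyping components plus eligibility bookkeeping:

* ``icd9_ssc_days`` / ``icd10_ssc_days`` — distinct calendar days bearing
  a systemic-sclerosis billing code (ICD-9 710.1; ICD-10-CM M34*).
  Multiple codes on one day count once: code occurrences represent
  distinct days, not encounters.
* ``any_icd10`` — whether the subject has at least one ICD-10-CM code of
  any condition, i.e. any data from the ICD-10 era.  Subjects without it
  are ineligible for algorithms that use ICD-10 counts.
* ``ana`` — antinuclear antibody status: positive when any titer reaches
  the 1:80 threshold, missing when the test was never performed.
* ``rp_keyword`` — a non-negated Raynaud's phenomenon mention in any
  inpatient or outpatient note.
* ``followup_years`` — span from first to last billing code of any
  condition, in years.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Sequence

from .model import ClinicalNote, CodeSystem, DiagnosisEvent, LabResult, strip_dot

if TYPE_CHECKING:  # pragma: no cover
    from .model import Cohort

DAYS_PER_YEAR = 365.25


# ---------------------------------------------------------------------------
# Code matching

@dataclass(frozen=True)
class CodeMatcher:
    """SSc billing-code definition: exact ICD-9 codes and ICD-10-CM prefixes.

    Matching is dot-insensitive ("M34.1" == "M341").
    """

    icd9_exact: frozenset[str] = frozenset({"7101"})
    icd10_prefixes: frozenset[str] = frozenset({"M34"})

    def __post_init__(self) -> None:
        if not self.icd9_exact or not self.icd10_prefixes:
            raise ValueError("matcher code sets must be non-empty")
        object.__setattr__(self, "icd9_exact", frozenset(strip_dot(c.upper()) for c in self.icd9_exact))
        object.__setattr__(
            self, "icd10_prefixes", frozenset(strip_dot(c.upper()) for c in self.icd10_prefixes)
        )

    def matches(self, event: DiagnosisEvent) -> bool:
        code = strip_dot(event.code)
        if event.system is CodeSystem.ICD9:
            return code in self.icd9_exact
        return any(code.startswith(p) for p in self.icd10_prefixes)


#: ICD-9 710.1 and the full M34* family.
SSC_MATCHER = CodeMatcher()
#: Systemic lupus erythematosus, the default sensitivity-analysis exclusion.
SLE_MATCHER = CodeMatcher(icd9_exact=frozenset({"7100"}), icd10_prefixes=frozenset({"M32"}))


def count_distinct_code_days(
    events: Iterable[DiagnosisEvent], matcher: CodeMatcher, system: CodeSystem
) -> int:
    """Number of distinct calendar days with a matching code in ``system``."""
    system = CodeSystem(system)
    return len({e.date for e in events if e.system is system and matcher.matches(e)})


def followup_years(events: Iterable[DiagnosisEvent]) -> float:
    """Years from first to last billing code of any condition; 0 if < 2 distinct dates."""
    dates = {e.date for e in events}
    if len(dates) < 2:
        return 0.0
    return (max(dates) - min(dates)).days / DAYS_PER_YEAR


# ---------------------------------------------------------------------------
# ANA titers

@dataclass(frozen=True)
class TiterParse:
    value: float
    bound: str  # "exact", "lower" (>= prefix) or "upper" (< prefix)


_TITER_RE = re.compile(
    r"""^\s*(?P<prefix>>=|<=|≥|≤|>|<)?\s*
        (?:1\s*:\s*)?(?P<denom>\d+(?:\.\d+)?)\s*$""",
    re.VERBOSE,
)


def parse_titer(raw: str) -> TiterParse | None:
    """Parse an ANA titer string to its ratio denominator.

    Accepts "1:80", ">=1:1280", "≥ 1:640", "<1:40" and bare numerals.
    Returns ``None`` for anything else (e.g. "negative"); never raises.
    A "<"/"<=" prefix yields an upper bound: the true titer is below the
    printed denominator, so such a result can never satisfy a threshold
    at or above it.
    """
    m = _TITER_RE.match(str(raw))
    if m is None:
        return None
    denom = float(m.group("denom"))
    if denom <= 0:
        return None
    prefix = m.group("prefix")
    if prefix in (">", ">=", "≥"):
        bound = "lower"
    elif prefix in ("<", "<=", "≤"):
        bound = "upper"
    else:
        bound = "exact"
    return TiterParse(denom, bound)


ANA_STATUSES = ("positive", "negative", "missing")


def ana_status(labs: Sequence[LabResult], threshold: float = 80) -> str:
    """ANA positivity with missingness.

    missing — no ANA result exists (testing never performed);
    positive — any parsed titer reaches ``threshold`` (an upper-bound
    result "<1:N" counts only if strictly-below-N can still reach it);
    negative — tested but never at threshold.  A present-but-unparseable
    result counts as performed: it cannot make a subject positive but
    does prevent missingness.
    """
    ana = [lr for lr in labs if lr.test.upper() == "ANA"]
    if not ana:
        return "missing"
    for lr in ana:
        if lr.titer is None:
            continue
        if lr.bound == "upper":
            continue  # true value strictly below lr.titer: cannot certify >= threshold
        if lr.titer >= threshold:
            return "positive"
    return "negative"


# ---------------------------------------------------------------------------
# Raynaud's keyword with negation

@dataclass(frozen=True)
class KeywordConfig:
    """Lexicon for the Raynaud's-phenomenon note feature.

    ``stems`` match any token starting with the stem, case-insensitively
    ("raynaud" covers "Raynaud's", "Raynauds", "Raynaud").  A match is
    negated when a trigger phrase ends within ``window`` tokens before
    it in the same sentence (a NegEx-style pre-trigger window standing
    in for manual absence review).
    """

    stems: tuple[str, ...] = ("raynaud",)
    triggers: tuple[str, ...] = ("no", "denies", "denied", "negative for", "without", "not have")
    window: int = 6


DEFAULT_KEYWORDS = KeywordConfig()

_SENTENCE_SPLIT = re.compile(r"[.?!;\n]")
_TOKEN = re.compile(r"[a-z0-9]+(?:'[a-z0-9]+)?")


def _sentences(text: str) -> list[str]:
    return [s for s in _SENTENCE_SPLIT.split(text) if s.strip()]


def _tokens(sentence: str) -> list[str]:
    return _TOKEN.findall(sentence.lower())


def _match_positions(tokens: Sequence[str], stems: Sequence[str]) -> list[int]:
    stems_l = [s.lower() for s in stems]
    return [i for i, tok in enumerate(tokens) if any(tok.startswith(s) for s in stems_l)]


def _negated(tokens: Sequence[str], pos: int, config: KeywordConfig) -> bool:
    lo = max(0, pos - config.window)
    for trig in config.triggers:
        words = trig.lower().split()
        # trigger must END inside the window [lo, pos)
        for end in range(lo + len(words) - 1, pos):
            start = end - len(words) + 1
            if start >= 0 and list(tokens[start : end + 1]) == words:
                return True
    return False


def detect_rp_keyword(
    notes: Iterable[ClinicalNote], config: KeywordConfig = DEFAULT_KEYWORDS
) -> bool:
    """True iff some note holds a keyword mention that is not negated."""
    for note in notes:
        for sent in _sentences(note.text):
            toks = _tokens(sent)
            for pos in _match_positions(toks, config.stems):
                if not _negated(toks, pos, config):
                    return True
    return False


# ---------------------------------------------------------------------------
# Composition

@dataclass(frozen=True)
class FeatureVector:
    subject_id: str
    icd9_ssc_days: int
    icd10_ssc_days: int
    any_icd10: bool
    ana: str  # positive | negative | missing
    rp_keyword: bool
    followup_years: float

    def __post_init__(self) -> None:
        if self.icd9_ssc_days < 0 or self.icd10_ssc_days < 0 or self.followup_years < 0:
            raise ValueError("counts and follow-up must be nonnegative")
        if self.ana not in ANA_STATUSES:
            raise ValueError(f"ana must be one of {ANA_STATUSES}")
        if self.icd10_ssc_days > 0 and not self.any_icd10:
            raise ValueError("icd10_ssc_days > 0 requires any_icd10")


@dataclass(frozen=True)
class ExtractionConfig:
    matcher: CodeMatcher = SSC_MATCHER
    ana_threshold: float = 80
    keywords: KeywordConfig = field(default_factory=KeywordConfig)


def extract_subject(
    subject_id: str,
    events: Sequence[DiagnosisEvent],
    labs: Sequence[LabResult],
    notes: Sequence[ClinicalNote],
    config: ExtractionConfig = ExtractionConfig(),
) -> FeatureVector:
    return FeatureVector(
        subject_id=subject_id,
        icd9_ssc_days=count_distinct_code_days(events, config.matcher, CodeSystem.ICD9),
        icd10_ssc_days=count_distinct_code_days(events, config.matcher, CodeSystem.ICD10CM),
        any_icd10=any(e.system is CodeSystem.ICD10CM for e in events),
        ana=ana_status(labs, config.ana_threshold),
        rp_keyword=detect_rp_keyword(notes, config.keywords),
        followup_years=followup_years(events),
    )


def extract_features(
    cohort: "Cohort", config: ExtractionConfig = ExtractionConfig()
) -> dict[str, FeatureVector]:
    """One FeatureVector per labeled subject, in label-file order."""
    return {
        sid: extract_subject(
            sid, cohort.events.get(sid, []), cohort.labs.get(sid, []), cohort.notes.get(sid, []),
            config,
        )
        for sid in cohort.labels
    }


def features_frame(features: dict[str, FeatureVector]):
    """Feature table as a pandas DataFrame indexed by subject_id."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "subject_id": fv.subject_id,
                "icd9_ssc_days": fv.icd9_ssc_days,
                "icd10_ssc_days": fv.icd10_ssc_days,
                "any_icd10": fv.any_icd10,
                "ana": fv.ana,
                "rp_keyword": fv.rp_keyword,
                "followup_years": fv.followup_years,
            }
            for fv in features.values()
        ]
    ).set_index("subject_id")
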