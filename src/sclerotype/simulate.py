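"""Seeded synthetic EHR cohort generator.

Emulates a chart-reviewed training set of code-positive potential SSc
subjects with the class-conditional structure of the source cohort:
per-class distributions of distinct-day SSc code counts, age, follow-up,
sex, ANA positivity/missingness and Raynaud's-phenomenon note content.
Default class profiles for cases and non-cases:

* ICD-9 distinct-day count: cases 10 +/- 16, non-cases 2 +/- 5
* ICD-10-CM distinct-day count: cases 6 +/- 7, non-cases 2 +/- 8
* age (years): cases 68 +/- 14, non-cases 59 +/- 20
* follow-up (years): cases 7 +/- 6, non-cases 10 +/- 7
* female fraction: cases 0.83, non-cases 0.89
* Raynaud's present: cases 0.95 (RP occurs in over 95% of SSc patients),
  non-cases 0.20

The stated mean/sd pairs have sd > mean, so no plain normal on the
nonnegative integers can realize them.  Counts default to a
round-then-clip-at-zero normal: the realized mean therefore exceeds the
configured one by a computable truncation bias
(:func:`truncated_round_normal_mean` gives the exact expectation, so
the bias can be subtracted when checking moment recovery).  A
moment-matched negative binomial is available as an alternative count
model.

Note text is template-based: a small bank of sentences with present,
negated, or no Raynaud's mentions — enough to exercise keyword and
negation handling, with no pretension to real clinical language.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

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

STUDY_START = dt.date(1995, 1, 1)
STUDY_END = dt.date(2017, 12, 31)

#: Titer denominators at or above the 1:80 positivity threshold.
POSITIVE_TITERS = (80, 160, 640, 1280)
NEGATIVE_TITER = 40

RP_PRESENT_SENTENCES = (
    "Longstanding Raynaud's phenomenon with color changes of the fingers in cold.",
    "She reports Raynaud's phenomenon and progressive skin tightening.",
    "Raynauds symptoms worse this winter, now on nifedipine.",
    "Exam notable for sclerodactyly; history of Raynaud's with digital ulcers.",
)
RP_NEGATED_SENTENCES = (
    "Patient denies Raynaud's phenomenon or digital ulcers.",
    "No Raynaud's, dysphagia, or skin tightening.",
    "Review of systems negative for Raynaud's phenomenon.",
    "She does not have Raynauds or telangiectasias.",
)
FILLER_SENTENCES = (
    "Patient seen in clinic for routine follow up.",
    "Blood pressure well controlled on current regimen.",
    "Will continue current medications and follow up in six months.",
    "Labs reviewed and discussed with the patient.",
)


@dataclass(frozen=True)
class ClassProfile:
    """Generator parameters for one chart-status class."""

    label: str  # ChartStatus value
    n: int
    icd9_days: tuple[float, float] = (10, 16)
    icd10_days: tuple[float, float] = (6, 7)
    age: tuple[float, float] = (68, 14)
    followup: tuple[float, float] = (7, 6)
    p_female: float = 0.83
    p_ana_positive: float = 0.90
    p_ana_missing: float = 0.15
    p_rp_present: float = 0.95
    p_rp_negated_mention: float = 0.5
    p_any_icd10: float = 0.90

    def __post_init__(self) -> None:
        ChartStatus(self.label)
        if self.n < 0:
            raise ValueError("n must be nonnegative")
        for nm in ("p_female", "p_ana_positive", "p_ana_missing", "p_rp_present",
                   "p_rp_negated_mention", "p_any_icd10"):
            v = getattr(self, nm)
            if not 0 <= v <= 1:
                raise ValueError(f"{nm} must lie in [0, 1], got {v}")
        for nm in ("icd9_days", "icd10_days", "age", "followup"):
            if getattr(self, nm)[1] < 0:
                raise ValueError(f"{nm} sd must be nonnegative")


def case_profile(n: int = 85, **overrides) -> ClassProfile:
    """Chart-confirmed SSc cases (training-set defaults)."""
    return ClassProfile(label="case", n=n, **overrides)


def non_case_profile(n: int = 70, label: str = "not_case", **overrides) -> ClassProfile:
    """Code-positive subjects ruled not cases on chart review."""
    defaults = dict(
        icd9_days=(2, 5), icd10_days=(2, 8), age=(59, 20), followup=(10, 7),
        p_female=0.89, p_ana_positive=0.55, p_ana_missing=0.30,
        p_rp_present=0.20, p_rp_negated_mention=0.5, p_any_icd10=0.90,
    )
    defaults.update(overrides)
    return ClassProfile(label=label, n=n, **defaults)


@dataclass(frozen=True)
class GeneratorConfig:
    """Full simulation configuration.

    Default profiles mirror a 200-subject chart-reviewed training set:
    85 cases, 70 non-cases, 24 uncertain, 21 with missing documentation
    (uncertain and missing subjects share the non-case data profile).
    ``same_day_dup_prob`` is the chance that an SSc code day carries
    extra duplicate codes (to exercise distinct-day collapsing);
    ``count_model`` is "truncated_normal" or "negative_binomial".
    """

    profiles: tuple[ClassProfile, ...] = ()
    seed: int = 0
    same_day_dup_prob: float = 0.2
    count_model: str = "truncated_normal"
    id_prefix: str = "S"

    def __post_init__(self) -> None:
        if not self.profiles:
            object.__setattr__(self, "profiles", default_profiles())
        if self.count_model not in ("truncated_normal", "negative_binomial"):
            raise ValueError(f"unknown count_model {self.count_model!r}")
        if not 0 <= self.same_day_dup_prob <= 1:
            raise ValueError("same_day_dup_prob must lie in [0, 1]")


def default_profiles() -> tuple[ClassProfile, ...]:
    return (
        case_profile(85),
        non_case_profile(70, label="not_case"),
        non_case_profile(24, label="uncertain"),
        non_case_profile(21, label="missing"),
    )


# ---------------------------------------------------------------------------
# Count models

def draw_counts(rng: np.random.Generator, mean: float, sd: float, n: int, model: str) -> np.ndarray:
    """Nonnegative integer counts with (approximately) the given moments."""
    if sd == 0:
        return np.full(n, int(round(mean)))
    if model == "negative_binomial":
        var = sd**2
        if var <= mean:  # NB needs overdispersion; fall back to Poisson
            return rng.poisson(mean, n)
        p = mean / var
        r = mean**2 / (var - mean)
        return rng.negative_binomial(r, p, n)
    x = np.rint(rng.normal(mean, sd, n))
    return np.clip(x, 0, None).astype(int)


def truncated_round_normal_mean(mean: float, sd: float) -> float:
    """Exact expectation of max(round(X), 0) for X ~ Normal(mean, sd).

    Sum of k * P(round(X) = k) over the integers, with the normal mass
    below 0.5 collapsing to zero.  This quantifies the upward bias the
    clipped count model introduces relative to the configured mean.
    """
    if sd == 0:
        return max(round(mean), 0)
    upper = int(np.ceil(mean + 12 * sd))
    ks = np.arange(1, upper + 1)
    p = stats.norm.cdf((ks + 0.5 - mean) / sd) - stats.norm.cdf((ks - 0.5 - mean) / sd)
    return float((ks * p).sum())


def truncation_bias(mean: float, sd: float) -> float:
    """Realized-minus-configured mean under the clipped count model."""
    return truncated_round_normal_mean(mean, sd) - mean


# ---------------------------------------------------------------------------
# Subject assembly

_FILLER_ICD9 = ("401.9", "530.81", "272.4")
_FILLER_ICD10 = ("I10", "K21.9", "E78.5")


def _pick_days(rng: np.random.Generator, start: dt.date, span_days: int, count: int) -> list[dt.date]:
    count = min(count, span_days + 1)
    offsets = rng.choice(span_days + 1, size=count, replace=False)
    return [start + dt.timedelta(days=int(o)) for o in sorted(offsets)]


def _simulate_subject(
    rng: np.random.Generator,
    sid: str,
    profile: ClassProfile,
    icd9_count: int,
    icd10_count: int,
    config: GeneratorConfig,
) -> tuple[list[DiagnosisEvent], list[LabResult], list[ClinicalNote], Demographics]:
    followup = max(float(rng.normal(*profile.followup)), 0.1)
    # a record must be at least long enough to hold its distinct code days
    span = max(int(round(followup * 365.25)), 1, icd9_count - 1, icd10_count - 1)
    latest_start = (STUDY_END - STUDY_START).days - span
    start = STUDY_START + dt.timedelta(days=int(rng.integers(0, max(latest_start, 1))))
    end = start + dt.timedelta(days=span)

    events: list[DiagnosisEvent] = []
    # anchor filler codes at the window edges so follow-up is well defined
    events.append(DiagnosisEvent(sid, _FILLER_ICD9[0], CodeSystem.ICD9, start))
    any_icd10 = icd10_count > 0 or rng.random() < profile.p_any_icd10
    end_system = CodeSystem.ICD10CM if any_icd10 else CodeSystem.ICD9
    end_code = _FILLER_ICD10[0] if any_icd10 else _FILLER_ICD9[1]
    events.append(DiagnosisEvent(sid, end_code, end_system, end))

    for system, code_bank, count in (
        (CodeSystem.ICD9, ("710.1",), icd9_count),
        (CodeSystem.ICD10CM, ("M34.0", "M34.1", "M34.81", "M34.9"), icd10_count),
    ):
        for day in _pick_days(rng, start, span, count):
            code = code_bank[int(rng.integers(len(code_bank)))]
            events.append(DiagnosisEvent(sid, code, system, day))
            if rng.random() < config.same_day_dup_prob:
                # same-day duplicates (e.g. clinic + lab encounters) must
                # collapse to one distinct day downstream
                for _ in range(int(rng.integers(1, 3))):
                    dup = code_bank[int(rng.integers(len(code_bank)))]
                    events.append(DiagnosisEvent(sid, dup, system, day))

    labs: list[LabResult] = []
    if rng.random() >= profile.p_ana_missing:
        positive = rng.random() < profile.p_ana_positive
        titers = [int(rng.choice(POSITIVE_TITERS))] if positive else [NEGATIVE_TITER]
        if rng.random() < 0.3:  # an extra low-titer result never flips status
            titers.append(NEGATIVE_TITER)
        for t in titers:
            day = start + dt.timedelta(days=int(rng.integers(0, span + 1)))
            labs.append(LabResult(sid, "ANA", f"1:{t}", float(t), "exact", day))

    notes: list[ClinicalNote] = []
    rp_present = rng.random() < profile.p_rp_present
    if rp_present:
        sent = RP_PRESENT_SENTENCES[int(rng.integers(len(RP_PRESENT_SENTENCES)))]
    elif rng.random() < profile.p_rp_negated_mention:
        sent = RP_NEGATED_SENTENCES[int(rng.integers(len(RP_NEGATED_SENTENCES)))]
    else:
        sent = ""
    filler = FILLER_SENTENCES[int(rng.integers(len(FILLER_SENTENCES)))]
    text = f"{filler} {sent}".strip()
    setting = NoteSetting.INPATIENT if rng.random() < 0.2 else NoteSetting.OUTPATIENT
    day = start + dt.timedelta(days=int(rng.integers(0, span + 1)))
    notes.append(ClinicalNote(sid, day, setting, text))

    demo = Demographics(
        subject_id=sid,
        age=float(np.clip(rng.normal(*profile.age), 18, 100).round(1)),
        sex="F" if rng.random() < profile.p_female else "M",
        race="White" if rng.random() < 0.75 else "Other",
    )
    return events, labs, notes, demo


def generate_cohort(config: GeneratorConfig = GeneratorConfig()) -> Cohort:
    """Simulate a cohort; fully deterministic for a given config."""
    rng = np.random.default_rng(config.seed)
    labels: dict[str, ChartLabel] = {}
    events: dict[str, list[DiagnosisEvent]] = {}
    labs: dict[str, list[LabResult]] = {}
    notes: dict[str, list[ClinicalNote]] = {}
    demographics: dict[str, Demographics] = {}

    idx = 0
    for profile in config.profiles:
        icd9_counts = draw_counts(rng, *profile.icd9_days, profile.n, config.count_model)
        icd10_counts = draw_counts(rng, *profile.icd10_days, profile.n, config.count_model)
        for i in range(profile.n):
            sid = f"{config.id_prefix}{idx:05d}"
            idx += 1
            labels[sid] = ChartLabel(sid, ChartStatus(profile.label))
            ev, lb, nt, demo = _simulate_subject(
                rng, sid, profile, int(icd9_counts[i]), int(icd10_counts[i]), config
            )
            events[sid], labs[sid], notes[sid], demographics[sid] = ev, lb, nt, demo
    return Cohort(labels=labels, events=events, labs=labs, notes=notes, demographics=demographics)


# ---------------------------------------------------------------------------
# Edge-case panel

def _edge(sid, status, events=(), labs=(), notes=(), age=60.0, sex="F"):
    return (
        ChartLabel(sid, ChartStatus(status)),
        list(events),
        list(labs),
        list(notes),
        Demographics(sid, age=age, sex=sex, race="White"),
    )


def edge_case_panel() -> list[tuple]:
    """Hand-built subjects exercising every extraction branch.

    Nine subjects: same-day triple coding, ANA never tested, negated and
    present keyword mentions, an ICD-10-era-only record, a single-event
    follow-up, an unparseable titer, multi-day ICD-10 coding, and an
    upper-bound titer.
    """
    d = dt.date
    mk = DiagnosisEvent
    panel = [
        _edge(
            "edge-same-day-triple", "case",
            events=[
                mk("edge-same-day-triple", "710.1", CodeSystem.ICD9, d(2014, 3, 2)),
                mk("edge-same-day-triple", "710.1", CodeSystem.ICD9, d(2014, 3, 2)),
                mk("edge-same-day-triple", "710.1", CodeSystem.ICD9, d(2014, 3, 2)),
            ],
        ),
        _edge(
            "edge-ana-never-tested", "case",
            events=[mk("edge-ana-never-tested", "710.1", CodeSystem.ICD9, d(2010, 1, 1)),
                    mk("edge-ana-never-tested", "710.1", CodeSystem.ICD9, d(2011, 1, 1))],
        ),
        _edge(
            "edge-denies-raynaud", "not_case",
            events=[mk("edge-denies-raynaud", "710.1", CodeSystem.ICD9, d(2012, 5, 5))],
            notes=[ClinicalNote("edge-denies-raynaud", d(2012, 5, 5), NoteSetting.OUTPATIENT,
                                "Patient denies Raynaud's phenomenon.")],
        ),
        _edge(
            "edge-present-raynaud", "case",
            events=[mk("edge-present-raynaud", "710.1", CodeSystem.ICD9, d(2012, 6, 6))],
            notes=[ClinicalNote("edge-present-raynaud", d(2012, 6, 6), NoteSetting.INPATIENT,
                                "Longstanding Raynaud's phenomenon with digital ulcers.")],
        ),
        _edge(
            "edge-icd10-era-only", "case",
            events=[mk("edge-icd10-era-only", "M34.1", CodeSystem.ICD10CM, d(2016, 2, 1)),
                    mk("edge-icd10-era-only", "M34.1", CodeSystem.ICD10CM, d(2016, 8, 1))],
        ),
        _edge(
            "edge-single-event", "not_case",
            events=[mk("edge-single-event", "710.1", CodeSystem.ICD9, d(2009, 9, 9))],
        ),
        _edge(
            "edge-unparseable-titer", "not_case",
            events=[mk("edge-unparseable-titer", "710.1", CodeSystem.ICD9, d(2013, 1, 1))],
            labs=[LabResult("edge-unparseable-titer", "ANA", "negative", None, "exact",
                            d(2013, 1, 2))],
        ),
        _edge(
            "edge-icd10-two-days", "case",
            events=[mk("edge-icd10-two-days", "M34.0", CodeSystem.ICD10CM, d(2016, 1, 1)),
                    mk("edge-icd10-two-days", "M34.81", CodeSystem.ICD10CM, d(2016, 1, 2))],
        ),
        _edge(
            "edge-upper-bound-titer", "not_case",
            events=[mk("edge-upper-bound-titer", "710.1", CodeSystem.ICD9, d(2014, 4, 4))],
            labs=[LabResult("edge-upper-bound-titer", "ANA", "<1:80", 80.0, "upper",
                            d(2014, 4, 5))],
        ),
    ]
    return panel


def inject_edge_cases(cohort: Cohort) -> Cohort:
    """Append the fixed edge-case panel to a cohort (new object)."""
    labels = dict(cohort.labels)
    events = {s: list(v) for s, v in cohort.events.items()}
    labs = {s: list(v) for s, v in cohort.labs.items()}
    notes = {s: list(v) for s, v in cohort.notes.items()}
    demographics = dict(cohort.demographics)
    for label, ev, lb, nt, demo in edge_case_panel():
        sid = label.subject_id
        if sid in labels:
            raise ValueError(f"edge-case id {sid} already present")
        labels[sid] = label
        events[sid], labs[sid], notes[sid] = ev, lb, nt
        demographics[sid] = demo
    return Cohort(labels=labels, events=events, labs=labs, notes=notes, demographics=demographics)


def config_manifest(config: GeneratorConfig) -> dict:
    """JSON-serializable echo of a generator configuration."""
    return {
        "seed": config.seed,
        "count_model": config.count_model,
        "same_day_dup_prob": config.same_day_dup_prob,
        "profiles": [dataclasses.asdict(p) for p in config.profiles],
    }
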