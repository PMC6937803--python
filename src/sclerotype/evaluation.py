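"""Validation metrics and cohort-comparison statistics.

PPV = confirmed cases among flagged subjects / all flagged subjects;
sensitivity = flagged confirmed cases / all confirmed cases; the F-score
is their harmonic mean, 2*PPV*sens/(PPV+sens).  All three are reported
on the percent scale, and the reporting convention rounds half-up to
integer percent while raw values are always retained (two published
grid rows are internally inconsistent with their own PPV/sensitivity,
so raw values must stay inspectable).

Metrics are computed over eligible subjects only: complete-case
exclusions are logged per subject with a reason and appear in neither
numerator nor denominator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Hashable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .algorithms import AlgorithmSpec, apply_algorithm, is_eligible
from .features import FeatureVector
from .model import AnalysisClass


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def f_score(ppv: float, sensitivity: float, rounded: bool = False) -> float:
    """Harmonic mean of PPV and sensitivity on the percent scale.

    Defined as 0 when both are 0.  ``rounded`` applies the table
    reporting convention (half-up to integer percent).
    """
    for v in (ppv, sensitivity):
        if not 0 <= v <= 100:
            raise ValueError(f"percent inputs must lie in [0, 100], got {v}")
    f = 0.0 if ppv + sensitivity == 0 else 2 * ppv * sensitivity / (ppv + sensitivity)
    return float(round_half_up(f)) if rounded else f


@dataclass(frozen=True)
class EvalResult:
    """Confusion counts and metrics for one algorithm on one cohort.

    ``ppv``/``sensitivity``/``f`` are raw percents, ``None`` when the
    denominator is empty (an algorithm flagging nobody has an undefined
    PPV, not a PPV of 0).  ``rounding`` names the reporting convention
    used by the ``*_rounded`` properties.
    """

    name: str
    n_eligible: int
    tp: int
    fp: int
    fn: int
    ppv: float | None
    sensitivity: float | None
    f: float | None
    exclusions: tuple[tuple[str, str], ...] = ()
    rounding: str = "table"

    @property
    def n_flagged(self) -> int:
        return self.tp + self.fp

    def _round(self, v: float | None) -> int | None:
        return None if v is None else round_half_up(v)

    @property
    def ppv_rounded(self) -> int | None:
        return self._round(self.ppv)

    @property
    def sensitivity_rounded(self) -> int | None:
        return self._round(self.sensitivity)

    @property
    def f_rounded(self) -> int | None:
        return self._round(self.f)


def evaluate_algorithm(
    features: Mapping[str, FeatureVector],
    classes: Mapping[str, AnalysisClass],
    spec: AlgorithmSpec,
) -> EvalResult:
    """Confusion counts and metrics for one rule over resolved labels.

    Subjects resolved as excluded (missing chart documentation) and
    subjects failing the rule's complete-case eligibility are removed
    from both numerator and denominator; each removal is recorded with
    its reason.
    """
    tp = fp = fn = tn = 0
    exclusions: list[tuple[str, str]] = []
    for sid, fv in features.items():
        cls = AnalysisClass(classes.get(sid, AnalysisClass.EXCLUDED))
        if cls is AnalysisClass.EXCLUDED:
            exclusions.append((sid, "label excluded"))
            continue
        ok, reason = is_eligible(fv, spec)
        if not ok:
            exclusions.append((sid, reason))
            continue
        flagged = apply_algorithm(fv, spec)
        is_case = cls is AnalysisClass.CASE
        if flagged and is_case:
            tp += 1
        elif flagged:
            fp += 1
        elif is_case:
            fn += 1
        else:
            tn += 1
    n_eligible = tp + fp + fn + tn
    ppv = 100 * tp / (tp + fp) if tp + fp > 0 else None
    sens = 100 * tp / (tp + fn) if tp + fn > 0 else None
    f = f_score(ppv, sens) if ppv is not None and sens is not None else None
    return EvalResult(
        name=spec.name, n_eligible=n_eligible, tp=tp, fp=fp, fn=fn,
        ppv=ppv, sensitivity=sens, f=f, exclusions=tuple(exclusions),
    )


def evaluate_grid(
    features: Mapping[str, FeatureVector],
    classes: Mapping[str, AnalysisClass],
    specs: Sequence[AlgorithmSpec],
) -> pd.DataFrame:
    """One report row per algorithm (raw and rounded metrics)."""
    rows = []
    for spec in specs:
        r = evaluate_algorithm(features, classes, spec)
        rows.append(
            {
                "algorithm": r.name, "n_eligible": r.n_eligible,
                "tp": r.tp, "fp": r.fp, "fn": r.fn,
                "ppv_raw": r.ppv, "sensitivity_raw": r.sensitivity, "f_raw": r.f,
                "ppv": r.ppv_rounded, "sensitivity": r.sensitivity_rounded, "f": r.f_rounded,
            }
        )
    return pd.DataFrame(rows)


def npv_screen(n_reviewed: int, n_true_cases: int) -> float:
    """NPV estimated from a chart-review screen of algorithm-negative subjects."""
    if n_reviewed <= 0:
        raise ValueError("n_reviewed must be positive")
    if not 0 <= n_true_cases <= n_reviewed:
        raise ValueError("n_true_cases must lie in [0, n_reviewed]")
    return 100 * (n_reviewed - n_true_cases) / n_reviewed


def percent_agreement(n_dual_reviewed: int, n_discordant: int) -> float:
    """Interrater agreement from a dual-review sample."""
    if n_dual_reviewed <= 0:
        raise ValueError("n_dual_reviewed must be positive")
    if not 0 <= n_discordant <= n_dual_reviewed:
        raise ValueError("n_discordant must lie in [0, n_dual_reviewed]")
    return 100 * (n_dual_reviewed - n_discordant) / n_dual_reviewed


def split_train_validate(
    universe: Sequence[Hashable], n_train: int, n_validate: int, seed: int
) -> tuple[set, set]:
    """Reproducible disjoint training / validation samples.

    The training set is drawn first, so for a fixed seed it does not
    depend on ``n_validate``; validation is drawn from the remainder.
    """
    universe = sorted(universe, key=str)
    if len(set(universe)) != len(universe):
        raise ValueError("universe contains duplicates")
    if n_train + n_validate > len(universe):
        raise ValueError("n_train + n_validate exceeds universe size")
    rng = np.random.default_rng(seed)
    train_idx = rng.choice(len(universe), size=n_train, replace=False)
    train = {universe[i] for i in train_idx}
    rest = [s for s in universe if s not in train]
    val_idx = rng.choice(len(rest), size=n_validate, replace=False)
    validate = {rest[i] for i in val_idx}
    return train, validate


def compare_cohorts(
    df: pd.DataFrame,
    group_col: str,
    continuous: Sequence[str] = (),
    categorical: Sequence[str] = (),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Class-comparison table: Mann-Whitney U for continuous variables,
    Pearson chi-square for categorical with Fisher's exact fallback when
    any expected cell count is below 5 (2x2 only).  Two-sided throughout;
    ``alpha`` is reported, never used to drop variables.  Constant
    variables are reported as not testable.
    """
    groups = sorted(df[group_col].dropna().unique(), key=str)
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 classes in {group_col!r}, got {groups}")
    a = df[df[group_col] == groups[0]]
    b = df[df[group_col] == groups[1]]
    rows = []
    for var in continuous:
        x, y = a[var].dropna(), b[var].dropna()
        if len(x) < 2 or len(y) < 2:
            rows.append({"variable": var, "test": "mann_whitney_u", "statistic": np.nan,
                         "p": np.nan, "testable": False})
            continue
        if pd.concat([x, y]).nunique() == 1:
            rows.append({"variable": var, "test": "mann_whitney_u", "statistic": np.nan,
                         "p": np.nan, "testable": False})
            continue
        stat, p = stats.mannwhitneyu(x, y, alternative="two-sided")
        rows.append({"variable": var, "test": "mann_whitney_u", "statistic": float(stat),
                     "p": float(p), "testable": True})
    for var in categorical:
        tab = pd.crosstab(df[var], df[group_col])
        if tab.shape[0] < 2:
            rows.append({"variable": var, "test": "chi_square", "statistic": np.nan,
                         "p": np.nan, "testable": False})
            continue
        chi2, p, _, expected = stats.chi2_contingency(tab, correction=False)
        test = "chi_square"
        stat = float(chi2)
        if (expected < 5).any() and tab.shape == (2, 2):
            _, p = stats.fisher_exact(tab.values, alternative="two-sided")
            test, stat = "fisher_exact", np.nan
        rows.append({"variable": var, "test": test, "statistic": stat,
                     "p": float(p), "testable": True})
    out = pd.DataFrame(rows)
    out["significant_at_alpha"] = out["p"] < alpha
    out.attrs["alpha"] = alpha
    return out
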