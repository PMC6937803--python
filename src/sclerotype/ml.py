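"""Tree-based classification on the four-feature table.

CART fits a single inspectable decision tree; the random forest uses
500 trees sampling 2 candidate variables per split by default.  Feature
importance is Gini (mean decrease in impurity) by default, with
permutation importance behind a flag.  ANA enters as a three-level
one-hot (positive / negative / missing) so the models can use all
subjects; a complete-case mode mirroring the rule-based ANA exclusion
is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from .evaluation import EvalResult, f_score
from .features import FeatureVector
from .model import AnalysisClass

BASE_FEATURES = ["icd9_ssc_days", "icd10_ssc_days", "ana", "rp_keyword"]


@dataclass(frozen=True)
class MLConfig:
    model: str = "random_forest"  # "cart" | "random_forest"
    n_trees: int = 500
    vars_per_split: int = 2
    seed: int = 0
    cv_folds: int = 5
    tuning_grid: Mapping[str, list] | None = None
    ana_encoding: str = "onehot"  # "onehot" | "complete_case"
    importance: str = "gini"  # "gini" | "permutation"

    def __post_init__(self) -> None:
        if self.model not in ("cart", "random_forest"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.ana_encoding not in ("onehot", "complete_case"):
            raise ValueError(f"unknown ana_encoding {self.ana_encoding!r}")


def encode_features(
    features: Mapping[str, FeatureVector], ana_encoding: str = "onehot"
) -> pd.DataFrame:
    """Design matrix from feature vectors.

    One-hot: columns icd9_ssc_days, icd10_ssc_days, rp_keyword,
    ana_positive, ana_negative, ana_missing.  Complete-case: subjects
    with missing ANA are dropped and a single ana_positive column kept.
    """
    rows = []
    for sid, fv in features.items():
        if ana_encoding == "complete_case" and fv.ana == "missing":
            continue
        row = {
            "subject_id": sid,
            "icd9_ssc_days": fv.icd9_ssc_days,
            "icd10_ssc_days": fv.icd10_ssc_days,
            "rp_keyword": int(fv.rp_keyword),
        }
        if ana_encoding == "onehot":
            for lvl in ("positive", "negative", "missing"):
                row[f"ana_{lvl}"] = int(fv.ana == lvl)
        else:
            row["ana_positive"] = int(fv.ana == "positive")
        rows.append(row)
    return pd.DataFrame(rows).set_index("subject_id") if rows else pd.DataFrame(
        columns=["icd9_ssc_days", "icd10_ssc_days", "rp_keyword"]
    )


@dataclass
class FittedModel:
    kind: str
    estimator: object
    feature_names: list[str]
    importances: pd.Series
    config: MLConfig
    classes_seen: list[str] = field(default_factory=list)

    @property
    def importance_ranking(self) -> list[str]:
        return list(self.importances.index)


def _labels_to_binary(classes: Mapping[str, AnalysisClass], index) -> np.ndarray:
    y = []
    for sid in index:
        cls = AnalysisClass(classes[sid])
        if cls is AnalysisClass.EXCLUDED:
            raise ValueError(f"subject {sid} has an excluded label; drop before fitting")
        y.append(int(cls is AnalysisClass.CASE))
    return np.asarray(y)


def fit_model(
    features: Mapping[str, FeatureVector],
    classes: Mapping[str, AnalysisClass],
    config: MLConfig = MLConfig(),
) -> FittedModel:
    """Fit CART or a random forest; deterministic given the config seed.

    When a tuning grid is supplied, parameters are selected by
    cross-validated F-score on seeded, class-stratified folds.
    """
    X = encode_features(features, config.ana_encoding)
    X = X.loc[[sid for sid in X.index
               if AnalysisClass(classes.get(sid, AnalysisClass.EXCLUDED)) is not AnalysisClass.EXCLUDED]]
    y = _labels_to_binary(classes, X.index)
    if len(np.unique(y)) < 2:
        raise ValueError("need both classes present to fit a classifier")

    if config.model == "cart":
        est = DecisionTreeClassifier(random_state=config.seed)
    else:
        est = RandomForestClassifier(
            n_estimators=config.n_trees,
            max_features=min(config.vars_per_split, X.shape[1]),
            random_state=config.seed,
        )

    if config.tuning_grid:
        cv = StratifiedKFold(n_splits=config.cv_folds, shuffle=True, random_state=config.seed)
        search = GridSearchCV(est, dict(config.tuning_grid), scoring="f1", cv=cv, refit=True)
        search.fit(X.values, y)
        est = search.best_estimator_
    else:
        est.fit(X.values, y)

    names = list(X.columns)
    if config.importance == "permutation":
        pi = permutation_importance(est, X.values, y, n_repeats=10, random_state=config.seed)
        scores = pi.importances_mean
    else:
        scores = est.feature_importances_
    imp = pd.Series(scores, index=names).sort_values(ascending=False, kind="stable")
    return FittedModel(
        kind=config.model, estimator=est, feature_names=names, importances=imp, config=config,
        classes_seen=["non_case", "case"],
    )


def predict(model: FittedModel, features: Mapping[str, FeatureVector]) -> dict[str, bool]:
    """Per-subject flag; a tied forest vote resolves to non-case."""
    X = encode_features(features, model.config.ana_encoding)
    if len(X) == 0:
        return {}
    if list(X.columns) != model.feature_names:
        raise ValueError(
            f"feature schema mismatch: trained on {model.feature_names}, got {list(X.columns)}"
        )
    proba = model.estimator.predict_proba(X.values)[:, 1]
    return {sid: bool(p > 0.5) for sid, p in zip(X.index, proba)}


def evaluate_model(
    model: FittedModel,
    features: Mapping[str, FeatureVector],
    classes: Mapping[str, AnalysisClass],
) -> EvalResult:
    """Confusion counts and PPV / sensitivity / F for model predictions.

    Subjects with excluded labels — and, in complete-case mode, missing
    ANA — are left out of both numerator and denominator.
    """
    preds = predict(model, features)
    tp = fp = fn = tn = 0
    exclusions = []
    for sid in features:
        cls = AnalysisClass(classes.get(sid, AnalysisClass.EXCLUDED))
        if cls is AnalysisClass.EXCLUDED:
            exclusions.append((sid, "label excluded"))
            continue
        if sid not in preds:
            exclusions.append((sid, "ANA never performed"))
            continue
        flagged, is_case = preds[sid], cls is AnalysisClass.CASE
        if flagged and is_case:
            tp += 1
        elif flagged:
            fp += 1
        elif is_case:
            fn += 1
        else:
            tn += 1
    ppv = 100 * tp / (tp + fp) if tp + fp > 0 else None
    sens = 100 * tp / (tp + fn) if tp + fn > 0 else None
    f = f_score(ppv, sens) if ppv is not None and sens is not None else None
    return EvalResult(
        name=f"{model.kind}", n_eligible=tp + fp + fn + tn, tp=tp, fp=fp, fn=fn,
        ppv=ppv, sensitivity=sens, f=f, exclusions=tuple(exclusions),
    )
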