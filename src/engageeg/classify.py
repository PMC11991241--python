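"""Within- and cross-subject high/low engagement classification.

Random-forest and SVM classifiers are evaluated on the per-epoch
engagement-index features. The evaluation design is:

* a stratified 80/20 train/test split (the holdout provides the
  reported metrics; stratification preserves the typical 2:1 high/low
  imbalance in both partitions);
* hyperparameter grid search confined to the training 80% — 10-fold CV
  for single-index within-subject models, 5-fold for combined features
  and cross-subject models, or a nested outer-5/inner-3 scheme for the
  combined within-subject models (the outer folds also provide a
  CV-mean estimate, reported alongside the holdout metrics);
* feature standardisation (zero mean, unit variance) fitted on training
  rows only, inside every CV fold, via a scikit-learn Pipeline — so
  neither the scaler nor the search ever sees test data;
* accuracy and binary F1 with *high* as the positive class (F1 is the
  primary metric because the classes are imbalanced), plus the
  confusion matrix, per subject and pooled.

Within-subject models are trained per participant on their own epochs;
the cross-subject model pools every retained participant's epochs into
one dataset (optionally, a leave-one-subject-out mode quantifies
generalisation to unseen subjects, since pooled splitting lets the
same subject appear in both partitions).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import accuracy_score, confusion_matrix, f1_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .exceptions import ConfigurationError, ValidationError
from .spectral import feature_columns

logger = logging.getLogger(__name__)

POSITIVE_CLASS = "high"

#: Default hyperparameter grids per classifier family.
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "random-forest": {
        "classifier__n_estimators": [100, 200, 300],
        "classifier__max_depth": [None, 10, 20, 30],
        "classifier__min_samples_split": [2, 5, 10],
        "classifier__min_samples_leaf": [1, 2, 4],
        "classifier__bootstrap": [True, False],
    },
    "svm": {
        "classifier__C": [0.1, 1, 10, 100],
        "classifier__gamma": ["scale", "auto"],
        "classifier__kernel": ["rbf", "linear"],
    },
}

__all__ = [
    "ModelSpec",
    "CVScheme",
    "EvaluationReport",
    "standardize",
    "evaluate_within_subject",
    "evaluate_cross_subject",
    "compare_reports",
    "plot_comparison",
    "DEFAULT_GRIDS",
    "POSITIVE_CLASS",
]


@dataclass(frozen=True)
class ModelSpec:
    """Classifier family plus its hyperparameter search grid."""

    family: str = "svm"
    grid: Mapping[str, list] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in DEFAULT_GRIDS:
            raise ConfigurationError(
                f"family must be one of {tuple(DEFAULT_GRIDS)}, got {self.family!r}"
            )
        if not self.grid:
            object.__setattr__(self, "grid", DEFAULT_GRIDS[self.family])

    def make_pipeline(self, seed: int | None = 0) -> Pipeline:
        if self.family == "random-forest":
            clf = RandomForestClassifier(random_state=seed)
        else:
            clf = SVC(random_state=seed)
        return Pipeline([("scaler", StandardScaler()), ("classifier", clf)])


@dataclass(frozen=True)
class CVScheme:
    """Split and tuning design for one evaluation run."""

    mode: str = "within-subject"
    holdout_fraction: float = 0.2
    tuning_folds: int = 10
    nested: bool = False
    outer_folds: int = 5
    inner_folds: int = 3
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("within-subject", "cross-subject"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        if not (0.0 < self.holdout_fraction <= 0.5):
            raise ConfigurationError("holdout_fraction must be in (0, 0.5]")
        if min(self.tuning_folds, self.outer_folds, self.inner_folds) < 2:
            raise ConfigurationError("all fold counts must be >= 2")


@dataclass(frozen=True)
class EvaluationReport:
    """Per-unit metrics, aggregates and provenance of one evaluation.

    ``per_unit`` has one row per subject (within-subject or
    leave-one-subject-out) or a single ``pooled`` row, with columns
    accuracy, f1, tn/fp/fn/tp, n_test and the chosen hyperparameters.
    """

    per_unit: pd.DataFrame
    metadata: dict

    def __post_init__(self) -> None:
        for _, row in self.per_unit.iterrows():
            n = row["tn"] + row["fp"] + row["fn"] + row["tp"]
            if n != row["n_test"]:
                raise ValidationError("confusion counts do not sum to test size")
            denom = 2 * row["tp"] + row["fp"] + row["fn"]
            f1 = 2 * row["tp"] / denom if denom > 0 else 0.0
            if abs(f1 - row["f1"]) > 1e-9:
                raise ValidationError("F1 inconsistent with confusion matrix")
            acc = (row["tp"] + row["tn"]) / n if n else 0.0
            if abs(acc - row["accuracy"]) > 1e-9:
                raise ValidationError("accuracy inconsistent with confusion matrix")

    @property
    def mean_accuracy(self) -> float:
        return float(self.per_unit["accuracy"].mean())

    @property
    def mean_f1(self) -> float:
        return float(self.per_unit["f1"].mean())

    @property
    def sd_f1(self) -> float:
        return float(self.per_unit["f1"].std(ddof=1)) if len(self.per_unit) > 1 else 0.0

    def by_age_group(self) -> pd.DataFrame | None:
        if "age_group" not in self.per_unit.columns:
            return None
        return self.per_unit.groupby("age_group")[["accuracy", "f1"]].mean()

    def summary(self) -> str:
        lines = [
            f"{self.metadata.get('family')} {self.metadata.get('mode')} "
            f"({self.metadata.get('feature_set')}): "
            f"accuracy {self.mean_accuracy:.2f}, F1 {self.mean_f1:.2f} "
            f"(SD {self.sd_f1:.2f}, n_units={len(self.per_unit)})"
        ]
        grp = self.by_age_group()
        if grp is not None and len(grp) > 1:
            for g, row in grp.iterrows():
                lines.append(f"  {g}: accuracy {row['accuracy']:.2f}, F1 {row['f1']:.2f}")
        return "\n".join(lines)


def standardize(
    table: pd.DataFrame, fit_on: Sequence[int] | pd.Index
) -> tuple[pd.DataFrame, dict]:
    """Z-score all feature columns using statistics from ``fit_on`` rows only.

    Returns the transformed table and the scaler parameters (means,
    scales, flagged zero-variance columns, which are passed through
    with scale 1).
    """
    fit_on = pd.Index(fit_on)
    if len(fit_on) == 0:
        raise ValidationError("fit_on must be non-empty")
    cols = feature_columns(table)
    scaler = StandardScaler()
    scaler.fit(table.loc[fit_on, cols].to_numpy())
    flagged = [c for c, v in zip(cols, scaler.var_) if v == 0]
    if flagged:
        logger.warning("zero-variance feature column(s): %s", flagged)
    out = table.copy()
    out[cols] = scaler.transform(table[cols].to_numpy())
    # zero-variance columns carry no scale information: pass through untouched
    for c in flagged:
        out[c] = table[c]
    params = {
        "columns": cols,
        "mean": scaler.mean_.tolist(),
        "scale": scaler.scale_.tolist(),
        "zero_variance": flagged,
    }
    return out, params


def _xy(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    cols = feature_columns(table)
    X = table[cols].to_numpy()
    y = (table["label"] == POSITIVE_CLASS).astype(int).to_numpy()
    return X, y


def _metrics_row(y_true: np.ndarray, y_pred: np.ndarray) -> dict:
    tn, fp, fn, tp = confusion_matrix(y_true, y_pred, labels=[0, 1]).ravel()
    return {
        "accuracy": accuracy_score(y_true, y_pred),
        "f1": f1_score(y_true, y_pred, pos_label=1, zero_division=0),
        "tn": int(tn), "fp": int(fp), "fn": int(fn), "tp": int(tp),
        "n_test": int(len(y_true)),
    }


def _tune_and_test(
    X_tr: np.ndarray,
    y_tr: np.ndarray,
    X_te: np.ndarray,
    y_te: np.ndarray,
    model: ModelSpec,
    scheme: CVScheme,
) -> dict:
    """Grid search on the training partition, metrics on the holdout."""
    def cv(folds: int) -> StratifiedKFold:
        return StratifiedKFold(n_splits=folds, shuffle=True, random_state=scheme.seed)

    row: dict = {}
    if scheme.nested:
        # outer folds give a tuning-stage CV estimate; never touch the holdout
        outer = cv(scheme.outer_folds)
        cv_scores = []
        for tr_idx, va_idx in outer.split(X_tr, y_tr):
            inner = GridSearchCV(
                model.make_pipeline(scheme.seed), dict(model.grid),
                cv=cv(scheme.inner_folds), scoring="f1", n_jobs=1,
            )
            inner.fit(X_tr[tr_idx], y_tr[tr_idx])
            cv_scores.append(
                f1_score(y_tr[va_idx], inner.predict(X_tr[va_idx]), zero_division=0)
            )
        row["cv_f1_mean"] = float(np.mean(cv_scores))
        final_folds = scheme.inner_folds
    else:
        final_folds = scheme.tuning_folds

    search = GridSearchCV(
        model.make_pipeline(scheme.seed), dict(model.grid),
        cv=cv(final_folds), scoring="f1", n_jobs=1,
    )
    search.fit(X_tr, y_tr)
    row.update(_metrics_row(y_te, search.predict(X_te)))
    row["best_params"] = str(search.best_params_)
    return row


def evaluate_within_subject(
    features: pd.DataFrame,
    model: ModelSpec | None = None,
    scheme: CVScheme | None = None,
    age_groups: Mapping[str, str] | None = None,
) -> EvaluationReport:
    """Train and test one model per subject on that subject's epochs."""
    model = model or ModelSpec()
    scheme = scheme or CVScheme(mode="within-subject")
    rows = []
    for sid, grp in features.groupby("subject_id", sort=True):
        X, y = _xy(grp)
        if len(np.unique(y)) < 2:
            raise ValidationError(
                f"subject {sid} has a single class; apply the retention filter first"
            )
        X_tr, X_te, y_tr, y_te = train_test_split(
            X, y,
            test_size=scheme.holdout_fraction,
            stratify=y if scheme.stratified else None,
            random_state=scheme.seed,
        )
        row = {"subject_id": str(sid)}
        row.update(_tune_and_test(X_tr, y_tr, X_te, y_te, model, scheme))
        if age_groups:
            row["age_group"] = age_groups.get(str(sid), "unknown")
        rows.append(row)
        logger.info("within-subject %s: F1 %.3f", sid, row["f1"])
    per_unit = pd.DataFrame(rows)
    meta = _meta(features, model, scheme, unit="subject")
    return EvaluationReport(per_unit=per_unit, metadata=meta)


def evaluate_cross_subject(
    features: pd.DataFrame,
    model: ModelSpec | None = None,
    scheme: CVScheme | None = None,
    split: str = "pooled",
    age_groups: Mapping[str, str] | None = None,
) -> EvaluationReport:
    """Pool every subject's epochs into one model.

    ``split='pooled'`` (default) performs the stratified 80/20 split on
    the pooled epochs, mirroring the study design; note a subject's
    epochs can then appear in both partitions, so this measures pooled
    fit rather than transfer. ``split='loso'`` holds out one complete
    subject per fold and reports per-subject transfer metrics.
    """
    model = model or ModelSpec()
    scheme = scheme or CVScheme(mode="cross-subject", tuning_folds=5)
    if features["subject_id"].nunique() < 2:
        raise ValidationError("cross-subject evaluation needs >= 2 subjects")
    if split not in ("pooled", "loso"):
        raise ConfigurationError("split must be 'pooled' or 'loso'")

    rows = []
    if split == "pooled":
        X, y = _xy(features)
        X_tr, X_te, y_tr, y_te = train_test_split(
            X, y,
            test_size=scheme.holdout_fraction,
            stratify=y if scheme.stratified else None,
            random_state=scheme.seed,
        )
        row = {"subject_id": "pooled"}
        row.update(_tune_and_test(X_tr, y_tr, X_te, y_te, model, scheme))
        rows.append(row)
    else:
        for sid in sorted(features["subject_id"].unique()):
            test_mask = features["subject_id"] == sid
            X_te, y_te = _xy(features[test_mask])
            X_tr, y_tr = _xy(features[~test_mask])
            row = {"subject_id": str(sid)}
            row.update(_tune_and_test(X_tr, y_tr, X_te, y_te, model, scheme))
            if age_groups:
                row["age_group"] = age_groups.get(str(sid), "unknown")
            rows.append(row)
    per_unit = pd.DataFrame(rows)
    meta = _meta(features, model, scheme, unit="pooled" if split == "pooled" else "subject")
    meta["split"] = split
    if split == "pooled":
        meta["validity_caveat"] = (
            "pooled splitting lets a subject contribute epochs to both "
            "train and test partitions"
        )
    return EvaluationReport(per_unit=per_unit, metadata=meta)


def _meta(features: pd.DataFrame, model: ModelSpec, scheme: CVScheme, unit: str) -> dict:
    cols = feature_columns(features)
    indices = sorted({c.split("_")[0] for c in cols})
    return {
        "family": model.family,
        "mode": scheme.mode,
        "unit": unit,
        "feature_set": "combined" if len(indices) > 1 else indices[0],
        "n_features": len(cols),
        "positive_class": POSITIVE_CLASS,
        "tuning_metric": "f1",
        "holdout_fraction": scheme.holdout_fraction,
        "nested": scheme.nested,
        "seed": scheme.seed,
        "subjects": sorted(features["subject_id"].astype(str).unique().tolist()),
        "n_rows": int(len(features)),
    }


def compare_reports(
    reports: Sequence[EvaluationReport], grouping: str = "classifier"
) -> pd.DataFrame:
    """Tabulate mean accuracy/F1 across reports by a grouping key.

    ``grouping`` is one of ``classifier``, ``feature_set`` or
    ``age_group``. All reports must describe the same cohort. The best
    cell by mean F1 is marked; exact ties are flagged.
    """
    if grouping not in ("classifier", "feature_set", "age_group"):
        raise ConfigurationError(f"unknown grouping {grouping!r}")
    cohorts = {tuple(r.metadata.get("subjects", [])) for r in reports}
    if len(cohorts) != 1:
        raise ValidationError("reports describe different cohorts; cannot compare")

    rows = []
    for r in reports:
        if grouping == "age_group":
            grp = r.by_age_group()
            if grp is None:
                raise ValidationError("report lacks age_group information")
            for g, vals in grp.iterrows():
                rows.append(
                    {
                        "group": g,
                        "family": r.metadata["family"],
                        "feature_set": r.metadata["feature_set"],
                        "accuracy": float(vals["accuracy"]),
                        "f1": float(vals["f1"]),
                    }
                )
        else:
            key = r.metadata["family"] if grouping == "classifier" else r.metadata["feature_set"]
            rows.append(
                {
                    "group": key,
                    "family": r.metadata["family"],
                    "feature_set": r.metadata["feature_set"],
                    "accuracy": r.mean_accuracy,
                    "f1": r.mean_f1,
                }
            )
    table = (
        pd.DataFrame(rows)
        .groupby("group", as_index=False)[["accuracy", "f1"]]
        .mean()
    )
    best_f1 = table["f1"].max()
    table["best"] = table["f1"] == best_f1
    table["tie"] = table["best"] & (table["best"].sum() > 1)
    return table


def plot_comparison(table: pd.DataFrame, metric: str = "f1", ax=None):
    """Clustered bar chart of a :func:`compare_reports` table."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ax.bar(table["group"].astype(str), table[metric])
    ax.set_ylabel(metric)
    ax.set_ylim(0, 1)
    ax.set_title(f"mean {metric} by group")
    return ax
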