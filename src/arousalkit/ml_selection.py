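"""Classifier model-selection harness.

Evaluates eight classifier families — quadratic discriminant analysis (QDA),
Gaussian naive Bayes (GNB), support vector machine (SVM), multilayer
perceptron (MLP), AdaBoost (ADB), k-nearest neighbours (KNN), decision tree
(DT) and random forest (RF) — on a labelled feature table with stratified
k-fold cross-validation, reporting accuracy and macro-averaged
precision/recall/F1 per (family, parameter setting). KNN, DT and RF sweep a
small default parameter grid; the grid is fully configurable.

Features are standardised inside each training fold only (scaler fitted on
the training split, applied to the test split), so no test-set statistics
leak into training. Stratified window-level folds are the default; pass
``groups`` for subject-grouped folds when windows from one subject must not
straddle the train/test boundary (window-level splits inflate scores on
multi-subject EEG).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.discriminant_analysis import QuadraticDiscriminantAnalysis
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.metrics import (
    accuracy_score,
    f1_score,
    precision_score,
    recall_score,
)
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "FeatureTable",
    "ModelReport",
    "default_grid",
    "build_feature_table",
    "evaluate_models",
    "select_best",
]


@dataclass
class FeatureTable:
    """Labelled feature matrix: one row per window/epoch."""

    features: pd.DataFrame
    labels: pd.Series
    groups: pd.Series | None = None

    def __post_init__(self) -> None:
        if len(self.features) != len(self.labels):
            raise ValueError("features and labels must align")
        if self.labels.isna().any():
            raise ValueError("missing labels")
        if self.features.columns.duplicated().any():
            raise ValueError("duplicate feature column names")
        counts = self.labels.value_counts()
        if len(counts) < 2:
            raise ValueError("need at least 2 classes")
        if counts.min() < 2:
            raise ValueError("need at least 2 rows per class")

    @property
    def n_classes(self) -> int:
        return self.labels.nunique()


@dataclass
class ModelReport:
    family: str
    params: dict
    accuracy: float
    precision: float
    recall: float
    f1: float
    fold_scores: list[float]

    def to_dict(self) -> dict:
        return {
            "family": self.family, "params": self.params,
            "accuracy": self.accuracy, "precision": self.precision,
            "recall": self.recall, "f1": self.f1,
            "fold_scores": self.fold_scores,
        }


def default_grid(seed: int = 0) -> list[tuple[str, dict, object]]:
    """The default (family, params, estimator) sweep.

    Single default settings for QDA/GNB/SVM/MLP/ADB; small grids for
    KNN (k in 3/5/7), DT (max depth 5/10/unlimited) and RF (50/100/200 trees).
    """
    grid: list[tuple[str, dict, object]] = [
        ("QDA", {}, QuadraticDiscriminantAnalysis()),
        ("GNB", {}, GaussianNB()),
        ("SVM", {"kernel": "rbf", "C": 1.0}, SVC(kernel="rbf", C=1.0, random_state=seed)),
        ("MLP", {"hidden_layer_sizes": (50,)},
         MLPClassifier(hidden_layer_sizes=(50,), max_iter=500, random_state=seed)),
        ("ADB", {"n_estimators": 50}, AdaBoostClassifier(n_estimators=50, random_state=seed)),
    ]
    for k in (3, 5, 7):
        grid.append(("KNN", {"n_neighbors": k}, KNeighborsClassifier(n_neighbors=k)))
    for depth in (5, 10, None):
        grid.append(("DT", {"max_depth": depth},
                     DecisionTreeClassifier(max_depth=depth, random_state=seed)))
    for trees in (50, 100, 200):
        grid.append(("RF", {"n_estimators": trees},
                     RandomForestClassifier(n_estimators=trees, random_state=seed)))
    return grid


def build_feature_table(
    windows,
    labels,
    extractors=("epoch_stats",),
    channels: list[str] | None = None,
    drop_invalid: bool = True,
) -> FeatureTable:
    """Flatten per-window, per-channel features into a labelled table.

    ``extractors`` names feature families: ``"epoch_stats"`` (the ten epoch
    statistics), ``"time"`` (the full time-domain catalogue) and
    ``"bandpower"`` (the five canonical band powers). Columns are named
    ``<CHANNEL>__<feature>`` in deterministic order. Rows containing
    non-finite features are dropped (with a warning) when ``drop_invalid``,
    else retained as-is.
    """
    from dataclasses import fields as dc_fields

    from .features_spectral import band_powers, estimate_psd
    from .features_time import (
        EpochStats,
        TimeFeatureSet,
        compute_time_features,
        epoch_statistics,
    )

    labels = list(labels)
    if len(labels) != len(windows):
        raise ValueError("one label per window required")
    rows = []
    for win in windows:
        names = channels or win.parent.channel_names
        row: dict[str, float] = {}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for name in names:
                x = win.channel(name)
                if "epoch_stats" in extractors:
                    st = epoch_statistics(win)[name]
                    for f in dc_fields(EpochStats):
                        row[f"{name}__{f.name}"] = getattr(st, f.name)
                if "time" in extractors:
                    tf = compute_time_features(x)
                    for f in dc_fields(TimeFeatureSet):
                        row[f"{name}__{f.name}"] = getattr(tf, f.name)
                if "bandpower" in extractors:
                    bp = band_powers(estimate_psd(x, win.parent.fs))
                    for band in ("delta", "theta", "alpha", "beta", "gamma"):
                        row[f"{name}__bp_{band}"] = getattr(bp, band)
        rows.append(row)
    feats = pd.DataFrame(rows)
    lab = pd.Series(labels, name="label")
    if drop_invalid:
        ok = np.isfinite(feats.to_numpy()).all(axis=1)
        if not ok.all():
            warnings.warn(f"dropping {int((~ok).sum())} rows with non-finite features")
            feats = feats.loc[ok].reset_index(drop=True)
            lab = lab.loc[ok].reset_index(drop=True)
    return FeatureTable(features=feats, labels=lab)


def evaluate_models(
    table: FeatureTable,
    n_folds: int = 10,
    seed: int = 0,
    grid: list[tuple[str, dict, object]] | None = None,
) -> list[ModelReport]:
    """Stratified k-fold cross-validation of every grid entry.

    Metrics are macro-averaged over classes and then averaged over folds.
    The fold count is reduced (with a warning) if the smallest class has
    fewer rows than ``n_folds``. Identical (table, seed, grid) gives
    bit-identical reports.
    """
    grid = default_grid(seed) if grid is None else grid
    X = table.features.to_numpy()
    y = table.labels.to_numpy()
    min_class = int(table.labels.value_counts().min())
    folds = min(n_folds, min_class)
    if folds < n_folds:
        warnings.warn(f"reducing folds from {n_folds} to {folds} (smallest class)")
    if table.groups is not None:
        splitter = StratifiedGroupKFold(n_splits=folds, shuffle=True, random_state=seed)
        split_args = (X, y, table.groups.to_numpy())
    else:
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        split_args = (X, y)
    splits = list(splitter.split(*split_args))

    reports = []
    for family, params, estimator in grid:
        accs, precs, recs, f1s = [], [], [], []
        failed = False
        for train, test in splits:
            model = Pipeline([
                ("scale", StandardScaler()),
                ("clf", clone(estimator)),
            ])
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    model.fit(X[train], y[train])
                    pred = model.predict(X[test])
            except Exception as exc:  # e.g. singular covariance for QDA
                warnings.warn(f"{family} {params} failed to fit: {exc}")
                failed = True
                break
            accs.append(accuracy_score(y[test], pred))
            precs.append(precision_score(y[test], pred, average="macro", zero_division=0))
            recs.append(recall_score(y[test], pred, average="macro", zero_division=0))
            f1s.append(f1_score(y[test], pred, average="macro", zero_division=0))
        if failed:
            nan = float("nan")
            reports.append(ModelReport(family=family, params=dict(params),
                                       accuracy=nan, precision=nan, recall=nan,
                                       f1=nan, fold_scores=[]))
            continue
        reports.append(ModelReport(
            family=family, params=dict(params),
            accuracy=float(np.mean(accs)), precision=float(np.mean(precs)),
            recall=float(np.mean(recs)), f1=float(np.mean(f1s)),
            fold_scores=[float(a) for a in accs],
        ))
    return reports


def select_best(reports: list[ModelReport]) -> ModelReport:
    """Highest accuracy; ties broken by F1, then family name alphabetically.

    Settings whose fit failed (NaN metrics) are ignored.
    """
    valid = [r for r in reports if np.isfinite(r.accuracy)]
    if not valid:
        raise ValueError("no model reports to select from")
    return max(valid, key=lambda r: (r.accuracy, r.f1, [-ord(c) for c in r.family]))
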