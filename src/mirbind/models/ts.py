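"""Site-level classifier: training, cross-validation, greedy feature selection.

The learner is a histogram gradient-boosted tree ensemble that handles
missing feature values natively, so NaN features flow through fit and
predict without imputation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import HistGradientBoostingClassifier
from sklearn.model_selection import StratifiedKFold

from mirbind.datasets import LABEL_COLUMN
from mirbind.models.metrics import MetricsReport, compute_metrics

DEFAULT_MODEL_CONFIG: Dict = {
    "max_iter": 150,
    "learning_rate": 0.1,
    "max_leaf_nodes": 31,
    "early_stopping": False,
}

# Light configuration for the inner loops of feature selection, where
# thousands of small fits are made.
LIGHT_MODEL_CONFIG: Dict = {
    "max_iter": 40,
    "learning_rate": 0.2,
    "max_leaf_nodes": 15,
    "early_stopping": False,
}


def make_classifier(
    config: Optional[Dict] = None,
    seed: int = 0,
    monotonic_cst: Optional[Sequence[int]] = None,
) -> HistGradientBoostingClassifier:
    params = dict(DEFAULT_MODEL_CONFIG)
    params.update(config or {})
    if monotonic_cst is not None:
        params["monotonic_cst"] = list(monotonic_cst)
    return HistGradientBoostingClassifier(random_state=seed, **params)


@dataclass
class ModelBundle:
    """A trained classifier plus everything needed to reproduce its predictions."""

    model: HistGradientBoostingClassifier
    feature_names: List[str]
    config: Dict
    seed: int
    registry_fingerprint: str = ""

    def save(self, path: Union[str, Path]) -> None:
        joblib.dump(
            {
                "model": self.model,
                "feature_names": self.feature_names,
                "config": self.config,
                "seed": self.seed,
                "registry_fingerprint": self.registry_fingerprint,
            },
            path,
        )

    @classmethod
    def load(cls, path: Union[str, Path]) -> "ModelBundle":
        d = joblib.load(path)
        return cls(**d)


def _feature_matrix(dataset: pd.DataFrame, features: Sequence[str]) -> np.ndarray:
    missing = [f for f in features if f not in dataset.columns]
    if missing:
        raise KeyError(f"features absent from dataset: {missing}")
    return dataset[list(features)].to_numpy(dtype=float)


def train_ts(
    dataset: pd.DataFrame,
    selected_features: Sequence[str],
    model_config: Optional[Dict] = None,
    seed: int = 0,
    registry_fingerprint: str = "",
    monotonic_cst: Optional[Sequence[int]] = None,
) -> ModelBundle:
    X = _feature_matrix(dataset, selected_features)
    y = dataset[LABEL_COLUMN].to_numpy(dtype=int)
    clf = make_classifier(model_config, seed=seed, monotonic_cst=monotonic_cst)
    clf.fit(X, y)
    return ModelBundle(
        model=clf,
        feature_names=list(selected_features),
        config=dict(model_config or DEFAULT_MODEL_CONFIG),
        seed=seed,
        registry_fingerprint=registry_fingerprint,
    )


def predict_sites(bundle: ModelBundle, sites_features: pd.DataFrame) -> np.ndarray:
    """Per-site binding confidence in [0, 1], order preserved."""
    if len(sites_features) == 0:
        return np.empty(0)
    X = _feature_matrix(sites_features, bundle.feature_names)
    return bundle.model.predict_proba(X)[:, 1]


def cross_validate(
    dataset: pd.DataFrame,
    k: int = 10,
    model_config: Optional[Dict] = None,
    seed: int = 0,
    features: Optional[Sequence[str]] = None,
    threshold: float = 0.5,
) -> Tuple[List[MetricsReport], Dict[str, Tuple[float, float]]]:
    """Stratified k-fold CV; returns per-fold reports and mean +/- sd summary."""
    if k < 2:
        raise ValueError("k must be >= 2")
    y = dataset[LABEL_COLUMN].to_numpy(dtype=int)
    counts = np.bincount(y, minlength=2)
    if counts.min() < k:
        raise ValueError(f"each class needs at least k={k} members")
    features = list(features) if features is not None else [
        c for c in dataset.columns
        if c != LABEL_COLUMN and pd.api.types.is_numeric_dtype(dataset[c])
    ]
    X = _feature_matrix(dataset, features)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    reports: List[MetricsReport] = []
    for train_idx, test_idx in skf.split(X, y):
        clf = make_classifier(model_config, seed=seed)
        clf.fit(X[train_idx], y[train_idx])
        scores = clf.predict_proba(X[test_idx])[:, 1]
        reports.append(compute_metrics(y[test_idx], scores, threshold))
    summary = {}
    for name in ("auc", "bacc", "f1", "mcc", "precision", "recall", "specificity"):
        vals = np.array([getattr(r, name) for r in reports], dtype=float)
        summary[name] = (float(np.mean(vals)), float(np.std(vals, ddof=1)))
    return reports, summary


def _cv_mcc(
    X: np.ndarray, y: np.ndarray, folds: List[Tuple[np.ndarray, np.ndarray]],
    model_config: Dict, seed: int,
) -> float:
    vals = []
    for train_idx, test_idx in folds:
        clf = make_classifier(model_config, seed=seed)
        clf.fit(X[train_idx], y[train_idx])
        scores = clf.predict_proba(X[test_idx])[:, 1]
        vals.append(compute_metrics(y[test_idx], scores).mcc)
    return float(np.mean(vals))


def greedy_forward_selection(
    dataset: pd.DataFrame,
    candidate_features: Sequence[str],
    k: int = 10,
    seed: int = 0,
    model_config: Optional[Dict] = None,
    max_features: int = 22,
    min_gain: float = 1e-4,
) -> List[Tuple[str, float]]:
    """Forward stepwise selection maximizing mean cross-validated MCC.

    At each iteration every remaining candidate is evaluated added to the
    current set and the best (ties broken by candidate order) is kept.  Stops
    at ``max_features`` or when the best gain falls below ``min_gain``.
    Returns the (feature, cv_mcc) trajectory.
    """
    candidates = list(candidate_features)
    if not candidates:
        raise ValueError("need at least one candidate feature")
    model_config = dict(model_config or LIGHT_MODEL_CONFIG)
    y = dataset[LABEL_COLUMN].to_numpy(dtype=int)
    X_all = _feature_matrix(dataset, candidates)
    col = {f: i for i, f in enumerate(candidates)}
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = list(skf.split(X_all, y))
    selected: List[str] = []
    trajectory: List[Tuple[str, float]] = []
    best_score = -np.inf
    while len(selected) < min(max_features, len(candidates)):
        round_best: Optional[Tuple[float, str]] = None
        for feat in candidates:
            if feat in selected:
                continue
            cols = [col[f] for f in selected + [feat]]
            score = _cv_mcc(X_all[:, cols], y, folds, model_config, seed)
            if round_best is None or score > round_best[0]:
                round_best = (score, feat)
        score, feat = round_best
        if trajectory and score - best_score < min_gain:
            break
        selected.append(feat)
        trajectory.append((feat, score))
        best_score = max(best_score, score)
    return trajectory


def permutation_importance_report(
    bundle: ModelBundle, dataset: pd.DataFrame, seed: int = 0, n_repeats: int = 5
) -> pd.DataFrame:
    """Drop in AUC when each feature is permuted (generic importance report)."""
    rng = np.random.default_rng(seed)
    X = _feature_matrix(dataset, bundle.feature_names)
    y = dataset[LABEL_COLUMN].to_numpy(dtype=int)
    base = compute_metrics(y, bundle.model.predict_proba(X)[:, 1]).auc
    rows = []
    for j, name in enumerate(bundle.feature_names):
        drops = []
        for _ in range(n_repeats):
            Xp = X.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            drops.append(base - compute_metrics(y, bundle.model.predict_proba(Xp)[:, 1]).auc)
        rows.append({"feature": name, "auc_drop_mean": float(np.mean(drops)),
                     "auc_drop_sd": float(np.std(drops, ddof=1))})
    return pd.DataFrame(rows).sort_values("auc_drop_mean", ascending=False).reset_index(drop=True)
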