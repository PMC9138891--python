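"""Interpretable feature-importance ranking.

Per workload level, feature weights are the mean absolute coefficients of a
linear model (linear SVM or elastic-net logistic regression) fitted on the
training portion of repeated 80:20 subject splits; per-repeat coefficient
vectors are L2-normalised before averaging so repeats contribute equally.
Per-level weights come from a one-vs-rest decomposition of the three-class
model (a multinomial alternative is exposed for logistic regression).
Features are then grouped per level into high / medium / low importance by
1-D k-means with three clusters, relabelled by descending cluster mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.multiclass import OneVsRestClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .classify import split_by_subject, _frame
from .errors import DataError, DegenerateDataError, ParameterError
from .features import FEATURE_NAMES
from .records import LEVELS

__all__ = [
    "LINEAR_MODELS",
    "extract_weights",
    "cluster_importance",
    "ImportanceRanking",
    "rank_importance",
    "rank_features",
    "ranking_report",
    "high_medium_features",
]

LINEAR_MODELS = ("svm_linear", "logistic_regression")
CLUSTER_ORDER = ("high", "medium", "low")


def _make_linear(model: str, seed: int, scheme: str):
    if model == "svm_linear":
        return LinearSVC(C=1.0, random_state=seed, max_iter=20000)
    if model == "logistic_regression":
        base = LogisticRegression(
            l1_ratio=0.5, C=1.0, solver="saga", max_iter=5000,
            random_state=seed,
        )
        return base if scheme == "multinomial" else OneVsRestClassifier(base)
    raise ParameterError(f"unknown linear model {model!r}; choose from {LINEAR_MODELS}")


def _coef_by_level(fitted, scheme: str) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(fitted, OneVsRestClassifier):
        coef = np.vstack([est.coef_ for est in fitted.estimators_])
    else:
        coef = fitted.coef_
    return np.asarray(coef, float), np.asarray(fitted.classes_)


def extract_weights(
    table,
    model: str,
    n_repeats: int = 1000,
    master_seed: int = 0,
    scheme: str = "ovr",
    features=None,
    ratio: float = 0.8,
) -> pd.DataFrame:
    """Mean per-level absolute weights over repeated subject resamples.

    Returns a (n_features x 3) DataFrame indexed by feature name with one
    column per workload level.  Features are standardized within each
    resample (fit on that sample) so weights are comparable across features.
    Repeats whose fit fails are re-drawn with the next derived seed.
    """
    if model not in LINEAR_MODELS:
        raise ParameterError(f"unknown linear model {model!r}; choose from {LINEAR_MODELS}")
    if scheme not in ("ovr", "multinomial"):
        raise ParameterError("scheme must be 'ovr' or 'multinomial'")
    frame = _frame(table)
    feats = list(features) if features is not None else list(FEATURE_NAMES)
    X_all = frame[feats].to_numpy(dtype=float)
    y_all = frame["level"].astype(str).to_numpy()
    groups = frame["subject"].to_numpy()

    root = np.random.SeedSequence(master_seed)
    children = list(root.spawn(n_repeats + 200))  # spare children for re-draws
    totals = {lvl: np.zeros(len(feats)) for lvl in LEVELS}
    done = 0
    ci = 0
    n_failed = 0
    while done < n_repeats:
        if ci >= len(children):
            raise DataError(f"too many failed importance repeats ({n_failed})")
        child = children[ci]
        ci += 1
        rng = np.random.default_rng(child)
        seed = int(child.generate_state(1)[0] % (2**31))
        train_subj, _ = split_by_subject(groups, ratio, rng)
        tr = np.isin(groups, train_subj)
        X, y = X_all[tr], y_all[tr]
        if len(set(y)) < 3:
            n_failed += 1
            continue
        try:
            Xs = StandardScaler().fit_transform(X)
            est = _make_linear(model, seed, scheme)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                est.fit(Xs, y)
            coef, classes = _coef_by_level(est, scheme)
        except Exception:
            n_failed += 1
            continue
        for row, cls in zip(np.abs(coef), classes):
            norm = float(np.linalg.norm(row))
            if norm > 0:
                totals[str(cls)] += row / norm
        done += 1
    weights = pd.DataFrame(
        {lvl: totals[lvl] / n_repeats for lvl in LEVELS}, index=pd.Index(feats, name="feature")
    )
    weights.attrs["n_failed"] = n_failed
    return weights


def cluster_importance(weights, n_clusters: int = 3, seed: int = 0) -> np.ndarray:
    """Group 1-D weights into labelled clusters by k-means.

    Returns an array of labels from ``("high", "medium", "low")`` assigned by
    descending cluster mean.  Requires at least ``n_clusters`` distinct
    values; 50 restarts make the contiguous 1-D optimum reliable on the 16
    feature weights this pipeline produces.
    """
    arr = np.asarray(weights, dtype=float).ravel()
    if not np.all(np.isfinite(arr)):
        raise DataError("weights must be finite")
    if len(np.unique(arr)) < n_clusters:
        raise DegenerateDataError(
            f"need at least {n_clusters} distinct weight values, got {len(np.unique(arr))}"
        )
    km = KMeans(n_clusters=n_clusters, n_init=50, tol=1e-10, random_state=seed)
    ids = km.fit_predict(arr.reshape(-1, 1))
    order = np.argsort(-km.cluster_centers_.ravel())  # descending mean weight
    label_of = {int(cid): CLUSTER_ORDER[rank] for rank, cid in enumerate(order)}
    return np.asarray([label_of[int(c)] for c in ids])


@dataclass
class ImportanceRanking:
    """Per-level sorted weights with high/medium/low cluster labels."""

    model: str
    n_repeats: int
    table: pd.DataFrame  # columns: level, feature, weight, cluster

    def level(self, level_id: str) -> pd.DataFrame:
        return self.table[self.table["level"] == level_id].reset_index(drop=True)


def rank_importance(
    weights: pd.DataFrame, model: str, n_repeats: int, seed: int = 0
) -> ImportanceRanking:
    """Cluster the per-level weight columns and assemble the ranking table."""
    rows = []
    for lvl in LEVELS:
        w = weights[lvl].to_numpy()
        labels = cluster_importance(w, seed=seed)
        order = np.argsort(-w)
        for idx in order:
            rows.append(
                {
                    "level": lvl,
                    "feature": weights.index[idx],
                    "weight": float(w[idx]),
                    "cluster": labels[idx],
                }
            )
    return ImportanceRanking(model=model, n_repeats=n_repeats, table=pd.DataFrame(rows))


def rank_features(weights: pd.DataFrame) -> list[str]:
    """Global feature ranking: unweighted mean of the per-level weights,
    descending — the ordering consumed by the accuracy-vs-feature-count curve."""
    return list(weights.mean(axis=1).sort_values(ascending=False).index)


def high_medium_features(ranking: ImportanceRanking, level_id: str) -> list[str]:
    sub = ranking.level(level_id)
    return list(sub[sub["cluster"].isin(["high", "medium"])]["feature"])


def ranking_report(rankings: dict[str, ImportanceRanking]) -> pd.DataFrame:
    """Per-level high+medium membership for each model, plus agreement.

    Each (level, feature) appears exactly once; the ``agreement`` column
    flags features on which all supplied models agree about high+medium
    membership (mirrors the observation that the per-model subsets are very
    similar).
    """
    rows = []
    for lvl in LEVELS:
        members = {name: set(high_medium_features(r, lvl)) for name, r in rankings.items()}
        for feat in FEATURE_NAMES:
            entry = {"level": lvl, "feature": feat}
            votes = []
            for name, sel in members.items():
                entry[f"{name}_high_medium"] = feat in sel
                votes.append(feat in sel)
            entry["agreement"] = len(set(votes)) == 1
            rows.append(entry)
    return pd.DataFrame(rows)
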