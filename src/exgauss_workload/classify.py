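"""Subject-independent three-class workload classification.

Protocol: subjects (not rows) are split 80:20 into train and test; all
three level rows of a subject travel together, so no participant ever
contributes to both partitions.  Features are z-scored on training rows
only for the scale-sensitive models.  The split/fit/score cycle is repeated
(200 times by default) and accuracy and macro-F1 are summarised as
mean (sd) across repeats.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score, f1_score
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .errors import DataError, ParameterError
from .features import FEATURE_NAMES, FeatureTable

__all__ = [
    "CLASSIFIER_NAMES",
    "make_classifier",
    "split_by_subject",
    "evaluate",
    "feature_curve",
    "EvaluationResult",
    "summarize",
]

CLASSIFIER_NAMES = (
    "decision_tree",
    "knn",
    "svm_linear",
    "svm_quadratic",
    "svm_cubic",
    "logistic_regression",
    "random_forest",
    "mlp",
)

#: Models whose features are z-scored on training rows; trees run on raw values.
STANDARDIZED = {"knn", "svm_linear", "svm_quadratic", "svm_cubic", "logistic_regression", "mlp"}

#: Kernel coefficient printed as 1/16 = 1 / (number of features).
SVM_GAMMA = 1.0 / 16.0


def make_classifier(name: str, seed: int | None = 0):
    """Instantiate one of the eight registered classifier configurations."""
    if name == "decision_tree":
        est = DecisionTreeClassifier(criterion="gini", max_depth=None, random_state=seed)
    elif name == "knn":
        est = KNeighborsClassifier(n_neighbors=5)
    elif name == "svm_linear":
        est = SVC(kernel="linear", C=1.0, gamma=SVM_GAMMA)
    elif name == "svm_quadratic":
        est = SVC(kernel="poly", degree=2, C=1.0, gamma=SVM_GAMMA)
    elif name == "svm_cubic":
        est = SVC(kernel="poly", degree=3, C=1.0, gamma=SVM_GAMMA)
    elif name == "logistic_regression":
        est = LogisticRegression(
            l1_ratio=0.5, C=1.0, solver="saga", max_iter=5000,
            random_state=seed,
        )
    elif name == "random_forest":
        est = RandomForestClassifier(n_estimators=100, criterion="gini", random_state=seed)
    elif name == "mlp":
        est = MLPClassifier(
            hidden_layer_sizes=(32, 16), activation="relu", max_iter=500,
            early_stopping=False, random_state=seed,
        )
    else:
        raise ParameterError(f"unknown classifier {name!r}; choose from {CLASSIFIER_NAMES}")
    if name in STANDARDIZED:
        return Pipeline([("scale", StandardScaler()), ("clf", est)])
    return est


def split_by_subject(subjects, ratio: float = 0.8, rng=None) -> tuple[list, list]:
    """Partition unique subject ids into train/test with |train| = round(ratio*n)."""
    uniq = sorted(set(subjects))
    if len(uniq) < 5:
        raise DataError(f"need at least 5 subjects to split, got {len(uniq)}")
    rng = np.random.default_rng(rng)
    perm = rng.permutation(len(uniq))
    n_train = int(round(ratio * len(uniq)))
    if not (0 < n_train < len(uniq)):
        raise DataError(f"ratio {ratio} leaves an empty partition")
    train = [uniq[i] for i in perm[:n_train]]
    test = [uniq[i] for i in perm[n_train:]]
    return train, test


@dataclass
class EvaluationResult:
    """Per-repeat accuracies/F1 of one classifier plus the audited splits."""

    classifier: str
    accuracies: np.ndarray
    f1_scores: np.ndarray
    n_features: int
    splits: list[tuple[tuple, tuple]] = field(default_factory=list, repr=False)
    n_redrawn: int = 0
    master_seed: int | None = None

    @property
    def n_repeats(self) -> int:
        return len(self.accuracies)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def sd_accuracy(self) -> float:
        return float(np.std(self.accuracies, ddof=1))

    @property
    def mean_f1(self) -> float:
        return float(np.mean(self.f1_scores))

    @property
    def sd_f1(self) -> float:
        return float(np.std(self.f1_scores, ddof=1))


def _frame(table) -> pd.DataFrame:
    return table.frame if isinstance(table, FeatureTable) else table


def evaluate(
    table,
    classifier: str,
    n_repeats: int = 200,
    master_seed: int = 0,
    features=None,
    ratio: float = 0.8,
) -> EvaluationResult:
    """Repeated subject-independent evaluation of one classifier.

    Every repeat draws a fresh 80:20 subject split, standardizes on the
    training rows only (where the model calls for it), fits, and scores
    accuracy and macro-F1 on the held-out subjects' rows.  A repeat whose
    training partition misses a class is re-drawn (counted); the absence of
    subject leakage is asserted on every repeat, not assumed.
    """
    frame = _frame(table)
    feats = list(features) if features is not None else list(FEATURE_NAMES)
    X = frame[feats].to_numpy(dtype=float)
    y = frame["level"].astype(str).to_numpy()
    groups = frame["subject"].to_numpy()
    if len(set(y)) < 2:
        raise DataError("need at least 2 classes present")

    root = np.random.SeedSequence(master_seed)
    children = root.spawn(n_repeats)
    accs = np.empty(n_repeats)
    f1s = np.empty(n_repeats)
    splits = []
    n_redrawn = 0
    for r, child in enumerate(children):
        rng = np.random.default_rng(child)
        model_seed = int(child.generate_state(1)[0] % (2**31))
        for _attempt in range(10):
            train_subj, test_subj = split_by_subject(groups, ratio, rng)
            assert not set(train_subj) & set(test_subj), "subject leakage"
            tr = np.isin(groups, train_subj)
            te = np.isin(groups, test_subj)
            if set(y[tr]) == set(y):
                break
            n_redrawn += 1
        clf = make_classifier(classifier, model_seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            clf.fit(X[tr], y[tr])
            pred = clf.predict(X[te])
        accs[r] = accuracy_score(y[te], pred)
        f1s[r] = f1_score(y[te], pred, average="macro")
        splits.append((tuple(train_subj), tuple(test_subj)))
    return EvaluationResult(
        classifier=classifier,
        accuracies=accs,
        f1_scores=f1s,
        n_features=len(feats),
        splits=splits,
        n_redrawn=n_redrawn,
        master_seed=master_seed,
    )


def feature_curve(
    table,
    classifier: str,
    ranking,
    n_repeats: int = 200,
    master_seed: int = 0,
) -> tuple[pd.DataFrame, int]:
    """Accuracy/F1 as a function of the number of top-ranked features.

    ``ranking`` is the ordered feature list (most important first) and must
    cover all 16 features.  The same master seed is used at every k, so the
    subject splits match across curve points; returns the per-k summary and
    the k maximising mean accuracy.
    """
    ranking = list(ranking)
    if sorted(ranking) != sorted(FEATURE_NAMES):
        raise ParameterError("ranking must cover all 16 features exactly once")
    rows = []
    for k in range(1, len(ranking) + 1):
        res = evaluate(
            table, classifier, n_repeats=n_repeats, master_seed=master_seed,
            features=ranking[:k],
        )
        rows.append(
            {
                "k": k,
                "mean_accuracy": res.mean_accuracy,
                "sd_accuracy": res.sd_accuracy,
                "mean_f1": res.mean_f1,
                "sd_f1": res.sd_f1,
            }
        )
    curve = pd.DataFrame(rows)
    best_k = int(curve.loc[curve["mean_accuracy"].idxmax(), "k"])
    return curve, best_k


def summarize(results) -> pd.DataFrame:
    """Mean (sd) accuracy/F1 per classifier, on the percent scale."""
    rows = []
    for res in results:
        rows.append(
            {
                "classifier": res.classifier,
                "accuracy_pct": 100 * res.mean_accuracy,
                "accuracy_sd_pct": 100 * res.sd_accuracy,
                "f1_pct": 100 * res.mean_f1,
                "f1_sd_pct": 100 * res.sd_f1,
                "n_features": res.n_features,
                "n_repeats": res.n_repeats,
            }
        )
    return pd.DataFrame(rows)
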