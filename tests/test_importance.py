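"""Feature-importance weights and the high/medium/low k-means grouping."""

import itertools

import numpy as np
import pandas as pd
import pytest

from exgauss_workload.errors import DegenerateDataError, ParameterError
from exgauss_workload.importance import (
    cluster_importance,
    extract_weights,
    high_medium_features,
    rank_features,
    rank_importance,
    ranking_report,
)
from exgauss_workload.records import LEVELS


def oracle_clusters(weights):
    """Exhaustive 1-D 3-means oracle: the optimal clustering of sorted values
    is contiguous, so try every pair of split points and minimise within-
    cluster sum of squares."""
    arr = np.asarray(weights, float)
    order = np.argsort(arr)
    s = arr[order]
    n = len(s)
    best, best_labels = np.inf, None
    for i, j in itertools.combinations(range(1, n), 2):
        groups = [s[:i], s[i:j], s[j:]]
        wss = sum(((g - g.mean()) ** 2).sum() for g in groups)
        if wss < best - 1e-15:
            labels_sorted = ["low"] * i + ["medium"] * (j - i) + ["high"] * (n - j)
            best, best_labels = wss, labels_sorted
    labels = np.empty(n, dtype=object)
    labels[order] = best_labels
    return labels


class TestClusterImportance:
    def test_three_tier_example(self):
        w = np.array([10, 9.5, 5, 4.8, 0.1, 0.05])
        labels = cluster_importance(w, seed=0)
        assert list(labels) == ["high", "high", "medium", "medium", "low", "low"]

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_partition_oracle(self, seed):
        rng = np.random.default_rng(seed)
        w = rng.gamma(1.5, 1.0, size=16)
        assert list(cluster_importance(w, seed=seed)) == list(oracle_clusters(w))

    def test_cluster_means_ordered(self, rng):
        w = rng.uniform(0, 1, 16)
        labels = cluster_importance(w, seed=1)
        means = {lab: w[labels == lab].mean() for lab in ("high", "medium", "low")}
        assert means["high"] > means["medium"] > means["low"]

    def test_too_few_distinct_values_error(self):
        with pytest.raises(DegenerateDataError):
            cluster_importance([1.0, 1.0, 1.0, 2.0], seed=0)


def _synthetic_table(rng, n_subjects=15, informative=("f00",), n_features=8, dup=None):
    """A feature frame where `informative` columns carry the level signal."""
    rows = []
    level_value = {"low": 0.0, "medium": 1.0, "high": 3.0}
    names = [f"f{i:02d}" for i in range(n_features)]
    for s in range(n_subjects):
        for lvl in LEVELS:
            row = {"subject": f"S{s:02d}", "level": lvl}
            for name in names:
                signal = level_value[lvl] if name in informative else 0.0
                row[name] = signal + rng.normal(0, 1)
            rows.append(row)
    frame = pd.DataFrame(rows)
    if dup:
        frame[dup] = frame[informative[0]]
    return frame, names + ([dup] if dup else [])


class TestExtractWeights:
    def test_shape_reproducibility_and_nonnegativity(self, rng):
        frame, names = _synthetic_table(rng)
        w1 = extract_weights(frame, "svm_linear", n_repeats=20, master_seed=4, features=names)
        w2 = extract_weights(frame, "svm_linear", n_repeats=20, master_seed=4, features=names)
        assert w1.shape == (len(names), 3)
        assert list(w1.columns) == list(LEVELS)
        assert (w1.to_numpy() >= 0).all()
        pd.testing.assert_frame_equal(w1, w2)

    def test_unknown_model_rejected(self, rng):
        frame, names = _synthetic_table(rng)
        with pytest.raises(ParameterError):
            extract_weights(frame, "random_forest", 5, 0, features=names)

    def test_duplicated_dominant_feature_shares_weight(self, rng):
        frame, names = _synthetic_table(rng, dup="f_dup")
        w = extract_weights(
            frame, "logistic_regression", n_repeats=40, master_seed=5, features=names
        )
        mean_w = w.mean(axis=1)
        a, b = mean_w["f00"], mean_w["f_dup"]
        noise = mean_w.drop(["f00", "f_dup"]).max()
        # the ridge component of the elastic net spreads weight over copies
        assert min(a, b) > noise
        assert abs(a - b) / max(a, b) < 0.5

    def test_zero_variance_feature_gets_zero_weight(self, rng):
        frame, names = _synthetic_table(rng)
        frame["f07"] = 2.5
        w = extract_weights(frame, "svm_linear", n_repeats=15, master_seed=6, features=names)
        assert w.loc["f07"].max() == pytest.approx(0.0, abs=1e-12)


class TestRankingReport:
    def test_noise_feature_lands_low_on_separated_cohort(self, sep_table):
        w = extract_weights(sep_table, "logistic_regression", n_repeats=100, master_seed=3)
        ranking = rank_importance(w, "logistic_regression", 100, seed=3)
        for lvl in LEVELS:
            sub = ranking.level(lvl).set_index("feature")
            assert sub.loc["tau_blink_count_10s", "cluster"] == "low"

    def test_dominant_feature_high_or_medium_everywhere(self, dom_table):
        w = extract_weights(dom_table, "logistic_regression", n_repeats=100, master_seed=3)
        ranking = rank_importance(w, "logistic_regression", 100, seed=3)
        for lvl in LEVELS:
            sub = ranking.level(lvl).set_index("feature")
            assert sub.loc["tau_response_time", "cluster"] in ("high", "medium")

    def test_report_lists_each_feature_once_per_level(self, dom_table):
        rankings = {}
        for model in ("svm_linear", "logistic_regression"):
            w = extract_weights(dom_table, model, n_repeats=60, master_seed=8)
            rankings[model] = rank_importance(w, model, 60, seed=8)
        report = ranking_report(rankings)
        counts = report.groupby(["level", "feature"], observed=True).size()
        assert (counts == 1).all()
        assert len(report) == 48  # 3 levels x 16 features
        # the two linear models broadly agree on what matters
        for lvl in LEVELS:
            svm = set(high_medium_features(rankings["svm_linear"], lvl))
            lr = set(high_medium_features(rankings["logistic_regression"], lvl))
            assert len(svm & lr) >= len(svm | lr) / 4

    def test_rank_features_orders_by_mean_weight(self):
        w = pd.DataFrame(
            {"low": [0.1, 0.9], "medium": [0.2, 0.8], "high": [0.3, 0.7]},
            index=pd.Index(["weak", "strong"], name="feature"),
        )
        assert rank_features(w) == ["strong", "weak"]
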