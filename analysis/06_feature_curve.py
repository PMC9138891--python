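#!/usr/bin/env python
"""Accuracy as a function of the number of top-ranked features for random
forest, decision tree and linear SVM, using the logistic-regression ranking
aggregated across levels; writes results/feature_curve.csv.
"""

from pathlib import Path

import pandas as pd

from exgauss_workload.classify import feature_curve
from exgauss_workload.features import FeatureTable
from exgauss_workload.importance import extract_weights, rank_features

ROOT = Path(__file__).resolve().parents[1]
N_REPEATS = 25
SEED = 14
MODELS = ("random_forest", "decision_tree", "svm_linear")


def main() -> None:
    features_csv = ROOT / "results" / "features.csv"
    if not features_csv.exists():
        raise SystemExit("run analysis/02_extract_features.py first")
    table = FeatureTable.from_csv(features_csv)

    weights = extract_weights(table, "logistic_regression", n_repeats=200, master_seed=SEED)
    ranking = rank_features(weights)
    print("feature ranking (most important first):")
    for i, name in enumerate(ranking, 1):
        print(f"  {i:2d}. {name}")

    frames = []
    for model in MODELS:
        curve, best_k = feature_curve(table, model, ranking, n_repeats=N_REPEATS,
                                      master_seed=SEED)
        curve.insert(0, "classifier", model)
        frames.append(curve)
        at_best = curve.loc[curve["k"] == best_k].iloc[0]
        print(f"{model}: best k = {best_k} "
              f"({100 * at_best['mean_accuracy']:.2f}% accuracy); "
              f"k=1 gives {100 * curve['mean_accuracy'].iloc[0]:.2f}%")
    out = ROOT / "results" / "feature_curve.csv"
    pd.concat(frames).to_csv(out, index=False, float_format="%.4f")
    print(f"curves -> {out}")


if __name__ == "__main__":
    main()
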