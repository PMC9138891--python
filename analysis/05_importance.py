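#!/usr/bin/env python
"""Per-level feature importance from the two interpretable linear models
(linear SVM, elastic-net logistic regression) over repeated subject
resamples, clustered into high/medium/low tiers by 1-D k-means; writes the
rankings and the cross-model report under results/.
"""

from pathlib import Path

from exgauss_workload.features import FeatureTable
from exgauss_workload.importance import (
    LINEAR_MODELS,
    extract_weights,
    high_medium_features,
    rank_importance,
    ranking_report,
)
from exgauss_workload.records import LEVELS

ROOT = Path(__file__).resolve().parents[1]
N_REPEATS = 200  # library default is 1000; reduced for a quick driver
SEED = 14


def main() -> None:
    features_csv = ROOT / "results" / "features.csv"
    if not features_csv.exists():
        raise SystemExit("run analysis/02_extract_features.py first")
    table = FeatureTable.from_csv(features_csv)

    rankings = {}
    for model in LINEAR_MODELS:
        weights = extract_weights(table, model, n_repeats=N_REPEATS, master_seed=SEED)
        ranking = rank_importance(weights, model, N_REPEATS, seed=SEED)
        ranking.table.to_csv(ROOT / "results" / f"importance_{model}.csv", index=False,
                             float_format="%.5f")
        rankings[model] = ranking
        print(f"\n{model}: high+medium cluster members per level")
        for lvl in LEVELS:
            print(f"  {lvl:7s} {', '.join(high_medium_features(ranking, lvl))}")

    report = ranking_report(rankings)
    report.to_csv(ROOT / "results" / "importance_report.csv", index=False)
    agree = report.groupby("level", observed=True)["agreement"].mean()
    print("\ncross-model agreement on high+medium membership per level:")
    print((100 * agree).round(1).to_string())


if __name__ == "__main__":
    main()
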