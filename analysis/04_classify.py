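#!/usr/bin/env python
"""Subject-independent three-class classification of workload level with the
eight registered classifiers; writes the mean (sd) accuracy / macro-F1
summary to results/classification_summary.csv.

Repeats are set to 50 here to keep the driver quick; the library default
(200) reproduces the full protocol.
"""

from pathlib import Path

from exgauss_workload.classify import CLASSIFIER_NAMES, evaluate, summarize
from exgauss_workload.features import FeatureTable

ROOT = Path(__file__).resolve().parents[1]
N_REPEATS = 50
SEED = 14


def main() -> None:
    features_csv = ROOT / "results" / "features.csv"
    if not features_csv.exists():
        raise SystemExit("run analysis/02_extract_features.py first")
    table = FeatureTable.from_csv(features_csv)
    results = [
        evaluate(table, name, n_repeats=N_REPEATS, master_seed=SEED)
        for name in CLASSIFIER_NAMES
    ]
    summary = summarize(results).sort_values("accuracy_pct", ascending=False)
    out = ROOT / "results" / "classification_summary.csv"
    summary.to_csv(out, index=False, float_format="%.2f")
    print(summary.to_string(index=False))
    best = summary.iloc[0]
    print(f"\nbest: {best['classifier']} at {best['accuracy_pct']:.2f}% "
          f"({best['accuracy_sd_pct']:.2f}) accuracy -> {out}")


if __name__ == "__main__":
    main()
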