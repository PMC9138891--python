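#!/usr/bin/env python
"""Friedman screen (subjects as blocks, three workload levels) over all 24
mu/sigma/tau candidates plus the Spearman correlation matrix of the 16
retained features; writes both reports under results/.

The diagnostic point mirrored here: sigma parameters of most measures carry
no significant level effect, supporting the fixed rule that discards sigma
from the modelling features.
"""

from pathlib import Path

import pandas as pd

from exgauss_workload.features import FeatureTable
from exgauss_workload.selection import screen_features

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    features_csv = ROOT / "results" / "features.csv"
    if not features_csv.exists():
        raise SystemExit("run analysis/02_extract_features.py first")
    table = FeatureTable.from_csv(features_csv)
    sigma_csv = ROOT / "results" / "features_sigma.csv"
    if sigma_csv.exists():
        table.sigma_frame = pd.read_csv(sigma_csv)

    report = screen_features(table)
    report.friedman.to_csv(ROOT / "results" / "screen_friedman.csv", index=False,
                           float_format="%.6g")
    report.spearman_rho.to_csv(ROOT / "results" / "screen_spearman_rho.csv",
                               float_format="%.4f")
    report.strong_pairs.to_csv(ROOT / "results" / "screen_strong_pairs.csv", index=False)

    fr = report.friedman
    mu_tau = fr[~fr["feature"].str.startswith("sigma")]
    sigma = fr[fr["feature"].str.startswith("sigma")]
    print(f"mu/tau features significant at alpha={report.alpha}: "
          f"{int(mu_tau['significant'].sum())}/{len(mu_tau)}")
    print(f"sigma diagnostics significant:                 "
          f"{int(sigma['significant'].sum())}/{len(sigma)}")
    print(f"strong correlations (|rho| >= {report.strong_threshold}): "
          f"{len(report.strong_pairs)}")
    print(fr.sort_values('p_value').head(8).to_string(index=False))


if __name__ == "__main__":
    main()
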