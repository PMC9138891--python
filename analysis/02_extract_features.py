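#!/usr/bin/env python
"""Read the fixture files written by 01_simulate_cohort.py back through the
IO/synchronisation layer, extract the 16 ex-Gaussian features per session,
and write the 90-row feature table to results/features.csv.

Going through the TSV round trip (rather than passing recordings in memory)
exercises the same path laboratory exports would take.
"""

from pathlib import Path

from exgauss_workload.features import build_dataset
from exgauss_workload.io_sync import read_eye_events, read_trial_log, synchronize
from exgauss_workload.records import LEVELS

ROOT = Path(__file__).resolve().parents[1]
DURATIONS = {"low": 90.0, "medium": 90.0, "high": 180.0}


def main() -> None:
    fixtures = ROOT / "scratch" / "cohort_fixtures"
    if not fixtures.exists():
        raise SystemExit("run analysis/01_simulate_cohort.py first")
    recordings = []
    subjects = sorted({p.name.split("_")[0] for p in fixtures.glob("*_eye.tsv")})
    for sid in subjects:
        for lvl in LEVELS:
            eye = read_eye_events(fixtures / f"{sid}_{lvl}_eye.tsv")
            trials = read_trial_log(fixtures / f"{sid}_{lvl}_trials.tsv")
            recordings.append(synchronize(eye, trials, sid, lvl, DURATIONS[lvl]))
    table = build_dataset(recordings, provenance={"source": "01_simulate_cohort fixtures"})
    out = ROOT / "results" / "features.csv"
    table.to_csv(out)
    table.sigma_frame.to_csv(ROOT / "results" / "features_sigma.csv", index=False,
                             float_format="%.9g")
    print(f"{len(table.frame)} rows x {len(table.feature_names)} features -> {out}")
    print(table.frame.iloc[:3, :6].to_string(index=False))


if __name__ == "__main__":
    main()
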