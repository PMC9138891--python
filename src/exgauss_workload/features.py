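"""Measure-series extraction and the 16-feature ex-Gaussian table.

Eight raw series per session: saccade amplitude, saccade duration, fixation
duration and single-trial response time come directly from event rows;
saccade, fixation, blink and correct-answer counts are computed over 10-s
windows.  Each series is cleansed (one highest and one lowest value removed)
and fitted with an ex-Gaussian MLE; the mu and tau of each measure enter the
final table while sigma is retained only as a diagnostic, giving 16 features
per (subject, level) row — 90 rows for the default 30-subject cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError
from .exgauss import FitResult, fit_exgauss
from .io_sync import trim_extremes
from .records import LEVELS, SessionRecording

__all__ = [
    "MEASURES",
    "FEATURE_NAMES",
    "SIGMA_NAMES",
    "SCHEMA_VERSION",
    "windowed_counts",
    "extract_measure_series",
    "extract_features",
    "FeatureVector",
    "FeatureTable",
    "build_dataset",
]

SCHEMA_VERSION = "1"

#: The eight measure series, in the order the feature schema freezes.
MEASURES = (
    "saccade_amplitude",
    "saccade_duration",
    "saccade_count_10s",
    "fixation_duration",
    "fixation_count_10s",
    "blink_count_10s",
    "correct_count_10s",
    "response_time",
)

#: Frozen schema: mu and tau of each measure, measure-major order.
FEATURE_NAMES = tuple(f"{p}_{m}" for m in MEASURES for p in ("mu", "tau"))

#: Diagnostic sigma columns (computed, screened, never modelled on).
SIGMA_NAMES = tuple(f"sigma_{m}" for m in MEASURES)

WINDOW_LENGTH_S = 10.0


def windowed_counts(onsets, duration: float, window_length: float = WINDOW_LENGTH_S) -> np.ndarray:
    """Count events per half-open window [k*w, (k+1)*w) over the session.

    ``duration`` must be a positive multiple of ``window_length`` (90 s and
    180 s both are); onsets outside [0, duration) are an error — the
    synchronisation step is responsible for dropping those.
    """
    n_windows = duration / window_length
    if duration <= 0 or abs(n_windows - round(n_windows)) > 1e-9:
        raise DataError(
            f"duration {duration} must be a positive multiple of window length {window_length}"
        )
    n_windows = int(round(n_windows))
    arr = np.asarray(onsets, dtype=float)
    if arr.size and (np.any(arr < 0) or np.any(arr >= duration)):
        raise DataError("onsets must lie in [0, duration)")
    idx = np.floor(arr / window_length).astype(int) if arr.size else np.empty(0, int)
    return np.bincount(idx, minlength=n_windows).astype(float)


def extract_measure_series(session: SessionRecording) -> dict[str, np.ndarray]:
    """The eight raw numeric series of one session, keyed by measure name."""
    for name, stream in [
        ("saccades", session.saccades),
        ("fixations", session.fixations),
        ("blinks", session.blinks),
        ("trials", session.trials),
    ]:
        if stream.shape[0] == 0:
            raise DataError(f"session {session.subject_id}/{session.level_id}: empty {name} stream")
    d = session.duration
    correct_onsets = session.trials[session.trials[:, 2] == 1.0, 0]
    return {
        "saccade_amplitude": session.saccades[:, 2],
        "saccade_duration": session.saccades[:, 1],
        "saccade_count_10s": windowed_counts(session.saccades[:, 0], d),
        "fixation_duration": session.fixations[:, 1],
        "fixation_count_10s": windowed_counts(session.fixations[:, 0], d),
        "blink_count_10s": windowed_counts(session.blinks[:, 0], d),
        "correct_count_10s": windowed_counts(correct_onsets, d),
        "response_time": session.trials[:, 1],
    }


@dataclass(frozen=True)
class FeatureVector:
    """One (subject, level) row: the 16 mu/tau features plus diagnostics."""

    subject_id: str
    level_id: str
    features: dict[str, float]
    sigmas: dict[str, float]
    fits: dict[str, FitResult]

    def __post_init__(self):
        if tuple(self.features) != FEATURE_NAMES:
            raise DataError("feature vector does not match the frozen 16-feature schema")
        if not all(np.isfinite(list(self.features.values()))):
            raise DataError("feature values must all be finite")


def extract_features(session: SessionRecording) -> FeatureVector:
    """Trim, fit and summarise all eight measures of one session.

    Counts are fitted with the continuous ex-Gaussian likelihood, without a
    continuity correction.  Trimming or fitting failures propagate with the
    measure name attached; a non-converged fit is kept but flagged in the
    per-measure :class:`FitResult` diagnostics.
    """
    series = extract_measure_series(session)
    features: dict[str, float] = {}
    sigmas: dict[str, float] = {}
    fits: dict[str, FitResult] = {}
    for measure in MEASURES:
        try:
            trimmed = trim_extremes(series[measure])
            fit = fit_exgauss(trimmed)
        except Exception as exc:
            raise type(exc)(
                f"session {session.subject_id}/{session.level_id}, measure {measure}: {exc}"
            ) from exc
        fits[measure] = fit
        sigmas[f"sigma_{measure}"] = fit.params.sigma
        features[f"mu_{measure}"] = fit.params.mu
        features[f"tau_{measure}"] = fit.params.tau
    ordered = {name: features[name] for name in FEATURE_NAMES}
    return FeatureVector(session.subject_id, session.level_id, ordered, sigmas, fits)


@dataclass
class FeatureTable:
    """The assembled dataset: one row per (subject, level).

    ``frame`` holds subject, level and the 16 modelling features;
    ``sigma_frame`` the eight diagnostic sigma columns; ``provenance`` the
    config hash / seeds of the cohort that produced it.
    """

    frame: pd.DataFrame
    sigma_frame: pd.DataFrame | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        expected = ["subject", "level", *FEATURE_NAMES]
        if list(self.frame.columns) != expected:
            raise DataError("feature table columns do not match the frozen schema")
        self.provenance.setdefault("schema_version", SCHEMA_VERSION)

    @property
    def feature_names(self) -> tuple[str, ...]:
        return FEATURE_NAMES

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False, float_format="%.9g")

    @classmethod
    def from_csv(cls, path) -> "FeatureTable":
        frame = pd.read_csv(path)
        return cls(frame=frame, provenance={"source": str(path)})


def build_dataset(cohort, provenance: dict | None = None) -> FeatureTable:
    """Extract features for every session of a cohort.

    Rows are ordered as the cohort is, one per session; with the default
    30-subject x 3-level cohort that is 90 rows.
    """
    rows, sig_rows = [], []
    for session in cohort:
        fv = extract_features(session)
        rows.append({"subject": fv.subject_id, "level": fv.level_id, **fv.features})
        sig_rows.append({"subject": fv.subject_id, "level": fv.level_id, **fv.sigmas})
    frame = pd.DataFrame(rows, columns=["subject", "level", *FEATURE_NAMES])
    sigma_frame = pd.DataFrame(sig_rows, columns=["subject", "level", *SIGMA_NAMES])
    frame["level"] = pd.Categorical(frame["level"], categories=list(LEVELS), ordered=True)
    sigma_frame["level"] = pd.Categorical(sigma_frame["level"], categories=list(LEVELS), ordered=True)
    return FeatureTable(frame=frame, sigma_frame=sigma_frame, provenance=dict(provenance or {}))
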