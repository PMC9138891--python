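"""Reading, synchronising and cleansing the two recording dialects.

The eye export is a tab-separated event table (timestamp, event type,
duration, optional saccade amplitude); the trial log is a tab-separated
DSST table (timestamp, response time, correct flag).  The two streams are
merged onto one session-relative clock by re-basing on the earlier of the
two first timestamps; events past the session duration are dropped with a
logged count.  Cleansing removes one highest and one lowest value from each
measure series of a session before distribution fitting.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError, LoadError, SynchronizationError, TooFewObservationsError
from .records import SessionRecording

__all__ = [
    "RawEventTable",
    "read_eye_events",
    "read_trial_log",
    "synchronize",
    "trim_extremes",
    "save_sessions",
    "load_sessions",
]

log = logging.getLogger(__name__)

EYE_COLUMNS = ["timestamp_s", "event_type", "duration_s", "amplitude_deg"]
TRIAL_COLUMNS = ["timestamp_s", "response_time_s", "correct"]
EVENT_TYPES = {"fixation", "saccade", "blink"}


@dataclass
class RawEventTable:
    """A validated, timestamp-sorted eye-event table (units: seconds)."""

    frame: pd.DataFrame
    source: str = ""
    units: str = "s"


def _read_tsv(path, columns: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise LoadError(f"no such file: {path}")
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in raw.columns]
    if missing:
        raise LoadError(f"{path}: missing columns {missing}")
    return raw


def _bad_lines(mask: pd.Series) -> list[int]:
    # +2: one for the header row, one for 1-based line numbering
    return [int(i) + 2 for i in mask[mask].index]


def read_eye_events(path) -> RawEventTable:
    """Load and validate an eye-event export; rows are sorted by timestamp."""
    raw = _read_tsv(path, EYE_COLUMNS)
    ts = pd.to_numeric(raw["timestamp_s"], errors="coerce")
    dur = pd.to_numeric(raw["duration_s"], errors="coerce")
    amp = pd.to_numeric(raw["amplitude_deg"].mask(raw["amplitude_deg"] == ""), errors="coerce")
    kind = raw["event_type"]

    problems: dict[str, list[int]] = {}
    for label, mask in [
        ("unparseable timestamp", ts.isna()),
        ("unparseable duration", dur.isna()),
        ("negative or zero duration", dur.notna() & (dur <= 0)),
        ("unknown event type", ~kind.isin(EVENT_TYPES)),
        ("saccade without amplitude", kind.eq("saccade") & amp.isna()),
        ("amplitude on non-saccade row", ~kind.eq("saccade") & raw["amplitude_deg"].ne("")),
    ]:
        lines = _bad_lines(mask)
        if lines:
            problems[label] = lines
    if problems:
        detail = "; ".join(f"{label}: lines {lines}" for label, lines in problems.items())
        raise LoadError(
            f"{path}: {detail}", lines=sorted({n for ls in problems.values() for n in ls})
        )

    frame = pd.DataFrame(
        {"timestamp_s": ts, "event_type": kind, "duration_s": dur, "amplitude_deg": amp}
    )
    frame = frame.sort_values("timestamp_s", kind="stable").reset_index(drop=True)
    return RawEventTable(frame=frame, source=str(path))


def read_trial_log(path) -> pd.DataFrame:
    """Load and validate a trial log; rows are sorted by timestamp."""
    raw = _read_tsv(path, TRIAL_COLUMNS)
    if len(raw) == 0:
        raise LoadError(f"{path}: a session must contain at least one trial")
    ts = pd.to_numeric(raw["timestamp_s"], errors="coerce")
    rt = pd.to_numeric(raw["response_time_s"], errors="coerce")
    corr = pd.to_numeric(raw["correct"], errors="coerce")

    problems: dict[str, list[int]] = {}
    for label, mask in [
        ("unparseable timestamp", ts.isna()),
        ("unparseable response time", rt.isna()),
        ("negative or zero response time", rt.notna() & (rt <= 0)),
        ("correct flag outside {0,1}", ~corr.isin([0, 1])),
    ]:
        lines = _bad_lines(mask)
        if lines:
            problems[label] = lines
    if problems:
        detail = "; ".join(f"{label}: lines {lines}" for label, lines in problems.items())
        raise LoadError(
            f"{path}: {detail}", lines=sorted({n for ls in problems.values() for n in ls})
        )

    frame = pd.DataFrame({"timestamp_s": ts, "response_time_s": rt, "correct": corr.astype(float)})
    return frame.sort_values("timestamp_s", kind="stable").reset_index(drop=True)


def synchronize(
    eye: RawEventTable,
    trials: pd.DataFrame,
    subject_id: str,
    level_id: str,
    duration: float,
) -> SessionRecording:
    """Merge eye events and trials onto a session-relative clock.

    Timestamps are shifted so the earlier of the two first timestamps becomes
    0; events with onsets at or beyond ``duration`` are dropped and counted.
    Raises :class:`SynchronizationError` when the two time ranges do not
    overlap at all.
    """
    ef = eye.frame if isinstance(eye, RawEventTable) else eye
    if len(ef) == 0 or len(trials) == 0:
        raise SynchronizationError("both streams must be non-empty")
    e0, e1 = float(ef["timestamp_s"].iloc[0]), float(ef["timestamp_s"].iloc[-1])
    t0, t1 = float(trials["timestamp_s"].iloc[0]), float(trials["timestamp_s"].iloc[-1])
    if e1 < t0 or t1 < e0:
        raise SynchronizationError(
            f"disjoint time ranges: eye [{e0}, {e1}] vs trials [{t0}, {t1}]"
        )
    origin = min(e0, t0)

    def _in_bounds(onsets: np.ndarray) -> np.ndarray:
        return (onsets >= 0) & (onsets < duration)

    streams = {}
    n_dropped = 0
    for kind, cols in [("fixation", 2), ("saccade", 3), ("blink", 2)]:
        sub = ef[ef["event_type"] == kind]
        onsets = sub["timestamp_s"].to_numpy(dtype=float) - origin
        data = [onsets, sub["duration_s"].to_numpy(dtype=float)]
        if cols == 3:
            data.append(sub["amplitude_deg"].to_numpy(dtype=float))
        arr = np.column_stack(data) if len(sub) else np.empty((0, cols))
        keep = _in_bounds(arr[:, 0]) if arr.size else np.empty(0, dtype=bool)
        n_dropped += int(arr.shape[0] - keep.sum()) if arr.size else 0
        streams[kind] = arr[keep] if arr.size else arr

    t_onsets = trials["timestamp_s"].to_numpy(dtype=float) - origin
    t_arr = np.column_stack(
        [t_onsets, trials["response_time_s"].to_numpy(float), trials["correct"].to_numpy(float)]
    )
    keep = _in_bounds(t_arr[:, 0])
    n_dropped += int(t_arr.shape[0] - keep.sum())
    t_arr = t_arr[keep]
    if n_dropped:
        log.info("synchronize(%s, %s): dropped %d out-of-session events", subject_id, level_id, n_dropped)

    return SessionRecording(
        subject_id=subject_id,
        level_id=level_id,
        duration=duration,
        fixations=streams["fixation"],
        saccades=streams["saccade"],
        blinks=streams["blink"],
        trials=t_arr,
        n_dropped=n_dropped,
    )


def trim_extremes(series) -> np.ndarray:
    """Remove exactly one minimal and one maximal value from a series.

    The first occurrence of each extreme is removed (ties leave the other
    tied values in place); the order of the remaining elements is preserved.
    """
    arr = np.asarray(series, dtype=float)
    if arr.ndim != 1:
        raise DataError("trim_extremes expects a 1-D series")
    if arr.size < 3:
        raise TooFewObservationsError(
            f"cannot trim a series of length {arr.size}; need at least 3"
        )
    i_min = int(np.argmin(arr))
    rest = np.delete(arr, i_min)
    i_max = int(np.argmax(rest))
    return np.delete(rest, i_max)


# ---------------------------------------------------------------------------
# JSON-lines session store
# ---------------------------------------------------------------------------

def save_sessions(recordings, path) -> None:
    """Serialize recordings as JSON lines (one session per line)."""
    with open(path, "w") as fh:
        for rec in recordings:
            obj = {
                "subject_id": rec.subject_id,
                "level_id": rec.level_id,
                "duration": rec.duration,
                "fixations": rec.fixations.tolist(),
                "saccades": rec.saccades.tolist(),
                "blinks": rec.blinks.tolist(),
                "trials": rec.trials.tolist(),
                "n_dropped": rec.n_dropped,
            }
            fh.write(json.dumps(obj) + "\n")


def load_sessions(path) -> list[SessionRecording]:
    """Load recordings from a JSON-lines session store."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            obj = json.loads(line)
            out.append(
                SessionRecording(
                    subject_id=obj["subject_id"],
                    level_id=obj["level_id"],
                    duration=obj["duration"],
                    fixations=np.asarray(obj["fixations"], float).reshape(-1, 2),
                    saccades=np.asarray(obj["saccades"], float).reshape(-1, 3),
                    blinks=np.asarray(obj["blinks"], float).reshape(-1, 2),
                    trials=np.asarray(obj["trials"], float).reshape(-1, 3),
                    n_dropped=int(obj.get("n_dropped", 0)),
                )
            )
    return out
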