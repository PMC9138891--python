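"""Session-level container shared by the generator, the IO layer and features."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError

__all__ = ["SessionRecording", "LEVELS"]

#: Workload level labels in task order (part 1, 2, 3).
LEVELS = ("low", "medium", "high")


def _as_2d(a, ncols: int) -> np.ndarray:
    arr = np.asarray(a, dtype=float)
    if arr.size == 0:
        return arr.reshape(0, ncols)
    if arr.ndim != 2 or arr.shape[1] != ncols:
        raise DataError(f"expected an (n, {ncols}) array, got shape {arr.shape}")
    return arr


@dataclass(eq=False)
class SessionRecording:
    """One subject x one workload level, with streams on a session-relative clock.

    Streams are float arrays: ``fixations`` (onset, duration), ``saccades``
    (onset, duration, amplitude in degrees), ``blinks`` (onset, duration),
    ``trials`` (onset, response_time, correct in {0, 1}).  All onsets live in
    the half-open interval [0, duration); onsets are non-decreasing within a
    stream.
    """

    subject_id: str
    level_id: str
    duration: float
    fixations: np.ndarray
    saccades: np.ndarray
    blinks: np.ndarray
    trials: np.ndarray
    n_dropped: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.fixations = _as_2d(self.fixations, 2)
        self.saccades = _as_2d(self.saccades, 3)
        self.blinks = _as_2d(self.blinks, 2)
        self.trials = _as_2d(self.trials, 3)
        self.validate()

    def validate(self) -> None:
        if self.duration <= 0:
            raise DataError(f"duration must be > 0, got {self.duration}")
        for name in ("fixations", "saccades", "blinks", "trials"):
            arr = getattr(self, name)
            if arr.size == 0:
                continue
            onsets = arr[:, 0]
            if np.any(onsets < 0) or np.any(onsets >= self.duration):
                raise DataError(f"{name}: onsets must lie in [0, {self.duration})")
            if np.any(np.diff(onsets) < 0):
                raise DataError(f"{name}: onsets must be non-decreasing")
            if np.any(arr[:, 1] <= 0):
                raise DataError(f"{name}: durations must be > 0")
        if self.trials.size and not np.all(np.isin(self.trials[:, 2], (0.0, 1.0))):
            raise DataError("trials: correct flag must be 0 or 1")

    def equals(self, other: "SessionRecording", atol: float = 0.0) -> bool:
        if (self.subject_id, self.level_id) != (other.subject_id, other.level_id):
            return False
        if self.duration != other.duration:
            return False
        for name in ("fixations", "saccades", "blinks", "trials"):
            a, b = getattr(self, name), getattr(other, name)
            if a.shape != b.shape:
                return False
            if a.size and not np.allclose(a, b, rtol=0.0, atol=atol):
                return False
        return True
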