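"""Synthetic cohort generator.

Stands in for the unavailable laboratory recordings: for each subject and
each of three workload levels (task parts of 90 s / 4 symbols, 90 s / 9
symbols, 180 s / 9 symbols) it generates a digit-symbol-substitution trial
log and an oculomotor event stream with the distributional structure the
analysis assumes — positively skewed ex-Gaussian measures whose parameters
shift with workload level, plus multiplicative subject-level random effects.

Event model: fixations and saccades alternate as a renewal sequence with
independent ex-Gaussian durations; blinks are an independent Poisson process
whose events pause the fixation/saccade stream.  Trials are packed
sequentially (onset = previous onset + response time + a fixed inter-trial
gap).  All timestamps are quantised to the recording resolution (1/300 s,
i.e. a 300 Hz clock).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import DataError, ParameterError
from .exgauss import ExGaussParams
from .records import LEVELS, SessionRecording

__all__ = [
    "LevelSpec",
    "CohortConfig",
    "generate_session",
    "generate_cohort",
    "null_cohort",
    "write_eye_export",
    "write_trial_log",
    "default_workload_config",
    "null_config",
    "strongly_separated_config",
    "dominant_feature_config",
    "EFFECT_MEASURES",
]

#: Measures that receive a per-subject multiplicative random effect on mu and tau.
EFFECT_MEASURES = ("response_time", "fixation_duration", "saccade_duration", "saccade_amplitude")

_EYE_HEADER = "timestamp_s\tevent_type\tduration_s\tamplitude_deg"
_TRIAL_HEADER = "timestamp_s\tresponse_time_s\tcorrect"


@dataclass(frozen=True)
class LevelSpec:
    """Generative description of one workload level (one task part)."""

    level_id: str
    duration: float
    n_symbols: int
    response_time: ExGaussParams
    fixation_duration: ExGaussParams
    saccade_duration: ExGaussParams
    saccade_amplitude: ExGaussParams
    blink_rate: float
    p_correct: float
    blink_duration: ExGaussParams = ExGaussParams(0.15, 0.03, 0.10)
    inter_trial_gap: float = 0.2
    #: sd of the log of the slow multiplicative drift applied to temporal
    #: measures per 10-s block — time-on-task fluctuation in processing
    #: efficiency.  It gives windowed counts realistic overdispersion;
    #: without it a renewal stream's counts are nearly deterministic and
    #: small-integer count series collapse to a single repeated value.
    temporal_drift_sd: float = 0.15
    #: sd of the per-block logit-normal fluctuation of the correct-answer
    #: probability — error bursts, the accuracy counterpart of the drift.
    accuracy_drift_sd: float = 1.0
    #: sd of the log of the per-block drift of manual response tempo; the
    #: trial stream fluctuates more strongly than oculomotor micro-dynamics.
    tempo_drift_sd: float = 0.30

    def __post_init__(self):
        if self.level_id not in LEVELS:
            raise ParameterError(f"level_id must be one of {LEVELS}, got {self.level_id!r}")
        if self.duration <= 0:
            raise ParameterError("duration must be > 0")
        if not (0 < self.p_correct <= 1):
            raise ParameterError("p_correct must be in (0, 1]")
        if self.blink_rate <= 0:
            raise ParameterError("blink_rate must be > 0")
        if self.inter_trial_gap < 0:
            raise ParameterError("inter_trial_gap must be >= 0")
        if self.temporal_drift_sd < 0:
            raise ParameterError("temporal_drift_sd must be >= 0")
        if self.accuracy_drift_sd < 0:
            raise ParameterError("accuracy_drift_sd must be >= 0")
        if self.tempo_drift_sd < 0:
            raise ParameterError("tempo_drift_sd must be >= 0")

    @property
    def implied_fixation_rate(self) -> float:
        """Fixations per second implied by the alternating renewal stream."""
        cycle = self.fixation_duration.mean + self.saccade_duration.mean
        return 1.0 / cycle


@dataclass(frozen=True)
class CohortConfig:
    """A cohort: n_subjects x the three level specs, with seeding rules.

    Child seeds are spawned deterministically from ``master_seed``:
    subject ``i``'s random-effect stream uses ``SeedSequence([master_seed, i])``
    and the session for subject ``i`` at level index ``j`` uses
    ``SeedSequence([master_seed, i, j])``, so any single session is
    individually reproducible.
    """

    level_specs: tuple[LevelSpec, LevelSpec, LevelSpec]
    n_subjects: int = 30
    subject_effect_sd: float = 0.08
    timestamp_resolution: float = 1.0 / 300.0
    master_seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ParameterError("n_subjects must be >= 2")
        if len(self.level_specs) != 3:
            raise ParameterError("exactly three level specs are required")
        if self.subject_effect_sd < 0:
            raise ParameterError("subject_effect_sd must be >= 0")
        if self.timestamp_resolution <= 0:
            raise ParameterError("timestamp_resolution must be > 0")


def _quantise(values: np.ndarray, resolution: float) -> np.ndarray:
    # Snap to the clock grid, then to 6 printed decimals so that a value
    # round-trips exactly through the TSV dialect.
    return np.round(np.round(np.asarray(values, dtype=float) / resolution) * resolution, 6)


def _scaled(p: ExGaussParams, factor: float) -> ExGaussParams:
    return ExGaussParams(p.mu * factor, p.sigma, p.tau * factor)


def _draw_positive(rng: np.random.Generator, p: ExGaussParams, floor: float) -> float:
    return max(float(rng.normal(p.mu, p.sigma) + rng.exponential(p.tau)), floor)


def generate_session(
    subject_id: str,
    level_spec: LevelSpec,
    subject_effects: dict[str, float] | None,
    seed,
    timestamp_resolution: float = 1.0 / 300.0,
) -> SessionRecording:
    """Generate one session (one subject at one workload level).

    ``subject_effects`` maps measure names (:data:`EFFECT_MEASURES`) to a
    multiplicative factor applied to that measure's mu and tau; missing keys
    default to 1.0.
    """
    rng = np.random.default_rng(seed)
    eff = dict.fromkeys(EFFECT_MEASURES, 1.0)
    if subject_effects:
        eff.update(subject_effects)
    res = timestamp_resolution
    duration = level_spec.duration

    rt_params = _scaled(level_spec.response_time, eff["response_time"])
    if duration < rt_params.mean:
        raise DataError(
            f"duration {duration} s too short for a single trial (mean RT {rt_params.mean:.3f} s)"
        )

    # --- slow temporal drift: one lognormal factor per 10-s block ----------
    n_blocks = int(math.ceil(duration / 10.0))
    drift = np.exp(rng.normal(0.0, level_spec.temporal_drift_sd, n_blocks))
    tempo = np.exp(rng.normal(0.0, level_spec.tempo_drift_sd, n_blocks))
    if level_spec.p_correct < 1.0 and level_spec.accuracy_drift_sd > 0:
        logit = math.log(level_spec.p_correct / (1.0 - level_spec.p_correct))
        shifts = rng.normal(0.0, level_spec.accuracy_drift_sd, n_blocks)
        p_block = 1.0 / (1.0 + np.exp(-(logit + shifts)))
    else:
        p_block = np.full(n_blocks, level_spec.p_correct)

    def _block(t: float) -> int:
        return min(int(t // 10.0), n_blocks - 1)

    def _drift(t: float) -> float:
        return float(drift[_block(t)])

    # --- trials: sequential packing ----------------------------------------
    onsets, rts, correct = [], [], []
    t = 0.0
    while t < duration:
        rt = _draw_positive(rng, _scaled(rt_params, float(tempo[_block(t)])), res)
        onsets.append(t)
        rts.append(rt)
        correct.append(1.0 if rng.random() < p_block[_block(t)] else 0.0)
        t += rt + level_spec.inter_trial_gap
    trials = np.column_stack([onsets, rts, correct])

    # --- blinks: Poisson process with drift-scaled gaps ---------------------
    blink_onsets = []
    t = float(rng.exponential(1.0 / level_spec.blink_rate))
    while t < duration:
        blink_onsets.append(t)
        t += float(rng.exponential(1.0 / level_spec.blink_rate)) * _drift(t)
    blink_durs = [_draw_positive(rng, level_spec.blink_duration, res) for _ in blink_onsets]
    blinks = (
        np.column_stack([blink_onsets, blink_durs]) if blink_onsets else np.empty((0, 2))
    )

    # --- fixation/saccade alternating renewal stream ------------------------
    fix_params = _scaled(level_spec.fixation_duration, eff["fixation_duration"])
    sac_params = _scaled(level_spec.saccade_duration, eff["saccade_duration"])
    amp_params = _scaled(level_spec.saccade_amplitude, eff["saccade_amplitude"])
    fixations, saccades = [], []
    blink_iv = [(b, b + d) for b, d in zip(blink_onsets, blink_durs)]
    bi = 0
    t = 0.0
    is_fixation = True
    while t < duration:
        # a blink in progress pauses the stream
        while bi < len(blink_iv) and blink_iv[bi][1] <= t:
            bi += 1
        if bi < len(blink_iv) and blink_iv[bi][0] <= t < blink_iv[bi][1]:
            t = blink_iv[bi][0] + (blink_iv[bi][1] - blink_iv[bi][0])
            continue
        if is_fixation:
            dur = _draw_positive(rng, _scaled(fix_params, _drift(t)), res)
            fixations.append((t, dur))
        else:
            dur = _draw_positive(rng, _scaled(sac_params, _drift(t)), res)
            amp = _draw_positive(rng, amp_params, 0.01)
            saccades.append((t, dur, amp))
        t += dur
        is_fixation = not is_fixation

    fixations = np.asarray(fixations) if fixations else np.empty((0, 2))
    saccades = np.asarray(saccades) if saccades else np.empty((0, 3))

    def _finish(arr: np.ndarray, n_time_cols: int) -> np.ndarray:
        if arr.size == 0:
            return arr
        out = arr.copy()
        out[:, :n_time_cols] = _quantise(out[:, :n_time_cols], res)
        out[:, 1] = np.maximum(out[:, 1], res)  # durations stay positive on the grid
        if out.shape[1] == 3 and n_time_cols == 2:  # saccade amplitude, printed at 6 dp
            out[:, 2] = np.round(out[:, 2], 6)
        return out[out[:, 0] < duration]

    return SessionRecording(
        subject_id=subject_id,
        level_id=level_spec.level_id,
        duration=duration,
        fixations=_finish(fixations, 2),
        saccades=_finish(saccades, 2),
        blinks=_finish(blinks, 2),
        trials=_finish(trials, 2),
        meta={"inter_trial_gap": level_spec.inter_trial_gap},
    )


def _subject_effects(config: CohortConfig, subject_index: int) -> dict[str, float]:
    rng = np.random.default_rng(np.random.SeedSequence([config.master_seed, subject_index]))
    return {
        m: float(math.exp(rng.normal(0.0, config.subject_effect_sd))) for m in EFFECT_MEASURES
    }


def generate_cohort(config: CohortConfig) -> list[SessionRecording]:
    """Generate ``n_subjects x 3`` sessions with consistent per-subject effects."""
    sessions = []
    for i in range(config.n_subjects):
        sid = f"S{i + 1:02d}"
        effects = _subject_effects(config, i)
        for j, spec in enumerate(config.level_specs):
            seed = np.random.SeedSequence([config.master_seed, i, j])
            try:
                sessions.append(
                    generate_session(sid, spec, effects, seed, config.timestamp_resolution)
                )
            except Exception as exc:  # re-raise with subject/level context
                raise type(exc)(f"subject {sid}, level {spec.level_id}: {exc}") from exc
    return sessions


def null_cohort(config: CohortConfig) -> list[SessionRecording]:
    """A cohort in which all three levels share the first level's generative
    parameters (labels keep their identity) — no class signal by construction."""
    base = config.level_specs[0]
    specs = tuple(
        replace(base, level_id=s.level_id, duration=s.duration, n_symbols=s.n_symbols)
        for s in config.level_specs
    )
    return generate_cohort(replace(config, level_specs=specs))


# ---------------------------------------------------------------------------
# TSV dialects (Tobii-Studio-style event export; DSST trial log)
# ---------------------------------------------------------------------------

def write_eye_export(recording: SessionRecording, path) -> None:
    """Write the eye-event TSV: one row per fixation/saccade/blink, by onset."""
    rows = []
    for onset, dur in recording.fixations:
        rows.append((onset, "fixation", dur, ""))
    for onset, dur, amp in recording.saccades:
        rows.append((onset, "saccade", dur, f"{amp:.6f}"))
    for onset, dur in recording.blinks:
        rows.append((onset, "blink", dur, ""))
    rows.sort(key=lambda r: (r[0], r[1]))
    with open(path, "w") as fh:
        fh.write(_EYE_HEADER + "\n")
        for onset, kind, dur, amp in rows:
            fh.write(f"{onset:.6f}\t{kind}\t{dur:.6f}\t{amp}\n")


def write_trial_log(recording: SessionRecording, path) -> None:
    """Write the DSST trial-log TSV: one row per trial, by onset."""
    with open(path, "w") as fh:
        fh.write(_TRIAL_HEADER + "\n")
        for onset, rt, corr in recording.trials:
            fh.write(f"{onset:.6f}\t{rt:.6f}\t{int(corr)}\n")


# ---------------------------------------------------------------------------
# Stock configurations
# ---------------------------------------------------------------------------

def _specs(rt, fix, sac, amp, blink, pc, durations=(90.0, 90.0, 180.0)) -> tuple[LevelSpec, ...]:
    n_symbols = (4, 9, 9)
    return tuple(
        LevelSpec(
            level_id=LEVELS[k],
            duration=durations[k],
            n_symbols=n_symbols[k],
            response_time=ExGaussParams(*rt[k]),
            fixation_duration=ExGaussParams(*fix[k]),
            saccade_duration=ExGaussParams(*sac[k]),
            saccade_amplitude=ExGaussParams(*amp[k]),
            blink_rate=blink[k],
            p_correct=pc[k],
        )
        for k in range(3)
    )


def default_workload_config(master_seed: int = 0, n_subjects: int = 30) -> CohortConfig:
    """The study-condition default: three parts of increasing workload.

    Response-time mu and tau grow ~25-30% per level, the correct-answer rate
    drops, and the tau of saccade measures grows — so the skewness of each
    temporal measure increases with workload while sigma stays put.  Units:
    seconds (times), degrees (amplitude), events/s (blink rate).
    """
    return CohortConfig(
        level_specs=_specs(
            rt=[(1.10, 0.15, 0.30), (1.40, 0.17, 0.45), (1.70, 0.19, 0.65)],
            fix=[(0.20, 0.040, 0.100), (0.22, 0.045, 0.130), (0.24, 0.050, 0.165)],
            sac=[(0.030, 0.006, 0.008), (0.032, 0.006, 0.014), (0.034, 0.006, 0.022)],
            amp=[(3.5, 0.8, 1.5), (3.3, 0.8, 1.9), (3.1, 0.8, 2.4)],
            blink=[0.5, 0.5, 0.5],
            pc=[0.95, 0.88, 0.80],
        ),
        n_subjects=n_subjects,
        master_seed=master_seed,
    )


def null_config(master_seed: int = 0, n_subjects: int = 30) -> CohortConfig:
    """All levels share one generative parameter set and equal 90-s durations.

    Equal durations keep windowed-count features at identical sample sizes
    across levels, so no estimator-variance artifact can stand in for a
    class signal.
    """
    rt = [(1.40, 0.17, 0.45)] * 3
    fix = [(0.22, 0.045, 0.130)] * 3
    sac = [(0.032, 0.006, 0.016)] * 3
    amp = [(3.3, 0.8, 1.9)] * 3
    return CohortConfig(
        level_specs=_specs(rt, fix, sac, amp, [0.5] * 3, [0.88] * 3, durations=(90.0,) * 3),
        n_subjects=n_subjects,
        master_seed=master_seed,
    )


def strongly_separated_config(master_seed: int = 0, n_subjects: int = 30) -> CohortConfig:
    """Very large, nearly non-overlapping level effects on several measures."""
    return CohortConfig(
        level_specs=_specs(
            rt=[(1.00, 0.12, 0.20), (1.50, 0.15, 0.50), (2.50, 0.20, 0.90)],
            fix=[(0.18, 0.035, 0.080), (0.24, 0.045, 0.150), (0.32, 0.055, 0.240)],
            sac=[(0.028, 0.005, 0.010), (0.033, 0.006, 0.018), (0.040, 0.007, 0.030)],
            amp=[(2.0, 0.5, 0.8), (4.0, 0.7, 1.8), (6.0, 0.9, 3.2)],
            blink=[0.5, 0.5, 0.5],
            pc=[0.98, 0.85, 0.65],
        ),
        n_subjects=n_subjects,
        master_seed=master_seed,
    )


def dominant_feature_config(master_seed: int = 0, n_subjects: int = 30) -> CohortConfig:
    """One dominant feature (tau of response time), everything else null.

    The response-time tau is spaced asymmetrically across levels
    (0.2 / 0.45 / 1.4 s) so that each one-vs-rest linear problem can use it:
    with symmetric spacing the middle class would be linearly invisible to
    the feature.  Fixation duration and saccade amplitude carry mild effects
    (a moderate-importance tier), while blink and saccade-duration features
    remain pure noise (identical generators at all levels), useful as a
    negative control in importance analyses.
    """
    return CohortConfig(
        level_specs=_specs(
            rt=[(1.20, 0.15, 0.20), (1.20, 0.15, 0.45), (1.20, 0.15, 1.40)],
            fix=[(0.21, 0.045, 0.115), (0.22, 0.045, 0.130), (0.235, 0.045, 0.150)],
            sac=[(0.032, 0.006, 0.014)] * 3,
            amp=[(3.20, 0.8, 1.80), (3.30, 0.8, 1.90), (3.45, 0.8, 2.05)],
            blink=[0.5] * 3,
            pc=[0.90] * 3,
        ),
        n_subjects=n_subjects,
        master_seed=master_seed,
    )
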