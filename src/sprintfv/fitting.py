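"""Radar trace handling: onset/end trimming and mono-exponential fitting.

The radar gun samples instantaneous velocity at a nominal 36.6 Hz while the
athlete sprints past a fixed distance (20 m in the reference protocol).  Raw
traces contain a pre-start segment (athlete standing, near-zero velocity) and
a post-finish segment; both are removed before fitting.  The model fitted is

    v(t) = MSS * (1 - exp(-(t - time_shift) / tau)),   v = 0 for t <= shift

where the free ``time_shift`` absorbs residual onset-detection error.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import (
    FitFailureError,
    InsufficientDataError,
    InsufficientTrialsError,
    InvalidInputError,
    NoMovementError,
)
from .model import SprintModelFit

__all__ = [
    "RadarTrace",
    "TrimReport",
    "trim_trace",
    "fit_sprint_model",
    "aggregate_trials",
    "DEFAULT_ONSET_THRESHOLD",
    "DEFAULT_ONSET_SUSTAIN",
    "MIN_SAMPLES",
]

DEFAULT_ONSET_THRESHOLD = 0.3  # m/s
DEFAULT_ONSET_SUSTAIN = 3  # consecutive samples
MIN_SAMPLES = 30


@dataclass(frozen=True)
class RadarTrace:
    """One radar velocity-time recording of a single sprint trial."""

    time: np.ndarray  # s
    velocity: np.ndarray  # m/s
    nominal_rate: float = 36.6  # Hz
    athlete_id: str | None = None
    session: str | None = None  # "pre" | "post"
    trial_index: int | None = None  # 1..3
    sprint_distance: float = 20.0  # m

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        v = np.asarray(self.velocity, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "velocity", v)
        if t.shape != v.shape or t.ndim != 1:
            raise InvalidInputError("time and velocity must be 1-D arrays of equal length")
        if t.size and np.any(np.diff(t) <= 0):
            raise InvalidInputError("sample times must be strictly increasing")
        if not np.all(np.isfinite(v)):
            raise InvalidInputError("velocities must be finite")

    def __len__(self) -> int:
        return int(self.time.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.time, "velocity_ms": self.velocity})


@dataclass(frozen=True)
class TrimReport:
    """What trimming removed from a raw trace."""

    n_leading_removed: int
    n_trailing_removed: int
    onset_time: float  # s, on the raw trace clock

    def __post_init__(self):
        if self.n_leading_removed < 0 or self.n_trailing_removed < 0:
            raise InvalidInputError("removal counts must be non-negative")


def trim_trace(
    trace: RadarTrace,
    onset_threshold: float = DEFAULT_ONSET_THRESHOLD,
    sustain: int = DEFAULT_ONSET_SUSTAIN,
) -> tuple[RadarTrace, TrimReport]:
    """Remove pre-onset and post-finish samples; re-zero time at onset.

    Onset is the first sample opening a run of ``sustain`` consecutive
    samples above ``onset_threshold``.  The trailing cut keeps samples up to
    the point where the trapezoid-integrated distance first reaches the
    trace's sprint distance.
    """
    if len(trace) == 0:
        raise InvalidInputError("empty trace")
    v = trace.velocity
    above = v > onset_threshold
    onset_idx = None
    run = 0
    for i, flag in enumerate(above):
        run = run + 1 if flag else 0
        if run == sustain:
            onset_idx = i - sustain + 1
            break
    if onset_idx is None:
        raise NoMovementError("no movement onset found (no sustained run above threshold)")

    t = trace.time[onset_idx:] - trace.time[onset_idx]
    vv = v[onset_idx:]
    # integrated distance from onset; keep through the first crossing
    dist = np.concatenate([[0.0], np.cumsum(np.diff(t) * (vv[1:] + vv[:-1]) / 2.0)])
    beyond = np.nonzero(dist >= trace.sprint_distance)[0]
    end = int(beyond[0]) + 1 if beyond.size else len(vv)
    n_trailing = len(vv) - end

    trimmed = replace(trace, time=t[:end], velocity=vv[:end])
    if len(trimmed) < MIN_SAMPLES:
        raise InsufficientDataError(
            f"only {len(trimmed)} samples remain after trimming (< {MIN_SAMPLES})"
        )
    return trimmed, TrimReport(onset_idx, n_trailing, float(trace.time[onset_idx]))


def _model_velocity(params: np.ndarray, t: np.ndarray) -> np.ndarray:
    mss, tau, shift = params
    out = mss * (1.0 - np.exp(-(t - shift) / tau))
    return np.where(t > shift, out, 0.0)


def fit_sprint_model(trace: RadarTrace, max_iter: int = 200) -> SprintModelFit:
    """Estimate (MSS, tau, time_shift) by bounded nonlinear least squares.

    Initialisation: MSS0 = max observed velocity, tau0 = time to first reach
    0.632*MSS0, shift0 = 0.  Bounded trust-region reflective solver; the
    time shift is constrained to [-0.5, 0.5] s.
    """
    t = trace.time
    v = trace.velocity
    if t.size < MIN_SAMPLES:
        raise InsufficientDataError(f"need at least {MIN_SAMPLES} samples, got {t.size}")
    vmax = float(v.max())
    if vmax <= 0:
        raise NoMovementError("trace has no positive velocity")
    reach = np.nonzero(v >= 0.632 * vmax)[0]
    tau0 = float(np.clip(t[reach[0]] if reach.size else 1.0, 0.1, 5.0))
    x0 = np.array([vmax, tau0, 0.0])
    lb = np.array([0.5 * vmax, 0.01, -0.5])
    ub = np.array([3.0 * vmax, 10.0, 0.5])
    x0 = np.clip(x0, lb, ub)

    res = least_squares(
        lambda p: _model_velocity(p, t) - v,
        x0,
        bounds=(lb, ub),
        method="trf",
        ftol=1e-12,
        xtol=1e-12,
        gtol=1e-12,
        max_nfev=max_iter * 10,
    )
    if not res.success:
        raise FitFailureError(
            "sprint model fit did not converge",
            diagnostics={"status": res.status, "message": res.message, "cost": res.cost,
                         "nfev": res.nfev, "x": res.x.tolist()},
        )
    mss, tau, shift = res.x
    rmse = float(np.sqrt(np.mean(res.fun**2)))
    return SprintModelFit(mss=float(mss), tau=float(tau), time_shift=float(shift),
                          rmse=rmse, n_samples=int(t.size))


def aggregate_trials(trials: Sequence[Mapping[str, float]] | pd.DataFrame) -> dict[str, float]:
    """Arithmetic mean of each derived variable across an athlete-session's trials.

    Trials are averaged at the derived-variable level (not the trace level):
    each trial contributes its own fitted profile and split times, and the
    per-variable means feed the statistical layer.
    """
    if isinstance(trials, pd.DataFrame):
        frame = trials
    else:
        frame = pd.DataFrame(list(trials))
    if len(frame) < 2:
        raise InsufficientTrialsError(f"need >= 2 trials to aggregate, got {len(frame)}")
    return frame.mean(axis=0).to_dict()
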