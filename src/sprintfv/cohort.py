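"""Synthetic study generator.

Builds a full two-group pre-post sprint study with the structure of the
reference design: 22 junior athletes (14 combined-sprint-training CST,
8 maximal-sprint-training MST), three 20 m radar-recorded sprint trials per
session, two sessions.  Each athlete carries a latent ground-truth
force-velocity profile (relative F0 in N/kg and v0 in m/s); a training
intervention is emulated as per-athlete multiplicative percent changes drawn
per group.  Radar traces are synthesised either by sampling the
mono-exponential velocity curve exactly (``mono_exp``) or by integrating the
linear force-velocity law with aerodynamic drag,
m dv/dt = F0 (1 - v/v0) - k v^2 (``linear_fv_ode``), then adding Gaussian
measurement noise at the nominal radar rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigError, InvalidInputError
from .model import (
    Athlete,
    EnvironmentConditions,
    SprintModelFit,
    drag_model,
    predict_velocity,
    split_time,
)
from .fitting import RadarTrace

__all__ = [
    "GroupEffect",
    "CohortConfig",
    "GroundTruthProfile",
    "SyntheticAthlete",
    "generate_cohort",
    "allocate_groups",
    "apply_intervention",
    "simulate_trace",
    "simulate_study",
]


@dataclass(frozen=True)
class GroupEffect:
    """Intervention effect for one group: mean and SD of percent change."""

    f0_rel_pct: tuple[float, float] = (0.0, 0.0)
    v0_pct: tuple[float, float] = (0.0, 0.0)


@dataclass(frozen=True)
class GroundTruthProfile:
    """Latent mechanical profile of one athlete (relative units).

    In ``mono_exp`` mode the drag-free correspondence maps it onto the
    velocity model: MSS = v0 and tau = v0 / F0_rel (F0_rel in N/kg is an
    acceleration, so v0/F0_rel has units of time).
    """

    f0_rel: float  # N/kg
    v0: float  # m/s

    def __post_init__(self):
        if self.f0_rel <= 0 or self.v0 <= 0:
            raise InvalidInputError("F0_rel and v0 must be positive")

    @property
    def mss(self) -> float:
        return self.v0

    @property
    def tau(self) -> float:
        return self.v0 / self.f0_rel


@dataclass(frozen=True)
class SyntheticAthlete:
    athlete: Athlete
    group: str
    pre: GroundTruthProfile
    post: GroundTruthProfile | None = None


@dataclass(frozen=True)
class CohortConfig:
    """Study-design parameters of the emulated cohort.

    Defaults reproduce the reference study: 22 athletes split 14 (CST) / 8
    (MST); anthropometrics Normal(58.5, 10.0) kg and Normal(1.74, 0.08) m;
    group-specific pre-test profile distributions and intervention percent
    changes taken from the study's summary table; trial-to-trial coefficient
    of variation 1.5% applied multiplicatively to MSS and tau; radar noise
    SD 0.05 m/s at 36.6 Hz over 20 m.
    """

    n_total: int = 22
    group_sizes: dict[str, int] = field(default_factory=lambda: {"CST": 14, "MST": 8})
    body_mass: tuple[float, float] = (58.5, 10.0)  # kg
    stature: tuple[float, float] = (1.74, 0.08)  # m
    pre_f0_rel: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"CST": (5.18, 0.49), "MST": (5.10, 0.51)}
    )
    pre_v0: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"CST": (8.31, 0.83), "MST": (7.80, 0.43)}
    )
    effects: dict[str, GroupEffect] = field(
        default_factory=lambda: {
            "CST": GroupEffect(f0_rel_pct=(11.19, 12.52), v0_pct=(-0.25, 6.08)),
            "MST": GroupEffect(f0_rel_pct=(-0.40, 8.47), v0_pct=(2.60, 2.87)),
        }
    )
    fv_correlation: float = 0.0  # between-athlete corr of F0_rel and v0
    trial_cv_percent: float = 1.5
    noise_sd: float = 0.05  # m/s
    sampling_rate: float = 36.6  # Hz
    sprint_distance: float = 20.0  # m
    n_trials: int = 3
    # physical truncation bounds for the latent draws
    min_mass: float = 30.0
    min_stature: float = 1.4
    min_f0_rel: float = 2.0
    min_v0: float = 5.0

    def __post_init__(self):
        if sum(self.group_sizes.values()) != self.n_total:
            raise ConfigError("group sizes must sum to n_total")
        for mean, sd, lo, what in (
            (self.body_mass[0], self.body_mass[1], self.min_mass, "body mass"),
            (self.stature[0], self.stature[1], self.min_stature, "stature"),
        ):
            if sd < 0:
                raise ConfigError(f"{what} SD must be non-negative")
            if mean < lo:
                raise ConfigError(f"{what} mean {mean} below truncation bound {lo}")
        for grp, (mean, sd) in self.pre_f0_rel.items():
            if mean < self.min_f0_rel or sd < 0:
                raise ConfigError(f"F0_rel config invalid for group {grp}")
        for grp, (mean, sd) in self.pre_v0.items():
            if mean < self.min_v0 or sd < 0:
                raise ConfigError(f"v0 config invalid for group {grp}")
        if not -1 < self.fv_correlation < 1:
            raise ConfigError("fv_correlation must be in (-1, 1)")


def _truncated_normal(rng, mean, sd, lower, size):
    """Draw Normal(mean, sd) truncated below `lower` by resampling."""
    if sd == 0:
        if mean <= lower:
            raise ConfigError(f"degenerate draw at {mean} below bound {lower}")
        return np.full(size, float(mean))
    out = rng.normal(mean, sd, size)
    for _ in range(1000):
        bad = out <= lower
        if not bad.any():
            return out
        out[bad] = rng.normal(mean, sd, bad.sum())
    raise ConfigError(f"truncation at {lower} rejects nearly all draws from N({mean},{sd})")


def generate_cohort(config: CohortConfig, seed: int | np.random.Generator) -> list[SyntheticAthlete]:
    """Draw athletes with anthropometrics and pre-session ground-truth profiles.

    Deterministic for a fixed seed.  Group membership follows the configured
    group sizes; pre-profile distributions are group-specific.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    athletes: list[SyntheticAthlete] = []
    idx = 0
    for grp, n in config.group_sizes.items():
        mass = _truncated_normal(rng, *config.body_mass, config.min_mass, n)
        stat = _truncated_normal(rng, *config.stature, config.min_stature, n)
        f0m, f0s = config.pre_f0_rel[grp]
        v0m, v0s = config.pre_v0[grp]
        z = rng.standard_normal((n, 2))
        r = config.fv_correlation
        z2 = r * z[:, 0] + np.sqrt(1 - r**2) * z[:, 1]
        f0 = f0m + f0s * z[:, 0]
        v0 = v0m + v0s * z2
        # truncate to physical range by per-athlete resampling
        for i in range(n):
            tries = 0
            while f0[i] <= config.min_f0_rel or v0[i] <= config.min_v0:
                zz = rng.standard_normal(2)
                f0[i] = f0m + f0s * zz[0]
                v0[i] = v0m + v0s * (r * zz[0] + np.sqrt(1 - r**2) * zz[1])
                tries += 1
                if tries > 1000:
                    raise ConfigError("profile truncation rejects nearly all draws")
        stat_clip = np.clip(stat, config.min_stature, 2.49)
        for i in range(n):
            idx += 1
            athletes.append(
                SyntheticAthlete(
                    athlete=Athlete(f"ath{idx:02d}", float(mass[i]), float(stat_clip[i])),
                    group=grp,
                    pre=GroundTruthProfile(float(f0[i]), float(v0[i])),
                )
            )
    return athletes


def allocate_groups(
    pre_test_times,
    sizes: tuple[int, int] = (14, 8),
    labels: tuple[str, str] = ("CST", "MST"),
    seed: int | np.random.Generator = 0,
) -> list[str]:
    """Rank-and-pair group allocation from pre-test 20 m times.

    Athletes are ranked ascending by time (1 = fastest) and adjacent pairs
    formed: (1,2), (3,4), ...  Within each split pair one member goes to
    each group by a seeded coin flip.  When target sizes are unequal, the
    surplus pairs assign both members to the larger group; surplus pairs are
    spread evenly across the ranking so group means stay balanced.
    """
    times = np.asarray(pre_test_times, dtype=float)
    n = times.size
    if n < 2:
        raise InvalidInputError("need at least 2 athletes to allocate")
    if sum(sizes) != n:
        raise InvalidInputError(f"group sizes {sizes} do not sum to {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    order = np.argsort(times, kind="stable")
    pairs = [order[i : i + 2] for i in range(0, n - n % 2, 2)]
    leftover = order[n - n % 2 :]

    large = 0 if sizes[0] >= sizes[1] else 1
    small = 1 - large
    n_surplus = (sizes[large] - sizes[small]) // 2
    surplus_idx = set(
        np.round(np.linspace(0, len(pairs) - 1, n_surplus)).astype(int).tolist()
    ) if n_surplus else set()

    groups = [""] * n
    for i, pair in enumerate(pairs):
        if i in surplus_idx:
            for a in pair:
                groups[a] = labels[large]
        else:
            flip = rng.integers(2)
            groups[pair[0]] = labels[small] if flip else labels[large]
            groups[pair[1]] = labels[large] if flip else labels[small]
    for a in leftover:  # odd athlete joins whichever group is short
        counts = [groups.count(l) for l in labels]
        short = int(np.argmin([counts[i] - sizes[i] for i in range(2)]))
        groups[a] = labels[short]
    return groups


def apply_intervention(
    cohort: list[SyntheticAthlete],
    effects: dict[str, GroupEffect],
    seed: int | np.random.Generator,
) -> list[SyntheticAthlete]:
    """Draw per-athlete multiplicative percent changes and attach post profiles.

    For each athlete, F0_rel and v0 change by independent draws from
    Normal(mean %, SD %) for the athlete's group; draws that would make a
    profile variable non-positive are resampled (truncation).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = []
    for sa in cohort:
        eff = effects[sa.group]
        for _ in range(1000):
            df0 = rng.normal(*eff.f0_rel_pct) if eff.f0_rel_pct[1] else eff.f0_rel_pct[0]
            dv0 = rng.normal(*eff.v0_pct) if eff.v0_pct[1] else eff.v0_pct[0]
            f0 = sa.pre.f0_rel * (1 + df0 / 100.0)
            v0 = sa.pre.v0 * (1 + dv0 / 100.0)
            if f0 > 0 and v0 > 0:
                break
        else:
            raise ConfigError("intervention effects keep producing non-positive profiles")
        out.append(replace(sa, post=GroundTruthProfile(f0, v0)))
    return out


def _ode_velocity(profile: GroundTruthProfile, mass: float, k_aero: float, t_end: float,
                  dt: float = 1e-3):
    """Integrate m dv/dt = F0 (1 - v/v0) - k v^2 with fixed-step RK4."""
    f0 = profile.f0_rel * mass

    def dv(v):
        return (f0 * (1.0 - v / profile.v0) - k_aero * v * v) / mass

    n = int(np.ceil(t_end / dt)) + 1
    t = np.arange(n) * dt
    v = np.zeros(n)
    for i in range(n - 1):
        k1 = dv(v[i])
        k2 = dv(v[i] + 0.5 * dt * k1)
        k3 = dv(v[i] + 0.5 * dt * k2)
        k4 = dv(v[i] + dt * k3)
        v[i + 1] = v[i] + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
    return t, v


def simulate_trace(
    profile: GroundTruthProfile,
    athlete: Athlete,
    env: EnvironmentConditions | None = None,
    noise_sd: float = 0.05,
    mode: str = "mono_exp",
    seed: int | np.random.Generator = 0,
    sampling_rate: float = 36.6,
    sprint_distance: float = 20.0,
    overrun: float = 0.3,
    pre_onset_duration: float = 0.0,
    pre_onset_noise_sd: float = 0.02,
    onset_delay: float = 0.0,
    **trace_meta,
) -> RadarTrace:
    """Synthesise one radar trace for a ground-truth profile.

    ``mono_exp`` samples the closed-form velocity curve exactly;
    ``linear_fv_ode`` integrates the drag-corrected linear force-velocity
    law (RK4, 1 ms step).  The trace runs until the athlete has covered
    ``sprint_distance`` plus an ``overrun`` margin (seconds), emulating the
    instruction to sprint past the finish marker.  Optionally a stationary
    pre-onset noise segment and an onset delay are prepended.
    """
    if not (np.isfinite(profile.f0_rel) and np.isfinite(profile.v0)):
        raise InvalidInputError("non-finite profile parameters")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dt = 1.0 / sampling_rate

    if mode == "mono_exp":
        fit = SprintModelFit(mss=profile.mss, tau=profile.tau)
        t_end = split_time(sprint_distance, fit) + overrun
        t = np.arange(0.0, t_end, dt)
        v = np.asarray(predict_velocity(np.maximum(t - onset_delay, 0.0), fit))
        v[t < onset_delay] = 0.0
    elif mode == "linear_fv_ode":
        env = env or EnvironmentConditions()
        k = drag_model(athlete, env.air_density).k_aero
        # generous horizon: drag-free time to distance plus margin
        fit0 = SprintModelFit(mss=profile.mss, tau=profile.tau)
        horizon = split_time(sprint_distance, fit0) * 1.5 + overrun + 1.0 + onset_delay
        tt, vv = _ode_velocity(profile, athlete.body_mass, k, horizon)
        x = np.concatenate([[0.0], np.cumsum(np.diff(tt) * (vv[1:] + vv[:-1]) / 2)])
        idx = np.nonzero(x >= sprint_distance)[0]
        t_end = (tt[idx[0]] if idx.size else tt[-1]) + overrun
        t = np.arange(0.0, t_end, dt)
        v = np.interp(np.maximum(t - onset_delay, 0.0), tt, vv)
        v[t < onset_delay] = 0.0
    else:
        raise InvalidInputError(f"unknown simulation mode {mode!r}")

    if noise_sd > 0:
        v = v + rng.normal(0.0, noise_sd, v.size)
    if pre_onset_duration > 0:
        n_pre = int(round(pre_onset_duration * sampling_rate))
        t = np.concatenate([np.arange(n_pre) * dt, t + n_pre * dt])
        v = np.concatenate([rng.normal(0.0, pre_onset_noise_sd, n_pre), v])
    return RadarTrace(
        time=t, velocity=v, nominal_rate=sampling_rate,
        sprint_distance=sprint_distance, **trace_meta
    )


def simulate_study(
    config: CohortConfig,
    seed: int,
    env: EnvironmentConditions | None = None,
    mode: str = "mono_exp",
    pre_onset_duration: float = 0.5,
) -> tuple[list[RadarTrace], list[SyntheticAthlete]]:
    """Full synthetic study: cohort, intervention, and all radar traces.

    Per athlete-session-trial, MSS and tau are perturbed multiplicatively by
    independent Normal(1, cv) draws (trial-to-trial variability) before the
    trace is synthesised.  Returns the traces and the ground-truth cohort.
    """
    rng = np.random.default_rng(seed)
    cohort = generate_cohort(config, rng)
    cohort = apply_intervention(cohort, config.effects, rng)
    env = env or EnvironmentConditions()
    cv = config.trial_cv_percent / 100.0
    traces = []
    for sa in cohort:
        for session, profile in (("pre", sa.pre), ("post", sa.post)):
            for trial in range(1, config.n_trials + 1):
                f_mss = max(rng.normal(1.0, cv), 0.5)
                f_tau = max(rng.normal(1.0, cv), 0.5)
                perturbed = GroundTruthProfile(
                    f0_rel=profile.mss * f_mss / (profile.tau * f_tau),
                    v0=profile.mss * f_mss,
                )
                traces.append(
                    simulate_trace(
                        perturbed,
                        sa.athlete,
                        env=env,
                        noise_sd=config.noise_sd,
                        mode=mode,
                        seed=rng,
                        sampling_rate=config.sampling_rate,
                        sprint_distance=config.sprint_distance,
                        pre_onset_duration=pre_onset_duration,
                        athlete_id=sa.athlete.athlete_id,
                        session=session,
                        trial_index=trial,
                    )
                )
    return traces, cohort
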