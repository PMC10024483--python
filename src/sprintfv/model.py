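"""Mono-exponential sprint kinematics and the macroscopic force-velocity model.

A maximal sprint acceleration from a standing start is modelled by the
mono-exponential velocity curve

    v(t) = MSS * (1 - exp(-t / tau))

with maximal sprint speed ``MSS`` (m/s) and time constant ``tau`` (s).
Differentiating and integrating give closed forms for acceleration and
position.  Treating the runner as a point mass, the net horizontal
antero-posterior force applied to the centre of mass is recovered by inverse
dynamics as

    F_hzt(t) = m * a(t) + k * v(t)^2

where ``k`` is an aerodynamic drag constant built from air density, estimated
frontal area and a fixed drag coefficient.  Over a maximal sprint, F_hzt is
very nearly an affine function of velocity; the intercepts and slope of that
line are the athlete's force-velocity profile: theoretical maximal force F0,
theoretical maximal velocity v0, their slope S_FV, and maximal horizontal
power Pmax = F0*v0/4.  Mechanical effectiveness is summarised by the ratio of
forces RF = F_hzt / sqrt(F_hzt^2 + (m*g)^2), its early-acceleration value
RF_max (evaluated at t = 0.3 s) and its linear decrement with velocity D_RF.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import optimize, stats

from .errors import InvalidInputError, ModelDegenerateError

__all__ = [
    "GRAVITY",
    "EnvironmentConditions",
    "Athlete",
    "SprintModelFit",
    "DragModel",
    "FvProfile",
    "SplitTimes",
    "air_density",
    "body_surface_area",
    "drag_model",
    "predict_velocity",
    "predict_acceleration",
    "predict_position",
    "horizontal_force",
    "ratio_of_forces",
    "derive_fv_profile",
    "split_time",
    "segment_time",
    "split_table",
]

#: Gravitational acceleration, m/s^2 (fixed).
GRAVITY = 9.81

#: Sea-level air density at 760 Torr and 0 degrees C, kg/m^3.
RHO_REFERENCE = 1.293

#: Drag coefficient of a running human (fixed in the validated model).
DRAG_COEFFICIENT = 0.9

#: Fraction of body surface area presented frontally while running.
FRONTAL_AREA_FRACTION = 0.266

#: Evaluation window start for RF variables, s: below this the model RF is
#: dominated by the non-physical t -> 0 limit.
RF_WINDOW_START = 0.3

TORR_PER_HPA = 760.0 / 1013.25


@dataclass(frozen=True)
class EnvironmentConditions:
    """Ambient conditions at the testing venue.

    Parameters
    ----------
    pressure_torr
        Barometric pressure in Torr (mmHg).  Use :meth:`from_hpa` for hPa.
    temperature_c
        Air temperature in degrees Celsius.
    """

    pressure_torr: float = 760.0
    temperature_c: float = 20.0

    def __post_init__(self):
        if self.pressure_torr <= 0:
            raise InvalidInputError(f"pressure must be positive, got {self.pressure_torr}")
        if self.temperature_c <= -273:
            raise InvalidInputError(f"temperature must exceed -273 C, got {self.temperature_c}")

    @classmethod
    def from_hpa(cls, pressure_hpa: float, temperature_c: float) -> "EnvironmentConditions":
        """Build from pressure in hectopascal; converted to Torr internally."""
        return cls(pressure_hpa * TORR_PER_HPA, temperature_c)

    @property
    def air_density(self) -> float:
        return air_density(self.pressure_torr, self.temperature_c)


@dataclass(frozen=True)
class Athlete:
    """Anthropometrics of one participant."""

    athlete_id: str
    body_mass: float  # kg
    stature: float  # m

    def __post_init__(self):
        if self.body_mass <= 0:
            raise InvalidInputError(f"body mass must be positive, got {self.body_mass}")
        if not 0.5 < self.stature < 2.5:
            raise InvalidInputError(f"stature {self.stature} m outside plausible range (0.5, 2.5)")


@dataclass(frozen=True)
class SprintModelFit:
    """Fitted mono-exponential parameters for one sprint trial.

    ``time_shift`` is the offset between the (trimmed, re-zeroed) recording
    clock and the true movement onset; model time is ``t - time_shift``.
    """

    mss: float  # maximal sprint speed, m/s
    tau: float  # time constant, s
    time_shift: float = 0.0  # s
    rmse: float = 0.0  # m/s
    n_samples: int = 0

    def __post_init__(self):
        if self.mss <= 0:
            raise InvalidInputError(f"MSS must be positive, got {self.mss}")
        if self.tau <= 0:
            raise InvalidInputError(f"tau must be positive, got {self.tau}")
        if self.rmse < 0:
            raise InvalidInputError("rmse must be non-negative")

    # Convenience wrappers evaluating the closed forms in *model* time
    # (i.e. time since movement onset).
    def velocity(self, t):
        return predict_velocity(t, self)

    def acceleration(self, t):
        return predict_acceleration(t, self)

    def position(self, t):
        return predict_position(t, self)


@dataclass(frozen=True)
class DragModel:
    """Aerodynamic drag description: F_drag = k_aero * v^2."""

    air_density_rho: float  # kg/m^3
    frontal_area: float  # m^2
    drag_coefficient_cd: float  # dimensionless
    k_aero: float  # kg/m

    def __post_init__(self):
        for name in ("air_density_rho", "frontal_area", "drag_coefficient_cd", "k_aero"):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"{name} must be positive")
        expected = 0.5 * self.air_density_rho * self.drag_coefficient_cd * self.frontal_area
        if not np.isclose(self.k_aero, expected, rtol=1e-9):
            raise InvalidInputError("k_aero inconsistent with 0.5*rho*Cd*A_f")


@dataclass(frozen=True)
class FvProfile:
    """Derived force-velocity-power variables, absolute and per unit body mass."""

    f0: float  # N
    f0_rel: float  # N/kg
    v0: float  # m/s
    pmax: float  # W
    pmax_rel: float  # W/kg
    s_fv: float  # N.s/m
    s_fv_rel: float  # N.s/m/kg
    rf_max: float  # fraction
    d_rf: float  # per (m/s)
    fv_linearity_r2: float

    def __post_init__(self):
        if self.f0 <= 0 or self.v0 <= 0:
            raise InvalidInputError("F0 and v0 must be positive")
        if self.s_fv >= 0:
            raise InvalidInputError("S_FV must be negative")
        if not 0 < self.rf_max < 1:
            raise InvalidInputError("RF_max must lie in (0, 1)")
        if self.d_rf >= 0:
            raise InvalidInputError("D_RF must be negative")
        if abs(self.pmax - self.f0 * self.v0 / 4) / self.pmax >= 0.002:
            raise InvalidInputError("Pmax inconsistent with F0*v0/4")

    def as_dict(self) -> dict[str, float]:
        return {
            "F0": self.f0,
            "F0_rel": self.f0_rel,
            "v0": self.v0,
            "Pmax": self.pmax,
            "Pmax_rel": self.pmax_rel,
            "S_FV": self.s_fv,
            "S_FV_rel": self.s_fv_rel,
            "RF_max": self.rf_max,
            "D_RF": self.d_rf,
            "fv_linearity_r2": self.fv_linearity_r2,
        }


@dataclass(frozen=True)
class SplitTimes:
    """Cumulative split times (distance m -> elapsed s) for one fitted trial."""

    times: Mapping[float, float]

    def __post_init__(self):
        ds = sorted(self.times)
        ts = [self.times[d] for d in ds]
        if any(t2 <= t1 for t1, t2 in zip(ts, ts[1:])):
            raise InvalidInputError("split times must increase strictly with distance")

    def segment(self, d1: float, d2: float) -> float:
        return self.times[d2] - self.times[d1]

    def as_dict(self, prefix: str = "t_") -> dict[str, float]:
        return {f"{prefix}{d:g}m": t for d, t in sorted(self.times.items())}


def air_density(pressure_torr: float, temperature_c: float) -> float:
    """Air density (kg/m^3) from barometric pressure (Torr) and temperature (C).

    rho = 1.293 * (P / 760) * (273 / (273 + T)); 1.293 kg/m^3 is the density
    at the 760 Torr / 0 C reference condition.
    """
    if pressure_torr <= 0:
        raise InvalidInputError(f"pressure must be positive, got {pressure_torr}")
    if temperature_c <= -273:
        raise InvalidInputError(f"temperature must exceed -273 C, got {temperature_c}")
    return RHO_REFERENCE * (pressure_torr / 760.0) * (273.0 / (273.0 + temperature_c))


def body_surface_area(stature: float, body_mass: float) -> float:
    """Du Bois body surface area (m^2) from stature (m) and mass (kg)."""
    return 0.2025 * stature**0.725 * body_mass**0.425


def drag_model(
    athlete: Athlete,
    rho: float,
    drag_coefficient: float = DRAG_COEFFICIENT,
    frontal_area_fraction: float = FRONTAL_AREA_FRACTION,
) -> DragModel:
    """Aerodynamic drag constant for an athlete at a given air density.

    Frontal area is a fixed fraction of Du Bois body surface area and the
    drag coefficient is fixed at 0.9 by default; both are exposed for
    sensitivity analysis only.
    """
    if rho <= 0:
        raise InvalidInputError(f"air density must be positive, got {rho}")
    bsa = body_surface_area(athlete.stature, athlete.body_mass)
    a_f = frontal_area_fraction * bsa
    k = 0.5 * rho * drag_coefficient * a_f
    return DragModel(rho, a_f, drag_coefficient, k)


def _check_model_time(t):
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise InvalidInputError("model time must be non-negative (after time-shift correction)")
    return t


def predict_velocity(t, fit: SprintModelFit):
    """v(t) = MSS * (1 - exp(-t/tau)) at model time t >= 0."""
    t = _check_model_time(t)
    return fit.mss * (1.0 - np.exp(-t / fit.tau))


def predict_acceleration(t, fit: SprintModelFit):
    """a(t) = (MSS/tau) * exp(-t/tau)."""
    t = _check_model_time(t)
    return fit.mss / fit.tau * np.exp(-t / fit.tau)


def predict_position(t, fit: SprintModelFit):
    """x(t) = MSS * (t + tau*exp(-t/tau)) - MSS*tau."""
    t = _check_model_time(t)
    return fit.mss * (t + fit.tau * np.exp(-t / fit.tau)) - fit.mss * fit.tau


def horizontal_force(t, fit: SprintModelFit, mass: float, drag: DragModel | None = None):
    """Net horizontal ground-reaction force, N: F = m*a(t) + k*v(t)^2."""
    if mass <= 0:
        raise InvalidInputError("mass must be positive")
    k = 0.0 if drag is None else drag.k_aero
    return mass * predict_acceleration(t, fit) + k * predict_velocity(t, fit) ** 2


def ratio_of_forces(t, fit: SprintModelFit, mass: float, drag: DragModel | None = None):
    """RF(t): horizontal force over the magnitude of the estimated total GRF."""
    f_h = horizontal_force(t, fit, mass, drag)
    return f_h / np.hypot(f_h, mass * GRAVITY)


def split_time(distance: float, fit: SprintModelFit) -> float:
    """Time (s) to cover `distance` (m) under the fitted model.

    Root of x(t) = d by bracketed root-finding; |x(t*) - d| < 1e-6 m.
    """
    if distance < 0:
        raise InvalidInputError("distance must be non-negative")
    if distance == 0:
        return 0.0
    # x(t) > MSS*(t - tau): upper bracket from the asymptote.
    hi = distance / fit.mss + fit.tau + 1.0
    return optimize.brentq(
        lambda t: predict_position(t, fit) - distance, 0.0, hi, xtol=1e-10, rtol=8.9e-16
    )


def segment_time(d1: float, d2: float, fit: SprintModelFit) -> float:
    """Elapsed time between the d1 and d2 marks: t(d2) - t(d1)."""
    if d2 < d1:
        raise InvalidInputError("d2 must not precede d1")
    return split_time(d2, fit) - split_time(d1, fit)


def split_table(fit: SprintModelFit, distances=(5.0, 10.0, 15.0, 20.0)) -> SplitTimes:
    """Cumulative split times at the requested distance marks."""
    return SplitTimes({float(d): split_time(float(d), fit) for d in distances})


def derive_fv_profile(
    fit: SprintModelFit,
    athlete: Athlete,
    env: EnvironmentConditions | None = None,
    sprint_distance: float = 20.0,
    n_grid: int = 1000,
    t_start: float = 0.001,
    drag: DragModel | None = None,
    include_drag: bool = True,
) -> FvProfile:
    """Derive the force-velocity-power profile from a fitted sprint model.

    Horizontal force is evaluated on a dense model-time grid covering the
    sprint (t in [t_start, t_end] with t_end the modelled time to cover
    ``sprint_distance``) and regressed linearly on velocity; F0 is the
    intercept, S_FV the slope, v0 = -F0/S_FV and Pmax = F0*v0/4.  RF_max is
    the ratio of forces at t = 0.3 s and D_RF the slope of RF against
    velocity over t >= 0.3 s.

    Parameters
    ----------
    env
        Ambient conditions used to build the drag model; ignored if ``drag``
        is given.  ``include_drag=False`` drops the aerodynamic term
        entirely (closed-form check mode).
    """
    if fit.mss < 0.1 or fit.tau < 1e-3:
        raise ModelDegenerateError(f"degenerate fit: MSS={fit.mss}, tau={fit.tau}")
    if include_drag and drag is None:
        env = env or EnvironmentConditions()
        drag = drag_model(athlete, env.air_density)
    if not include_drag:
        drag = None

    m = athlete.body_mass
    t_end = split_time(sprint_distance, fit)
    t = np.linspace(t_start, t_end, n_grid)
    v = predict_velocity(t, fit)
    f = horizontal_force(t, fit, m, drag)

    slope, intercept, r, _, _ = stats.linregress(v, f)
    f0 = float(intercept)
    s_fv = float(slope)
    v0 = -f0 / s_fv
    pmax = f0 * v0 / 4.0

    rf_max = float(ratio_of_forces(RF_WINDOW_START, fit, m, drag))
    t_rf = t[t >= RF_WINDOW_START]
    if t_rf.size < 10:  # very short sprint: extend window to the end anyway
        t_rf = np.linspace(RF_WINDOW_START, max(t_end, RF_WINDOW_START + 0.5), 200)
    rf = ratio_of_forces(t_rf, fit, m, drag)
    v_rf = predict_velocity(t_rf, fit)
    d_rf = float(stats.linregress(v_rf, rf).slope)

    return FvProfile(
        f0=f0,
        f0_rel=f0 / m,
        v0=v0,
        pmax=pmax,
        pmax_rel=pmax / m,
        s_fv=s_fv,
        s_fv_rel=s_fv / m,
        rf_max=rf_max,
        d_rf=d_rf,
        fv_linearity_r2=float(r**2),
    )
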