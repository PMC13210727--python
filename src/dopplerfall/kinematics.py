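"""Rigid-plate trip-fall angle dynamics.

The falling body is modelled as a rigid plate of height ``H`` pivoting about
its bottom edge under gravity.  With the tilt angle ``theta`` measured from
vertical, the equation of motion is

    d2theta/dt2 = a * sin(theta),        a = 3 g / (2 H)

(the plate mass cancels).  A trip fall starts upright (theta = 0) with an
initial tip velocity ``v0``, i.e. ``theta_dot(0) = v0 / H``, and ends when
the plate reaches the floor at ``theta = pi/2``.  The nonlinear equation is
integrated with a fixed-step fourth-order Runge-Kutta scheme at the radar
sampling interval (1 ms); the small-angle linearization has the closed form

    theta_lin(t) = v0 / (H * sqrt(a)) * sinh(sqrt(a) * t)

which is useful for the early phase of the motion but underestimates the
fall duration (sin(theta) <= theta weakens the restoring torque... here the
*driving* torque, so the nonlinear fall is slower).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FallDynamicsParams",
    "AngleTrajectory",
    "integrate_fall_angle",
    "linearized_fall_angle",
    "fall_duration",
]


@dataclass(frozen=True)
class FallDynamicsParams:
    """Parameters of the rigid-plate fall-angle ODE.

    Attributes
    ----------
    plate_height_H : float
        Plate (body) height in metres.
    initial_tip_velocity_v0 : float
        Initial tip speed in m/s; the initial angular rate is ``v0 / H``.
    gravity_g : float
        Gravitational acceleration in m/s^2.
    time_step : float
        Integration/sampling step in seconds (1 ms matches the 1 kHz
        baseband sampling).
    max_angle : float
        Terminal tilt angle in radians (pi/2 = floor contact).
    time_cap : float
        Wall-clock cap for non-terminating integrations (v0 = 0 leaves the
        plate at an unstable equilibrium); 10 s is unambiguous failure for
        a motion that physically lasts 1-2 s.
    """

    plate_height_H: float
    initial_tip_velocity_v0: float
    gravity_g: float = 9.81
    time_step: float = 0.001
    max_angle: float = math.pi / 2
    time_cap: float = 10.0

    def __post_init__(self) -> None:
        if self.plate_height_H <= 0:
            raise ValueError("plate_height_H must be positive")
        if self.initial_tip_velocity_v0 < 0:
            raise ValueError("initial_tip_velocity_v0 must be >= 0")
        if self.time_step <= 0:
            raise ValueError("time_step must be positive")
        if not (0 < self.max_angle <= math.pi / 2):
            raise ValueError("max_angle must lie in (0, pi/2]")

    @property
    def angular_accel_a(self) -> float:
        """ODE coefficient a = 3 g / (2 H), in 1/s^2."""
        return 1.5 * self.gravity_g / self.plate_height_H


@dataclass
class AngleTrajectory:
    """Time-sampled fall angle and angular rate.

    ``terminated`` is True when ``theta`` reached ``max_angle`` before the
    time cap; the terminal sample is clipped to exactly ``max_angle`` so
    downstream geometry never sees an overshoot.
    """

    times: np.ndarray
    theta: np.ndarray
    theta_dot: np.ndarray
    terminated: bool
    params: FallDynamicsParams = field(repr=False, default=None)


def _rk4_step(theta: float, omega: float, dt: float, a: float) -> tuple[float, float]:
    # state derivative: (theta' = omega, omega' = a sin theta)
    k1t, k1w = omega, a * math.sin(theta)
    k2t, k2w = omega + 0.5 * dt * k1w, a * math.sin(theta + 0.5 * dt * k1t)
    k3t, k3w = omega + 0.5 * dt * k2w, a * math.sin(theta + 0.5 * dt * k2t)
    k4t, k4w = omega + dt * k3w, a * math.sin(theta + dt * k3t)
    return (
        theta + dt / 6.0 * (k1t + 2 * k2t + 2 * k3t + k4t),
        omega + dt / 6.0 * (k1w + 2 * k2w + 2 * k3w + k4w),
    )


def integrate_fall_angle(params: FallDynamicsParams) -> AngleTrajectory:
    """Integrate the nonlinear fall-angle ODE with fixed-step RK4.

    Integration runs from theta = 0, theta_dot = v0/H until the first sample
    where theta >= max_angle (that sample is clipped to max_angle), or until
    the time cap when the motion never reaches the terminal angle.
    """
    a = params.angular_accel_a
    dt = params.time_step
    n_cap = int(round(params.time_cap / dt))

    thetas = [0.0]
    omegas = [params.initial_tip_velocity_v0 / params.plate_height_H]
    terminated = False
    th, om = thetas[0], omegas[0]
    for _ in range(n_cap):
        th, om = _rk4_step(th, om, dt, a)
        if th >= params.max_angle:
            thetas.append(params.max_angle)
            omegas.append(om)
            terminated = True
            break
        thetas.append(th)
        omegas.append(om)

    n = len(thetas)
    return AngleTrajectory(
        times=np.arange(n) * dt,
        theta=np.asarray(thetas),
        theta_dot=np.asarray(omegas),
        terminated=terminated,
        params=params,
    )


def linearized_fall_angle(params: FallDynamicsParams, t) -> np.ndarray | float:
    """Closed-form small-angle solution theta_lin(t) = v0/(H sqrt(a)) sinh(sqrt(a) t).

    Accepts a scalar or array of non-negative times; no clipping is applied.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be non-negative")
    sqrt_a = math.sqrt(params.angular_accel_a)
    out = (
        params.initial_tip_velocity_v0
        / (params.plate_height_H * sqrt_a)
        * np.sinh(sqrt_a * t_arr)
    )
    return float(out) if np.isscalar(t) else out


def fall_duration(traj: AngleTrajectory) -> float:
    """Time of floor contact: first sample where theta reached max_angle."""
    if not traj.terminated:
        raise ValueError(
            "trajectory did not terminate: v0 too small or time cap too short"
        )
    return float(traj.times[-1])
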