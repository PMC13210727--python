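"""Range trajectories D(t) for the three motion classes.

* ``fall``:    the physics-informed plate model — tilt angle from the
  nonlinear pendulum ODE, effective range D = K * D_tilde(theta(t)), held
  constant after floor contact (a body at rest on the floor).
* ``walk``:    a kinematic gait stand-in — a torso point translating along a
  heading with cadence/stride scaled by body height and a speed factor RV,
  plus periodic bob and leg-swing range modulation.  It contracts only on
  qualitative spectral structure (a sustained Doppler line with cadence
  harmonics), not on biomechanical fidelity.
* ``breathe``: a chest-wall stand-in — a millimetric sinusoid at the
  breathing frequency, attenuated by facing angle.

All classes produce strictly positive range sampled at 1 kHz.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import PlateGeometry, area_integrated_range, effective_range
from .kinematics import FallDynamicsParams, integrate_fall_angle, linearized_fall_angle
from .radar import RangeSeries

__all__ = [
    "FallTrialParams",
    "GaitTrialParams",
    "BreathTrialParams",
    "fall_range_trajectory",
    "gait_range_trajectory",
    "respiration_range_trajectory",
]

FS = 1000.0  # baseband sampling rate, Hz


@dataclass(frozen=True)
class FallTrialParams:
    body_height_H: float
    body_width_W: float
    v0: float
    K: float
    fall_azimuth_phi: float = 0.0
    sensor_range_d: float = 2.5
    sensor_height_h: float = 1.3
    post_fall_hold: float = 0.5

    def __post_init__(self) -> None:
        if min(self.body_height_H, self.body_width_W, self.K, self.sensor_range_d) <= 0:
            raise ValueError("H, W, K and d must be positive")
        if not (-math.pi <= self.fall_azimuth_phi < math.pi):
            raise ValueError("phi must lie in [-pi, pi)")


@dataclass(frozen=True)
class GaitTrialParams:
    body_height_H: float
    body_width_W: float
    speed_factor_RV: float
    heading_phi: float = 0.0
    start_range_d: float = 2.5
    sensor_height_h: float = 1.3
    n_steps: int = 4

    def __post_init__(self) -> None:
        if not (0.5 <= self.speed_factor_RV <= 3.0):
            raise ValueError("speed_factor_RV must lie in [0.5, 3.0]")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")


@dataclass(frozen=True)
class BreathTrialParams:
    breathing_freq: float
    chest_amplitude: float = 0.008
    facing_phi: float = 0.0
    sensor_range_d: float = 2.5
    duration: float = 10.0

    def __post_init__(self) -> None:
        if not (0.1 <= self.breathing_freq <= 0.5):
            raise ValueError("breathing_freq must lie in [0.1, 0.5] Hz")
        if self.chest_amplitude < 0:
            raise ValueError("chest_amplitude must be >= 0")


def fall_range_trajectory(
    p: FallTrialParams,
    dyn: FallDynamicsParams | None = None,
    linearized: bool = False,
) -> RangeSeries:
    """Effective range of a trip fall sampled at 1 kHz.

    ``linearized=True`` replaces the nonlinear tilt trajectory with the
    closed-form small-angle solution (ablation condition); its angle is
    clipped at pi/2 and the trial ends at the first clipped sample.
    """
    if dyn is None:
        dyn = FallDynamicsParams(
            plate_height_H=p.body_height_H, initial_tip_velocity_v0=p.v0
        )
    elif not math.isclose(dyn.plate_height_H, p.body_height_H, rel_tol=1e-9):
        raise ValueError("plate height mismatch between trial and dynamics params")

    if linearized:
        if p.v0 <= 0:
            raise ValueError("linearized fall requires v0 > 0")
        sqrt_a = math.sqrt(dyn.angular_accel_a)
        t_end = math.asinh(dyn.max_angle * p.body_height_H * sqrt_a / p.v0) / sqrt_a
        times = np.arange(0.0, t_end + dyn.time_step, dyn.time_step)
        theta = np.minimum(linearized_fall_angle(dyn, times), dyn.max_angle)
    else:
        traj = integrate_fall_angle(dyn)
        if not traj.terminated:
            raise ValueError("fall never reached the terminal angle (v0 too small?)")
        times, theta = traj.times, traj.theta

    geom = PlateGeometry(
        plate_width_W=p.body_width_W,
        plate_height_H=p.body_height_H,
        sensor_range_d=p.sensor_range_d,
        sensor_height_h=p.sensor_height_h,
        fall_azimuth_phi=p.fall_azimuth_phi,
        effective_range_factor_K=p.K,
    )
    d_eff = effective_range(area_integrated_range(theta, geom), p.K)

    n_hold = int(round(p.post_fall_hold * FS))
    d_full = np.concatenate([d_eff, np.full(n_hold, d_eff[-1])])
    t_full = np.arange(len(d_full)) / FS
    return RangeSeries(times=t_full, range_D=d_full, label="fall")


def gait_range_trajectory(p: GaitTrialParams) -> RangeSeries:
    """Radial range of the gait stand-in over ``n_steps`` steps.

    Cadence f_c = 1.8*sqrt(RV) steps/s and step length 0.26*H*sqrt(RV) give
    a translation speed 0.468*H*RV (linear in RV, ~0.8 m/s for H = 1.7 m at
    RV = 1).  Vertical bob at 2 f_c and a leg-swing range modulation at f_c
    put cadence harmonics in the micro-Doppler spectrum.
    """
    h_scale = p.body_height_H / 1.7
    cadence = 1.8 * math.sqrt(p.speed_factor_RV)
    step_len = 0.26 * p.body_height_H * math.sqrt(p.speed_factor_RV)
    speed = step_len * cadence
    duration = p.n_steps / cadence
    t = np.arange(0.0, duration, 1.0 / FS)

    # horizontal track relative to the sensor foot point
    x_par = p.start_range_d - speed * t * math.cos(p.heading_phi)
    x_perp = speed * t * math.sin(p.heading_phi)
    h_eff = p.sensor_height_h - 0.012 * h_scale * np.sin(2 * np.pi * 2 * cadence * t)
    d = np.sqrt(x_par**2 + x_perp**2 + h_eff**2)
    d = d + 0.025 * h_scale * np.sin(2 * np.pi * cadence * t)
    return RangeSeries(times=t, range_D=d, label="walk")


def respiration_range_trajectory(p: BreathTrialParams) -> RangeSeries:
    """Chest-wall stand-in: D = d0 + A sin(2 pi f_b t) * max(cos phi, 0.2).

    The facing-angle factor is floored at 0.2 so an orthogonally facing
    subject still returns a (weak) respiratory signal.
    """
    t = np.arange(0.0, p.duration, 1.0 / FS)
    proj = max(math.cos(p.facing_phi), 0.2)
    d = p.sensor_range_d + p.chest_amplitude * np.sin(2 * np.pi * p.breathing_freq * t) * proj
    return RangeSeries(times=t, range_D=d, label="breathe")
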