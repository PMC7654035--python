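"""Dissolved-oxygen control loop for an oxystat stirred-tank fermentation.

A single PI controller maps the dO2 error (percent of air saturation) to a
0-100 % controller output.  A split-range cascade translates that output into
stepwise actuator commands: the agitation ramp (100-300 rpm) is used first,
the airflow ramp (0-10 SLPM of compressed air) second, so both actuators stay
at low levels early in the batch and rise independently as oxygen demand
grows.  The sensor model reproduces an amperometric O2 probe with Gaussian
read noise, a hard detection floor and a bounded over-range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "ControllerConfig",
    "SensorModel",
    "ActuatorState",
    "ControlTrace",
    "pi_step",
    "cascade_map",
    "sensor_read",
    "closed_loop",
]

#: 6 ppb dissolved O2 expressed in percent air saturation, assuming
#: 8.0 mg O2 / L at air saturation and 28 degC (0.006 mg/L / 8.0 mg/L).
DETECTION_FLOOR_PCT = 0.075


@dataclass(frozen=True)
class ControllerConfig:
    """PI gains and split-range cascade geometry.

    ``u_split`` is the controller-output percentage at which actuation hands
    over from the agitation ramp to the airflow ramp.  Actuator commands are
    quantized ("stepwise" actuation): rpm to ``rpm_step`` below the linear
    ramp, airflow to the nearest ``airflow_step``.
    """

    set_point: float = 95.0          # % air saturation
    kp: float = 5.0                  # dimensionless
    ki: float = 40.0                 # 1/h
    sample_interval: float = 1.0 / 60.0  # h
    u_split: float = 50.0            # % controller output
    rpm_bounds: tuple[float, float] = (100.0, 300.0)
    airflow_bounds: tuple[float, float] = (0.0, 10.0)
    rpm_step: float = 10.0           # rpm
    airflow_step: float = 0.1        # SLPM
    integral_limits: tuple[float, float] = (-2.5, 2.5)  # %*h

    def __post_init__(self) -> None:
        if not (0.0 < self.u_split < 100.0):
            raise ValueError(f"u_split must lie in (0, 100), got {self.u_split}")
        if self.sample_interval <= 0.0:
            raise ValueError("sample_interval must be positive")
        if self.rpm_step <= 0.0 or self.airflow_step <= 0.0:
            raise ValueError("actuator quanta must be positive")
        if self.rpm_bounds[0] >= self.rpm_bounds[1]:
            raise ValueError("rpm_bounds must be (min, max) with min < max")
        if self.airflow_bounds[0] >= self.airflow_bounds[1]:
            raise ValueError("airflow_bounds must be (min, max) with min < max")
        if self.integral_limits[0] >= self.integral_limits[1]:
            raise ValueError("integral_limits must be (lo, hi) with lo < hi")


@dataclass(frozen=True)
class SensorModel:
    """Amperometric dO2 probe: Gaussian noise, detection floor, +/-1% span."""

    noise_sd: float = 0.5            # % air saturation
    detection_floor: float = DETECTION_FLOOR_PCT
    accuracy: float = 0.01           # relative span error

    def __post_init__(self) -> None:
        if self.noise_sd < 0.0:
            raise ValueError("noise_sd must be non-negative")
        if self.detection_floor < 0.0:
            raise ValueError("detection_floor must be non-negative")


@dataclass
class ActuatorState:
    """Snapshot of the actuation chain at one control instant."""

    rpm: float
    airflow: float                   # SLPM
    controller_output: float         # % in [0, 100]
    integral: float                  # %*h


@dataclass
class ControlTrace:
    """Closed-loop trajectory sampled at the controller interval."""

    time_h: np.ndarray
    dO2_pct: np.ndarray              # measured (recorded) dO2
    dO2_true_pct: np.ndarray
    output_pct: np.ndarray
    rpm: np.ndarray
    airflow_slpm: np.ndarray
    states: list                     # plant states, one per sample


def pi_step(
    config: ControllerConfig, measured: float, integral: float
) -> tuple[float, float]:
    """One PI update: returns (output in [0, 100] %, new integral).

    The integral term is clamped to ``config.integral_limits`` and, as
    anti-windup, is not accumulated while the raw output is saturated in the
    same direction as the error.
    """
    if not math.isfinite(measured):
        raise ValueError(f"non-finite dO2 measurement: {measured!r}")
    dt = config.sample_interval
    if dt <= 0.0:
        raise ValueError("sample_interval must be positive")
    error = config.set_point - measured
    lo, hi = config.integral_limits
    candidate = min(max(integral + error * dt, lo), hi)
    raw = config.kp * error + config.ki * candidate
    if (raw > 100.0 and error > 0.0) or (raw < 0.0 and error < 0.0):
        candidate = integral  # saturated against the error: freeze integral
        raw = config.kp * error + config.ki * candidate
    return min(max(raw, 0.0), 100.0), candidate


def cascade_map(config: ControllerConfig, output: float) -> tuple[float, float]:
    """Split-range map from controller output to (rpm, airflow).

    Monotone non-decreasing and piecewise linear in ``output``: below
    ``u_split`` agitation ramps from its minimum to its maximum (floored to
    the rpm quantum) with airflow at minimum; above, agitation is pinned at
    maximum and airflow ramps up (rounded to the airflow quantum).
    """
    if not (0.0 <= output <= 100.0):
        raise ValueError(f"controller output outside [0, 100]: {output}")
    rpm_min, rpm_max = config.rpm_bounds
    air_min, air_max = config.airflow_bounds
    if output <= config.u_split:
        frac = output / config.u_split
        rpm = rpm_min + frac * (rpm_max - rpm_min)
        rpm = rpm_min + math.floor((rpm - rpm_min) / config.rpm_step + 1e-9) * config.rpm_step
        airflow = air_min
    else:
        rpm = rpm_max
        frac = (output - config.u_split) / (100.0 - config.u_split)
        airflow = air_min + frac * (air_max - air_min)
        airflow = air_min + round((airflow - air_min) / config.airflow_step) * config.airflow_step
    rpm = min(max(rpm, rpm_min), rpm_max)
    airflow = min(max(airflow, air_min), air_max)
    return rpm, airflow


def sensor_read(
    model: SensorModel,
    true_dO2: float,
    rng: np.random.Generator | int | None = None,
) -> float:
    """Simulated probe reading: noisy, floored, span-limited."""
    if true_dO2 < 0.0:
        raise ValueError(f"true dO2 must be non-negative, got {true_dO2}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    reading = true_dO2 + (rng.normal(0.0, model.noise_sd) if model.noise_sd > 0 else 0.0)
    hi = 100.0 * (1.0 + model.accuracy)
    return min(max(reading, model.detection_floor), hi)


def closed_loop(
    config: ControllerConfig,
    sensor: SensorModel,
    plant_step: Callable,
    initial_state,
    read_dO2: Callable[[object], float],
    horizon: float,
    seed: int | np.random.Generator = 0,
) -> ControlTrace:
    """Run the sampled-data loop: read sensor, PI, cascade, advance plant.

    ``plant_step(state, rpm, airflow, dt) -> state`` must be free of side
    effects; actuators are held between samples (zero-order hold).  The full
    trace, including the plant state at every sample, is returned and is
    reproducible for a fixed seed.
    """
    if horizon <= 0.0:
        raise ValueError("horizon must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(horizon / config.sample_interval))
    times = np.empty(n + 1)
    meas = np.empty(n + 1)
    true = np.empty(n + 1)
    outs = np.empty(n + 1)
    rpms = np.empty(n + 1)
    airs = np.empty(n + 1)
    states: list = []

    state = initial_state
    integral = 0.0
    for k in range(n + 1):
        t = k * config.sample_interval
        c_true = read_dO2(state)
        if not math.isfinite(c_true):
            raise FloatingPointError(
                f"plant returned non-finite dO2 at t = {t:.4f} h"
            )
        c_meas = sensor_read(sensor, max(c_true, 0.0), rng)
        output, integral = pi_step(config, c_meas, integral)
        rpm, airflow = cascade_map(config, output)
        times[k], meas[k], true[k] = t, c_meas, c_true
        outs[k], rpms[k], airs[k] = output, rpm, airflow
        states.append(state)
        if k < n:
            state = plant_step(state, rpm, airflow, config.sample_interval)
    return ControlTrace(times, meas, true, outs, rpms, airs, states)
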