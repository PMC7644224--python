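"""Thermal stimulus models: spatial gradients and temporal ramps.

Two stimulus geometries are used in C. elegans thermotaxis work and both are
represented here:

* :class:`ThermalGradient` — a linear spatial gradient across an agar plate,
  mapping an (x, y) position to a temperature.  The standard "short" assay
  gradient spans 23-28 degC at 0.5 degC/cm across a 10 cm plate, with worms
  started at the 25.5 degC centre isotherm.
* :class:`TemperatureRamp` — a linear temporal ramp delivered to an
  immobilised animal during calcium imaging, mapping time to temperature.
  The standard imaging stimulus rises at 0.05 degC/s, chosen to approximate
  the temperature change experienced by a worm crawling on the short
  gradient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["ThermalGradient", "TemperatureRamp", "short_gradient", "temperature_at"]


@dataclass(frozen=True)
class ThermalGradient:
    """Linear spatial thermal gradient on a rectangular plate.

    Parameters
    ----------
    temp_at_origin : float
        Temperature in degC at the coordinate origin.
    slope : float
        Gradient steepness in degC per cm along the gradient axis; must be
        non-negative.
    axis_angle : float
        Direction of *increasing* temperature in degrees (0 deg = toward
        warm, the shared orientation convention).
    bounds : tuple
        Plate extent ``(xmin, xmax, ymin, ymax)`` in cm.
    clamp_range : tuple
        ``(tmin, tmax)`` in degC; returned temperatures are clamped into
        this interval (the physical plate cannot exceed its set points).
    """

    temp_at_origin: float
    slope: float
    axis_angle: float = 0.0
    bounds: tuple = (0.0, 10.0, 0.0, 10.0)
    clamp_range: tuple = (-273.15, math.inf)

    def __post_init__(self):
        if self.slope < 0:
            raise ValueError(f"gradient slope must be >= 0, got {self.slope}")
        tmin, tmax = self.clamp_range
        if not tmin < tmax:
            raise ValueError(f"clamp_range min must be < max, got {self.clamp_range}")
        xmin, xmax, ymin, ymax = self.bounds
        if not (xmin < xmax and ymin < ymax):
            raise ValueError(f"degenerate plate bounds {self.bounds}")

    @property
    def warm_axis_deg(self) -> float:
        """Direction of increasing temperature (alias for ``axis_angle``)."""
        return self.axis_angle

    def contains(self, x_cm: float, y_cm: float) -> bool:
        xmin, xmax, ymin, ymax = self.bounds
        return (xmin <= x_cm <= xmax) and (ymin <= y_cm <= ymax)

    def temperature_at(self, x_cm: float, y_cm: float) -> float:
        """Temperature in degC at an in-bounds position (cm)."""
        xmin, xmax, ymin, ymax = self.bounds
        if not xmin <= x_cm <= xmax:
            raise ValueError(
                f"x position {x_cm} cm outside plate bounds [{xmin}, {xmax}]"
            )
        if not ymin <= y_cm <= ymax:
            raise ValueError(
                f"y position {y_cm} cm outside plate bounds [{ymin}, {ymax}]"
            )
        theta = math.radians(self.axis_angle)
        proj = x_cm * math.cos(theta) + y_cm * math.sin(theta)
        temp = self.temp_at_origin + self.slope * proj
        tmin, tmax = self.clamp_range
        return float(min(max(temp, tmin), tmax))

    def center(self) -> tuple:
        xmin, xmax, ymin, ymax = self.bounds
        return ((xmin + xmax) / 2.0, (ymin + ymax) / 2.0)


def temperature_at(gradient: ThermalGradient, position) -> float:
    """Functional form of :meth:`ThermalGradient.temperature_at`."""
    x, y = position
    return gradient.temperature_at(x, y)


def short_gradient() -> ThermalGradient:
    """The standard short assay gradient: 23-28 degC at 0.5 degC/cm.

    A 10 cm plate with the cold edge at the origin and temperature
    increasing along +x; the plate centre (5, 5) sits at 25.5 degC, where
    animals are placed at the start of an assay.
    """
    return ThermalGradient(
        temp_at_origin=23.0,
        slope=0.5,
        axis_angle=0.0,
        bounds=(0.0, 10.0, 0.0, 10.0),
        clamp_range=(23.0, 28.0),
    )


@dataclass(frozen=True)
class TemperatureRamp:
    """Linear temperature ramp in time, T(t) = start_temp + rate * (t - start_time).

    ``rate = 0`` encodes a constant-temperature stimulus.  Beyond
    ``start_time + duration`` the temperature holds at the final ramp value
    (the controller plateaus); before ``start_time`` it holds at
    ``start_temp``.
    """

    start_temp: float
    rate: float
    start_time: float = 0.0
    duration: float = 240.0

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError(f"ramp duration must be > 0, got {self.duration}")

    @property
    def end_temp(self) -> float:
        return self.start_temp + self.rate * self.duration

    def temperature(self, t):
        """Temperature in degC at time(s) ``t`` (seconds)."""
        t = np.asarray(t, dtype=float)
        elapsed = np.clip(t - self.start_time, 0.0, self.duration)
        temp = self.start_temp + self.rate * elapsed
        if temp.ndim == 0:
            return float(temp)
        return temp

    def time_at_temperature(self, temp: float) -> float:
        """First time at which the ramp reaches ``temp`` (requires rate != 0)."""
        if self.rate == 0:
            raise ValueError("time_at_temperature undefined for a constant stimulus")
        t = self.start_time + (temp - self.start_temp) / self.rate
        lo, hi = sorted((self.start_temp, self.end_temp))
        if not lo <= temp <= hi:
            raise ValueError(
                f"temperature {temp} degC outside ramp range [{lo}, {hi}]"
            )
        return float(t)
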