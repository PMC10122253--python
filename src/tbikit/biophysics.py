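"""Weight-drop and bubble-collapse biophysics.

Characterizes the injury stimulus delivered by the device: impact energy
and velocity of the falling weight (free fall plus an optional rubber-band
spring assist), growth/collapse kinematics fitted to a bubble radius-time
trace, the point-sink 1/r^2 velocity decay away from the bubble front, and
an empirical quadratic pressure-velocity law calibrated on the observed
(~1 m/s, 10 Pa) surface-pressure anchor.  The quadratic law is descriptive
-- a dynamic-pressure-like calibration through the measured anchors -- not
a cavitation (Rayleigh-Plesset) solution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

__all__ = [
    "DeviceSpec",
    "BubbleTrace",
    "PressureLaw",
    "drop_kinematics",
    "bubble_speeds",
    "sink_velocity",
    "collapse_pressure",
]


@dataclass(frozen=True)
class DeviceSpec:
    """Geometry and mechanics of the weight-drop device.

    Defaults: a 36.74-g metal cylinder (6 cm long, 1 cm diameter) falling
    freely down a 12-cm tube.  ``rubber_stiffness_n_m = 0`` means free fall;
    a positive stiffness models the optional rubber-band accelerator as an
    ideal linear spring.
    """

    weight_mass_kg: float = 0.03674
    weight_length_m: float = 0.06
    weight_diameter_m: float = 0.01
    drop_height_m: float = 0.12
    rubber_stiffness_n_m: float = 0.0
    g_m_s2: float = 9.81

    def __post_init__(self) -> None:
        if self.weight_mass_kg <= 0 or self.drop_height_m < 0:
            raise ValueError("mass must be positive and height non-negative")
        if self.rubber_stiffness_n_m < 0 or self.g_m_s2 <= 0:
            raise ValueError("stiffness must be >= 0 and g > 0")


@dataclass
class BubbleTrace:
    """Radius-time series of the air bubble under the nozzle."""

    times_s: np.ndarray
    radius_m: np.ndarray

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.radius_m = np.asarray(self.radius_m, dtype=float)
        if self.times_s.shape != self.radius_m.shape or self.times_s.ndim != 1:
            raise ValueError("times_s and radius_m must be equal-length 1-D arrays")
        if len(self.times_s) > 1 and np.any(np.diff(self.times_s) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.radius_m < 0):
            raise ValueError("radii must be non-negative")


@dataclass(frozen=True)
class PressureLaw:
    """Quadratic surface-pressure law ``p = C v^2``.

    ``C`` is fixed by one (velocity, pressure) anchor; the default anchor
    (1 m/s, 10 Pa) gives C = 10 Pa s^2/m^2 and reproduces the 1000 Pa
    observed at 10 m/s instantaneous front velocity.
    """

    coefficient_pa_per_m2_s2: float
    anchor_velocity_m_s: float = 1.0
    anchor_pressure_pa: float = 10.0

    @classmethod
    def from_anchor(
        cls, velocity_m_s: float = 1.0, pressure_pa: float = 10.0
    ) -> "PressureLaw":
        if velocity_m_s <= 0 or pressure_pa <= 0:
            raise ValueError("anchor velocity and pressure must be positive")
        return cls(
            coefficient_pa_per_m2_s2=pressure_pa / velocity_m_s**2,
            anchor_velocity_m_s=velocity_m_s,
            anchor_pressure_pa=pressure_pa,
        )


def drop_kinematics(spec: DeviceSpec, rubber_stretch_m: float = 0.0) -> dict:
    """Impact energy (J) and velocity (m/s) of the falling weight.

    Free fall: ``E = m g h`` and ``v = sqrt(2 g h)``.  With a rubber band
    stretched by ``rubber_stretch_m`` the stored spring energy
    ``k x^2 / 2`` is added and the velocity follows from the energy balance
    ``m v^2 / 2 = E``.
    """
    if rubber_stretch_m < 0:
        raise ValueError("rubber_stretch_m must be non-negative")
    energy = spec.weight_mass_kg * spec.g_m_s2 * spec.drop_height_m
    energy += 0.5 * spec.rubber_stiffness_n_m * rubber_stretch_m**2
    velocity = float(np.sqrt(2.0 * energy / spec.weight_mass_kg))
    return {"impact_energy_j": float(energy), "impact_velocity_m_s": velocity}


def bubble_speeds(trace: BubbleTrace, median_prefilter: bool = False) -> dict:
    """Growth and collapse speeds from a radius-time trace.

    The trace is segmented at its global radius maximum; growth speed is the
    least-squares slope over the rising segment, collapse speed the absolute
    slope from the maximum to the first return to zero (or the trace end).
    ``median_prefilter`` applies a 3-point median filter first, which
    removes single-sample jitter before segmentation.  A monotone trace has
    no collapse phase: its speed is ``nan``, flagged with a warning.
    """
    r = trace.radius_m.copy()
    t = trace.times_s
    if len(r) < 2:
        raise ValueError("trace needs at least two samples")
    if median_prefilter and len(r) >= 3:
        r = ndimage.median_filter(r, size=3, mode="nearest")
    i_max = int(np.argmax(r))
    if i_max >= 1:
        growth = float(stats.linregress(t[: i_max + 1], r[: i_max + 1]).slope)
    else:
        growth = float("nan")
        warnings.warn("no rising segment before the radius maximum")
    if i_max < len(r) - 1:
        fall_r = r[i_max:]
        zeros = np.flatnonzero(fall_r <= 0)
        stop = i_max + (zeros[0] + 1 if len(zeros) else len(fall_r))
        collapse = abs(float(stats.linregress(t[i_max:stop], r[i_max:stop]).slope))
    else:
        collapse = float("nan")
        warnings.warn("monotone trace: collapse speed undefined")
    ratio = collapse / growth if growth and np.isfinite(growth) else float("nan")
    return {
        "growth_speed_m_s": growth,
        "collapse_speed_m_s": collapse,
        "collapse_to_growth_ratio": ratio,
    }


def sink_velocity(
    v_front_m_s: float, bubble_radius_m: float, distance_m: float
) -> float:
    """Point-sink flow speed ``v(r) = v_front (R/r)^2`` outside the bubble."""
    if bubble_radius_m <= 0:
        raise ValueError("bubble_radius_m must be positive")
    if distance_m < bubble_radius_m:
        raise ValueError("distance_m must be >= bubble_radius_m")
    return float(v_front_m_s * (bubble_radius_m / distance_m) ** 2)


def collapse_pressure(law: PressureLaw, v_m_s: float) -> float:
    """Surface pressure magnitude ``p = C v^2`` (Pa) at front velocity v."""
    if v_m_s < 0:
        raise ValueError("velocity must be non-negative")
    return float(law.coefficient_pa_per_m2_s2 * v_m_s**2)
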