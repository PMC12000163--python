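"""Domain types for the horizontal-syringe sedimentation model.

All quantities are SI internally (m, kg, s, Pa·s). Convenience
constructors accepting laboratory units (µm, mm, g/cm³, mPa·s,
µl/min) live in :mod:`syrsed.config`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "InvalidParameterError",
    "ParticleSpec",
    "BufferSpec",
    "SyringeSpec",
    "ModelConstants",
    "Kinematics",
    "HalfLifeEstimate",
    "ConcentrationCurve",
]


class InvalidParameterError(ValueError):
    """A physical parameter violates its invariant."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise InvalidParameterError(msg)


@dataclass(frozen=True)
class ParticleSpec:
    """A rigid spherical particle.

    Parameters
    ----------
    radius : float
        Particle radius r_P in metres.
    density : float
        Particle mass density ρ_P in kg/m³.
    """

    radius: float
    density: float

    def __post_init__(self) -> None:
        _require(self.radius > 0, f"particle radius must be > 0, got {self.radius}")
        _require(self.density > 0, f"particle density must be > 0, got {self.density}")

    @property
    def volume(self) -> float:
        """Particle volume in m³."""
        return (4.0 / 3.0) * math.pi * self.radius**3

    @property
    def mass(self) -> float:
        """Particle mass in kg."""
        return self.volume * self.density


@dataclass(frozen=True)
class BufferSpec:
    """The suspending liquid (e.g. PBS or water).

    Parameters
    ----------
    density : float
        Buffer mass density ρ_B in kg/m³.
    viscosity : float
        Dynamic viscosity η in Pa·s.
    """

    density: float
    viscosity: float

    def __post_init__(self) -> None:
        _require(self.density > 0, f"buffer density must be > 0, got {self.density}")
        _require(self.viscosity > 0, f"buffer viscosity must be > 0, got {self.viscosity}")


@dataclass(frozen=True)
class SyringeSpec:
    """Horizontal syringe geometry: a cylindrical barrel with a small
    cylindrical outlet on the end wall.

    The barrel axis is horizontal (z); gravity acts along −y. The
    outlet centre sits at (x=0, y=outlet_offset) on the end wall:
    ``outlet_offset = 0`` is a concentric outlet, ``-(R_S - R_O)``
    puts the outlet flush with the bottom edge (eccentric-bottom) and
    ``+(R_S - R_O)`` flush with the top edge (eccentric-top).

    All lengths in metres.
    """

    barrel_radius: float
    barrel_length: float
    outlet_radius: float
    outlet_length: float = 5e-3
    outlet_offset: float = 0.0

    def __post_init__(self) -> None:
        _require(self.barrel_radius > 0, "barrel radius must be > 0")
        _require(self.barrel_length > 0, "barrel length must be > 0")
        _require(self.outlet_length > 0, "outlet length must be > 0")
        _require(
            0 < self.outlet_radius < self.barrel_radius,
            f"outlet radius must satisfy 0 < R_O < R_S, got R_O={self.outlet_radius}, "
            f"R_S={self.barrel_radius}",
        )
        _require(
            abs(self.outlet_offset) <= self.barrel_radius - self.outlet_radius + 1e-15,
            f"|outlet_offset| must be <= R_S - R_O = "
            f"{self.barrel_radius - self.outlet_radius}, got {self.outlet_offset}",
        )

    @property
    def cross_section_area(self) -> float:
        """Barrel cross-section area A_S = πR_S² in m²."""
        return math.pi * self.barrel_radius**2

    @property
    def volume(self) -> float:
        """Barrel volume in m³ (outlet tube excluded)."""
        return self.cross_section_area * self.barrel_length

    def eccentric_bottom(self) -> "SyringeSpec":
        """Same barrel with the outlet flush with the bottom edge."""
        return SyringeSpec(
            self.barrel_radius,
            self.barrel_length,
            self.outlet_radius,
            self.outlet_length,
            -(self.barrel_radius - self.outlet_radius),
        )

    def eccentric_top(self) -> "SyringeSpec":
        """Same barrel with the outlet flush with the top edge."""
        return SyringeSpec(
            self.barrel_radius,
            self.barrel_length,
            self.outlet_radius,
            self.outlet_length,
            self.barrel_radius - self.outlet_radius,
        )


@dataclass(frozen=True)
class ModelConstants:
    """Physical constants. g in m/s²."""

    g: float = 9.81

    def __post_init__(self) -> None:
        _require(self.g > 0, "g must be > 0")


@dataclass(frozen=True)
class Kinematics:
    """Settling kinematics of a particle.

    ``terminal_velocity`` is signed: negative means the particle
    sinks (heavier than the buffer), positive means it floats.
    ``relaxation_time`` is the exponential time constant with which
    the terminal velocity is approached; for micron-scale particles
    it is microseconds, which justifies treating the settling
    velocity as instantaneous.
    """

    terminal_velocity: float
    relaxation_time: float

    def travelled_distance(self, t: float) -> float:
        """Settling path |v_T|·t covered after time t (seconds)."""
        return abs(self.terminal_velocity) * t


@dataclass
class HalfLifeEstimate:
    """Concentration half-life with its model bounds.

    ``lower_bound``/``upper_bound`` are the two limiting-case
    half-lives (no-lift and full-lift regimes). ``t_half`` and the
    dimensionless sedimentation constant ``K_S`` are optional: they
    are only set when a specific operating point is known.
    """

    lower_bound: float
    upper_bound: float
    t_half: Optional[float] = None
    K_S: Optional[float] = None


_CURVE_SOURCES = ("analytic_upper", "analytic_lower", "simulated", "measured")


@dataclass
class ConcentrationCurve:
    """Effective-concentration ratio C_E(t)/C_0 sampled in time.

    ``source`` records provenance: one of ``analytic_upper``
    (full-cross-section lens model), ``analytic_lower`` (circular-
    segment model), ``simulated`` (particle tracking) or ``measured``
    (counter trace). ``effective_area`` optionally carries the
    corresponding A_E(t) series in m². ``meta`` holds the specs that
    produced the curve.
    """

    times: np.ndarray
    ratio: np.ndarray
    source: str
    effective_area: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.ratio = np.asarray(self.ratio, dtype=float)
        if self.source not in _CURVE_SOURCES:
            raise InvalidParameterError(
                f"curve source must be one of {_CURVE_SOURCES}, got {self.source!r}"
            )
        if self.times.shape != self.ratio.shape:
            raise InvalidParameterError("times and ratio must have the same shape")

    def __len__(self) -> int:
        return len(self.times)
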