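"""Closed-form sedimentation model for a horizontal syringe.

A suspension loaded in a horizontal syringe settles under the
particle–buffer density mismatch. Because all suspended particles
translate downward at the same terminal velocity, the region of the
barrel cross-section still occupied by particles shrinks as a rigid
translation of the initial disk, and the effective concentration
C_E(t)/C_0 equals the ratio of that effective area to the initial
one. Two limiting geometries bracket the dynamics:

* full cross-section effective (high flow-rate: the converging flow
  near the nozzle lifts every particle out) — the effective area is
  the lens-shaped intersection of two equal circles offset by the
  settling path, and the half-life is t_1/2 ≈ 0.8·R_S/|v_T|;
* only the half above a concentric nozzle effective (low flow-rate:
  nothing below the nozzle can ever leave) — the effective area is a
  circular segment and t_1/2 ≈ 0.4·R_S/|v_T|.

Real operating points fall between the two, summarized by the
empirical sedimentation constant K_S ∈ [0.4, 0.8] in
t_1/2 = K_S·R_S/|v_T|.
"""

from __future__ import annotations

import math
import warnings
from typing import Iterable, Sequence, Tuple

import numpy as np

from .specs import (
    BufferSpec,
    ConcentrationCurve,
    HalfLifeEstimate,
    InvalidParameterError,
    Kinematics,
    ModelConstants,
    ParticleSpec,
    SyringeSpec,
)

__all__ = [
    "terminal_velocity",
    "stokes_relaxation_time",
    "kinematics",
    "effective_area_lens",
    "effective_area_segment",
    "concentration_ratio_upper",
    "concentration_ratio_lower",
    "analytic_curve",
    "half_life_boundary_coefficients",
    "half_life_bounds",
    "half_life_estimate",
    "sedimentation_constant",
    "fit_sedimentation_constant",
    "einstein_viscosity_increment",
    "K_S_RANGE",
]

#: Range of the empirical sedimentation constant spanned by the two
#: boundary regimes (rounded to the customary one-decimal values).
K_S_RANGE = (0.4, 0.8)


def terminal_velocity(
    p: ParticleSpec, b: BufferSpec, c: ModelConstants = ModelConstants()
) -> float:
    """Signed Stokes terminal velocity v_T in m/s.

    v_T = 2·g·r_P²·(ρ_B − ρ_P)/(9η): the settling velocity at which
    the net gravitational force on a sphere balances Stokes drag.
    Negative when the particle is denser than the buffer (it sinks),
    positive when lighter (it floats).
    """
    return 2.0 * c.g * p.radius**2 * (b.density - p.density) / (9.0 * b.viscosity)


def stokes_relaxation_time(p: ParticleSpec, b: BufferSpec) -> float:
    """Exponential time constant (s) to reach the terminal velocity.

    τ = m/(6πηr_P) = (2/9)·ρ_P·r_P²/η. For micron-scale particles in
    aqueous buffers this is of order microseconds, so the advection
    model can treat the settling velocity as instantaneous.
    """
    return (2.0 / 9.0) * p.density * p.radius**2 / b.viscosity


def kinematics(
    p: ParticleSpec, b: BufferSpec, c: ModelConstants = ModelConstants()
) -> Kinematics:
    """Bundle terminal velocity and relaxation time."""
    return Kinematics(
        terminal_velocity=terminal_velocity(p, b, c),
        relaxation_time=stokes_relaxation_time(p, b),
    )


def _validate_area_args(R_S, d_T) -> None:
    if np.any(np.asarray(R_S) <= 0):
        raise InvalidParameterError(f"R_S must be > 0, got {R_S}")
    if np.any(np.asarray(d_T) < 0):
        raise InvalidParameterError(f"d_T must be >= 0, got {d_T}")


def effective_area_lens(R_S, d_T):
    """Area (m²) of the intersection of two circles of radius R_S
    whose centres are a distance d_T apart.

    This is the effective area when the whole cross-section counts:
    the initial disk intersected with itself translated downward by
    the settling path d_T. Zero once d_T ≥ 2R_S (complete
    sedimentation). Accepts scalars or arrays.
    """
    _validate_area_args(R_S, d_T)
    R_S, d_T = np.broadcast_arrays(np.asarray(R_S, float), np.asarray(d_T, float))
    x = np.clip(d_T / (2.0 * R_S), 0.0, 1.0)
    area = 2.0 * R_S**2 * np.arccos(x) - 0.5 * d_T * np.sqrt(
        np.maximum(4.0 * R_S**2 - d_T**2, 0.0)
    )
    area = np.where(d_T >= 2.0 * R_S, 0.0, np.maximum(area, 0.0))
    return area if area.ndim else float(area)


def effective_area_segment(R_S, d_T):
    """Area (m²) of the circular segment of radius R_S above a chord
    a height d_T over the centre.

    This is the effective area with a concentric nozzle and no lift:
    only particles initially above the nozzle can leave, and that
    population shrinks to the segment above height d_T. Zero once
    d_T ≥ R_S. Accepts scalars or arrays.
    """
    _validate_area_args(R_S, d_T)
    R_S, d_T = np.broadcast_arrays(np.asarray(R_S, float), np.asarray(d_T, float))
    x = np.clip(d_T / R_S, 0.0, 1.0)
    area = R_S**2 * np.arccos(x) - d_T * np.sqrt(np.maximum(R_S**2 - d_T**2, 0.0))
    area = np.where(d_T >= R_S, 0.0, np.maximum(area, 0.0))
    return area if area.ndim else float(area)


def _ratio(x):
    """(2/π)(acos(x) − x√(1−x²)) with clamping to [0, 1]."""
    x = np.clip(x, 0.0, 1.0)
    val = (2.0 / math.pi) * (np.arccos(x) - x * np.sqrt(1.0 - x**2))
    return np.clip(val, 0.0, 1.0)


def concentration_ratio_upper(v_T_mag, R_S, t):
    """Upper-boundary effective-concentration ratio C_E(t)/C_0.

    Lens model (full cross-section effective):
    (2/π)[acos(x) − x√(1−x²)] with x = |v_T|·t/(2R_S). Equals 1 at
    t = 0 and 0 at t = 2R_S/|v_T|, when the settling path equals the
    barrel diameter. ``v_T_mag = 0`` returns 1 for all t (no
    sedimentation). Accepts scalar or array t.
    """
    if np.any(np.asarray(R_S) <= 0):
        raise InvalidParameterError("R_S must be > 0")
    if np.any(np.asarray(t) < 0):
        raise InvalidParameterError("t must be >= 0")
    if np.any(np.asarray(v_T_mag) < 0):
        raise InvalidParameterError("v_T_mag must be >= 0 (pass |v_T|)")
    t_arr = np.asarray(t, dtype=float)
    if np.all(np.asarray(v_T_mag) == 0):
        out = np.ones_like(t_arr)
        return out if out.ndim else 1.0
    out = _ratio(np.asarray(v_T_mag) * t_arr / (2.0 * np.asarray(R_S)))
    return out if out.ndim else float(out)


def concentration_ratio_lower(v_T_mag, R_S, t):
    """Lower-boundary effective-concentration ratio C_E(t)/C_0.

    Segment model (concentric nozzle, no lift):
    (2/π)[acos(y) − y√(1−y²)] with y = |v_T|·t/R_S. Equals 1 at t = 0
    and 0 at t = R_S/|v_T|, when the settling path equals the barrel
    radius. Same conventions as :func:`concentration_ratio_upper`.
    """
    if np.any(np.asarray(R_S) <= 0):
        raise InvalidParameterError("R_S must be > 0")
    if np.any(np.asarray(t) < 0):
        raise InvalidParameterError("t must be >= 0")
    if np.any(np.asarray(v_T_mag) < 0):
        raise InvalidParameterError("v_T_mag must be >= 0 (pass |v_T|)")
    t_arr = np.asarray(t, dtype=float)
    if np.all(np.asarray(v_T_mag) == 0):
        out = np.ones_like(t_arr)
        return out if out.ndim else 1.0
    out = _ratio(np.asarray(v_T_mag) * t_arr / np.asarray(R_S))
    return out if out.ndim else float(out)


def analytic_curve(
    p: ParticleSpec,
    b: BufferSpec,
    s: SyringeSpec,
    c: ModelConstants = ModelConstants(),
    times=None,
    boundary: str = "upper",
    n_samples: int = 512,
) -> ConcentrationCurve:
    """Sample one boundary curve for the given system.

    If ``times`` is omitted, samples uniformly from 0 to the
    depletion time of the chosen boundary. Returns a
    :class:`ConcentrationCurve` with the matching A_E(t) series.
    """
    v = abs(terminal_velocity(p, b, c))
    if v == 0:
        raise InvalidParameterError(
            "particle and buffer densities are equal: no sedimentation, "
            "the concentration curve is identically 1"
        )
    R = s.barrel_radius
    if boundary == "upper":
        t_end = 2.0 * R / v
        if times is None:
            times = np.linspace(0.0, t_end, n_samples)
        ratio = concentration_ratio_upper(v, R, times)
        area = effective_area_lens(R, v * np.asarray(times, float))
        source = "analytic_upper"
    elif boundary == "lower":
        t_end = R / v
        if times is None:
            times = np.linspace(0.0, t_end, n_samples)
        ratio = concentration_ratio_lower(v, R, times)
        area = effective_area_segment(R, v * np.asarray(times, float))
        source = "analytic_lower"
    else:
        raise InvalidParameterError(f"boundary must be 'upper' or 'lower', got {boundary!r}")
    return ConcentrationCurve(
        times=np.asarray(times, float),
        ratio=np.atleast_1d(ratio),
        source=source,
        effective_area=np.atleast_1d(area),
        meta={"particle": p, "buffer": b, "syringe": s, "constants": c},
    )


def half_life_boundary_coefficients(tol: float = 1e-12) -> Tuple[float, float]:
    """Dimensionless half-life coefficients (lower, upper) of the two
    boundary curves, i.e. the k in t_1/2 = k·R_S/|v_T|.

    Both boundaries share the functional form
    (2/π)[acos(u) − u√(1−u²)] in the scaled settling path u, so the
    half-concentration root u* is solved once by bisection on [0, 1]
    (the function decreases monotonically from 1 to 0). The lower
    boundary uses u = |v_T|t/R_S giving k = u*, the upper uses
    u = |v_T|t/(2R_S) giving k = 2u*; the upper coefficient is twice
    the lower exactly. Rounded to one decimal they are 0.4 and 0.8.
    """
    lo, hi = 0.0, 1.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _ratio(mid) > 0.5:
            lo = mid
        else:
            hi = mid
    root = 0.5 * (lo + hi)
    return root, 2.0 * root


def half_life_bounds(
    p: ParticleSpec,
    b: BufferSpec,
    s: SyringeSpec,
    c: ModelConstants = ModelConstants(),
) -> HalfLifeEstimate:
    """Limiting-case half-life bounds for a particle/buffer/syringe.

    Returns a :class:`HalfLifeEstimate` whose bounds are the lower
    (no-lift) and upper (full-lift) boundary coefficients times
    R_S/|v_T|. Density-matched suspensions (ρ_P = ρ_B) do not
    sediment at all; both bounds are then infinite.
    """
    v = abs(terminal_velocity(p, b, c))
    if v == 0.0:
        return HalfLifeEstimate(lower_bound=math.inf, upper_bound=math.inf)
    k_lo, k_hi = half_life_boundary_coefficients()
    scale = s.barrel_radius / v
    return HalfLifeEstimate(lower_bound=k_lo * scale, upper_bound=k_hi * scale)


def half_life_estimate(
    p: ParticleSpec,
    b: BufferSpec,
    s: SyringeSpec,
    c: ModelConstants = ModelConstants(),
    K_S: float = 0.4,
) -> float:
    """Concentration half-life t_1/2 = K_S·R_S/|v_T| in seconds.

    K_S is the empirical sedimentation constant; it grows with the
    flow-rate between the no-lift (0.4) and full-lift (0.8) regimes.
    A value outside [0.4, 0.8] is allowed but triggers a warning.
    Returns ``inf`` for density-matched suspensions.
    """
    if K_S <= 0:
        raise InvalidParameterError(f"K_S must be > 0, got {K_S}")
    if not (K_S_RANGE[0] <= K_S <= K_S_RANGE[1]):
        warnings.warn(
            f"K_S={K_S} is outside the model range {K_S_RANGE}; "
            "the estimate extrapolates beyond the boundary regimes",
            stacklevel=2,
        )
    v = abs(terminal_velocity(p, b, c))
    if v == 0.0:
        return math.inf
    return K_S * s.barrel_radius / v


def sedimentation_constant(t_half: float, v_T_mag: float, R_S: float) -> float:
    """Invert t_1/2 = K_S·R_S/|v_T| for the sedimentation constant."""
    if v_T_mag <= 0 or R_S <= 0:
        raise InvalidParameterError("v_T_mag and R_S must be > 0")
    if t_half < 0:
        raise InvalidParameterError("t_half must be >= 0")
    return t_half * v_T_mag / R_S


def fit_sedimentation_constant(
    points: Sequence[Tuple[float, float, float]]
) -> Tuple[float, float]:
    """Least-squares fit of pooled half-lives to t_1/2 = K_S·R_S/|v_T|.

    ``points`` is an iterable of (t_half [s], R_S [m], v_T_mag [m/s])
    triples from different experiments/simulations. The model has no
    intercept, so the regression is through the origin with predictor
    x = R_S/v_T; the coefficient of determination is computed against
    the zero-intercept model, R² = 1 − Σ(y−ŷ)²/Σy².
    """
    pts = list(points)
    if len(pts) < 2:
        raise InvalidParameterError(
            f"need at least 2 (t_half, R_S, v_T) points to fit, got {len(pts)}"
        )
    t = np.array([q[0] for q in pts], dtype=float)
    x = np.array([q[1] / q[2] for q in pts], dtype=float)
    if np.any(x <= 0):
        raise InvalidParameterError("R_S/v_T must be positive for every point")
    K = float(np.dot(x, t) / np.dot(x, x))
    ss_res = float(np.sum((t - K * x) ** 2))
    ss_tot = float(np.sum(t**2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return K, r2


def einstein_viscosity_increment(
    p: ParticleSpec, number_concentration: float, b: BufferSpec
) -> float:
    """Viscosity increase (Pa·s) due to the suspended particles.

    Einstein's dilute-suspension relation Δη = 2.5·φ·η with volume
    fraction φ = n·(4/3)πr_P³. Used to confirm that at typical
    working concentrations (~10⁶ particles/ml) the suspension leaves
    the buffer viscosity essentially unchanged.
    """
    if number_concentration < 0:
        raise InvalidParameterError("number concentration must be >= 0")
    phi = number_concentration * p.volume
    return 2.5 * phi * b.viscosity
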