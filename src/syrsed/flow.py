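"""Steady creeping-flow velocity field inside the syringe barrel.

Geometry and conventions: the barrel is a horizontal cylinder of
radius R_S and length L_S; x is horizontal-transverse, y vertical
(gravity along −y), z axial with the plunger at z = 0 and the outlet
on the end wall at z = L_S. The outlet is a small tube of radius R_O
whose centre sits at (0, outlet_offset) on the end wall.

Two backends provide the velocity field:

``superposition`` (default)
    A fast semi-analytic closure: Poiseuille flow in the bulk of the
    barrel blending into a half-space point sink at the outlet
    centre. The sink is capped inside one outlet radius (removing
    the 1/r² singularity) and smoothly tapered to zero two barrel
    radii upstream of the end wall; the Poiseuille amplitude at each
    axial station is rescaled so the net axial flux through every
    cross-section equals the imposed flow-rate Q. It supports
    eccentric outlets. The wall no-slip condition is not honoured by
    the sink term — accepted, since particle capture happens at the
    wall anyway and the model needs the field mainly for the lift
    near the nozzle and the bulk advection.

``stokes_axisym``
    A numerical axisymmetric creeping-flow solution of the
    stream-function biharmonic problem E⁴ψ = 0 on an (r, z) grid,
    with Poiseuille inflow at the plunger, no-slip walls and
    Poiseuille outflow into the outlet tube. Concentric outlets
    only; used to validate the superposition closure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.interpolate import RegularGridInterpolator

from .specs import InvalidParameterError, SyringeSpec

__all__ = [
    "DomainError",
    "UnsupportedConfigurationError",
    "FlowField",
    "poiseuille_velocity",
    "sink_velocity",
    "build_flow_field",
    "cross_section_flux",
    "export_field",
]


class DomainError(ValueError):
    """Point outside the fluid domain."""


class UnsupportedConfigurationError(ValueError):
    """Backend cannot handle the requested geometry."""


def _smoothstep(u):
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def poiseuille_velocity(s: SyringeSpec, Q: float, point) -> np.ndarray:
    """Fully developed laminar pipe-flow velocity at a point.

    Axial component 2Q/(πR_S²)·(1 − ρ²/R_S²), zero transverse
    components. Raises :class:`DomainError` for points outside the
    barrel.
    """
    x, y, z = (float(v) for v in point)
    rho2 = x * x + y * y
    R2 = s.barrel_radius**2
    if rho2 > R2 * (1 + 1e-12) or z < -1e-12 or z > s.barrel_length * (1 + 1e-12):
        raise DomainError(f"point {point} is outside the barrel")
    vz = 2.0 * Q / (math.pi * R2) * (1.0 - rho2 / R2)
    return np.array([0.0, 0.0, vz])


def sink_velocity(outlet_center, Q: float, point, cap_radius: float = None) -> np.ndarray:
    """Half-space point-sink velocity at a point.

    Magnitude Q/(2πr²) directed toward the outlet centre, where r is
    the distance to the centre. Inside ``cap_radius`` the magnitude
    is clamped to its value at the cap (removing the singularity of
    the idealized sink); the default cap is zero (pure sink).
    """
    c = np.asarray(outlet_center, dtype=float)
    p = np.asarray(point, dtype=float)
    d = c - p
    r = float(np.linalg.norm(d))
    if r == 0.0:
        return np.zeros(3)
    r_eff = max(r, cap_radius or 0.0)
    mag = Q / (2.0 * math.pi * r_eff**2)
    return mag * d / r


@dataclass
class FlowField:
    """Velocity field inside the barrel.

    ``evaluate`` maps points of shape (..., 3) — columns (x, y, z) in
    metres — to velocity vectors in m/s of the same shape. The field
    is vectorized; single points may be passed as length-3 sequences.
    """

    syringe: SyringeSpec
    flow_rate: float
    backend: str
    _eval: Callable = field(repr=False)

    def evaluate(self, points) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        single = pts.ndim == 1
        out = self._eval(np.atleast_2d(pts))
        return out[0] if single else out.reshape(pts.shape)


# --------------------------------------------------------------------------
# superposition backend


class _Superposition:
    """Flux-preserving Poiseuille + capped sink blend (unit machinery)."""

    #: sink taper extends this many barrel radii upstream of the end wall
    TAPER_RADII = 2.0

    def __init__(self, s: SyringeSpec, Q: float):
        self.s = s
        self.Q = Q
        self.center = np.array([0.0, s.outlet_offset, s.barrel_length])
        self.R2 = s.barrel_radius**2
        self.pois_scale = 2.0 / (math.pi * self.R2)  # axial vel per unit Q on axis
        self.taper_len = self.TAPER_RADII * s.barrel_radius
        self._build_flux_correction()

    def _sink_unit(self, pts: np.ndarray) -> np.ndarray:
        """Tapered, capped sink velocity per unit flow-rate.

        The cap radius is a quarter outlet radius: large enough to
        bound the step size of a tracked particle, small enough that
        the sink still carries essentially the whole flow-rate
        through the outlet disk (a cap at the full outlet radius
        would starve the outlet and push the flux correction into
        the end wall).
        """
        d = self.center[None, :] - pts
        r = np.linalg.norm(d, axis=1)
        r_eff = np.maximum(r, 0.25 * self.s.outlet_radius)
        mag = 1.0 / (2.0 * math.pi * r_eff**2)
        h = self.s.barrel_length - pts[:, 2]
        taper = 1.0 - _smoothstep(h / self.taper_len)
        with np.errstate(invalid="ignore", divide="ignore"):
            unit = np.where(r[:, None] > 0, d / r[:, None], 0.0)
        return (mag * taper)[:, None] * unit

    def _build_flux_correction(self, n_z: int = 101, n_r: int = 96, n_th: int = 64):
        """Tabulate c_P(z) so that total axial flux equals Q at every z.

        The Poiseuille term carries flux c_P(z)·Q and the sink term
        F_sink(z); setting c_P = 1 − F_sink/Q (per unit Q) keeps the
        total at Q. F_sink is evaluated by midpoint polar quadrature
        over the cross-section.
        """
        L, R = self.s.barrel_length, self.s.barrel_radius
        z0 = max(0.0, L - self.taper_len)
        z_tab = np.linspace(z0, L, n_z)
        r_mid = (np.arange(n_r) + 0.5) * (R / n_r)
        th = (np.arange(n_th) + 0.5) * (2.0 * math.pi / n_th)
        rr, tt = np.meshgrid(r_mid, th, indexing="ij")
        xs, ys = (rr * np.cos(tt)).ravel(), (rr * np.sin(tt)).ravel()
        w = (rr * (R / n_r) * (2.0 * math.pi / n_th)).ravel()  # area weights
        flux = np.empty(n_z)
        pts = np.column_stack([xs, ys, np.zeros_like(xs)])
        for k, z in enumerate(z_tab):
            pts[:, 2] = z
            flux[k] = float(np.dot(self._sink_unit(pts)[:, 2], w))
        self._z_tab = z_tab
        self._cp_tab = 1.0 - flux

    def _cp(self, z: np.ndarray) -> np.ndarray:
        return np.interp(z, self._z_tab, self._cp_tab, left=1.0, right=self._cp_tab[-1])

    def __call__(self, pts: np.ndarray) -> np.ndarray:
        if self.Q == 0.0:
            return np.zeros_like(pts)
        rho2 = pts[:, 0] ** 2 + pts[:, 1] ** 2
        vz_pois = self.pois_scale * np.maximum(1.0 - rho2 / self.R2, 0.0)
        v = self._sink_unit(pts)
        v[:, 2] += self._cp(pts[:, 2]) * vz_pois
        return self.Q * v


# --------------------------------------------------------------------------
# stokes_axisym backend


class _StokesAxisym:
    """Axisymmetric creeping flow via the stream function.

    Solves E⁴ψ = 0 (E² = ∂rr − (1/r)∂r + ∂zz) as the coupled system
    E²ψ = χ, E²χ = 0 with second-order finite differences and a
    direct sparse solve. Boundary conditions: ψ = 0 on the axis;
    ψ = Q/2π and ∂ψ/∂r = 0 (no-slip) on the barrel wall; Poiseuille
    inflow profile at the plunger; Poiseuille outflow into the
    outlet tube on the end wall, solid no-slip wall elsewhere on it.
    Wall vorticity rows use the standard ghost-node (Thom) closure.
    """

    def __init__(self, s: SyringeSpec, Q: float, nr: int = 64, nz: int = 256):
        if s.outlet_offset != 0.0:
            raise UnsupportedConfigurationError(
                "stokes_axisym supports concentric outlets only "
                f"(outlet_offset={s.outlet_offset}); use the superposition backend"
            )
        self.s, self.Q = s, Q
        R = s.barrel_radius
        # solve in units of R_S with psi scaled by Q/2pi: keeps the
        # biharmonic system well conditioned regardless of SI magnitudes
        L = s.barrel_length / R
        RO = s.outlet_radius / R
        r = np.linspace(0.0, 1.0, nr + 1)
        z = np.linspace(0.0, L, nz + 1)
        dr, dz = r[1] - r[0], z[1] - z[0]
        psi_w = 1.0

        def psi_pipe(rr, a):
            # scaled stream function of Poiseuille flow in a pipe of radius a
            return 2.0 * (rr**2 / a**2) - rr**4 / a**4

        if Q == 0.0:
            self.u_r = np.zeros((nr + 1, nz + 1))
            self.u_z = np.zeros((nr + 1, nz + 1))
        else:
            psi = self._solve(r, z, dr, dz, psi_w, psi_pipe, RO)
            u_r, u_z = self._velocities(psi, r, dr, dz)
            vel_scale = Q / (2.0 * math.pi * R**2)
            self.u_r, self.u_z = vel_scale * u_r, vel_scale * u_z
        self.r_grid, self.z_grid = r * R, z * R
        self._interp_ur = RegularGridInterpolator(
            (self.r_grid, self.z_grid), self.u_r, bounds_error=False, fill_value=None
        )
        self._interp_uz = RegularGridInterpolator(
            (self.r_grid, self.z_grid), self.u_z, bounds_error=False, fill_value=None
        )

    def _solve(self, r, z, dr, dz, psi_w, psi_pipe, RO):
        nr, nz = len(r) - 1, len(z) - 1
        npts = (nr + 1) * (nz + 1)

        def kpsi(i, j):
            return i * (nz + 1) + j

        def kchi(i, j):
            return npts + i * (nz + 1) + j

        rows, cols, vals, rhs = [], [], [], np.zeros(2 * npts)
        eq = 0

        def add(row_entries, b=0.0):
            nonlocal eq
            for c, v in row_entries:
                rows.append(eq)
                cols.append(c)
                vals.append(v)
            rhs[eq] = b
            eq += 1

        idr2, idz2 = 1.0 / dr**2, 1.0 / dz**2
        for i in range(nr + 1):
            ri = r[i]
            for j in range(nz + 1):
                if i == 0:  # axis: psi = 0, chi = 0
                    add([(kpsi(i, j), 1.0)], 0.0)
                    add([(kchi(i, j), 1.0)], 0.0)
                    continue
                if i == nr:  # barrel wall: psi fixed, Thom closure for chi
                    add([(kpsi(i, j), 1.0)], psi_w)
                    add([(kchi(i, j), 1.0), (kpsi(i - 1, j), -2.0 * idr2)],
                        -2.0 * idr2 * psi_w)
                    continue
                c_rp = idr2 - 1.0 / (2.0 * dr * ri)
                c_rm = idr2 + 1.0 / (2.0 * dr * ri)
                if j == 0:  # plunger inlet: Poiseuille profile, dpsi/dz = 0
                    add([(kpsi(i, j), 1.0)], psi_pipe(ri, r[-1]))
                    add([(kchi(i, j), 1.0),
                         (kpsi(i + 1, j), -c_rp), (kpsi(i - 1, j), -c_rm),
                         (kpsi(i, j), 2.0 * idr2 + 2.0 * idz2),
                         (kpsi(i, j + 1), -2.0 * idz2)], 0.0)
                    continue
                if j == nz:  # end wall / outlet tube entrance
                    val = psi_pipe(ri, RO) if ri <= RO else psi_w
                    add([(kpsi(i, j), 1.0)], val)
                    add([(kchi(i, j), 1.0),
                         (kpsi(i + 1, j), -c_rp), (kpsi(i - 1, j), -c_rm),
                         (kpsi(i, j), 2.0 * idr2 + 2.0 * idz2),
                         (kpsi(i, j - 1), -2.0 * idz2)], 0.0)
                    continue
                # interior: E2 psi - chi = 0 ; E2 chi = 0
                add([(kpsi(i + 1, j), c_rp), (kpsi(i - 1, j), c_rm),
                     (kpsi(i, j), -2.0 * idr2 - 2.0 * idz2),
                     (kpsi(i, j + 1), idz2), (kpsi(i, j - 1), idz2),
                     (kchi(i, j), -1.0)], 0.0)
                add([(kchi(i + 1, j), c_rp), (kchi(i - 1, j), c_rm),
                     (kchi(i, j), -2.0 * idr2 - 2.0 * idz2),
                     (kchi(i, j + 1), idz2), (kchi(i, j - 1), idz2)], 0.0)

        A = sp.csr_matrix((vals, (rows, cols)), shape=(2 * npts, 2 * npts))
        sol = spla.spsolve(A.tocsc(), rhs)
        return sol[:npts].reshape(nr + 1, nz + 1)

    @staticmethod
    def _velocities(psi, r, dr, dz):
        nr1, nz1 = psi.shape
        u_z = np.zeros_like(psi)
        u_r = np.zeros_like(psi)
        # u_z = (1/r) dpsi/dr
        u_z[1:-1, :] = (psi[2:, :] - psi[:-2, :]) / (2.0 * dr) / r[1:-1, None]
        u_z[0, :] = 2.0 * psi[1, :] / dr**2  # axis limit psi ~ u_z r^2/2
        u_z[-1, :] = 0.0  # no-slip wall
        # u_r = -(1/r) dpsi/dz
        dpsi_dz = np.zeros_like(psi)
        dpsi_dz[:, 1:-1] = (psi[:, 2:] - psi[:, :-2]) / (2.0 * dz)
        dpsi_dz[:, 0] = (psi[:, 1] - psi[:, 0]) / dz
        dpsi_dz[:, -1] = (psi[:, -1] - psi[:, -2]) / dz
        u_r[1:, :] = -dpsi_dz[1:, :] / r[1:, None]
        return u_r, u_z

    def __call__(self, pts: np.ndarray) -> np.ndarray:
        x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
        rho = np.hypot(x, y)
        rc = np.clip(rho, self.r_grid[0], self.r_grid[-1])
        zc = np.clip(z, self.z_grid[0], self.z_grid[-1])
        q = np.column_stack([rc, zc])
        ur = self._interp_ur(q)
        uz = self._interp_uz(q)
        out = np.zeros_like(pts)
        with np.errstate(invalid="ignore", divide="ignore"):
            cx = np.where(rho > 0, x / rho, 0.0)
            cy = np.where(rho > 0, y / rho, 0.0)
        out[:, 0] = ur * cx
        out[:, 1] = ur * cy
        out[:, 2] = uz
        return out


# --------------------------------------------------------------------------


def build_flow_field(
    s: SyringeSpec, Q: float, backend: str = "superposition", **kwargs
) -> FlowField:
    """Construct the velocity field for a syringe at flow-rate Q (m³/s).

    ``backend`` is ``"superposition"`` (default, any outlet position)
    or ``"stokes_axisym"`` (concentric only; accepts ``nr``/``nz``
    grid sizes). Q = 0 yields the zero field.
    """
    if Q < 0:
        raise InvalidParameterError(f"flow rate must be >= 0, got {Q}")
    if backend == "superposition":
        impl = _Superposition(s, Q)
    elif backend == "stokes_axisym":
        impl = _StokesAxisym(s, Q, **kwargs)
    else:
        raise InvalidParameterError(
            f"unknown backend {backend!r}; use 'superposition' or 'stokes_axisym'"
        )
    return FlowField(syringe=s, flow_rate=Q, backend=backend, _eval=impl)


def cross_section_flux(f: FlowField, z: float, n_r: int = 128, n_th: int = 96) -> float:
    """Net axial volume flux (m³/s) through the cross-section at z.

    Midpoint polar quadrature of the axial velocity over the barrel
    disk; used to verify mass conservation of the field backends.
    """
    s = f.syringe
    if z < 0 or z > s.barrel_length:
        raise DomainError(f"z={z} outside barrel [0, {s.barrel_length}]")
    R = s.barrel_radius
    r_mid = (np.arange(n_r) + 0.5) * (R / n_r)
    th = (np.arange(n_th) + 0.5) * (2.0 * math.pi / n_th)
    rr, tt = np.meshgrid(r_mid, th, indexing="ij")
    pts = np.column_stack(
        [(rr * np.cos(tt)).ravel(), (rr * np.sin(tt)).ravel(),
         np.full(rr.size, float(z))]
    )
    w = (rr * (R / n_r) * (2.0 * math.pi / n_th)).ravel()
    vz = f.evaluate(pts)[:, 2]
    return float(np.dot(vz, w))


def export_field(f: FlowField, path, n_x: int = 21, n_y: int = 21, n_z: int = 41) -> None:
    """Sample the field on a regular grid and write tabular text.

    One row per in-barrel sample: x y z vx vy vz (SI units).
    """
    s = f.syringe
    R, L = s.barrel_radius, s.barrel_length
    xs = np.linspace(-R, R, n_x)
    ys = np.linspace(-R, R, n_y)
    zs = np.linspace(0.0, L, n_z)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    inside = pts[:, 0] ** 2 + pts[:, 1] ** 2 <= R**2
    pts = pts[inside]
    v = f.evaluate(pts)
    header = (
        f"flow field export: backend={f.backend} Q={f.flow_rate} m^3/s\n"
        f"syringe: R_S={R} L_S={L} R_O={s.outlet_radius} offset={s.outlet_offset}\n"
        "x y z vx vy vz"
    )
    np.savetxt(path, np.column_stack([pts, v]), header=header)
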