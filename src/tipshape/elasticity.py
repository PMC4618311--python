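"""Cell-wall elasticity: thin-shell inflation and material-property estimation.

The wall is modelled as a thin, homogeneous, isotropic, linearly elastic
shell loaded by a uniform internal (turgor) pressure.  All pressures are
normalised by the turgor pressure ``P``, so the only material parameters are
the modulus ratio ``E/P`` (dimensionless) and the Poisson ratio ``nu``.  The
stress-free (resting) geometry is what a plasmolysed cell relaxes to; the
turgid geometry is the equilibrium of the resting shell inflated at unit
normalised pressure.

The solver discretises the axisymmetric meridian into nodes and minimises
the total potential energy

    Pi = int W dA0  -  p * V(deformed)

over the node positions, with ``W`` the membrane strain-energy density per
unit resting area written in engineering strains of the meridional and
circumferential stretches, and ``V`` the enclosed volume (so pressure acts
as a follower load, always normal to the deformed surface).  A
``bending_shear`` variant adds a plate-like bending energy on the change of
curvature; transverse shear compliance is not modelled separately (the
Kirchhoff thin-shell limit).

The modulus enters only through the membrane stiffness ``E*t`` and bending
stiffness ``E*t^3/12``; the wall thickness is specified as a
thickness-to-radius ratio.  The default ratio is calibrated so that the
thin-cylinder estimator maps the benchmark plasmolysis strains
(0.13 meridional, 0.24 circumferential) to ``E/P ~ 44`` — the thickness
itself is not an observable of this analysis, only ``E*t/(P*R)`` is.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import interpolate, optimize
from scipy.spatial import cKDTree

from .geometry import MeridianContour, PlanarOutline, reconstruct_meridian

__all__ = [
    "DEFAULT_THICKNESS_TO_RADIUS",
    "ElasticParams",
    "ShellSolution",
    "cylinder_estimator",
    "inflate_shell",
    "fit_elastic_params",
    "inflate_septum",
    "outline_to_meridian",
]

#: Reverse-engineered so that strains (0.13, 0.24) give E/P ~ 44 via the
#: thin-cylinder estimator; not an independently measured wall thickness.
DEFAULT_THICKNESS_TO_RADIUS = 0.0974


@dataclass
class ElasticParams:
    """Normalised wall material properties.

    ``e_over_p``: Young's modulus over turgor pressure (> 0).
    ``nu``: Poisson ratio; near-zero and slightly negative values are
    admissible (2D fibre networks under tension can have nu <= 0).
    ``thickness_to_radius``: wall thickness as a fraction of the cell
    radius; enters only through the products ``E*t`` and ``E*t^3``.
    """

    e_over_p: float
    nu: float
    thickness_to_radius: float = DEFAULT_THICKNESS_TO_RADIUS

    def __post_init__(self) -> None:
        if self.e_over_p <= 0:
            raise ValueError("E/P must be positive")
        if not (-1.0 < self.nu < 0.5):
            raise ValueError(f"Poisson ratio {self.nu} outside (-1, 0.5)")
        if self.thickness_to_radius <= 0:
            raise ValueError("thickness_to_radius must be positive")


@dataclass
class ShellSolution:
    resting: MeridianContour
    deformed: MeridianContour
    lambda_s: np.ndarray  # meridional stretch per segment
    lambda_theta: np.ndarray  # circumferential stretch per segment
    model: str = "membrane"
    residual: float = 0.0
    params: ElasticParams | None = None


# --------------------------------------------------------------------------
# thin-cylinder estimator
# --------------------------------------------------------------------------

def cylinder_estimator(
    eps_meridional: float,
    eps_circumferential: float,
    thickness_to_radius: float = DEFAULT_THICKNESS_TO_RADIUS,
) -> ElasticParams:
    """Material properties from mid-cell plasmolysis strains.

    In a thin-walled cylindrical pressure vessel the circumferential stress
    is twice the meridional stress, so the strain ratio
    ``rho = eps_circ / eps_merid`` fixes the Poisson ratio:

        nu = (0.5 * rho - 1) / (rho - 0.5)

    and the circumferential strain then fixes the modulus:

        E/P = (R/t) * (1 - nu/2) / eps_circ.

    Raises ``ValueError`` outside the thin-cylinder regime (``rho <= 0.5``)
    or when the implied ``nu`` hits the admissibility boundary (``rho = 1``
    maps to ``nu = -1``).
    """
    if eps_meridional <= 0 or eps_circumferential <= 0:
        raise ValueError("plasmolysis strains must be positive")
    rho = eps_circumferential / eps_meridional
    if rho <= 0.5:
        raise ValueError(f"strain ratio rho={rho:.3f} <= 0.5: outside the "
                         "thin-cylinder regime")
    nu = (0.5 * rho - 1.0) / (rho - 0.5)
    if nu <= -1.0 + 1e-12:
        raise ValueError(f"strain ratio rho={rho:.3f} implies nu={nu:.3f} at or "
                         "beyond the admissibility boundary nu=-1")
    e_over_p = (1.0 / thickness_to_radius) * (1.0 - nu / 2.0) / eps_circumferential
    return ElasticParams(e_over_p=e_over_p, nu=nu,
                         thickness_to_radius=thickness_to_radius)


# --------------------------------------------------------------------------
# discrete shell mesh
# --------------------------------------------------------------------------

class _ShellMesh:
    """Discrete axisymmetric shell: resting metric + boundary conditions.

    ``boundary``:
      - "closed": full meridian pole-to-pole (r = 0 at both ends); the last
        node's z is the translation gauge.
      - "open": pole to flank; the base node's z is fixed (gauge) and the
        enclosed volume is closed by a flat lid at the base, which applies
        the correct axial tension from the rest of the cell.
      - "clamped": pole to a fixed edge (both r and z pinned), used for the
        septum clamped at the old-wall junction.
    """

    def __init__(self, L0: np.ndarray, rho0: np.ndarray, boundary: str,
                 C: float, nu: float, D: float = 0.0,
                 kappa_s0: np.ndarray | None = None,
                 kappa_t0: np.ndarray | None = None,
                 edge: tuple[float, float] | None = None):
        self.L0 = np.asarray(L0, dtype=float)          # (n-1,) resting lengths
        self.rho0 = np.asarray(rho0, dtype=float)      # (n,) resting radii
        self.n = len(self.rho0)
        self.boundary = boundary
        self.C = C        # membrane stiffness  E t / (1 - nu^2), units P*um
        self.nu = nu
        self.D = D        # bending stiffness E t^3 / (12 (1 - nu^2)), P*um^3
        self.kappa_s0 = kappa_s0
        self.kappa_t0 = kappa_t0
        self.edge = edge
        self.rho0m = 0.5 * (self.rho0[1:] + self.rho0[:-1])
        self.A0 = 2.0 * np.pi * self.rho0m * self.L0

    # -- packing ------------------------------------------------------------

    def pack(self, r: np.ndarray, z: np.ndarray) -> np.ndarray:
        if self.boundary == "closed":
            return np.concatenate([r[1:-1], z[:-1]])
        if self.boundary == "open":
            return np.concatenate([r[1:], z[:-1]])
        if self.boundary == "clamped":
            return np.concatenate([r[1:-1], z[:-1]])
        raise ValueError(self.boundary)

    def unpack(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        n = self.n
        r = np.empty(n)
        z = np.empty(n)
        if self.boundary == "closed":
            r[0] = r[-1] = 0.0
            r[1:-1] = x[: n - 2]
            z[:-1] = x[n - 2:]
            z[-1] = 0.0
        elif self.boundary == "open":
            r[0] = 0.0
            r[1:] = x[: n - 1]
            z[:-1] = x[n - 1:]
            z[-1] = 0.0
        else:  # clamped
            r[0] = 0.0
            r[-1], z_e = self.edge
            r[1:-1] = x[: n - 2]
            z[:-1] = x[n - 2:]
            z[-1] = z_e
        return r, z

    # -- energy and gradient ------------------------------------------------

    def membrane_energy_grad(self, x: np.ndarray, pressure: float):
        with np.errstate(over="ignore", invalid="ignore"):
            return self._membrane_energy_grad(x, pressure)

    def _membrane_energy_grad(self, x: np.ndarray, pressure: float):
        r, z = self.unpack(x)
        dr = np.diff(r)
        dz = np.diff(z)
        l = np.hypot(dr, dz)
        eps_s = l / self.L0 - 1.0
        rm = 0.5 * (r[1:] + r[:-1])
        eps_t = rm / self.rho0m - 1.0
        C, nu = self.C, self.nu
        W = 0.5 * C * (eps_s**2 + 2 * nu * eps_s * eps_t + eps_t**2)
        E = float(np.sum(W * self.A0))
        Ns = C * (eps_s + nu * eps_t) * self.A0
        Nt = C * (eps_t + nu * eps_s) * self.A0

        g_r = np.zeros_like(r)
        g_z = np.zeros_like(z)
        cs_r = Ns * dr / (l * self.L0)
        cs_z = Ns * dz / (l * self.L0)
        np.add.at(g_r, np.arange(1, self.n), cs_r)
        np.add.at(g_r, np.arange(0, self.n - 1), -cs_r)
        np.add.at(g_z, np.arange(1, self.n), cs_z)
        np.add.at(g_z, np.arange(0, self.n - 1), -cs_z)
        ct = 0.5 * Nt / self.rho0m
        np.add.at(g_r, np.arange(1, self.n), ct)
        np.add.at(g_r, np.arange(0, self.n - 1), ct)

        # volume (meridian descending in z; closed by flat lid for "open")
        V = float(-np.pi * np.sum(rm**2 * dz))
        gV_r = np.zeros_like(r)
        gV_z = np.zeros_like(z)
        vr = -np.pi * rm * dz
        np.add.at(gV_r, np.arange(1, self.n), vr)
        np.add.at(gV_r, np.arange(0, self.n - 1), vr)
        np.add.at(gV_z, np.arange(1, self.n), -np.pi * rm**2)
        np.add.at(gV_z, np.arange(0, self.n - 1), np.pi * rm**2)

        total = E - pressure * V
        g_r -= pressure * gV_r
        g_z -= pressure * gV_z
        grad = self._pack_grad(g_r, g_z)
        return total, grad

    def _pack_grad(self, g_r: np.ndarray, g_z: np.ndarray) -> np.ndarray:
        if self.boundary == "closed":
            return np.concatenate([g_r[1:-1], g_z[:-1]])
        if self.boundary == "open":
            return np.concatenate([g_r[1:], g_z[:-1]])
        return np.concatenate([g_r[1:-1], g_z[:-1]])

    def bending_energy_grad(self, x: np.ndarray):
        """Plate-like bending energy on the change of curvature, with an
        analytic gradient (discrete turning angles; circumferential
        curvature from the averaged segment normal angle)."""
        r, z = self.unpack(x)
        dr = np.diff(r)
        dz = np.diff(z)
        l = np.hypot(dr, dz)
        inv_l2 = 1.0 / (l * l)
        # turning angle beta_i at interior nodes between segments i-1 and i
        ux, uy = dr[:-1], dz[:-1]
        wx, wy = dr[1:], dz[1:]
        beta = np.arctan2(ux * wy - uy * wx, ux * wx + uy * wy)
        lbar = 0.5 * (l[:-1] + l[1:])
        kappa_s = -beta / lbar  # outward-convex positive (z descending)
        phi_seg = np.arctan2(-dz, dr)
        phi = 0.5 * (phi_seg[:-1] + phi_seg[1:])
        r_int = np.maximum(r[1:-1], 1e-9)
        kappa_t = np.sin(phi) / r_int
        dks = kappa_s - self.kappa_s0[1:-1]
        dkt = kappa_t - self.kappa_t0[1:-1]
        A0n = np.zeros(self.n)
        np.add.at(A0n, np.arange(1, self.n), 0.5 * self.A0)
        np.add.at(A0n, np.arange(0, self.n - 1), 0.5 * self.A0)
        Ai = A0n[1:-1]
        D, nu = self.D, self.nu
        E = float(np.sum(0.5 * D * (dks**2 + 2 * nu * dks * dkt + dkt**2) * Ai))
        Ms = D * (dks + nu * dkt) * Ai  # dE/d kappa_s at node i
        Mt = D * (dkt + nu * dks) * Ai  # dE/d kappa_t

        g_r = np.zeros_like(r)
        g_z = np.zeros_like(z)
        idx = np.arange(1, self.n - 1)

        # kappa_s = -beta/lbar:  dE += Ms * (-(dbeta)/lbar + beta*dlbar/lbar^2)
        cb = -Ms / lbar                      # coefficient on dbeta
        cl = Ms * beta / lbar**2             # coefficient on dlbar
        # dbeta: beta = theta(w) - theta(u); dtheta(v)/dv = perp(v)/|v|^2
        pux, puy = -uy * inv_l2[:-1], ux * inv_l2[:-1]
        pwx, pwy = -wy * inv_l2[1:], wx * inv_l2[1:]
        # u = x_i - x_{i-1}: d theta(u)/dx_i = perp(u)/|u|^2, /dx_{i-1} = -...
        np.add.at(g_r, idx - 1, cb * pux)
        np.add.at(g_z, idx - 1, cb * puy)
        np.add.at(g_r, idx, cb * (-pux - pwx))
        np.add.at(g_z, idx, cb * (-puy - pwy))
        np.add.at(g_r, idx + 1, cb * pwx)
        np.add.at(g_z, idx + 1, cb * pwy)
        # dlbar = 0.5 (d|u| + d|w|);  d|u|/dx_i = u/|u|, /dx_{i-1} = -u/|u|
        uhx, uhy = ux / l[:-1], uy / l[:-1]
        whx, why = wx / l[1:], wy / l[1:]
        np.add.at(g_r, idx - 1, -0.5 * cl * uhx)
        np.add.at(g_z, idx - 1, -0.5 * cl * uhy)
        np.add.at(g_r, idx, 0.5 * cl * (uhx - whx))
        np.add.at(g_z, idx, 0.5 * cl * (uhy - why))
        np.add.at(g_r, idx + 1, 0.5 * cl * whx)
        np.add.at(g_z, idx + 1, 0.5 * cl * why)

        # kappa_t = sin(phi)/r_i
        cphi = Mt * np.cos(phi) / r_int
        crr = -Mt * np.sin(phi) / r_int**2
        np.add.at(g_r, idx, crr)
        # phi = (phi_seg[i-1] + phi_seg[i])/2; phi_seg_j = theta(q_j),
        # q_j = (dr_j, -dz_j): dtheta(q)/dq = perp(q)/|q|^2
        pqx = dz * inv_l2   # perp(q)_x = -q_y = dz
        pqy = dr * inv_l2   # perp(q)_y = q_x = dr
        # dq_j/dr_{j+1} = (1,0); /dr_j = (-1,0); /dz_{j+1} = (0,-1); /dz_j = (0,1)
        half_u = 0.5 * cphi
        # segment i-1 (left of node i): endpoints i-1, i
        np.add.at(g_r, idx, half_u * pqx[:-1])
        np.add.at(g_r, idx - 1, -half_u * pqx[:-1])
        np.add.at(g_z, idx, -half_u * pqy[:-1])
        np.add.at(g_z, idx - 1, half_u * pqy[:-1])
        # segment i (right of node i): endpoints i, i+1
        np.add.at(g_r, idx + 1, half_u * pqx[1:])
        np.add.at(g_r, idx, -half_u * pqx[1:])
        np.add.at(g_z, idx + 1, -half_u * pqy[1:])
        np.add.at(g_z, idx, half_u * pqy[1:])

        return E, self._pack_grad(g_r, g_z)

    def objective(self, x: np.ndarray, pressure: float, with_bending: bool,
                  scale: float = 1.0):
        E, g = self.membrane_energy_grad(x, pressure)
        if with_bending and self.D > 0:
            with np.errstate(over="ignore", invalid="ignore"):
                Eb, gb = self.bending_energy_grad(x)
            E += Eb
            g = g + gb
        if not np.isfinite(E):  # runaway trial step: force a backtrack
            E = 1e30
            g = np.nan_to_num(g, nan=0.0, posinf=1e15, neginf=-1e15)
        return E / scale, g / scale


def _solution_meridian(r: np.ndarray, z: np.ndarray) -> MeridianContour:
    dr = np.diff(r)
    dz = np.diff(z)
    l = np.hypot(dr, dz)
    s = np.concatenate([[0.0], np.cumsum(l)])
    phi_seg = np.arctan2(-dz, dr)
    phi = np.empty_like(r)
    phi[1:-1] = 0.5 * (phi_seg[:-1] + phi_seg[1:])
    phi[0] = 0.0 if abs(r[0]) < 1e-9 else phi_seg[0]
    phi[-1] = phi_seg[-1] if abs(r[-1]) > 1e-9 else np.pi
    lbar = 0.5 * (l[:-1] + l[1:])
    kappa_s = np.empty_like(r)
    ux, uy = dr[:-1] / l[:-1], dz[:-1] / l[:-1]
    wx, wy = dr[1:] / l[1:], dz[1:] / l[1:]
    beta = np.arctan2(ux * wy - uy * wx, ux * wx + uy * wy)
    kappa_s[1:-1] = -beta / lbar
    kappa_s[0] = kappa_s[1]
    kappa_s[-1] = kappa_s[-2]
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa_t = np.where(np.abs(r) > 1e-9,
                           np.sin(phi) / np.where(np.abs(r) > 1e-9, r, 1.0),
                           kappa_s)
    return MeridianContour(s=s, phi=phi, r=r, z=z, kappa_s=kappa_s, kappa_theta=kappa_t)


def _stiffnesses(params: ElasticParams, radius_ref: float, pressure_unit: float = 1.0):
    t = params.thickness_to_radius * radius_ref
    C = params.e_over_p * t / (1.0 - params.nu**2)
    D = params.e_over_p * t**3 / (12.0 * (1.0 - params.nu**2))
    return C * pressure_unit, D * pressure_unit


def inflate_shell(
    resting: MeridianContour,
    params: ElasticParams,
    pressure: float = 1.0,
    model: str = "membrane",
    n_nodes: int | None = None,
    boundary: str | None = None,
    init: tuple[np.ndarray, np.ndarray] | None = None,
    tol: float = 0.0,
) -> ShellSolution:
    """Inflate a resting meridian to static equilibrium at the given
    normalised pressure.

    The boundary is inferred from the resting shape when not given: a
    meridian returning to the axis (``r[-1] ~ 0``) is treated as a closed
    cell, otherwise as an open half-cell whose base carries the axial
    tension of the omitted part of the cell.

    Raises ``RuntimeError`` with the residual history on non-convergence.
    """
    if model not in ("membrane", "bending_shear"):
        raise ValueError(f"unknown model {model!r}")
    m = resting if n_nodes is None else resting.resampled(n_nodes)
    r0, z0 = m.r.copy(), m.z.copy()
    z0 = z0 - z0[-1]
    L0 = np.hypot(np.diff(r0), np.diff(z0))
    if np.any(L0 <= 0):
        raise ValueError("degenerate resting meridian (zero-length segment)")
    if boundary is None:
        boundary = "closed" if abs(r0[-1]) < 1e-6 * max(r0) else "open"
    radius_ref = float(np.max(r0))
    C, D = _stiffnesses(params, radius_ref)
    mesh = _ShellMesh(L0, r0, boundary, C, params.nu,
                      D=D if model == "bending_shear" else 0.0,
                      kappa_s0=m.kappa_s, kappa_t0=m.kappa_theta,
                      edge=(r0[-1], z0[-1]))
    if init is not None:
        x0 = mesh.pack(init[0], init[1] - init[1][-1])
    else:
        x0 = mesh.pack(r0, z0)
    with_bending = model == "bending_shear"
    res = optimize.minimize(
        mesh.objective, x0, args=(pressure, with_bending, 1.0), jac=True,
        method="L-BFGS-B",
        options={"maxiter": 50000, "maxfun": 100000, "ftol": tol,
                 "gtol": 1e-12, "maxcor": 30},
    )
    residual = float(np.max(np.abs(res.jac)) / (C * np.mean(mesh.A0)))
    if not res.success and residual > 1e-3:
        raise RuntimeError(
            f"shell solver did not converge: {res.message}; "
            f"relative residual {residual:.2e}")
    r, z = mesh.unpack(res.x)
    l = np.hypot(np.diff(r), np.diff(z))
    lam_s = l / L0
    lam_t = 0.5 * (r[1:] + r[:-1]) / mesh.rho0m
    deformed = _solution_meridian(r, z)
    resting_m = _solution_meridian(r0, z0)
    return ShellSolution(resting=resting_m, deformed=deformed,
                         lambda_s=lam_s, lambda_theta=lam_t,
                         model=model, residual=residual, params=params)


# --------------------------------------------------------------------------
# outline -> meridian (symmetrisation)
# --------------------------------------------------------------------------

def outline_to_meridian(outline: PlanarOutline, n: int = 200,
                        smooth: float = 0.0) -> MeridianContour:
    """Symmetrised pole-to-pole meridian of a closed rod-shaped outline.

    The outline (micrometres) is axis-aligned by principal axes, split into
    the two halves on either side of the axis, and the two are averaged —
    the axisymmetry assumption made explicit.  ``smooth`` is passed to the
    periodic smoothing spline used to resample the raw outline (0 keeps the
    data untouched).
    """
    pts = outline.points_um()
    pts = pts - pts.mean(axis=0)
    # principal axis
    _, _, vt = np.linalg.svd(pts, full_matrices=False)
    ax = vt[0]
    rot = np.array([[ax[0], ax[1]], [-ax[1], ax[0]]])
    pts = pts @ rot.T
    if smooth > 0:
        tck, _ = interpolate.splprep([pts[:, 0], pts[:, 1]],
                                     s=smooth * len(pts), per=True, k=3)
        u = np.linspace(0, 1, 8 * len(pts), endpoint=False)
        pts = np.column_stack(interpolate.splev(u, tck))
    upper = pts[pts[:, 1] > 0]
    lower = pts[pts[:, 1] < 0]
    x_lo = max(upper[:, 0].min(), lower[:, 0].min())
    x_hi = min(upper[:, 0].max(), lower[:, 0].max())
    # average half-width as a function of axial position
    x_grid = np.linspace(x_lo, x_hi, 4 * n)

    def half_profile(h):
        order = np.argsort(h[:, 0])
        return np.interp(x_grid, h[order, 0], np.abs(h[order, 1]))

    rad = 0.5 * (half_profile(upper) + half_profile(lower))
    # extend to the poles: close with the outline's extreme x
    x_min_all, x_max_all = pts[:, 0].min(), pts[:, 0].max()
    x_full = np.concatenate([[x_min_all], x_grid, [x_max_all]])
    r_full = np.concatenate([[0.0], rad, [0.0]])
    # arclength parametrisation pole -> pole (z along -x so pole 0 at x_max)
    x_full = x_full[::-1]
    r_full = r_full[::-1]
    dx = np.diff(x_full)
    drr = np.diff(r_full)
    seg = np.hypot(dx, drr)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    s_new = np.linspace(0, s[-1], n)
    r_new = np.interp(s_new, s, r_full)
    z_new = np.interp(s_new, s, x_full)
    z_new = z_new - z_new[-1]
    r_new[0] = r_new[-1] = 0.0
    return _solution_meridian(r_new, z_new)


# --------------------------------------------------------------------------
# plasmolysis fit
# --------------------------------------------------------------------------

def _contour_misfit(sol_meridian: MeridianContour, target: MeridianContour) -> float:
    """Symmetric mean-squared point-to-curve distance between two meridians
    (each mirrored about the axis to a full profile)."""

    def cloud(m):
        return np.column_stack([np.concatenate([m.z, m.z]),
                                np.concatenate([m.r, -m.r])])

    a = cloud(sol_meridian.resampled(240))
    b = cloud(target.resampled(240))
    # align axially by volume centroid (z weighted by r^2)
    for c in (a, b):
        w = c[:, 1] ** 2 + 1e-12
        c[:, 0] -= np.sum(c[:, 0] * w) / np.sum(w)
    ta, tb = cKDTree(a), cKDTree(b)
    d_ab = ta.query(b)[0]
    d_ba = tb.query(a)[0]
    return float(0.5 * (np.mean(d_ab**2) + np.mean(d_ba**2)))


def fit_elastic_params(
    plasmolysed: PlanarOutline | MeridianContour,
    turgid: PlanarOutline | MeridianContour,
    model: str = "membrane",
    smooth: float = 0.0,
    n_nodes: int = 90,
    grid_e: np.ndarray | None = None,
    grid_nu: np.ndarray | None = None,
    thickness_to_radius: float = DEFAULT_THICKNESS_TO_RADIUS,
    mismatch_warn: float = 0.05,
) -> tuple[ElasticParams, float]:
    """Estimate (E/P, nu) by numerically inflating the plasmolysed contour.

    Pipeline: extract and symmetrise both contours, take the plasmolysed
    meridian as the stress-free resting shape, inflate it at unit pressure
    for candidate material properties, and keep the pair minimising the
    contour mismatch with the turgid shape (coarse grid search refined by
    Nelder-Mead).

    Returns ``(params, residual)`` with ``residual`` the RMS contour
    mismatch in micrometres.  Warns (via the returned residual and a
    ``RuntimeWarning``) when the best fit remains poor, e.g. when the two
    outlines are not the same cell.
    """
    import warnings as _w

    rest = (plasmolysed if isinstance(plasmolysed, MeridianContour)
            else outline_to_meridian(plasmolysed, n=n_nodes, smooth=smooth))
    targ = (turgid if isinstance(turgid, MeridianContour)
            else outline_to_meridian(turgid, n=n_nodes, smooth=smooth))
    rest = rest.resampled(n_nodes)

    if grid_e is None:
        grid_e = np.geomspace(20.0, 150.0, 6)
    if grid_nu is None:
        grid_nu = np.linspace(-0.3, 0.45, 6)

    # warm-start candidates only from the best-scoring solution so far:
    # re-using an arbitrary previous solution lets one diverged candidate
    # poison every later solve
    warm: dict = {"x": None, "score": np.inf}

    def score(log_e: float, nu: float) -> float:
        e = float(np.exp(log_e))
        if not (1.0 < e < 1e4) or not (-0.95 < nu < 0.49):
            return 1e6
        p = ElasticParams(e, nu, thickness_to_radius)
        try:
            sol = inflate_shell(rest, p, model=model, init=warm["x"])
        except RuntimeError:
            return 1e6
        if not (np.all(np.isfinite(sol.deformed.r))
                and np.all(np.isfinite(sol.deformed.z))):
            return 1e6
        val = _contour_misfit(sol.deformed, targ)
        if val < warm["score"] and val < 1.0:  # um^2; reject runaway shapes
            warm["x"] = (sol.deformed.r, sol.deformed.z)
            warm["score"] = val
        return val

    best = (np.inf, None)
    for e in grid_e:
        for nu in grid_nu:
            v = score(np.log(e), nu)
            if v < best[0]:
                best = (v, (np.log(e), nu))
    res = optimize.minimize(lambda x: score(x[0], x[1]), np.asarray(best[1]),
                            method="Nelder-Mead",
                            options={"xatol": 1e-4, "fatol": 1e-14,
                                     "maxfev": 300})
    log_e, nu = res.x
    rms = float(np.sqrt(res.fun))
    params = ElasticParams(float(np.exp(log_e)), float(np.clip(nu, -0.949, 0.489)),
                           thickness_to_radius)
    if rms > mismatch_warn * np.max(rest.r):
        _w.warn(f"poor plasmolysis fit (RMS {rms:.3g} um): the outlines may "
                "not belong to the same cell", RuntimeWarning)
    at_bound = (params.e_over_p <= grid_e[0] * 0.5 or
                params.e_over_p >= grid_e[-1] * 2.0)
    if at_bound:
        _w.warn("fitted E/P stuck near the search bounds", RuntimeWarning)
    return params, rms


# --------------------------------------------------------------------------
# septum -> new end
# --------------------------------------------------------------------------

def inflate_septum(
    septum_radius: float,
    resting_length_factor: float,
    params: ElasticParams,
    pressure: float = 1.0,
    n_nodes: int = 80,
    model: str = "bending_shear",
) -> ShellSolution:
    """Inflate the division septum into a new-end cap.

    The resting state is a flat disc whose meridional resting length is
    ``resting_length_factor * septum_radius`` (the septum is laid down
    inside the mother wall and carries no load until cell separation, so its
    resting length exceeds its observed span).  The rim is clamped at the
    old-wall junction at radius ``septum_radius``; inflation bulges the disc
    into a cap and leaves a curvature ridge at the junction — the division
    scar.
    """
    if resting_length_factor < 1.0:
        raise ValueError("resting_length_factor must be >= 1")
    if septum_radius <= 0:
        raise ValueError("septum_radius must be positive")
    Ls = resting_length_factor * septum_radius
    # resting: flat disc in the plane z = 0, radius coordinate = arclength
    s = np.linspace(0.0, Ls, n_nodes)
    L0 = np.diff(s)
    r0 = s.copy()
    radius_ref = septum_radius
    C, D = _stiffnesses(params, radius_ref)
    mesh = _ShellMesh(L0, r0, "clamped", C, params.nu,
                      D=D if model == "bending_shear" else 0.0,
                      kappa_s0=np.zeros(n_nodes), kappa_t0=np.zeros(n_nodes),
                      edge=(septum_radius, 0.0))
    # initial guess: spherical cap with matching chord and arc length
    f = resting_length_factor

    def arc_chord(psi):
        return psi / np.sin(psi) - f

    if f > 1.0 + 1e-9:
        psi = optimize.brentq(arc_chord, 1e-6, np.pi - 1e-6)
        Rc = septum_radius / np.sin(psi)
        ang = np.linspace(0.0, psi, n_nodes)
        r_init = Rc * np.sin(ang)
        z_init = Rc * (np.cos(ang) - np.cos(psi))
    else:
        r_init = r0 * (septum_radius / Ls)
        z_init = 1e-3 * septum_radius * np.cos(np.pi * r_init / (2 * septum_radius))
    x0 = mesh.pack(r_init, z_init)
    res = optimize.minimize(mesh.objective, x0,
                            args=(pressure, model == "bending_shear", 1.0),
                            jac=True, method="L-BFGS-B",
                            options={"maxiter": 50000, "maxfun": 100000,
                                     "ftol": 0.0, "gtol": 1e-12, "maxcor": 30})
    r, z = mesh.unpack(res.x)
    if z[0] < z[-1]:  # select the outward-bulged branch
        z = 2 * z[-1] - z
    l = np.hypot(np.diff(r), np.diff(z))
    deformed = _solution_meridian(r, z)
    return ShellSolution(resting=_solution_meridian(r0, np.zeros(n_nodes)),
                         deformed=deformed,
                         lambda_s=l / L0,
                         lambda_theta=0.5 * (r[1:] + r[:-1]) / mesh.rho0m,
                         model=model,
                         residual=float(np.max(np.abs(res.jac))),
                         params=params)
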