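"""Morphogenetic growth model: wall incorporation + elastic stretch.

The model posits a stress-free (resting) wall configuration that grows by
incorporation of new material and is elastically stretched by turgor.  Per
time step:

1. the resting meridian is inflated to elastic equilibrium at unit
   normalised pressure (membrane shell solve);
2. the incorporation profile — indexed by *deformed* arclength from the
   pole, where fluorescence and fiducial data live — is mapped back onto
   the resting material points;
3. the resting metric grows multiplicatively and isotropically at the local
   areal incorporation rate (the observed anisotropy of expansion then
   emerges mechanically, from the force balance, not from the growth rule).

Under a localised incorporation profile the cell end converges to a steady
travelling shape (the stable old-end geometry); a hemispherical new end fed
the same incorporation converges to the same attractor.

Time is internally rescaled so that the maximal per-step resting strain
increment is fixed (default 0.5%), which makes the steady shape invariant
to the overall amplitude of the incorporation profile — amplitude only sets
the pace of growth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import interpolate, optimize
from scipy.integrate import trapezoid

from .elasticity import ElasticParams, _ShellMesh, _solution_meridian
from .geometry import CurvatureKymograph, MeridianContour
from .kinematics import ExpansionProfile
from .profiles import FluorescenceProfile

__all__ = [
    "GrowthSimulation",
    "simulate_end_evolution",
    "predicted_expansion",
    "material_property_scan",
    "marker_driven_shape",
]


@dataclass
class GrowthSimulation:
    """State and history of one growth run."""

    params: ElasticParams
    incorporation: object  # callable s_um -> areal rate (normalised)
    steady_resting: tuple[np.ndarray, np.ndarray]  # (L0, rho0)
    steady_deformed: MeridianContour
    kymograph: CurvatureKymograph
    convergence: np.ndarray  # max |d kappa| per step
    converged: bool
    tip_advance_per_step: float
    fiducial_s: tuple[np.ndarray, np.ndarray] | None = None  # (s before, after)
    area_balance: np.ndarray | None = None  # relative mass-bookkeeping error
    n_steps: int = 0


# --------------------------------------------------------------------------
# internals
# --------------------------------------------------------------------------

def _inflate_state(L0, rho0, params, warm, n_ref):
    """Equilibrium of the open pole-to-flank shell given its resting metric."""
    radius_ref = float(np.max(rho0))
    t = params.thickness_to_radius * radius_ref
    C = params.e_over_p * t / (1.0 - params.nu**2)
    mesh = _ShellMesh(L0, rho0, "open", C, params.nu, D=0.0,
                      kappa_s0=None, kappa_t0=None, edge=None)
    if warm is not None and len(warm[0]) == len(rho0):
        x0 = mesh.pack(warm[0], warm[1] - warm[1][-1])
    else:
        # embed the resting metric approximately: radius = rho0, z from ds
        dz = np.sqrt(np.maximum(L0**2 - np.diff(rho0) ** 2, 1e-12))
        z = -np.concatenate([[0.0], np.cumsum(dz)])
        z -= z[-1]
        x0 = mesh.pack(rho0 * 1.02, z * 1.02)
    # in-loop solves are warm-started after a tiny growth increment, so a
    # relative-f stall criterion is accurate enough and ~2x faster than
    # grinding to the gradient floor
    res = optimize.minimize(mesh.objective, x0, args=(1.0, False, 1.0), jac=True,
                            method="L-BFGS-B",
                            options={"maxiter": 50000, "maxfun": 100000,
                                     "ftol": 1e-12, "gtol": 1e-10, "maxcor": 30})
    r, z = mesh.unpack(res.x)
    if (not np.all(np.isfinite(r)) or not np.all(np.isfinite(z))
            or np.max(np.abs(r)) > 20.0 * radius_ref):
        # soft membranes balloon at this pressure: no stable equilibrium
        raise RuntimeError(
            "equilibrium solve ran away (no stable inflated state at these "
            "material properties)")
    return r, z, mesh


def _deformed_arclength(r, z):
    return np.concatenate([[0.0], np.cumsum(np.hypot(np.diff(r), np.diff(z)))])


def _kappa_profile(r, z, s_grid):
    m = _solution_meridian(r, z)
    return np.interp(s_grid, m.s, m.kappa_s)


# --------------------------------------------------------------------------
# main simulation
# --------------------------------------------------------------------------

def simulate_end_evolution(
    initial_cap: MeridianContour,
    incorporation,
    params: ElasticParams,
    steps: int = 400,
    n_nodes: int = 60,
    strain_step: float = 0.005,
    converge_tol: float = 1e-3,
    converge_patience: int = 5,
    kymo_every: int = 5,
    flush_steps: int = 0,
) -> GrowthSimulation:
    """Evolve a cell end under localised wall incorporation.

    ``initial_cap`` is an open pole-to-flank meridian taken as the initial
    resting configuration.  ``incorporation`` maps deformed meridional
    distance from the pole (micrometre) to a non-negative areal deposition
    rate; it must be localised (decaying along the meridian).  The time step
    is chosen so the maximal per-step areal strain increment is
    ``2 * strain_step`` (i.e. linear strain increment ``strain_step``).

    Convergence: the pole-frame meridional curvature profile changes by less
    than ``converge_tol`` (1/um) per step for ``converge_patience``
    consecutive steps.  ``flush_steps`` continues the run that many steps
    past convergence so material laid down during the initial transient is
    advected out of the fixed-length domain before the steady surface is
    measured.  Raises ``RuntimeError`` on oscillatory divergence of the
    equilibrium residual (suggesting a smaller ``strain_step``).
    """
    m0 = initial_cap.resampled(n_nodes)
    a_test = np.asarray([float(incorporation(s)) for s in
                         np.linspace(0, m0.s_max, 50)])
    if np.any(a_test < 0):
        raise ValueError("incorporation must be non-negative")
    if a_test[-5:].mean() > 0.25 * a_test.max():
        raise ValueError("incorporation profile does not decay along the "
                         "meridian: no steady tip")
    L0 = np.hypot(np.diff(m0.r), np.diff(m0.z))
    rho0 = m0.r.copy()
    S0 = float(np.sum(L0))
    s_grid = np.linspace(0.0, 0.85 * S0, 80)
    warm = None
    kymo_cols = []
    kymo_t = []
    conv = []
    balance = []
    converged = False
    streak = 0
    prev_kappa = None
    step_count = 0
    r = z = None
    time_now = 0.0
    for it in range(steps):
        r, z, mesh = _inflate_state(L0, rho0, params, warm, n_nodes)
        warm = (r, z)
        s_def = _deformed_arclength(r, z)
        kappa = _kappa_profile(r, z, s_grid)
        if prev_kappa is not None:
            dk = float(np.max(np.abs(kappa - prev_kappa)))
            conv.append(dk)
            if dk < converge_tol:
                streak += 1
                if streak >= converge_patience and not converged:
                    converged = True
                    flush_left = flush_steps
            else:
                streak = 0
        prev_kappa = kappa
        if it % kymo_every == 0 or converged or it == steps - 1:
            kymo_cols.append(kappa)
            kymo_t.append(time_now)
        if converged:
            if flush_left <= 0:
                step_count = it + 1
                break
            flush_left -= 1
        # growth: areal rate a(s_def); dt so that max node strain = strain_step
        a_node = np.asarray([float(incorporation(si)) for si in s_def])
        a_max = float(a_node.max())
        if a_max <= 0:
            step_count = it + 1
            converged = True
            break
        dt = 2.0 * strain_step / a_max
        g_node = np.exp(0.5 * a_node * dt)
        g_seg = np.sqrt(g_node[1:] * g_node[:-1])
        seg_area = 2 * np.pi * 0.5 * (rho0[1:] + rho0[:-1]) * L0
        area_before = float(np.sum(seg_area))
        a_seg = 0.5 * (a_node[1:] + a_node[:-1])
        expected_gain = float(np.sum(seg_area * a_seg * dt))
        L0 = L0 * g_seg
        rho0 = rho0 * g_node
        area_after = float(np.sum(2 * np.pi * 0.5 * (rho0[1:] + rho0[:-1]) * L0))
        balance.append((area_after - area_before - expected_gain)
                       / max(expected_gain, 1e-30))
        time_now += dt
        # remesh: uniform resting arclength on [0, S0], trim advected excess
        s0_cum = np.concatenate([[0.0], np.cumsum(L0)])
        s0_new = np.linspace(0.0, S0, n_nodes)
        rho0 = np.interp(s0_new, s0_cum, rho0)
        rho0[0] = 0.0
        r_w = np.interp(s0_new, s0_cum, r)
        z_w = np.interp(s0_new, s0_cum, z)
        r_w[0] = 0.0
        warm = (r_w, z_w)
        L0 = np.diff(s0_new)
        step_count = it + 1
    if converge_tol > 0 and conv and len(conv) > 20:
        tail = np.asarray(conv[-10:])
        if not converged and np.all(tail > 2 * converge_tol) and tail[-1] > tail[0]:
            raise RuntimeError("growth step unstable (residual increasing); "
                               "reduce strain_step")

    # one extra growth+inflate pass without remeshing: virtual fiducials
    s_before = _deformed_arclength(r, z)
    a_node = np.asarray([float(incorporation(si)) for si in s_before])
    a_max = float(max(a_node.max(), 1e-12))
    dt = 2.0 * strain_step / a_max
    g_node = np.exp(0.5 * a_node * dt)
    g_seg = np.sqrt(g_node[1:] * g_node[:-1])
    r2, z2, _ = _inflate_state(L0 * g_seg, rho0 * g_node, params, (r, z), n_nodes)
    s_after = _deformed_arclength(r2, z2)
    n_tail = max(3, n_nodes // 6)
    dh = float(np.median((s_after - s_before)[-n_tail:]))

    steady = _solution_meridian(r, z)
    kymo = CurvatureKymograph(np.asarray(kymo_cols).T, s_grid,
                              np.asarray(kymo_t))
    return GrowthSimulation(
        params=params, incorporation=incorporation,
        steady_resting=(L0, rho0), steady_deformed=steady,
        kymograph=kymo, convergence=np.asarray(conv), converged=converged,
        tip_advance_per_step=dh, fiducial_s=(s_before, s_after),
        area_balance=np.asarray(balance), n_steps=step_count)


# --------------------------------------------------------------------------
# measured expansion of the simulated surface
# --------------------------------------------------------------------------

def predicted_expansion(sim: GrowthSimulation, lam_smooth: float = 1e-4) -> ExpansionProfile:
    """Strain rates of the simulated steady surface, measured exactly as the
    fiducial analysis measures them on data: virtual fiducials advected over
    one growth increment, displacements normalised by the tip advance, and
    the velocity differentiated on the steady meridian.

    Raises when the simulation did not converge.
    """
    if not sim.converged:
        raise RuntimeError("simulation not converged; expansion undefined")
    s_b, s_a = sim.fiducial_s
    dh = sim.tip_advance_per_step
    v_samples = (s_a - s_b) / dh
    # monotone, v(0)=0; smooth lightly before differentiating
    spl = interpolate.make_smoothing_spline(s_b, v_samples, lam=lam_smooth)
    m = sim.steady_deformed
    s = m.s
    v = np.clip(spl(s), 0.0, None)
    v[0] = 0.0
    eps_s = spl.derivative()(s)
    with np.errstate(divide="ignore", invalid="ignore"):
        eps_t = np.where(m.r > 1e-9, v * np.cos(m.phi) / np.maximum(m.r, 1e-300),
                         eps_s)
    areal = eps_s + eps_t
    s0 = 0.05 * s[-1]
    r0 = float(np.interp(s0, s, m.r))
    v0 = float(max(np.interp(s0, s, v), 1e-12))
    w_rel = m.r / max(r0, 1e-12)
    l_rel = v / v0
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(w_rel > 1e-12, (w_rel - l_rel) / np.maximum(w_rel, 1e-300), 0.0)
    vf = np.maximum(v, 1e-12)
    transit = np.concatenate([[0.0], np.cumsum(np.diff(s) / (0.5 * (vf[1:] + vf[:-1])))])
    return ExpansionProfile(s=s, eps_s=eps_s, eps_theta=eps_t, areal=areal,
                            anisotropy=alpha, transit=transit)


def expansion_selfconsistency(
    sim: GrowthSimulation,
    window: float = 3.5,
) -> float:
    """Relative L2 misfit between the measured areal expansion of the
    simulated surface and the incorporation profile that drove it.

    The incorporation amplitude is a rate (arbitrary units) while the
    measured expansion is per unit tip advance, so the comparison is made
    after a least-squares amplitude match, over the growth domain
    (``s <= window``, which holds essentially all of the expansion).
    """
    prof = predicted_expansion(sim)
    s = prof.s
    c = s <= window
    a_in = np.asarray([float(sim.incorporation(x)) for x in s[c]])
    pred = prof.areal[c]
    scale = trapezoid(a_in * pred, s[c]) / max(trapezoid(a_in * a_in, s[c]), 1e-30)
    num = trapezoid((pred - scale * a_in) ** 2, s[c])
    den = max(trapezoid((scale * a_in) ** 2, s[c]), 1e-30)
    return float(np.sqrt(num / den))


# --------------------------------------------------------------------------
# material-property scan
# --------------------------------------------------------------------------

def material_property_scan(
    target: ExpansionProfile,
    incorporation,
    e_grid: np.ndarray,
    nu_grid: np.ndarray,
    initial_cap: MeridianContour | None = None,
    reference: tuple[float, float] | None = None,
    band_coverage: float = 0.95,
    **sim_kwargs,
) -> dict:
    """Misfit map of simulated vs target areal-expansion profiles over a
    grid of material properties.

    Per grid point the growth model is run to its steady state and the
    (integral-normalised) predicted areal profile is scored against the
    target with an L2 misfit.  Points whose prediction stays inside the
    target's confidence band (when present) for at least ``band_coverage``
    of the grid form the admissible region.  ``reference`` selects, among
    admissible points, the one closest to an external estimate (e.g. from
    plasmolysis) in (log E/P, nu) space.

    Solver failures at individual grid points are recorded, not fatal.
    """
    e_grid = np.asarray(e_grid, dtype=float)
    nu_grid = np.asarray(nu_grid, dtype=float)
    if initial_cap is None:
        radius = 1.75
        initial_cap = MeridianContour.hemisphere(radius, flank=4.0, n=120)
    s_eval = target.s
    t_norm = target.areal / max(trapezoid(target.areal, s_eval), 1e-30)
    scores = np.full((len(e_grid), len(nu_grid)), np.nan)
    admissible = np.zeros_like(scores, dtype=bool)
    failures = []
    for i, e in enumerate(e_grid):
        for j, nu in enumerate(nu_grid):
            try:
                p = ElasticParams(e, nu)
                sim = simulate_end_evolution(initial_cap, incorporation, p,
                                             **sim_kwargs)
                prof = predicted_expansion(sim)
            except (RuntimeError, ValueError) as exc:
                failures.append(((float(e), float(nu)), str(exc)))
                continue
            pred = np.interp(s_eval, prof.s, prof.areal)
            p_norm = pred / max(trapezoid(pred, s_eval), 1e-30)
            scores[i, j] = float(np.sqrt(trapezoid((p_norm - t_norm) ** 2, s_eval))
                                 / np.sqrt(trapezoid(t_norm**2, s_eval)))
            if target.band is not None:
                scale = max(trapezoid(target.areal, s_eval), 1e-30)
                inside = np.abs(p_norm - t_norm) <= target.band / scale
                admissible[i, j] = float(np.mean(inside)) >= band_coverage
    out = {"e_grid": e_grid, "nu_grid": nu_grid, "scores": scores,
           "admissible": admissible, "failures": failures}
    if np.all(np.isnan(scores)):
        warnings.warn("no grid point produced a converged simulation")
        out["argmin"] = None
        return out
    i, j = np.unravel_index(np.nanargmin(scores), scores.shape)
    out["argmin"] = (float(e_grid[i]), float(nu_grid[j]))
    if target.band is not None and not admissible.any():
        warnings.warn("admissible region is empty: confidence band "
                      "unattainably tight for this model family")
    if reference is not None:
        cand = admissible if (target.band is not None and admissible.any()) \
            else ~np.isnan(scores)
        best = None
        for i in range(len(e_grid)):
            for j in range(len(nu_grid)):
                if not cand[i, j]:
                    continue
                d = ((np.log(e_grid[i]) - np.log(reference[0])) ** 2
                     + (nu_grid[j] - reference[1]) ** 2)
                if best is None or d < best[0]:
                    best = (d, (float(e_grid[i]), float(nu_grid[j])))
        out["selected"] = best[1] if best else None
    return out


# --------------------------------------------------------------------------
# marker-driven shape prediction
# --------------------------------------------------------------------------

def marker_driven_shape(
    profile: FluorescenceProfile,
    params: ElasticParams,
    initial_radius: float = 1.75,
    flank: float = 4.0,
    **sim_kwargs,
) -> tuple[MeridianContour, dict]:
    """Steady cell-end shape when the marker's cortical profile drives wall
    incorporation.

    The (symmetrised, normalised) profile is used directly as the areal
    incorporation rate; amplitude is irrelevant to the steady shape.
    Returns the steady deformed meridian and a report with the end width,
    pole curvature and convergence diagnostics.  Raises when the profile
    does not decay (no steady tip exists).
    """
    s_abs = np.abs(profile.s)
    order = np.argsort(s_abs)
    s_sorted = s_abs[order]
    g_sorted = np.clip(profile.gamma[order], 0.0, None)

    def incorporation(si):
        if si >= s_sorted[-1]:
            return float(g_sorted[-1])
        return float(np.interp(si, s_sorted, g_sorted))

    cap = MeridianContour.hemisphere(initial_radius, flank=flank, n=120)
    sim = simulate_end_evolution(cap, incorporation, params, **sim_kwargs)
    m = sim.steady_deformed
    report = {
        "end_width": float(2.0 * np.max(m.r)),
        "pole_curvature": float(m.kappa_s[1]),
        "converged": sim.converged,
        "n_steps": sim.n_steps,
        "marker": profile.label,
    }
    return m, report
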