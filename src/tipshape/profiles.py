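"""Cortical fluorescence-profile analysis.

A marker's cortical distribution is summarised by its normalised intensity
profile ``gamma(s)`` along the meridional coordinate (pole-centred).  Two
widths quantify a profile: the full-width at half-area (FWHA) and the
full-width at 95% area (FW95A) — the widths of the central interval holding
50% / 95% of the area under the curve with equal lateral remainders, i.e.
inter-quantile ranges of the profile viewed as a density.

Because wall-assembly effectors reside in the periplasmic space, they are
advected with the expanding wall; the steady-state advected concentration
``chi(s)`` of free material deposited according to ``gamma`` obeys

    v dchi/ds = gamma^alpha - (k + A) chi

with ``v`` the meridional velocity, ``A`` the areal expansion, ``k`` the
incorporation rate and ``alpha`` a deposition nonlinearity exponent.  For
large ``k`` the advected profile converges to the deposition profile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import interpolate, ndimage, stats
from scipy.cluster import hierarchy
from scipy.integrate import cumulative_trapezoid, solve_ivp, trapezoid
from scipy.spatial.distance import pdist, squareform

from .geometry import MeridianContour, PlanarOutline, resample_outline
from .kinematics import ExpansionProfile, VelocityProfile, strain_rates

__all__ = [
    "FluorescenceProfile",
    "AdvectionParams",
    "MarkerDendrogram",
    "extract_profile",
    "area_correct",
    "condition_profile",
    "central_width",
    "advect_profile",
    "compare_and_cluster_markers",
    "ergodicity_check",
    "fwha_vs_width",
]


@dataclass
class FluorescenceProfile:
    """Conditioned cortical intensity profile, pole-centred.

    ``gamma`` is scaled to [0, 1] (background = spline minimum subtracted,
    peak scaled to 1).  ``raw`` optionally keeps the per-frame profiles the
    conditioned curve was averaged from; ``sd`` is the across-frame band.
    """

    s: np.ndarray
    gamma: np.ndarray
    label: str = ""
    sd: np.ndarray | None = None
    raw: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)

    def fwha(self) -> float:
        return central_width(self.s, self.gamma, 0.5)

    def fw95a(self) -> float:
        return central_width(self.s, self.gamma, 0.95)


@dataclass
class AdvectionParams:
    """Incorporation rate ``k`` (per unit transit time) and deposition
    nonlinearity exponent (power applied to the fluorescence profile)."""

    k: float
    deposition_exponent: float = 1.0

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("incorporation rate k must be >= 0")
        if self.deposition_exponent <= 0:
            raise ValueError("deposition exponent must be positive")


@dataclass
class MarkerDendrogram:
    labels: list[str]
    distances: np.ndarray  # condensed or square, stored square
    linkage: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.distances, dtype=float)
        if d.ndim == 1:
            d = squareform(d)
        self.distances = d

    def to_newick(self) -> str:
        """Newick string with branch lengths from merge heights."""
        tree = hierarchy.to_tree(self.linkage)

        def rec(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.10g}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            return f"({left},{right}):{length:.10g}"

        if tree.is_leaf():
            return f"{self.labels[tree.id]}:0;"
        left = rec(tree.left, tree.dist)
        right = rec(tree.right, tree.dist)
        return f"({left},{right});"

    def cut(self, n_clusters: int) -> np.ndarray:
        return hierarchy.fcluster(self.linkage, n_clusters, criterion="maxclust")


# --------------------------------------------------------------------------
# extraction and conditioning
# --------------------------------------------------------------------------

def extract_profile(
    frames: np.ndarray,
    outline: PlanarOutline,
    window_h: float,
    pole_point: np.ndarray | None = None,
    n_samples: int = 400,
    n_window: int = 9,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate pixel intensity in a narrow window centred on the contour.

    For every contour sample the intensity is summed over ``n_window``
    points spread +-``window_h`` (micrometres) along the local normal
    (bilinear interpolation).  Returns ``(s, profiles)`` where ``s`` is the
    signed meridional distance from the pole (micrometres; the contour
    sample nearest ``pole_point``, or the first sample when omitted) and
    ``profiles`` has one row per frame.
    """
    stack = np.asarray(frames, dtype=float)
    if stack.ndim == 2:
        stack = stack[None]
    if window_h <= 0:
        raise ValueError("window height must be positive")
    fine = resample_outline(outline, n_samples)
    pts = fine.points
    tang = np.roll(pts, -1, axis=0) - np.roll(pts, 1, axis=0)
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    normals = np.column_stack([tang[:, 1], -tang[:, 0]])
    h_px = window_h / outline.pixel_size
    offsets = np.linspace(-h_px, h_px, n_window)
    ny, nx = stack.shape[1:]
    rows = []
    truncated = False
    for frame in stack:
        acc = np.zeros(n_samples)
        for off in offsets:
            q = pts + off * normals
            if (q < -0.5).any() or (q[:, 0] > nx - 0.5).any() or (q[:, 1] > ny - 0.5).any():
                truncated = True
            acc += ndimage.map_coordinates(frame, [q[:, 1], q[:, 0]], order=1,
                                           mode="constant")
        rows.append(acc)
    if truncated:
        warnings.warn("sampling window exits the image; intensities truncated")
    seg = np.hypot(*np.diff(np.vstack([pts, pts[:1]]), axis=0).T)
    arc = np.concatenate([[0.0], np.cumsum(seg)])[:-1] * outline.pixel_size
    if pole_point is None:
        i0 = 0
    else:
        i0 = int(np.argmin(np.sum((pts - np.asarray(pole_point)) ** 2, axis=1)))
    per = arc[-1] + seg[-1] * outline.pixel_size
    s = (arc - arc[i0] + per / 2) % per - per / 2
    order = np.argsort(s)
    return s[order], np.asarray(rows)[:, order]


def area_correct(
    s: np.ndarray,
    intensity: np.ndarray,
    meridian: MeridianContour,
    window_h: float,
) -> np.ndarray:
    """Convert contour-window intensity to per-area density.

    The wall area seen by a window of height ``h`` at a point with
    circumferential curvature radius ``R_theta`` is ``ds * sqrt(2 h R_theta)``;
    dividing by it removes the (weak, square-root-damped) curvature bias.
    Raises ``ValueError`` when ``kappa_theta <= 0`` somewhere on the profile.
    """
    kt = np.interp(np.abs(s), meridian.s, meridian.kappa_theta)
    if np.any(kt <= 0):
        raise ValueError("non-positive circumferential curvature on the profile")
    r_theta = 1.0 / kt
    return np.asarray(intensity, dtype=float) / np.sqrt(2.0 * window_h * r_theta)


def condition_profile(
    s: np.ndarray,
    raw_frames: np.ndarray,
    p_smooth: float = 0.8,
    symmetrize: bool = True,
    label: str = "",
) -> FluorescenceProfile:
    """Average frames, smooth, subtract background, normalise peak to 1.

    The smoothing spline minimises ``p * sum (y - f)^2 + (1 - p) * int f''^2``
    (the convention in which ``p = 0.8`` is a weak smoothing); the
    background is the spline minimum and the peak is scaled to 1.  With
    ``symmetrize`` the profile is averaged with its mirror about ``s = 0``.
    Raises on a flat (zero-range) input for which the normalisation is
    undefined.
    """
    s = np.asarray(s, dtype=float)
    frames = np.atleast_2d(np.asarray(raw_frames, dtype=float))
    mean = frames.mean(axis=0)
    if not 0 < p_smooth <= 1:
        raise ValueError("smoothing parameter must be in (0, 1]")
    if p_smooth < 1:
        lam = (1.0 - p_smooth) / p_smooth
        spl = interpolate.make_smoothing_spline(s, mean, lam=lam)
        fitted = spl(s)
    else:
        fitted = mean
    if symmetrize:
        fitted = 0.5 * (fitted + np.interp(-s, s, fitted))
    lo = float(fitted.min())
    hi = float(fitted.max())
    if hi - lo <= 0:
        raise ValueError("flat profile: normalisation undefined")
    gamma = (fitted - lo) / (hi - lo)
    sd = frames.std(axis=0, ddof=1) / (hi - lo) if len(frames) > 1 else None
    return FluorescenceProfile(s=s, gamma=gamma, label=label, sd=sd, raw=frames)


# --------------------------------------------------------------------------
# widths
# --------------------------------------------------------------------------

def central_width(s: np.ndarray, y: np.ndarray, fraction: float) -> float:
    """Width of the central interval containing ``fraction`` of the area.

    The interval is chosen so the two lateral remainders are equal in area:
    its ends are the ``(1 -+ fraction)/2`` quantiles of the profile viewed as
    a density (cumulative-area inversion on the grid).  FWHA is
    ``fraction = 0.5``, FW95A is ``fraction = 0.95``.
    """
    s = np.asarray(s, dtype=float)
    y = np.clip(np.asarray(y, dtype=float), 0.0, None)
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    cum = cumulative_trapezoid(y, s, initial=0.0)
    total = cum[-1]
    if total <= 0:
        raise ValueError("zero total area: width undefined")
    cum /= total
    lo = (1.0 - fraction) / 2.0
    hi = (1.0 + fraction) / 2.0
    # cumulative is monotone non-decreasing; invert with interp on unique knots
    s_lo = float(np.interp(lo, cum, s))
    s_hi = float(np.interp(hi, cum, s))
    return s_hi - s_lo


# --------------------------------------------------------------------------
# advection-incorporation model
# --------------------------------------------------------------------------

def advect_profile(
    profile: FluorescenceProfile,
    velocity: VelocityProfile,
    meridian: MeridianContour,
    params: AdvectionParams,
    s0_fraction: float = 0.01,
    return_both: bool = False,
):
    """Steady-state advected concentration ``chi(s)`` of free wall material.

    Solves ``v dchi/ds = gamma^alpha - (k + A) chi`` on (0, s_max] by two
    independent routes — direct ODE integration from the regular pole limit
    ``chi(0) = gamma(0)^alpha / (k + A(0))``, and the closed-form quadrature

        chi(s) = (1 / (v r)) int_0^s gamma^alpha r exp(-k (tau(s)-tau(xi))) dxi

    with ``tau`` the transit time — and returns the quadrature solution (or
    both when ``return_both``).  The two agree to discretisation accuracy;
    their maximum relative difference is available for cross-checking.
    """
    m = meridian
    exp_profile = strain_rates(velocity, m)
    s = m.s
    if len(profile.s) != len(s) or not np.allclose(profile.s, s):
        gamma = np.interp(s, profile.s, profile.gamma)
    else:
        gamma = profile.gamma
    gamma = np.clip(gamma, 0.0, None)
    alpha = params.deposition_exponent
    k = params.k
    src = gamma**alpha
    v = velocity(m.phi)
    if np.any(v[1:] <= 0):
        raise ValueError("velocity must be positive away from the pole")
    A = exp_profile.areal
    pole = v[0] < 1e-8  # regular singular point at a true pole (v(0)=0)
    i0 = max(1, int(np.searchsorted(s, s0_fraction * s[-1]))) if pole else 1

    # closed form via a stable exponential-integrator recurrence on
    # I(s) = int_0^s gamma^alpha r exp(-k (tau(s)-tau(xi))) dxi.
    # Transit-time *increments* are used directly: the pole makes tau itself
    # a divergent cumulative sum whose later increments would be lost to
    # floating-point absorption.
    r = np.maximum(m.r, 1e-30)
    vf = np.maximum(v, 1e-30)
    dtau = np.diff(s) * 0.5 * (1.0 / vf[1:] + 1.0 / vf[:-1])
    g = src * r
    gv = g * vf
    I = np.zeros_like(s)
    for j in range(i0, len(s)):
        if k == 0:
            I[j] = I[j - 1] + 0.5 * (g[j] + g[j - 1]) * (s[j] - s[j - 1])
            continue
        u = k * dtau[j - 1]
        d = np.exp(-min(u, 700.0))
        # exact integral of the tau-linear interpolant of (gamma^alpha r v):
        # c1 = int e^{-k(dt - t)} dt / dt,  c2 covers the linear part
        if u > 1e-4:
            c1 = -np.expm1(-u) / u
            c2 = (u - 1.0 + d) / (u * u)
        else:
            c1 = 1.0 - u / 2.0 + u * u / 6.0
            c2 = 0.5 - u / 6.0
        step = dtau[j - 1] * (gv[j - 1] * c1 + (gv[j] - gv[j - 1]) * c2)
        I[j] = I[j - 1] * d + step
    with np.errstate(divide="ignore", invalid="ignore"):
        chi_cf = I / (vf * r)
    if pole:
        chi0 = src[0] / (k + A[0]) if (k + A[0]) > 1e-12 else 0.0
        chi_cf[:i0] = chi0 + (chi_cf[i0] - chi0) * (s[:i0] / s[i0]) ** 2
        chi_cf[0] = chi0
    else:
        chi_cf[0] = 0.0  # open inlet: nothing deposited upstream

    # direct ODE integration
    v_i = interpolate.interp1d(s, v, kind="cubic")
    A_i = interpolate.interp1d(s, A, kind="cubic")
    g_i = interpolate.interp1d(s, src, kind="cubic")

    def rhs(si, chi):
        return (g_i(si) - (k + A_i(si)) * chi) / v_i(si)

    sol = solve_ivp(rhs, (s[i0], s[-1]), [chi_cf[i0]], t_eval=s[i0:],
                    method="LSODA", rtol=1e-10, atol=1e-12)
    chi_ode = chi_cf.copy()
    chi_ode[i0:] = sol.y[0]
    if return_both:
        return chi_cf, chi_ode
    return chi_cf


# --------------------------------------------------------------------------
# marker comparison / clustering
# --------------------------------------------------------------------------

def compare_and_cluster_markers(
    profiles_list: list[FluorescenceProfile],
    metric: str = "width_features",
    method: str = "single",
    shape_fn=None,
    n_kappa: int = 20,
) -> MarkerDendrogram:
    """Agglomerative clustering of markers by distribution affinity.

    ``metric = "width_features"`` uses the feature vector [FWHA, FW95A];
    ``metric = "predicted_curvature"`` uses the meridional curvature of the
    steady cell-end shape each marker predicts when its profile drives wall
    incorporation (``shape_fn(profile) -> MeridianContour``, typically
    ``growth.marker_driven_shape``), sampled at ``n_kappa`` meridional
    positions.  Distances are euclidean; linkage method configurable
    (single/average/complete).  Markers whose shape prediction fails are
    dropped with a warning.
    """
    if len(profiles_list) < 2:
        raise ValueError("need at least two markers")
    feats = []
    labels = []
    for i, p in enumerate(profiles_list):
        lab = p.label or f"marker{i}"
        if metric == "width_features":
            feats.append([p.fwha(), p.fw95a()])
            labels.append(lab)
        elif metric == "predicted_curvature":
            if shape_fn is None:
                raise ValueError("predicted_curvature metric needs shape_fn")
            try:
                mer = shape_fn(p)
            except Exception as exc:  # noqa: BLE001 - per-marker isolation
                warnings.warn(f"shape prediction failed for {lab}: {exc}")
                continue
            grid = np.linspace(0, mer.s_max * 0.8, n_kappa)
            feats.append(np.interp(grid, mer.s, mer.kappa_s))
            labels.append(lab)
        else:
            raise ValueError(f"unknown metric {metric!r}")
    if len(feats) < 2:
        raise ValueError("fewer than two markers with usable features")
    X = np.asarray(feats, dtype=float)
    cond = pdist(X, metric="euclidean")
    Z = hierarchy.linkage(cond, method=method)
    return MarkerDendrogram(labels=labels, distances=cond, linkage=Z)


def ergodicity_check(
    single_cell_widths: np.ndarray,
    population_widths: np.ndarray,
    level: float = 0.05,
) -> dict:
    """Two-sample comparison of FWHA distributions over time vs population.

    A marker is 'ergodic' when the width distribution of one cell followed
    through time matches the across-cell distribution at a time point.
    Kolmogorov-Smirnov two-sample test; ``flagged`` when p < level.
    """
    a = np.asarray(single_cell_widths, dtype=float)
    b = np.asarray(population_widths, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    stat, pval = stats.ks_2samp(a, b, method="asymp")
    return {"statistic": float(stat), "p_value": float(pval),
            "flagged": bool(pval < level), "level": level,
            "n_time": len(a), "n_population": len(b)}


def fwha_vs_width(
    fwha_by_genotype: dict[str, np.ndarray],
    width_by_genotype: dict[str, np.ndarray],
    reference_slope: float | None = None,
) -> dict:
    """FWHA-vs-cell-width trend across genotype groups.

    Returns per-group means +- sd and the slope of group-mean FWHA against
    group-mean width (with standard error), optionally compared against a
    reference line (e.g. the wild-type width/expansion relation).  With a
    single group the slope is reported as undefined (NaN).
    """
    groups = sorted(fwha_by_genotype)
    if sorted(width_by_genotype) != groups:
        raise ValueError("genotype keys must match between the two tables")
    table = {}
    xs, ys = [], []
    for g in groups:
        f = np.asarray(fwha_by_genotype[g], dtype=float)
        w = np.asarray(width_by_genotype[g], dtype=float)
        table[g] = {"fwha_mean": float(f.mean()),
                    "fwha_sd": float(f.std(ddof=1)) if len(f) > 1 else 0.0,
                    "width_mean": float(w.mean()),
                    "width_sd": float(w.std(ddof=1)) if len(w) > 1 else 0.0,
                    "n": len(f)}
        xs.append(w.mean())
        ys.append(f.mean())
    if len(groups) < 2:
        slope = intercept = stderr = np.nan
    else:
        res = stats.linregress(xs, ys)
        slope, intercept, stderr = float(res.slope), float(res.intercept), float(res.stderr)
    out = {"groups": table, "slope": slope, "intercept": intercept,
           "slope_stderr": stderr}
    if reference_slope is not None and np.isfinite(slope):
        out["follows_reference"] = bool(
            abs(slope - reference_slope) <= 2 * (stderr if np.isfinite(stderr) else np.inf))
        out["reference_slope"] = reference_slope
    return out
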