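"""Cell-end geometry: outline tracking, curvature, poles, kymographs, meridians.

The quantification is Eulerian and axisymmetric: every field is expressed as a
function of the meridional arclength ``s`` measured from the pole of the
growing end.  A closed planar outline (pixels) is turned into a meridional
curvature profile ``kappa_s(s)``; conversely an axisymmetric meridian
(``s, phi, r, z``) is reconstructed from a curvature profile by integrating

    phi(s) = int_0^s kappa_s d(xi)
    r(s)   = int_0^s cos(phi) d(xi)
    z(s)   = -int_0^s sin(phi) d(xi)
    kappa_theta = sin(phi) / r        (-> kappa_s at the pole)

where ``phi`` is the angle of the outward normal with respect to the cell
axis, so that ``phi = 0`` at the pole and ``phi = pi/2`` on the cylindrical
flank.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import interpolate, ndimage
from scipy.integrate import cumulative_trapezoid
from shapely.geometry import LineString, Point

__all__ = [
    "PlanarOutline",
    "MeridianContour",
    "CurvatureKymograph",
    "resample_outline",
    "track_outlines",
    "meridional_curvature",
    "locate_pole",
    "arclength_from_pole",
    "canonical_end_shape",
    "curvature_kymograph",
    "reconstruct_meridian",
]


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------

@dataclass
class PlanarOutline:
    """Closed cell outline in image coordinates.

    ``points`` is an ordered ``(n, 2)`` array of ``(x, y)`` positions in
    pixels (0-based, x right, y down); the polygon is implicitly closed
    (last point connects back to the first).
    """

    points: np.ndarray
    pixel_size: float = 1.0  # micrometre per pixel
    frame: int = 0
    timestamp: float = 0.0  # minutes

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("outline points must be an (n, 2) array")
        if len(self.points) < 3:
            raise ValueError("outline needs at least 3 points")

    @property
    def n_points(self) -> int:
        return len(self.points)

    def points_um(self) -> np.ndarray:
        return self.points * self.pixel_size

    def perimeter(self) -> float:
        """Perimeter in pixels."""
        closed = np.vstack([self.points, self.points[:1]])
        return float(np.sum(np.hypot(*np.diff(closed, axis=0).T)))


@dataclass
class MeridianContour:
    """Axisymmetric meridian sampled on an arclength grid (``s=0`` at pole).

    All lengths in micrometres, curvatures in 1/micrometre.
    """

    s: np.ndarray
    phi: np.ndarray
    r: np.ndarray
    z: np.ndarray
    kappa_s: np.ndarray
    kappa_theta: np.ndarray

    def __post_init__(self) -> None:
        for name in ("s", "phi", "r", "z", "kappa_s", "kappa_theta"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))

    @property
    def s_max(self) -> float:
        return float(self.s[-1])

    def phi_of_s(self, s: np.ndarray) -> np.ndarray:
        return np.interp(s, self.s, self.phi)

    def r_of_s(self, s: np.ndarray) -> np.ndarray:
        return np.interp(s, self.s, self.r)

    def has_flank(self, tol: float = 0.15) -> bool:
        """True when the meridian reaches a cylindrical flank (phi ~ pi/2)."""
        return bool(np.any(self.phi > np.pi / 2 - tol))

    def resampled(self, n: int) -> "MeridianContour":
        s_new = np.linspace(self.s[0], self.s[-1], n)
        return MeridianContour(
            s=s_new,
            phi=np.interp(s_new, self.s, self.phi),
            r=np.interp(s_new, self.s, self.r),
            z=np.interp(s_new, self.s, self.z),
            kappa_s=np.interp(s_new, self.s, self.kappa_s),
            kappa_theta=np.interp(s_new, self.s, self.kappa_theta),
        )

    # -- canonical shapes ---------------------------------------------------

    @staticmethod
    def hemisphere(radius: float, flank: float = 0.0, n: int = 200) -> "MeridianContour":
        """Hemispherical cap of given radius, optionally continued by a
        cylindrical flank of meridional length ``flank`` (exact geometry)."""
        s_cap = np.pi * radius / 2.0
        s = np.linspace(0.0, s_cap + flank, n)
        on_cap = s <= s_cap
        ang = s / radius
        phi = np.where(on_cap, ang, np.pi / 2)
        r = np.where(on_cap, radius * np.sin(ang), radius)
        z = np.where(on_cap, -radius * (1 - np.cos(ang)), -radius - (s - s_cap))
        kappa_s = np.where(on_cap, 1.0 / radius, 0.0)
        kappa_t = np.where(r > 1e-12, np.sin(phi) / np.maximum(r, 1e-300), kappa_s)
        return MeridianContour(s=s, phi=phi, r=r, z=z, kappa_s=kappa_s, kappa_theta=kappa_t)

    @staticmethod
    def spheroid_cap(radius: float, aspect: float = 1.5, flank: float = 0.0,
                     n: int = 200) -> "MeridianContour":
        """Prolate/oblate spheroidal cap of equatorial radius ``radius`` and
        polar semi-axis ``aspect * radius`` (aspect > 1 is pointier than a
        hemisphere, < 1 flatter), optionally continued by a cylinder."""
        c = aspect * radius
        t = np.linspace(0.0, np.pi / 2, 20 * n)
        r = radius * np.sin(t)
        z = -c * (1 - np.cos(t))
        ds = np.hypot(np.gradient(r, t), np.gradient(z, t))
        s = cumulative_trapezoid(ds, t, initial=0.0)
        phi = np.arctan2(c * np.sin(t), radius * np.cos(t))
        s_grid = np.linspace(0.0, s[-1], n)
        phi_g = np.interp(s_grid, s, phi)
        r_g = np.interp(s_grid, s, r)
        z_g = np.interp(s_grid, s, z)
        kappa_s = np.gradient(phi_g, s_grid)
        if flank > 0:
            extra = np.linspace(0, flank, max(int(n * flank / s[-1]), 8))[1:]
            s_grid = np.concatenate([s_grid, s[-1] + extra])
            phi_g = np.concatenate([phi_g, np.full(len(extra), np.pi / 2)])
            r_g = np.concatenate([r_g, np.full(len(extra), radius)])
            z_g = np.concatenate([z_g, z[-1] - extra])
            kappa_s = np.concatenate([kappa_s, np.zeros(len(extra))])
        with np.errstate(divide="ignore", invalid="ignore"):
            kappa_t = np.where(r_g > 1e-12, np.sin(phi_g) / np.maximum(r_g, 1e-300),
                               kappa_s)
        return MeridianContour(s=s_grid, phi=phi_g, r=r_g, z=z_g,
                               kappa_s=kappa_s, kappa_theta=kappa_t)

    @staticmethod
    def capsule(radius: float, length: float, n: int = 400) -> "MeridianContour":
        """Closed rod (two hemispherical caps + cylinder), pole to pole
        (exact geometry).  ``length`` is the pole-to-pole axial length.
        """
        cyl = length - 2.0 * radius
        if cyl < 0:
            raise ValueError("length must exceed the cell diameter")
        s_cap = np.pi * radius / 2.0
        s_tot = 2 * s_cap + cyl
        s = np.linspace(0.0, s_tot, n)
        phi = np.empty(n)
        r = np.empty(n)
        z = np.empty(n)
        kappa_s = np.zeros(n)
        top = s <= s_cap
        midd = (s > s_cap) & (s < s_cap + cyl)
        bot = s >= s_cap + cyl
        ang = s[top] / radius
        phi[top] = ang
        r[top] = radius * np.sin(ang)
        z[top] = -radius * (1 - np.cos(ang))
        kappa_s[top] = 1.0 / radius
        phi[midd] = np.pi / 2
        r[midd] = radius
        z[midd] = -radius - (s[midd] - s_cap)
        ang2 = (s[bot] - s_cap - cyl) / radius
        phi[bot] = np.pi / 2 + ang2
        r[bot] = radius * np.cos(ang2)
        z[bot] = -radius - cyl - radius * np.sin(ang2)
        kappa_s[bot] = 1.0 / radius
        kappa_t = np.where(r > 1e-12, np.sin(phi) / np.maximum(r, 1e-300), kappa_s)
        return MeridianContour(s=s, phi=phi, r=r, z=z, kappa_s=kappa_s, kappa_theta=kappa_t)

    def to_outline(self, pixel_size: float = 1.0, frame: int = 0) -> PlanarOutline:
        """Mirror the meridian about the axis into a closed planar outline.

        The axis runs along image x; the returned outline is in pixels.
        """
        x = -self.z
        y = self.r
        upper = np.column_stack([x, y])
        lower = np.column_stack([x[::-1], -y[::-1]])
        pts = np.vstack([upper, lower[1:-1]]) / pixel_size
        return PlanarOutline(pts, pixel_size=pixel_size, frame=frame)


@dataclass
class CurvatureKymograph:
    """Meridional curvature vs (signed meridional distance, time)."""

    kappa: np.ndarray  # (n_s, n_t)
    s: np.ndarray  # micrometre, signed about the pole
    t: np.ndarray  # minutes
    missing: np.ndarray = field(default=None)  # bool per column

    def __post_init__(self) -> None:
        self.kappa = np.asarray(self.kappa, dtype=float)
        self.s = np.asarray(self.s, dtype=float)
        self.t = np.asarray(self.t, dtype=float)
        if self.missing is None:
            self.missing = np.zeros(len(self.t), dtype=bool)
        if self.kappa.shape != (len(self.s), len(self.t)):
            raise ValueError("kymograph matrix shape must be (n_s, n_t)")


# --------------------------------------------------------------------------
# outline resampling and tracking
# --------------------------------------------------------------------------

def resample_outline(outline: PlanarOutline, n: int, smooth: float = 0.0) -> PlanarOutline:
    """Resample a closed outline at ``n`` uniformly spaced points using a
    periodic cubic spline through the anchor points."""
    pts = outline.points
    # drop duplicate closing point if present
    if np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    tck, _ = interpolate.splprep([pts[:, 0], pts[:, 1]], s=smooth * len(pts), per=True, k=3)
    # uniform in arclength: oversample then invert cumulative length
    u_fine = np.linspace(0, 1, 20 * len(pts), endpoint=False)
    xy = np.column_stack(interpolate.splev(u_fine, tck))
    seg = np.hypot(*np.diff(np.vstack([xy, xy[:1]]), axis=0).T)
    arc = np.concatenate([[0.0], np.cumsum(seg)])[:-1]
    arc_targets = np.linspace(0, arc[-1] + seg[-1], n, endpoint=False)
    u_new = np.interp(arc_targets, arc, u_fine)
    xy_new = np.column_stack(interpolate.splev(u_new, tck))
    return PlanarOutline(xy_new, pixel_size=outline.pixel_size,
                         frame=outline.frame, timestamp=outline.timestamp)


def _outline_normals(pts: np.ndarray) -> np.ndarray:
    """Unit normals of a closed polyline (central differences)."""
    tang = np.roll(pts, -1, axis=0) - np.roll(pts, 1, axis=0)
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    return np.column_stack([tang[:, 1], -tang[:, 0]])


def _contour_intensity(image_interp, pts: np.ndarray, n_eval: int = 720) -> float:
    """Mean pixel intensity at ``n_eval`` uniformly spaced samples around
    the closed contour.  Deliberately not arclength-weighted: a weighted
    integral would reward lengthening the contour inside a bright band."""
    closed = np.vstack([pts, pts[:1]])
    seg = np.hypot(*np.diff(closed, axis=0).T)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0, arc[-1], n_eval, endpoint=False)
    x = np.interp(targets, arc, closed[:, 0])
    y = np.interp(targets, arc, closed[:, 1])
    vals = image_interp(np.vstack([y, x]))
    return float(np.mean(vals))


def track_outlines(
    image_stack: np.ndarray,
    initial_polygon: PlanarOutline,
    step: float = 0.25,
    max_sweeps: int = 60,
) -> list[PlanarOutline]:
    """Track a closed cell outline through an image stack.

    Anchor points are moved by small steps (default 0.25 px) orthogonal to
    the curve; a step is kept only when it increases the integral of the
    pixel intensity around the whole closed contour (accept-if-improves hill
    climbing).  Each frame is initialised from the previous frame's result.

    Raises ``RuntimeError`` (with the frame index) when the contour leaves
    the image.
    """
    stack = np.asarray(image_stack, dtype=float)
    if stack.ndim == 2:
        stack = stack[None]
    outlines: list[PlanarOutline] = []
    pts = initial_polygon.points.copy()
    h, w = stack.shape[1:]
    for j, frame in enumerate(stack):
        interp_fn = lambda yx: ndimage.map_coordinates(frame, yx, order=1, mode="constant")
        best = _contour_intensity(interp_fn, pts)
        for _ in range(max_sweeps):
            normals = _outline_normals(pts)
            improved = False
            for sign in (+1.0, -1.0):
                for i in range(len(pts)):
                    trial = pts.copy()
                    trial[i] = pts[i] + sign * step * normals[i]
                    val = _contour_intensity(interp_fn, trial)
                    if val > best + 1e-12:
                        pts = trial
                        best = val
                        improved = True
            if not improved:
                break
        if (pts[:, 0].min() < -1 or pts[:, 0].max() > w or
                pts[:, 1].min() < -1 or pts[:, 1].max() > h):
            raise RuntimeError(f"contour left the image at frame {j}")
        outlines.append(PlanarOutline(pts.copy(), pixel_size=initial_polygon.pixel_size,
                                      frame=j))
    return outlines


# --------------------------------------------------------------------------
# curvature
# --------------------------------------------------------------------------

def meridional_curvature(
    outline: PlanarOutline,
    segment_length: float | None = None,
    n_fine: int = 1800,
) -> tuple[np.ndarray, np.ndarray]:
    """Meridional curvature ``kappa_s = alpha / l`` along a closed outline.

    The outline is resampled at ``n_fine`` uniformly spaced points (spacing
    ``l``, default the perimeter / n_fine) and the curvature at each point is
    the turning angle ``alpha`` between successive segments divided by the
    segment length ``l``, converted to 1/micrometre.  Positive curvature is
    outward-convex for a counter-clockwise outline; the sign is normalised so
    that the mean curvature of the closed contour is positive.

    Returns ``(arclength_um, kappa_um)`` sampled at the fine points.
    """
    per = outline.perimeter()
    if segment_length is not None:
        n_fine = max(16, int(round(per / segment_length)))
        if segment_length > per / 16:
            warnings.warn("segment length is coarse relative to the contour")
    fine = resample_outline(outline, n_fine)
    pts = fine.points
    l_px = fine.perimeter() / n_fine
    prev = pts - np.roll(pts, 1, axis=0)
    nxt = np.roll(pts, -1, axis=0) - pts
    cross = prev[:, 0] * nxt[:, 1] - prev[:, 1] * nxt[:, 0]
    alpha = np.arctan2(cross, np.sum(prev * nxt, axis=1))
    kappa_px = alpha / l_px
    if kappa_px.mean() < 0:  # orientation convention
        kappa_px = -kappa_px
    arc_px = np.arange(n_fine) * l_px
    return arc_px * outline.pixel_size, kappa_px / outline.pixel_size


# --------------------------------------------------------------------------
# pole location
# --------------------------------------------------------------------------

def locate_pole(
    first_outline: PlanarOutline,
    last_outline: PlanarOutline,
    n_candidates: int = 360,
    manual_shift: int = 0,
) -> int:
    """Index (into a ``n_candidates``-point resampling of ``first_outline``)
    of the growth pole, defined as the contour point whose orthogonal path to
    the last outline is longest.

    ``manual_shift`` displaces the detected pole by that many resampled
    points, mirroring the manual symmetry correction used when asymmetric
    contours misplace the pole.

    Raises ``ValueError`` when the outlines coincide (no growth).
    """
    a = resample_outline(first_outline, n_candidates).points
    b = resample_outline(last_outline, n_candidates).points
    if np.allclose(a, b, atol=1e-6):
        raise ValueError("no growth; pole undefined")
    target = LineString(np.vstack([b, b[:1]]))
    normals = _outline_normals(a)
    diag = 4.0 * max(first_outline.perimeter(), last_outline.perimeter())
    lengths = np.full(n_candidates, -1.0)
    for i, (p, nrm) in enumerate(zip(a, normals)):
        ray = LineString([p, p + diag * nrm])
        inter = ray.intersection(target)
        if inter.is_empty:
            continue
        d = inter.distance(Point(p)) if inter.geom_type == "Point" else \
            min(g.distance(Point(p)) for g in getattr(inter, "geoms", [inter]))
        lengths[i] = d
    if lengths.max() < 0:
        raise ValueError("no orthogonal path from first to last outline")
    return int((np.argmax(lengths) + manual_shift) % n_candidates)


def arclength_from_pole(outline: PlanarOutline, pole_point: np.ndarray,
                        n_fine: int = 1800) -> tuple[np.ndarray, np.ndarray]:
    """Curvature profile indexed by signed meridional distance from the pole.

    The outline is finely resampled; the sample nearest ``pole_point`` is
    taken as ``s = 0`` and distance along the contour is signed (negative on
    one side of the pole, positive on the other).

    Returns ``(s_um, kappa_um)`` sorted by ``s``.
    """
    arc, kappa = meridional_curvature(outline, n_fine=n_fine)
    fine = resample_outline(outline, len(arc))
    i0 = int(np.argmin(np.sum((fine.points - np.asarray(pole_point)) ** 2, axis=1)))
    s = arc - arc[i0]
    per = arc[-1] + (arc[1] - arc[0])
    s = (s + per / 2) % per - per / 2
    order = np.argsort(s)
    return s[order], kappa[order]


def canonical_end_shape(
    profiles: list[tuple[np.ndarray, np.ndarray]],
    s_grid: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Symmetric average curvature profile over many ends/frames.

    Each profile is ``(s, kappa)`` with ``s`` signed about the pole.  The
    profiles are resampled on a common grid, each one is made symmetrical by
    averaging its left and right sides, and the pointwise mean and standard
    deviation across profiles are returned as ``(s, mean, sd)`` on the
    non-negative half-grid mirrored to ``[-s_max, s_max]``.
    """
    if not profiles:
        raise ValueError("need at least one profile")
    if s_grid is None:
        s_max = min(min(-p[0][0], p[0][-1]) for p in profiles)
        s_grid = np.linspace(0.0, s_max, 200)
    sym = []
    for s, k in profiles:
        right = np.interp(s_grid, s, k)
        left = np.interp(s_grid, -s[::-1], k[::-1])
        sym.append(0.5 * (left + right))
    sym = np.asarray(sym)
    mean = sym.mean(axis=0)
    sd = sym.std(axis=0, ddof=1) if len(sym) > 1 else np.zeros_like(mean)
    s_full = np.concatenate([-s_grid[::-1], s_grid[1:]])
    mean_full = np.concatenate([mean[::-1], mean[1:]])
    sd_full = np.concatenate([sd[::-1], sd[1:]])
    return s_full, mean_full, sd_full


def curvature_kymograph(
    outlines: list[PlanarOutline],
    pole_points: list[np.ndarray | None],
    s_grid: np.ndarray | None = None,
    timestamps: np.ndarray | None = None,
) -> CurvatureKymograph:
    """Assemble curvature-vs-time matrix in the pole frame.

    Column ``j`` is the meridional curvature of frame ``j`` sampled at fixed
    signed meridional distances from that frame's pole.  Frames whose pole is
    ``None`` are flagged missing (NaN column).
    """
    if s_grid is None:
        s_grid = np.linspace(-4.0, 4.0, 161)
    n_t = len(outlines)
    mat = np.full((len(s_grid), n_t), np.nan)
    missing = np.zeros(n_t, dtype=bool)
    for j, (o, p) in enumerate(zip(outlines, pole_points)):
        if p is None:
            missing[j] = True
            continue
        s, k = arclength_from_pole(o, p)
        mat[:, j] = np.interp(s_grid, s, k)
    t = np.asarray(timestamps if timestamps is not None
                   else [o.timestamp for o in outlines], dtype=float)
    return CurvatureKymograph(mat, s_grid, t, missing)


# --------------------------------------------------------------------------
# meridian reconstruction
# --------------------------------------------------------------------------

def reconstruct_meridian(s: np.ndarray, kappa_s: np.ndarray) -> MeridianContour:
    """Integrate a curvature profile into an axisymmetric meridian.

    Raises ``ValueError`` when the normal angle exceeds pi (the meridian
    would fold back over the axis).
    """
    s = np.asarray(s, dtype=float)
    kappa_s = np.asarray(kappa_s, dtype=float)
    phi = cumulative_trapezoid(kappa_s, s, initial=0.0)
    if np.any(phi > np.pi + 1e-9):
        raise ValueError("normal angle exceeds pi: meridian self-folds")
    r = cumulative_trapezoid(np.cos(phi), s, initial=0.0)
    z = -cumulative_trapezoid(np.sin(phi), s, initial=0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa_theta = np.where(r > 1e-12, np.sin(phi) / np.maximum(r, 1e-300), kappa_s)
    return MeridianContour(s=s, phi=phi, r=r, z=z, kappa_s=kappa_s, kappa_theta=kappa_theta)
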