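"""Synthetic data generators for every pipeline input.

Each generator emulates one kind of experimental record with the geometric
and statistical structure the analysis assumes:

* bright-field-like image stacks of a growing rod-shaped cell, with the
  ground-truth outlines returned alongside;
* wall-bound fiducial (Qdot) tracks advected by a prescribed meridional
  velocity field, with fluctuating per-interval growth increments;
* bell-shaped cortical fluorescence profiles of configurable family and
  width, plus frame noise;
* plasmolysed/turgid contour pairs generated by the forward elastic model.

All generators are deterministic given the scenario seed; independent
generators draw from independently-seeded streams so adding one output kind
never perturbs another.

Default scenario values emulate the study conditions: pixel size 67 nm,
cell radius 1.75 um, 10-min imaging intervals with a mean tip advance of
0.1 um per interval and +-50% lognormal fluctuation of the increments.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import gamma as gamma_fn

from .elasticity import ElasticParams, inflate_shell
from .geometry import MeridianContour, PlanarOutline, reconstruct_meridian
from .kinematics import QdotTrack, VelocityProfile

__all__ = [
    "SyntheticScenario",
    "end_meridian",
    "synth_cell_image_stack",
    "synth_qdot_tracks",
    "synth_fluorescence_profiles",
    "synth_plasmolysis_pair",
]


@dataclass
class SyntheticScenario:
    """Reproducible description of a synthetic experiment.

    ``end_shape`` is "hemisphere" or "pointy"; for pointy ends the
    meridional curvature decays as ``exp(-(s/w)^p)`` with exponent
    ``pointy_exponent``.  ``mean_step`` is the mean tip advance per frame
    interval (micrometre) and ``fluctuation`` the lognormal sigma of the
    per-interval multiplier (0.4 gives roughly +-50% spurts).
    """

    seed: int = 0
    pixel_size: float = 0.067  # micrometre per pixel
    cell_radius: float = 1.75  # micrometre
    end_shape: str = "hemisphere"
    pointy_exponent: float = 2.0
    n_frames: int = 12
    mean_step: float = 0.1  # micrometre tip advance per frame interval
    fluctuation: float = 0.4  # lognormal sigma of growth multipliers
    frame_interval: float = 10.0  # minutes
    noise_sd_intensity: float = 0.05  # image / profile intensity units
    noise_sd_length: float = 0.0  # micrometre, on positions/outlines

    def __post_init__(self) -> None:
        if self.cell_radius <= 0:
            raise ValueError("cell_radius must be positive")
        if self.mean_step < 0:
            raise ValueError("mean tip advance must be >= 0")

    def rng(self, stream: str) -> np.random.Generator:
        # deterministic stream hash (builtin hash() is salted per process)
        digest = hashlib.sha256(stream.encode()).digest()
        h = int.from_bytes(digest[:4], "little") % (2**31)
        return np.random.default_rng([self.seed % (2**31), h])

    def growth_increments(self) -> np.ndarray:
        """Per-interval tip advances dh >= 0 (lognormal spurts, i.i.d.)."""
        n = self.n_frames - 1
        if self.mean_step == 0 or n <= 0:
            return np.zeros(max(n, 0))
        g = self.rng("growth")
        mult = g.lognormal(mean=-0.5 * self.fluctuation**2,
                           sigma=self.fluctuation, size=n)
        return self.mean_step * mult


def end_meridian(scenario: SyntheticScenario, flank: float = 4.0,
                 n: int = 300, width: float = 1.0) -> MeridianContour:
    """Ground-truth end meridian for the scenario's end-shape family.

    Pointy ends: ``kappa_s(s) = k0 exp(-(s/w)^p)`` with ``k0`` chosen so the
    normal angle reaches pi/2, then rescaled so the flank radius equals the
    scenario's cell radius.
    """
    R = scenario.cell_radius
    if scenario.end_shape == "hemisphere":
        return MeridianContour.hemisphere(R, flank=flank, n=n)
    if scenario.end_shape != "pointy":
        raise ValueError(f"unknown end shape {scenario.end_shape!r}")
    p = scenario.pointy_exponent
    w = width
    k0 = (np.pi / 2) / (w * gamma_fn(1.0 + 1.0 / p))
    s = np.linspace(0.0, 5.0 * w, n)
    kappa = k0 * np.exp(-((s / w) ** p))
    m = reconstruct_meridian(s, kappa)
    scale = R / m.r[-1]
    s2 = np.concatenate([m.s * scale, m.s[-1] * scale + np.linspace(0, flank, 50)[1:]])
    k2 = np.concatenate([m.kappa_s / scale, np.zeros(49)])
    return reconstruct_meridian(s2, k2)


# --------------------------------------------------------------------------
# image stacks
# --------------------------------------------------------------------------

def _cell_outline_um(scenario: SyntheticScenario, length: float,
                     n_pts: int = 400) -> np.ndarray:
    """Closed outline (um) of a rod of the given axial length; the growing
    end (at +x) uses the scenario's end-shape family."""
    R = scenario.cell_radius
    grow_end = end_meridian(scenario, flank=0.5, n=200)
    # growing end cap: axial extent from pole
    xg = -grow_end.z  # >= 0, pole at 0
    yg = grow_end.r
    # other end: hemisphere
    th = np.linspace(0, np.pi / 2, 100)
    xo = R * (1 - np.cos(th))
    yo = R * np.sin(th)
    cap_len = xg[-1]
    cyl = max(length - cap_len - R, 0.2)
    # build upper half from growing pole (x = length) to far pole (x = 0)
    x_up = np.concatenate([length - xg, np.full(2, length - cap_len - cyl / 2),
                           xo[::-1]])
    y_up = np.concatenate([yg, [R, R], yo[::-1]])
    order = np.argsort(-x_up)
    x_up, y_up = x_up[order], y_up[order]
    pts_up = np.column_stack([x_up, y_up])
    pts_lo = np.column_stack([x_up[::-1], -y_up[::-1]])
    pts = np.vstack([pts_up, pts_lo[1:-1]])
    # resample uniformly
    seg = np.hypot(*np.diff(np.vstack([pts, pts[:1]]), axis=0).T)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    t = np.linspace(0, arc[-1], n_pts, endpoint=False)
    x = np.interp(t, arc, np.concatenate([pts[:, 0], pts[:1, 0]]))
    y = np.interp(t, arc, np.concatenate([pts[:, 1], pts[:1, 1]]))
    return np.column_stack([x, y])


def synth_cell_image_stack(
    scenario: SyntheticScenario,
    initial_length: float = 8.0,
    band_sigma_px: float = 1.5,
    contrast: float = 1.0,
    margin_um: float = 1.0,
) -> tuple[np.ndarray, list[PlanarOutline]]:
    """Image stack of a growing cell + ground-truth outlines.

    Each frame shows a closed bright band (Gaussian cross-section, fixed
    width and contrast) along the ground-truth outline; the outline advances
    by the scenario's growth increments at the +x end.  Returns
    ``(stack, outlines)`` with outlines in pixel coordinates.
    """
    dh = scenario.growth_increments()
    lengths = initial_length + np.concatenate([[0.0], np.cumsum(dh)])
    px = scenario.pixel_size
    w_um = lengths[-1] + 2 * margin_um
    h_um = 2 * scenario.cell_radius + 2 * margin_um
    nx = int(np.ceil(w_um / px))
    ny = int(np.ceil(h_um / px))
    noise_rng = scenario.rng("image-noise")
    stack = np.empty((len(lengths), ny, nx), dtype=np.float32)
    outlines = []
    yy, xx = np.mgrid[0:ny, 0:nx]
    pix = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
    for j, L in enumerate(lengths):
        pts = _cell_outline_um(scenario, L)
        pts_px = (pts + [margin_um, h_um / 2]) / px
        dense_i = np.linspace(0, len(pts_px), 4000, endpoint=False)
        dense = np.column_stack([
            np.interp(dense_i, np.arange(len(pts_px) + 1),
                      np.concatenate([pts_px[:, 0], pts_px[:1, 0]])),
            np.interp(dense_i, np.arange(len(pts_px) + 1),
                      np.concatenate([pts_px[:, 1], pts_px[:1, 1]])),
        ])
        d, _ = cKDTree(dense).query(pix, k=1)
        img = contrast * np.exp(-0.5 * (d / band_sigma_px) ** 2)
        img = img.reshape(ny, nx)
        if scenario.noise_sd_intensity > 0:
            img = img + noise_rng.normal(0.0, scenario.noise_sd_intensity,
                                         img.shape)
        stack[j] = img
        outlines.append(PlanarOutline(pts_px, pixel_size=px, frame=j,
                                      timestamp=j * scenario.frame_interval))
    return stack, outlines


# --------------------------------------------------------------------------
# fiducial tracks
# --------------------------------------------------------------------------

def synth_qdot_tracks(
    velocity: VelocityProfile,
    meridian: MeridianContour,
    n_tracks: int,
    scenario: SyntheticScenario,
) -> list[QdotTrack]:
    """Fiducial tracks advected by ``v(phi)`` under fluctuating growth.

    Per interval the meridional displacement is exactly
    ``ds = v(phi(s_start)) * dh + noise`` (noise sd =
    ``scenario.noise_sd_length``, clipped so noiseless tracks with v >= 0
    never move toward the pole).  Initial positions are uniform over the cap
    and upper flank.  Requires a meridian with a cylindrical flank (the
    equator normalises v to 1).
    """
    if n_tracks < 1:
        raise ValueError("need at least one track")
    if not meridian.has_flank():
        raise ValueError("meridian has no cylindrical flank: tracks need an "
                         "equator for the v = 1 normalisation")
    dh = scenario.growth_increments()
    rng = scenario.rng("qdots")
    s_init = rng.uniform(0.0, 0.8 * meridian.s_max, size=n_tracks)
    tracks = []
    for i in range(n_tracks):
        s = [float(s_init[i])]
        for h in dh:
            phi = float(meridian.phi_of_s(np.asarray(s[-1])))
            ds = float(velocity(phi)) * h
            if scenario.noise_sd_length > 0:
                ds = max(ds + rng.normal(0.0, scenario.noise_sd_length), 0.0)
            s.append(s[-1] + ds)
        tracks.append(QdotTrack(np.asarray(s), dh.copy(), label=f"qdot{i}"))
    return tracks


# --------------------------------------------------------------------------
# fluorescence profiles
# --------------------------------------------------------------------------

def _gamma_truth(family: str, params: dict, s: np.ndarray) -> np.ndarray:
    if family == "gaussian":
        sig = float(params["sigma"])
        if sig <= 0:
            raise ValueError("sigma must be positive")
        return np.exp(-0.5 * (s / sig) ** 2)
    if family == "cosine_power":
        W = float(params["width"])
        p = float(params.get("power", 2.0))
        if W <= 0 or p <= 0:
            raise ValueError("width and power must be positive")
        out = np.zeros_like(s)
        inside = np.abs(s) < W
        out[inside] = np.cos(np.pi * s[inside] / (2 * W)) ** p
        return out
    if family == "plateau":
        W = float(params["width"])
        if W <= 0:
            raise ValueError("width must be positive")
        return (np.abs(s) <= W / 2).astype(float)
    raise ValueError(f"unknown profile family {family!r}")


def synth_fluorescence_profiles(
    family: str,
    params: dict,
    n_cells: int,
    n_frames: int,
    scenario: SyntheticScenario,
    s_grid: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Frame-wise raw cortical profiles + ground truth.

    Returns ``(s, raw, gamma_truth)`` where ``raw`` has shape
    ``(n_cells, n_frames, len(s))``: ground truth times a per-frame
    lognormal amplitude factor, plus i.i.d. intensity noise and a constant
    background offset (so conditioning has something to subtract).
    """
    if n_frames < 1 or n_cells < 1:
        raise ValueError("need n_cells >= 1 and n_frames >= 1")
    if s_grid is None:
        s_grid = np.linspace(-6.0, 6.0, 241)
    truth = _gamma_truth(family, params, s_grid)
    rng = scenario.rng(f"fluor-{family}")
    amp = rng.lognormal(0.0, 0.1, size=(n_cells, n_frames, 1))
    background = 0.2
    raw = amp * truth[None, None, :] + background
    if scenario.noise_sd_intensity > 0:
        raw = raw + rng.normal(0.0, scenario.noise_sd_intensity, raw.shape)
    return s_grid, raw, truth


# --------------------------------------------------------------------------
# plasmolysis pairs
# --------------------------------------------------------------------------

def synth_plasmolysis_pair(
    params: ElasticParams,
    resting: MeridianContour | None = None,
    noise_sd: float = 0.0,
    scenario: SyntheticScenario | None = None,
    n_outline: int = 240,
) -> tuple[PlanarOutline, PlanarOutline]:
    """Plasmolysed/turgid outline pair from the forward elastic model.

    The turgid outline is the resting (plasmolysed) rod inflated at unit
    pressure with the given material properties; both outlines get i.i.d.
    Gaussian point noise of sd ``noise_sd`` (micrometre).  Solver failures
    propagate.  The ground truth is carried by ``params``.
    """
    scenario = scenario or SyntheticScenario()
    if resting is None:
        resting = MeridianContour.capsule(scenario.cell_radius, 10.0, n=200)
    sol = inflate_shell(resting, params)
    rng = scenario.rng("plasmolysis")

    def to_noisy_outline(m: MeridianContour, frame: int) -> PlanarOutline:
        out = m.to_outline(pixel_size=scenario.pixel_size, frame=frame)
        pts = out.points
        if noise_sd > 0:
            pts = pts + rng.normal(0.0, noise_sd / scenario.pixel_size,
                                   pts.shape)
        # resample to a uniform point count for realism
        idx = np.linspace(0, len(pts), n_outline, endpoint=False).astype(int)
        return PlanarOutline(pts[idx], pixel_size=scenario.pixel_size,
                             frame=frame)

    plasmolysed = to_noisy_outline(sol.resting, frame=0)
    turgid = to_noisy_outline(sol.deformed, frame=1)
    return plasmolysed, turgid
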