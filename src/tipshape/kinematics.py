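"""Wall-expansion kinematics from fiducial (Qdot) tracks.

Growth increments at a cell end fluctuate strongly from interval to
interval, so raw fiducial displacements are noisy.  Normalising each
meridional displacement ``ds`` by the tip advance ``dh`` of the same
interval yields the relative displacement ``v = ds/dh``, which collapses
onto a single master curve ``v(phi)`` (``phi`` the normal angle, 0 at the
pole, pi/2 at the equator).  The master curve is fitted with

    v(phi) = sin(phi) * (a + b*phi**2 + c*phi**4),
    subject to v(pi/2) = 1  (normalised to 1 at the equator),

and differentiated on the meridian into Eulerian strain rates per unit tip
advance:

    eps_s  = dv/ds                 (meridional)
    eps_th = v * cos(phi) / r      (circumferential; -> eps_s at the pole)
    A      = eps_s + eps_th        (areal expansion)

The deformation anisotropy of a wall element born near the pole is
``alpha = (w - l)/w`` where ``w`` and ``l`` are its evolving width and
meridional length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid, trapezoid

from .geometry import MeridianContour

__all__ = [
    "QdotTrack",
    "VelocityProfile",
    "ExpansionProfile",
    "relative_displacement",
    "fit_velocity_profile",
    "strain_rates",
    "expansion_summary",
]

_Q = (np.pi / 2) ** 2  # constraint abscissa phi^2 at the equator


@dataclass
class QdotTrack:
    """Meridional positions of one wall-bound fiducial through time.

    ``s``: per-frame meridional distance from the pole (micrometre);
    ``dh``: per-interval tip growth increment (micrometre, >= 0), length
    ``len(s) - 1``.
    """

    s: np.ndarray
    dh: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        self.dh = np.asarray(self.dh, dtype=float)
        if len(self.dh) != len(self.s) - 1:
            raise ValueError("dh must have one entry per frame interval")
        if np.any(self.dh < 0):
            raise ValueError("tip growth increments must be >= 0")

    @property
    def ds(self) -> np.ndarray:
        return np.diff(self.s)


@dataclass
class VelocityProfile:
    """Coefficients of the constrained meridional velocity fit.

    ``v(phi) = sin(phi) * (a + b*phi^2 + c*phi^4)`` with
    ``a + b*(pi/2)^2 + c*(pi/2)^4 = 1`` enforced exactly.
    """

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        # re-project a on the constraint to absorb rounding
        self.a = 1.0 - self.b * _Q - self.c * _Q**2

    def __call__(self, phi: np.ndarray) -> np.ndarray:
        phi = np.asarray(phi, dtype=float)
        return np.sin(phi) * (self.a + self.b * phi**2 + self.c * phi**4)

    def dv_dphi(self, phi: np.ndarray) -> np.ndarray:
        phi = np.asarray(phi, dtype=float)
        poly = self.a + self.b * phi**2 + self.c * phi**4
        dpoly = 2 * self.b * phi + 4 * self.c * phi**3
        return np.cos(phi) * poly + np.sin(phi) * dpoly


@dataclass
class ExpansionProfile:
    """Strain-rate fields per unit tip advance on a common meridional grid."""

    s: np.ndarray
    eps_s: np.ndarray
    eps_theta: np.ndarray
    areal: np.ndarray
    anisotropy: np.ndarray
    transit: np.ndarray
    band: np.ndarray | None = None  # optional confidence half-width on areal

    def __post_init__(self) -> None:
        for name in ("s", "eps_s", "eps_theta", "areal", "anisotropy", "transit"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))


# --------------------------------------------------------------------------


def relative_displacement(
    track: QdotTrack,
    meridian: MeridianContour,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-interval relative displacement samples ``(phi, v = ds/dh)``.

    Each interval's displacement is attached to the normal angle at the
    interval's starting position.  Intervals with ``dh = 0`` are excluded
    (the normalisation is undefined there) with a warning.
    """
    ds = track.ds
    dh = track.dh
    ok = dh > 0
    if not np.all(ok):
        warnings.warn(f"excluded {np.count_nonzero(~ok)} interval(s) with "
                      "zero tip advance")
    phi = meridian.phi_of_s(track.s[:-1][ok])
    return phi, ds[ok] / dh[ok]


def fit_velocity_profile(
    phi: np.ndarray,
    v: np.ndarray,
) -> VelocityProfile:
    """Constrained least squares for ``v(phi) = sin(phi)(a + b phi^2 + c phi^4)``.

    The equality constraint ``v(pi/2) = 1`` is eliminated exactly by
    substituting ``a = 1 - b (pi/2)^2 - c (pi/2)^4``, leaving an ordinary
    two-parameter linear fit.  Requires at least 3 samples with genuine
    spread in ``phi``.
    """
    phi = np.asarray(phi, dtype=float)
    v = np.asarray(v, dtype=float)
    if len(phi) < 3:
        raise ValueError("need at least 3 samples")
    if np.ptp(phi) < 1e-6:
        raise ValueError("degenerate sample spread in phi")
    sin = np.sin(phi)
    # residual: v - sin*(1 - bQ - cQ^2 + b phi^2 + c phi^4)
    y = v - sin
    X = np.column_stack([sin * (phi**2 - _Q), sin * (phi**4 - _Q**2)])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    b, c = float(coef[0]), float(coef[1])
    return VelocityProfile(a=1.0 - b * _Q - c * _Q**2, b=b, c=c)


def strain_rates(
    velocity: VelocityProfile,
    meridian: MeridianContour,
    s0_fraction: float = 0.02,
) -> ExpansionProfile:
    """Eulerian strain rates per unit tip advance on the meridian grid.

    ``eps_s = dv/ds = v'(phi) * kappa_s``; ``eps_theta = v cos(phi) / r``
    with the pole limit taken by l'Hopital (both tend to the same isotropic
    value at the pole).  The transit coordinate ``t(s) = int ds'/v`` starts
    from ``s0 = s0_fraction * s_max`` since the pole (``v = 0``) is a
    logarithmic singularity.

    The element anisotropy tracks a wall element born at ``s0``:
    ``w(s)/w0 = r(s)/r(s0)``, ``l(s)/l0 = v(s)/v(s0)`` (the transit
    relation for an infinitesimal element), ``alpha = (w - l)/w``.
    """
    m = meridian
    if np.any((m.r <= 0) & (m.s > 1e-9)):
        raise ValueError("meridian radius vanishes away from the pole")
    phi = m.phi
    v = velocity(phi)
    eps_s = velocity.dv_dphi(phi) * m.kappa_s
    with np.errstate(divide="ignore", invalid="ignore"):
        eps_t = np.where(m.r > 1e-9, v * np.cos(phi) / np.maximum(m.r, 1e-300), eps_s)
    areal = eps_s + eps_t
    s0 = max(s0_fraction * m.s_max, m.s[1])
    v_floor = np.maximum(v, 1e-12)
    inv_v = 1.0 / v_floor
    transit = cumulative_trapezoid(inv_v, m.s, initial=0.0)
    transit -= np.interp(s0, m.s, transit)
    r0 = float(np.interp(s0, m.s, m.r))
    v0 = float(np.interp(s0, m.s, v_floor))
    w_rel = m.r / max(r0, 1e-12)
    l_rel = v / v0
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(w_rel > 1e-12, (w_rel - l_rel) / np.maximum(w_rel, 1e-300), 0.0)
    return ExpansionProfile(s=m.s, eps_s=eps_s, eps_theta=eps_t, areal=areal,
                            anisotropy=alpha, transit=transit)


def expansion_summary(
    profile: ExpansionProfile,
    meridian: MeridianContour,
    within: float = 3.0,
) -> dict:
    """Localisation and anisotropy report.

    ``fraction_within``: fraction of the total areal expansion — integrated
    with the axisymmetric surface weight ``2 pi r ds`` — that falls within
    meridional distance ``within`` of the pole.  Also reports the peak
    anisotropy and the element dimension trajectories.
    """
    s = profile.s
    r = np.interp(s, meridian.s, meridian.r)
    w = 2.0 * np.pi * r
    total = trapezoid(profile.areal * w, s)
    mask = s <= within
    inside = trapezoid((profile.areal * w)[mask], s[mask]) if np.count_nonzero(mask) > 1 else 0.0
    frac = float(inside / total) if total > 0 else np.nan
    weight = np.clip(profile.areal, 0.0, None) * w
    wsum = trapezoid(weight, s)
    mean_alpha = float(trapezoid(profile.anisotropy * weight, s) / wsum) if wsum > 0 else np.nan
    return {
        "fraction_within": frac,
        "within_um": float(within),
        "peak_anisotropy": float(np.max(profile.anisotropy)),
        "expansion_weighted_anisotropy": mean_alpha,
        "w_over_w0": (np.interp(s, meridian.s, meridian.r)
                      / max(float(np.interp(s[1], meridian.s, meridian.r)), 1e-12)),
        "total_expansion": float(total),
    }
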