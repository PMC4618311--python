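"""Readers and writers for the package's table formats.

All tables are tab-separated with a header line; ``#`` lines are comments
and CRLF line endings are tolerated.  Floats are written with %.10g so
every domain type round-trips losslessly at that precision.  Reports and
fitted parameters go to JSON; dendrograms to Newick.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import CurvatureKymograph, MeridianContour, PlanarOutline
from .kinematics import ExpansionProfile, QdotTrack, VelocityProfile
from .profiles import FluorescenceProfile

__all__ = [
    "write_outlines", "read_outlines",
    "write_meridian", "read_meridian",
    "write_tracks", "read_tracks",
    "write_profile", "read_profile",
    "write_expansion", "read_expansion",
    "write_kymograph", "read_kymograph",
    "write_json", "read_json",
]

_FLOAT = "%.10g"


def _read_tsv(path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}; "
                         f"found {list(df.columns)}")
    return df


def _write_tsv(df: pd.DataFrame, path, header_comment: str = "") -> None:
    path = Path(path)
    with open(path, "w", newline="\n") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, float_format=_FLOAT)


# -- outlines ---------------------------------------------------------------

def write_outlines(outlines: list[PlanarOutline], path) -> None:
    rows = []
    for o in outlines:
        for x, y in o.points:
            rows.append((o.frame, x, y))
    df = pd.DataFrame(rows, columns=["frame", "x_px", "y_px"])
    px = outlines[0].pixel_size if outlines else 1.0
    _write_tsv(df, path, f"pixel_size_um={_FLOAT % px}")


def read_outlines(path) -> list[PlanarOutline]:
    px = 1.0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") and "pixel_size_um=" in line:
                px = float(line.split("=", 1)[1])
            if not line.startswith("#"):
                break
    df = _read_tsv(path, ["frame", "x_px", "y_px"])
    out = []
    for f, grp in df.groupby("frame", sort=True):
        out.append(PlanarOutline(grp[["x_px", "y_px"]].to_numpy(),
                                 pixel_size=px, frame=int(f)))
    return out


# -- meridians --------------------------------------------------------------

def write_meridian(m: MeridianContour, path) -> None:
    df = pd.DataFrame({"s_um": m.s, "phi_rad": m.phi, "r_um": m.r,
                       "z_um": m.z, "kappa_s": m.kappa_s,
                       "kappa_theta": m.kappa_theta})
    _write_tsv(df, path)


def read_meridian(path) -> MeridianContour:
    df = _read_tsv(path, ["s_um", "phi_rad", "r_um", "z_um",
                          "kappa_s", "kappa_theta"])
    return MeridianContour(s=df["s_um"], phi=df["phi_rad"], r=df["r_um"],
                           z=df["z_um"], kappa_s=df["kappa_s"],
                           kappa_theta=df["kappa_theta"])


# -- tracks -----------------------------------------------------------------

def write_tracks(tracks: list[QdotTrack], path) -> None:
    rows = []
    for t in tracks:
        for j, s in enumerate(t.s):
            dh = t.dh[j - 1] if j > 0 else np.nan
            rows.append((t.label, j, s, dh))
    df = pd.DataFrame(rows, columns=["track", "frame", "s_um", "dh_um"])
    _write_tsv(df, path, "dh_um is the tip advance over the interval ending "
                         "at this frame")


def read_tracks(path) -> list[QdotTrack]:
    df = _read_tsv(path, ["track", "frame", "s_um", "dh_um"])
    out = []
    for lab, grp in df.groupby("track", sort=False):
        grp = grp.sort_values("frame")
        out.append(QdotTrack(grp["s_um"].to_numpy(),
                             grp["dh_um"].to_numpy()[1:], label=str(lab)))
    return out


# -- fluorescence profiles --------------------------------------------------

def write_profile(p: FluorescenceProfile, path) -> None:
    df = pd.DataFrame({"s_um": p.s, "intensity": p.gamma})
    if p.sd is not None:
        df["sd"] = p.sd
    _write_tsv(df, path, f"marker={p.label}")


def read_profile(path) -> FluorescenceProfile:
    label = ""
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") and "marker=" in line:
                label = line.split("=", 1)[1].strip()
            if not line.startswith("#"):
                break
    df = _read_tsv(path, ["s_um", "intensity"])
    return FluorescenceProfile(s=df["s_um"].to_numpy(),
                               gamma=df["intensity"].to_numpy(),
                               sd=df["sd"].to_numpy() if "sd" in df else None,
                               label=label)


# -- expansion profiles -----------------------------------------------------

def write_expansion(e: ExpansionProfile, path) -> None:
    df = pd.DataFrame({"s_um": e.s, "eps_s": e.eps_s, "eps_theta": e.eps_theta,
                       "areal": e.areal, "anisotropy": e.anisotropy,
                       "transit": e.transit})
    if e.band is not None:
        df["band"] = e.band
    _write_tsv(df, path)


def read_expansion(path) -> ExpansionProfile:
    df = _read_tsv(path, ["s_um", "eps_s", "eps_theta", "areal",
                          "anisotropy", "transit"])
    return ExpansionProfile(s=df["s_um"], eps_s=df["eps_s"],
                            eps_theta=df["eps_theta"], areal=df["areal"],
                            anisotropy=df["anisotropy"], transit=df["transit"],
                            band=df["band"].to_numpy() if "band" in df else None)


# -- kymographs -------------------------------------------------------------

def write_kymograph(k: CurvatureKymograph, path) -> None:
    cols = {"s_um": k.s}
    for j, t in enumerate(k.t):
        cols[f"t{_FLOAT % t}"] = k.kappa[:, j]
    _write_tsv(pd.DataFrame(cols), path, "columns are minutes")


def read_kymograph(path) -> CurvatureKymograph:
    df = _read_tsv(path, ["s_um"])
    tcols = [c for c in df.columns if c.startswith("t")]
    t = np.asarray([float(c[1:]) for c in tcols])
    return CurvatureKymograph(df[tcols].to_numpy(), df["s_um"].to_numpy(), t)


def render_kymograph_png(k: CurvatureKymograph, path, cmap: str = "inferno") -> None:
    """Render curvature-vs-time as a heat map."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    t0, t1 = float(k.t[0]), float(k.t[-1])
    if t1 <= t0:  # missing/identical timestamps: fall back to frame index
        t0, t1 = 0.0, float(len(k.t))
    extent = [t0, t1, k.s[0], k.s[-1]]
    im = ax.imshow(k.kappa, aspect="auto", origin="lower", extent=extent,
                   cmap=cmap)
    ax.set_xlabel("time (min)")
    ax.set_ylabel("meridional distance from pole (um)")
    fig.colorbar(im, ax=ax, label="kappa_s (1/um)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# -- JSON -------------------------------------------------------------------

def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_json(report: dict, path) -> None:
    Path(path).write_text(json.dumps(_jsonable(report), indent=2,
                                     sort_keys=True) + "\n")


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())
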