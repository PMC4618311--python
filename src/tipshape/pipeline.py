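"""End-to-end pipeline runner: synthetic data -> geometry -> kinematics ->
elasticity -> growth -> profiles, with a manifest for reproducibility.

A run is fully determined by its config (serialisable mapping) + seed; the
manifest records the config hash, the seed and every artifact written, so
re-running the same config yields byte-identical numeric tables.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import elasticity, geometry, growth, io, kinematics, profiles, synthetic

__all__ = ["PipelineConfig", "run_pipeline", "STAGES"]

#: execution order and upstream dependencies
STAGES = {
    "synthesize": [],
    "geometry": ["synthesize"],
    "kinematics": ["synthesize"],
    "elasticity": ["synthesize"],
    "growth": ["kinematics"],
    "profiles": ["synthesize"],
}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration.

    ``stages``: subset of :data:`STAGES` to run (dependencies must be
    included or already satisfied by a previous run into ``outdir``).
    ``params`` holds per-stage keyword parameters; unknown stages or
    parameters are rejected before execution.
    """

    outdir: str
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    params: dict = field(default_factory=dict)
    version: str = "0.1.0"

    def validate(self) -> None:
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stage(s): {unknown}")
        bad = [k for k in self.params if k not in STAGES]
        if bad:
            raise ValueError(f"parameters for unknown stage(s): {bad}")

    def as_dict(self) -> dict:
        return {"outdir": str(self.outdir), "seed": self.seed,
                "stages": list(self.stages), "params": self.params,
                "version": self.version}

    def digest(self) -> str:
        blob = json.dumps(self.as_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _require(outdir: Path, stage: str, produced: set[str]) -> None:
    for dep in STAGES[stage]:
        if dep in produced:
            continue
        if not (outdir / f".stage_{dep}").exists():
            raise RuntimeError(f"stage '{stage}' needs upstream stage "
                               f"'{dep}' which has not been run")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages in dependency order.

    Returns the manifest (also written to ``manifest.json``): config hash,
    seed, and the artifacts each stage wrote.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"config": config.as_dict(), "config_hash": config.digest(),
                "artifacts": {}}
    produced: set[str] = set()
    arts = manifest["artifacts"]

    scenario = synthetic.SyntheticScenario(
        seed=config.seed, **config.params.get("synthesize", {}))
    run_order = [s for s in STAGES if s in config.stages]

    for stage in run_order:
        _require(outdir, stage, produced)
        files: list[str] = []

        if stage == "synthesize":
            meridian = synthetic.end_meridian(scenario, flank=3.0)
            io.write_meridian(meridian, outdir / "truth_meridian.tsv")
            files.append("truth_meridian.tsv")
            vel = kinematics.VelocityProfile(1.0, 0.0, 0.0)
            tracks = synthetic.synth_qdot_tracks(vel, meridian, 12, scenario)
            io.write_tracks(tracks, outdir / "qdot_tracks.tsv")
            files.append("qdot_tracks.tsv")
            s_g, raw, _ = synthetic.synth_fluorescence_profiles(
                "gaussian", {"sigma": 1.2}, 1, 8, scenario)
            prof = profiles.condition_profile(s_g, raw[0], label="synthetic")
            io.write_profile(prof, outdir / "marker_profile.tsv")
            files.append("marker_profile.tsv")
            stack, outlines = synthetic.synth_cell_image_stack(scenario)
            io.write_outlines(outlines, outdir / "truth_outlines.tsv")
            files.append("truth_outlines.tsv")
            import tifffile

            tifffile.imwrite(outdir / "image_stack.tif", stack,
                             photometric="minisblack")
            files.append("image_stack.tif")

        elif stage == "geometry":
            outlines = io.read_outlines(outdir / "truth_outlines.tsv")
            kwargs = config.params.get("geometry", {})
            s_grid = np.linspace(-3.5, 3.5, kwargs.get("n_s", 101))
            pole_pts = []
            try:
                pole_idx = geometry.locate_pole(outlines[0], outlines[-1])
                fine0 = geometry.resample_outline(outlines[0], 360)
                pole_xy = fine0.points[pole_idx]
            except ValueError:
                pole_xy = None
            for o in outlines:
                if pole_xy is None:
                    pole_pts.append(None)
                else:
                    fine = geometry.resample_outline(o, 360)
                    i = int(np.argmin(np.sum((fine.points - pole_xy) ** 2,
                                             axis=1)))
                    pole_pts.append(fine.points[i])
            kym = geometry.curvature_kymograph(outlines, pole_pts, s_grid)
            io.write_kymograph(kym, outdir / "curvature_kymograph.tsv")
            files.append("curvature_kymograph.tsv")
            io.render_kymograph_png(kym, outdir / "curvature_kymograph.png")
            files.append("curvature_kymograph.png")

        elif stage == "kinematics":
            meridian = io.read_meridian(outdir / "truth_meridian.tsv")
            tracks = io.read_tracks(outdir / "qdot_tracks.tsv")
            phis, vs = [], []
            for t in tracks:
                p_, v_ = kinematics.relative_displacement(t, meridian)
                phis.append(p_)
                vs.append(v_)
            vel = kinematics.fit_velocity_profile(np.concatenate(phis),
                                                  np.concatenate(vs))
            exp = kinematics.strain_rates(vel, meridian)
            io.write_expansion(exp, outdir / "expansion_profile.tsv")
            files.append("expansion_profile.tsv")
            io.write_json({"a": vel.a, "b": vel.b, "c": vel.c},
                          outdir / "velocity_fit.json")
            files.append("velocity_fit.json")

        elif stage == "elasticity":
            kwargs = config.params.get("elasticity", {})
            truth = elasticity.ElasticParams(
                kwargs.get("e_over_p", 58.0), kwargs.get("nu", 0.033))
            pl, tu = synthetic.synth_plasmolysis_pair(
                truth, noise_sd=kwargs.get("noise_sd", 0.0), scenario=scenario)
            fit, resid = elasticity.fit_elastic_params(
                pl, tu, n_nodes=kwargs.get("n_nodes", 70))
            io.write_json({"e_over_p": fit.e_over_p, "nu": fit.nu,
                           "residual_um": resid,
                           "truth": {"e_over_p": truth.e_over_p,
                                     "nu": truth.nu}},
                          outdir / "elastic_fit.json")
            files.append("elastic_fit.json")

        elif stage == "growth":
            kwargs = dict(config.params.get("growth", {}))
            e_over_p = kwargs.pop("e_over_p", 40.0)
            nu = kwargs.pop("nu", 0.3)
            sigma = kwargs.pop("sigma", 1.45)
            params = elasticity.ElasticParams(e_over_p, nu)
            cap = geometry.MeridianContour.hemisphere(
                scenario.cell_radius, flank=2.75, n=120)
            sim = growth.simulate_end_evolution(
                cap, lambda s: float(np.exp(-(s / sigma) ** 2)), params,
                steps=kwargs.pop("steps", 1500),
                n_nodes=kwargs.pop("n_nodes", 50),
                strain_step=kwargs.pop("strain_step", 0.01), **kwargs)
            io.write_meridian(sim.steady_deformed, outdir / "steady_end.tsv")
            files.append("steady_end.tsv")
            io.write_kymograph(sim.kymograph, outdir / "growth_kymograph.tsv")
            files.append("growth_kymograph.tsv")
            io.render_kymograph_png(sim.kymograph,
                                    outdir / "growth_kymograph.png")
            files.append("growth_kymograph.png")
            report = {"converged": sim.converged, "n_steps": sim.n_steps,
                      "end_width_um": float(2 * sim.steady_deformed.r.max()),
                      "pole_curvature": float(sim.steady_deformed.kappa_s[1])}
            if sim.converged:
                report["expansion_selfconsistency_l2"] = \
                    growth.expansion_selfconsistency(sim)
            io.write_json(report, outdir / "growth_report.json")
            files.append("growth_report.json")

        elif stage == "profiles":
            prof = io.read_profile(outdir / "marker_profile.tsv")
            report = {"fwha_um": prof.fwha(), "fw95a_um": prof.fw95a()}
            io.write_json(report, outdir / "profile_widths.json")
            files.append("profile_widths.json")

        (outdir / f".stage_{stage}").write_text("done\n")
        produced.add(stage)
        arts[stage] = files

    io.write_json(manifest, outdir / "manifest.json")
    return manifest
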