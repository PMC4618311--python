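# Methods

`tipshape` quantifies how a walled, tip-growing cell (the model organism is
the fission yeast *Schizosaccharomyces pombe*) shapes its growth domains,
and implements a morphogenetic model in which cell-end geometry emerges
from two ingredients only: the mechanics of the turgor-loaded cell wall and
the spatial pattern of new wall incorporation. This note records the model
assumptions, the numerical choices, what the synthetic-data generators do
and do not emulate, and the known limitations.

## Coordinate conventions

All analysis is axisymmetric and Eulerian. A cell end is described by its
meridian: arclength `s` (µm) measured from the pole, normal angle `phi(s)`
(0 at the pole, π/2 on the cylindrical flank), radius `r(s)`, axial
coordinate `z(s)`, meridional curvature `kappa_s = dphi/ds` and
circumferential curvature `kappa_theta = sin(phi)/r` (continuing to
`kappa_s` at the pole). A curvature profile is integrated into a meridian
via `phi = ∫ kappa_s`, `dr/ds = cos(phi)`, `dz/ds = -sin(phi)`; the
reconstruction and the turning-angle curvature estimator
(`kappa_s = alpha/l` on a finely resampled contour, default spacing 0.1 px
= 6.7 nm at the default pixel size) are mutual inverses, which the tests
verify as a round trip.

Lengths are micrometres everywhere; pixels appear only at the image
boundary (default pixel size 0.067 µm).

## Outline tracking and the pole

Outlines are tracked by accept-if-improves hill climbing: anchor points
(typically 60) move in ±0.25 px steps along the local normal and a step is
kept when it increases the mean pixel intensity sampled at a fixed number
of uniformly spaced points around the closed contour. The score is
deliberately *not* an arclength-weighted integral — a weighted integral is
maximised by lengthening the contour inside a bright band, which makes the
tracker diverge.

The growth pole is the contour point whose orthogonal path to the last
outline of the sequence is longest. Asymmetric contours can misplace it;
a `manual_shift` offset is provided, and the left/right symmetry of the
resulting curvature profile is itself the quality check (axisymmetric
synthetic inputs must give mirror-symmetric profiles, a property test).

## Wall-expansion kinematics

Growth increments at a cell end fluctuate strongly, so fiducial (Qdot)
displacements are normalised per interval: `v = Δs/Δh`, with `Δh` the tip
advance of the same interval. This collapses all intervals onto one master
curve `v(phi)`, fitted by least squares with the canonical form
`v(phi) = sin(phi)(a + b phi² + c phi⁴)` under the exact equality
constraint `v(π/2) = 1` (the constraint is eliminated by substitution, so
it holds to machine precision in every fit; the fit is unweighted).
Strain rates per unit tip advance follow the Eulerian relations for a
steady shape with tangential surface flow:

    eps_s  = dv/ds,   eps_theta = v cos(phi)/r,   A = eps_s + eps_theta,

with the pole limit taken by l'Hôpital (expansion is always isotropic at
the pole). The transit time `t(s) = ∫ ds'/v` starts from a small offset
`s0` (default 2% of the meridian) because the pole is a logarithmic
singularity of `1/v`. Element anisotropy tracks a wall element born near
the pole: width `w ∝ r(s)`, meridional length `l ∝ v(s)` (the transit
relation for an infinitesimal element), `alpha = (w - l)/w`.

## Elastic shell model

The wall is a thin, homogeneous, isotropic, linearly elastic shell loaded
by uniform turgor. Pressures are normalised by turgor `P`, leaving two
material parameters: `E/P` and the Poisson ratio `nu` (values near zero
and slightly negative are admissible — 2D fibre networks under tension can
show them). The wall thickness enters only through `E·t` and `E·t³`; it is
configured as a thickness-to-radius ratio whose default (0.0974) makes the
thin-cylinder estimator map the benchmark mid-cell plasmolysis strains
(0.13 meridional, 0.24 circumferential) to `E/P ≈ 44`. The thickness is
not an observable of this analysis.

The solver discretises the meridian into nodes and minimises total
potential energy (membrane strain energy on the resting metric, written in
engineering strains of the stretches, minus pressure × enclosed volume, so
pressure is a follower load) with L-BFGS-B and an analytic gradient.
Boundary conditions: closed cell (both poles on the axis), open half-cell
(flat "lid" closes the volume term, which applies exactly the axial tension
of the omitted half), or clamped rim (septum). The `bending_shear` variant
adds a plate-like bending energy on the change of curvature
(`D = E t³ / 12(1-ν²)`); transverse shear compliance is not modelled — the
model is a Kirchhoff thin shell, which reproduces the high-curvature
septum and plasmolysed shapes this package simulates.

Numerical notes:

* Convergence uses the optimizer's relative-f stall criterion with a tight
  gradient floor; validation against the closed forms (cylinder:
  `eps_theta = (PR/Et)(1-ν/2)`, `eps_s = (PR/Et)(½-ν)`; sphere:
  `eps = (PR/2Et)(1-ν)`) is run at small pressure where the linear forms
  are exact, and passes within 2% with <0.5% grid-doubling sensitivity.
* A linear membrane has no stable inflated state below a critical
  stiffness (pressure work outruns quadratic strain energy — ballooning).
  At unit pressure and the default thickness ratio this happens for
  `E/P ≲ 30`; the growth loop detects the runaway and raises, and the
  property scan records such grid points as failures.
* Plasmolysis fitting inflates the symmetrised plasmolysed meridian
  (assumed stress-free) over a coarse (E/P, ν) grid refined by
  Nelder-Mead, minimising the symmetric mean-squared point-to-curve
  distance to the turgid outline. Candidates are warm-started only from
  the best-scoring solution so far; warm-starting from arbitrary previous
  candidates lets one diverged solve poison all later ones.

## Septum inflation

The division septum is modelled as a flat disc whose resting meridional
length exceeds its observed span (it is laid down inside the mother wall
and carries no load before separation). The rim is clamped at the old-wall
junction; inflation bulges the disc into a near-hemispherical cap whose
pole deflection grows monotonically with the resting-length factor, and
the cap meets the old wall at an angular jump — the division scar reads as
a curvature ridge at the junction. The default factor 1.3 (resting length
30% over the septum radius) produces the hemispherical new-end geometry.

## Growth model

The model separates biochemistry from mechanics: a stress-free resting
configuration grows by material incorporation, and the observed (turgid)
shape is its elastic equilibrium. Per step:

1. inflate the resting meridian (membrane model, open boundary);
2. evaluate the incorporation profile at the *deformed* arclength from the
   pole (fluorescence and fiducial data live on the turgid surface);
3. grow the resting metric multiplicatively and isotropically at the local
   areal rate. Observed anisotropy is *not* imposed — it emerges from the
   force balance, and the measured expansion of the simulated surface
   indeed favours the circumferential direction, as on real cells.

The step size is chosen so the largest per-step linear strain increment is
0.5–1.5% (1% default in the long runs); with this choice the trajectory is
invariant to the amplitude of the incorporation profile (amplitude sets
the clock, not the shape). The material grid is resampled to uniform
resting arclength each step and trimmed at the base, keeping the domain a
fixed resting length; a `flush_steps` option continues the run past
convergence so material laid down during the initial transient is advected
out of the domain before the steady surface is measured. Convergence is
declared when the pole-frame curvature profile changes by less than
1e-3 µm⁻¹ per step over several consecutive steps. Mass bookkeeping
(resting-area gain per step vs integrated incorporation) closes within 1%.

The default incorporation profile is a Gaussian of width σ = 1.45 µm.
This value was calibrated once so that the model's emergent steady cell
width at the selected material properties (E/P = 40, ν = 0.3) matches the
organism's ~3.5 µm cell width — a real cell's incorporation profile and
radius are mutually consistent, and the resulting steady state places
>90% of surface expansion within 3 µm of the pole, as observed.

Predicted expansion is measured on the simulated surface exactly as the
Qdot analysis measures it on data: virtual fiducials advected over one
growth increment, displacements divided by the tip advance, and the
velocity differentiated on the steady meridian (a lightly smoothing spline
replaces the constrained polynomial here, to avoid imposing the fit
family on the model's own output). Self-consistency — predicted areal
expansion vs the incorporation input — is scored as relative L2 after a
least-squares amplitude match over the growth domain (s ≤ 3.5 µm): the
input is a rate in arbitrary units while the measurement is per unit tip
advance, so only the shapes are commensurate. The residual ~4% is
physical: wall elements restretch elastically as they move through the
gradient of elastic strain, which adds to observed expansion without any
incorporation. The property scan scores integral-normalised areal
profiles by relative L2 on a (E/P, ν) grid, flags the sub-region inside
the target's confidence band, and can select the admissible point nearest
an external (plasmolysis) estimate.

## Fluorescence profiles

Raw cortical profiles are window integrals (±h along the contour normal).
Conditioning: average frames, smooth with a cubic smoothing spline in the
convention `p·Σ(y-f)² + (1-p)·∫f''²` with p = 0.8 (weak smoothing; mapped
to `scipy.interpolate.make_smoothing_spline` via λ = (1-p)/p), subtract
the spline minimum, scale the peak to 1, and (by default) symmetrise about
the pole before widths are computed. The curvature-area correction divides
by `ds·√(2 h R_theta)`; since `R_theta` varies by ~10% and enters under a
square root, the correction is a ≤5% effect.

FWHA / FW95A are the widths of the central interval holding 50% / 95% of
the area under the profile with equal lateral remainders — inter-quantile
ranges of the profile read as a density, computed by cumulative-area
inversion on the grid (ties broken toward the pole-centred interval).
Gaussian references: FWHA = 1.349σ, FW95A = 3.92σ.

The advection–incorporation model for periplasmic wall material is the
steady state of `v·dχ/ds = γ^α - (k + A)·χ`, with deposition nonlinearity
implemented as the power `γ^α` (the minimal one-parameter choice) and
incorporation rate `k`. It is solved by two independent routes — stiff ODE
integration from the regular pole limit `χ(0) = γ(0)^α/(k + A(0))`, and
the closed-form quadrature with an exponential-integrator recurrence that
uses transit-time *increments* (the pole makes the cumulative transit time
divergent, and a naive cumulative sum loses all later increments to
floating-point absorption). The two agree to 1e-4 relative on a
2000-point grid; for large `k` the advected profile converges monotonically
to the deposition profile.

Marker comparison uses euclidean distances on either [FWHA, FW95A] feature
vectors or the predicted steady-end curvature profiles, with agglomerative
linkage (single by default, configurable), exported as Newick. Ergodicity
(time-average vs population-average widths) is tested with a two-sample
Kolmogorov–Smirnov statistic at level 0.05.

## Synthetic data

The generators produce every input the pipeline consumes, with the
geometric and statistical structure the analysis assumes:

* image stacks: a Gaussian-profile bright band along the ground-truth
  outline of a growing rod (band width and contrast are fixed constants;
  only the outline position matters downstream), plus i.i.d. intensity
  noise;
* growth increments: lognormal i.i.d. multipliers around a mean tip
  advance of 0.1 µm per 10-min interval (σ = 0.4, roughly ±50% spurts).
  Real spurts are anticorrelated between the two cell ends; i.i.d. is
  sufficient to test the master-curve normalisation, which is the property
  the generator exists to stress;
* fiducial tracks: per-interval Euler advection `Δs = v(phi(s))·Δh`
  (+ optional clipped noise), matching the analyzer's convention exactly so
  noiseless round trips are machine-precision;
* fluorescence profiles: gaussian / cosine-power / plateau families with
  per-frame lognormal amplitude jitter, constant background and i.i.d.
  noise;
* plasmolysed/turgid pairs: forward runs of the shell model itself with
  optional contour-point noise.

What the generators do **not** emulate: realistic optics (PSF,
deconvolution artefacts), photobleaching, anticorrelated end-to-end growth
fluctuations, non-axisymmetric shapes, Qdot detachment. Tests passing on
synthetic data therefore demonstrate the correctness and statistical
behaviour of the estimators under the model's assumptions, not robustness
to every imaging artefact of real data.

## Problem sizes and defaults

Shell solves use 50–240 nodes (growth loop 45–60; closed-form validation
240). Long growth runs use 1%-strain steps, converge in roughly 300–900
steps and are flushed for ~550 further steps; scans use slightly coarser
settings (45 nodes, 1.2% steps). The recovery studies use 8–20 synthetic
plasmolysis pairs at 1% contour noise. These sizes give grid-doubling
sensitivities below half a percent where the tests assert closed-form
agreement.

## Known limitations

* The membrane constitutive law is linear in engineering strain on the
  resting metric; at the ~25–30% strains of a turgid cell this is a model
  choice, not an approximation theorem (the inverse problems are
  self-consistent because forward and inverse use the same law).
* No viscoelasticity, wall-thickness gradients, anisotropic elastic
  constants, or residual stress in the plasmolysed state.
* The soft-wall ballooning limit (`E/P ≲ 30` at default thickness)
  restricts the scannable parameter domain.
* The growth model has no cell-cycle control: NETO-like activation is an
  input (choice of initial cap and incorporation), not an output.
* Single-end simulations; tip splitting and non-axisymmetric modes are out
  of scope.
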