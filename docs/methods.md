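# Methods

`aneuflow` is a desk-scale, end-to-end reconstruction of a deep-learning
pipeline for predicting cerebral-aneurysm hemodynamics before and after
flow-diverting (FD) stent placement.  Every stage — geometry synthesis, flow
field generation, point-cloud data sets, network training, error evaluation —
is seeded, self-contained and runs on one CPU.  This note records the models,
the parameters that matter, the numerical choices, and what the synthetic
setting does and does not demonstrate.

## Geometry model

An idealized side-wall aneurysm is the union of a circular tube (parent
artery) and a sphere (sac).  Five morphological parameters are drawn
uniformly and independently within clinically motivated ranges:

| parameter | meaning                                   | range    | unit  |
|-----------|-------------------------------------------|----------|-------|
| DA        | sac diameter                              | 8–12     | mm    |
| CC        | sac-center to centerline distance         | 6–8      | mm    |
| DP        | parent-artery diameter                    | 8–12     | mm    |
| CP        | centerline curvature (type 2 only)        | 0.01–0.033 | mm⁻¹ |
| LA        | sac location along the curved artery      | 0–180    | deg   |

Type-1 models have a straight artery (CP = 0); type-2 models a
constant-curvature arc.  Draws must satisfy `CC < (DA+DP)/2` and
`CC + DA/2 > DP/2` (the sphere crosses the wall without being swallowed or
detached); violating draws are rejected and resampled.

The centerline provides 10·DP of run-up upstream of the sac (developed
inflow) and 5·DP downstream.  Because a constant-curvature arc is
homogeneous, the sac's angular position is realized as a bounded upstream
extension, `s_sac = 10·DP + (LA/180)·ΔL` with
`ΔL = min(5·DP, θ_max/CP − 15·DP)` and `θ_max = 5.8 rad`; the cap, and the
companion rejection rule `15·DP·CP ≤ θ_max`, keep the tube from wrapping
onto itself at the high-curvature, large-diameter corner of the parameter
box.  Type-1 models use the `LA = 0` attachment (sac at `s = 10·DP`), which
is also the type-2 limit as CP → 0, so the two families agree in that limit
pointwise (a tested invariant).

The solid is implicit: `sdf(q) = min(sdf_tube, sdf_sphere)`, negative
inside.  A point belongs to the *aneurysm sac* region iff it lies inside the
sphere and outside the tube; neck-interior points (inside both) count as
parent artery so sac statistics are independent of lumen flow.  The neck
orifice is approximated by the circle of radius
`r_neck = sqrt((DA/2)² − (CC − DP/2)²)` on the locally planar wall.

Surface and interior point samplers emulate CFD node distributions:
area/volume-proportional seeded sampling with the interior density doubled
within 0.1·DP of the wall (boundary-refined meshes).  All coordinates are in
meters, inlet centered at the origin with inlet normal +x.

## Flow surrogate

The training-data source is a semi-analytic steady-flow generator whose
contract is the set of flow features steady laminar CFD produces in these
geometries (blood: ρ = 1050 kg/m³, μ = 0.0035 Pa·s; inlet mass flow
0.004375 kg/s; zero outlet pressure):

* **Parent artery.** Poiseuille profile `v = 2 v_mean (1 − (r/R)²)` with
  `v_mean = ṁ/(ρπR²)`, exactly normalized to the inlet mass flow.  For
  curved arteries the axial profile is multiplied by `1 + k (r/R) cos ψ`
  (ψ measured from the outer wall), skewing flow toward the outer wall; the
  skew `k = 0.25·tanh(2.4·sqrt(R·CP))` grows smoothly with a Dean-like
  `sqrt(R·CP)` scaling and the factor integrates to zero net flux, so mass
  conservation is exact.  A weak two-cell in-plane circulation (amplitude
  0.3·k·v_mean, from a stream function `~ sin ψ ρ²(1−ρ²)²`) represents the
  curvature-induced secondary flow.
* **Sac.** A single recirculating vortex about the axis `ê_d × n̂`
  (distal direction × neck normal), speed profile
  `g(ρ) = 6.75 ρ²(1−ρ)` of the normalized spherical radius — zero at the
  core and at the wall, peak at ρ = 2/3 — scaled by the orifice inflow
  speed, plus a Gaussian inflow jet entering at the distal neck edge
  (width 0.15·DA, wall-damped).  The orifice speed is modeled as
  `0.35·v_mean·(1 + 0.5 k)·(0.85 + 0.3 sin LA)`; its dependence on LA and
  CP is a modeling choice, not a measured relation.
* **Pressure.** Axial Hagen–Poiseuille gradient `8 μ v_mean / R²` anchored
  to zero at the outlet; inside the sac the neck-level pressure plus a
  stagnation-scale perturbation (0.3·½ρv_neck², shaped in ρ).
* **Post-operative state.** The FD stent is a thin porous layer on the neck
  patch (thickness 150 μm, permeability K = 0.001489 mm², loss coefficient
  C = 7665 m⁻¹) exerting the Darcy–Forchheimer sink
  `S = −(μ/K · v + C·½ρ|v|·v)`.  Integrated across the thin layer this is a
  pressure-jump law `ΔP(v) = t·(μ/K·v + C·½ρv²)`; the transmitted orifice
  speed solves `ΔP(v_th) = ½ρv_mean²` (positive root of the quadratic).
  Driving the layer with the parent-artery dynamic head gives a transmitted
  fraction of roughly 0.2–0.3 — a strong but finite shunt, consistent with
  the velocity reduction flow diverters produce; driving it with the much
  weaker orifice-jet head would predict a near-total (≥ 97 %) shutdown.
  Post-operative sac velocity scales by this factor pointwise, and sac
  pressure drops by `ΔP(v_th)`.
* **Noise.** A seeded smooth random field (sums of 8 Gaussian bumps per
  component, normalized to |η| ≤ 1) perturbs velocity by
  `fraction·|v|·η` (default 2 % of the local speed) and pressure
  analogously, so the learning task is not exactly low-dimensional.  No-slip
  and the outlet anchor survive the noise by construction.

The surrogate drops what the study conditions do not require: unsteadiness,
turbulence, non-Newtonian rheology, fluid–structure interaction and wall
shear stress.  Externally computed fields can replace it through the
legacy-VTK import adapter, making the learning stack CFD-agnostic.

## Data sets

Each model contributes a *model point cloud* (boundary coordinates only) and
a *query point cloud* (interior coordinates with per-point velocity and
pressure).  Four variants are assembled — {pre, post}-operative ×
{velocity, pressure} — sharing geometry and sampling, and split 9:1 into
train/test stratified by model type with per-stratum floored test counts
(500 models at 100/400 give exactly 450/50 with 90 type 1 + 360 type 2).
Post-operative query clouds include points in the stent-layer region with no
FD label.  Serialization: legacy-VTK polydata, ASCII PLY, or a compressed
archive with a JSON manifest.

## Network

A double-input, double-sampling-channel point-cloud regressor:

* shared per-point primary stage (widths 64–64–128, ReLU) applied to both
  clouds — FC1/FC2 weight sharing;
* global channel 128→256→512 followed by a coordinate-wise max over model
  points (order-invariant geometry descriptor, tiled to every query point);
* local channel 128→128 per query point;
* stitched 640-d (512+128) feature through an output stack 640→256→128→out
  (3 velocity components or 1 pressure value, linear output).

Training: mean absolute error, Adam (lr 0.001, β₁ 0.9, β₂ 0.999, δ 1e−8),
one model per optimization step (batch size 1).  Additions this
implementation makes, as its own design choices:

* **Cosine learning-rate decay** from 0.001 to 0 over the epoch budget.
  MAE sign gradients give Adam constant-magnitude steps, so constant-lr
  training stalls at a noise floor; annealing is what lets the loss keep
  falling.  The best-validation-loss weights are checkpointed (10 % of the
  training pairs held out; patience-based stopping).
* **Input normalization**: per-pair centering on the model-cloud centroid
  (translation invariance, a tested property) and scaling by one
  train-set-global radius.  Per-pair scaling would erase absolute vessel
  size, which — at fixed inlet mass flow — determines the velocity scale.
* **Target standardization** per data set, with vector targets sharing one
  scale (per-component standardization would inflate the small transverse
  velocity components and unbalance the MAE loss).
* **Input-derived target scaling** (optional, on by default in the
  pipeline): targets are multiplied by `(R̂/R_ref)^p` before
  standardization, where R̂ is the lumen radius read off the inlet-cap
  points of the model cloud (the pose convention puts the inlet in the
  x = 0 plane) — p = 2 for velocity (v_mean ~ R⁻²) and p = 3 for pressure
  (axial drop ~ R⁻³).  The factor is computed from inputs only and inverted
  at prediction, so the network learns a dimensionless field shape.
* Per-step subsampling of large clouds (default 800 query / 400 model
  points per step) keeps one optimization step affordable; prediction and
  evaluation always use all points.

## Error metrics

For one model with reference values Q and predictions Q̂ over N₂ points:

* `NMAE = 100 · mean|Qᵢ − Q̂ᵢ| / (Max|Q| − Min|Q|)` — the magnitude range is
  taken over the *whole model*, also when a sub-region (the sac) is
  evaluated; renormalizing by a sub-region's own small range would make the
  region metric explode for near-uniform sac fields.
* `MRE = 100 · mean|Qᵢ − Q̂ᵢ|/|Qᵢ|` over points with
  `|Qᵢ| ≥ 10⁻³·max|Q|` (whole-model max).  The floor is this package's
  guard — the per-point ratio is unbounded as the true value vanishes near
  walls — and the number of excluded points is always reported.

Velocity fields are scalarized to their magnitude before either metric
(per-component mode behind a flag).  Reports aggregate mean ± std across
test models, for the whole model and the sac region separately; the ± is
across models, not points.

## Scaled-down study conditions and what they show

The package's `desk` preset is the study configuration used by the tests
and the acceptance script: 50 models per variant (10 type 1, 40 type 2),
~2,000 query points and ~600 boundary points per model, 2 % field noise,
9:1 stratified split, velocity networks trained 250 epochs and pressure
networks 120 epochs (≈ 10,000 / 5,000 Adam steps), about 11–13 minutes for
all four variants on one CPU.  Sizes were chosen so a full run fits a
single desktop session.

Two findings about this scale are worth recording honestly:

* **Per-model capacity is not the limit.**  Trained against a single held
  -out geometry, the network reaches whole-model NMAE < 1 % and MRE ≈ 9 %
  (≈ 8,000 steps), so the architecture and optimizer can represent and fit
  the surrogate fields to well inside the headline error bounds.
* **Geometry interpolation is the limit.**  With 36 type-2 training
  geometries the test error on unseen type-2 models plateaus near
  10–15 % NMAE.  This is a property of the sample size, not of the
  network: a random forest given the *oracle* morphological parameters as
  extra features does worse (17–20 %) on the same split.  High-curvature
  arteries curl 90°–330°, so fields at fixed spatial locations decorrelate
  sharply across the 4-parameter geometry family, and 36 samples
  undersample it.  Error bounds quoted for full-size data sets (an order
  of magnitude more geometries and two orders more points) should not be
  expected to transfer to this scale, and the relative-error metric is
  additionally dominated by slow near-wall points once the absolute error
  exceeds a few percent of the local speed.

What the passing tests do show: exact mass-flux recovery and closed-form
profile/pressure oracles; the porous-layer quadratic and its transmission
root; strict post-operative sac-speed reduction across 50 seeded geometries,
monotone in the loss coefficient; network permutation invariance and
equivariance; deterministic regeneration of every data set from recorded
seeds; and the qualitative orderings — type-2 errors above type-1, sac
errors above whole-model — that the underlying physics makes harder to
learn.  What they do not show: performance on real, patient-derived lumen
geometries or real CFD fields, pulsatile flow, or the full-size training
regime.

## Numerical choices and degenerate inputs

* Implicit-solid containment uses a 1e−9 m tolerance so boundary quadrature
  nodes count as inside; field generation rejects outside points with their
  indices.
* The transmission factor is the closed-form positive root of the
  Forchheimer quadratic (no iteration); its consistency with the
  pressure-drop law is tested to 1e−9 relative.
* The MRE floor, exclusion counting and the exact-zero exclusion are the
  guards against unbounded per-point ratios; NMAE raises on zero-range
  (degenerate) fields rather than returning infinity.
* Stratified splitting floors the per-stratum test count with an epsilon
  guard against `n·(1−ratio)` landing just below an integer in floating
  point.
* Network weights are float32; He initialization; the max-pool gradient
  routes to argmax rows.  Training is bit-reproducible for a fixed seed on
  a fixed BLAS; across BLAS builds reproducibility is best-effort
  (documented, not asserted).
* Geometry construction enforces only geometric validity, so limit studies
  (CP → 0) may use curvatures below the sampled range; range enforcement
  happens at the sampler.

## Known limitations

* Idealized tube-plus-sphere lumens only; no fusiform or bifurcation
  aneurysms, no patient-specific reconstruction.
* The surrogate's neck-inflow law and sac vortex are plausible but not
  CFD-calibrated; they define the learning task, not a validated
  hemodynamic prediction.
* Isotropic scalar permeability and loss coefficient on the neck patch.
* The generalization plateau above means desk-scale error statistics are
  conservative relative to the full-size configuration.
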