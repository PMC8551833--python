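# Methods

`lvestim` studies whether the passive material properties and loading of the
left ventricle can be recovered from imaging-style kinematic observations by
optimising the inputs of a frozen neural surrogate of a mechanics model. This
note records the model, the design choices, and what the synthetic studies do
and do not demonstrate.

## Forward model

The ventricular wall is reduced to an incompressible thick-walled spherical
shell (reference endocardial radius `A`, epicardial radius `B`) of a
Fung/Guccione-type exponential material,

    psi = c1/2 * (exp(Q) - 1)
    Q   = c2*E_ff^2 + c3*(E_cc^2 + E_rr^2 + E_cr^2) + 2*c4*(E_fc^2 + E_fr^2)

with fibres along the local circumferential direction, `c3 = 3.67` and
`c4 = 25.77` held fixed (their identifiability from macro-scale kinematics is
poor), and `c1` (kPa) and `c2` (dimensionless) free. Under spherical symmetry
the inflation kinematics are exact: a reference radius `R` maps to
`r(R) = (R^3 + a^3 - A^3)^(1/3)`, so incompressibility holds to machine
precision and every displacement field is purely radial. The inflated inner
radius `a` solves the radial equilibrium integral
`p = \int_a^b lam * W'(lam) / r dr` (64-point Gauss-Legendre quadrature,
Brent root-finding, 1e-10 tolerance), where `W(lam)` is the energy along the
symmetric deformation path. Two independent oracles guard the implementation:
exact volume conservation across the wall, and agreement of the equilibrium
pressure with the derivative of total stored energy with respect to cavity
volume (virtual work) to 0.5%.

### Geometry calibration

The shell radii default to `A = 25 mm`, `B = 25.75 mm`. The thin wall is a
deliberate compliance calibration, not an anatomical thickness: a closed
spherical wall admits no bending, so at a realistic 10 mm thickness the shell
is several times stiffer than a diastolic ventricle and its fibre strains at
the stiff end of the physiological parameter window (`c1 = 5 kPa`,
`c2 = 40`, `p = 0.9 kPa`) would be ~0.015 — a regime in which `c2` has
essentially no kinematic signature and no estimator could recover it. With a
0.75 mm wall the shell reproduces the kinematic regime the estimation problem
is posed in: stiff-corner wall displacement ≈ 2.2 mm (the same order as the
1 mm observation noise), mid-range displacement ≈ 3.7 mm, soft-corner maximum
≈ 10 mm, fibre strains 0.02–0.5, and a strictly monotone pressure–radius
response over the whole window (verified numerically; the exponential
stiffening excludes balloon-type limit points).

## Synthetic observations

All observations are generated by the forward model; there is no model error
between the data-generating process and the physics the surrogate is trained
on, which matches the design of the estimation study (the estimators see
surrogate-approximation error and observation noise only).

* Full-field observations: seeded uniform samples of the wall volume
  (default 1109 material points) with their exact displacement vectors.
* Contour observations: endo- and epicardial sphere samples on Fibonacci
  lattices under seeded random rotations (quasi-uniform spacing keeps the
  directed-distance discretisation floor low). Defaults: 7579 points per
  observed (loaded) surface, 1072 per sparse reference surface. The same
  material surface points are observed at every frame of a trace.
* Pressure traces: linear from 0.15 kPa (the lower training bound, taken as
  the diastasis load) to the end-diastolic pressure, default 10 frames.
* Observation error: `u_eps = (r/|r|) * eta` with `r` drawn component-wise
  U(0,1) and `eta ~ N(0, sigma)`, `sigma = 1 mm` (≈ two MRI pixels) — added
  to displacement vectors and to loaded-surface points, never to reference
  surfaces. The U(0,1) components confine directions to the positive octant;
  this literal convention is the default and a uniform-sphere alternative is
  provided. Because the magnitude `eta` is symmetric about zero, the
  effective error is sign-symmetric along a random octant direction.

## Displacement surrogate

A fully connected tanh network maps `(x, y, z, p, c1, c2)` to the 3-D
displacement of the material point at `x` (mm). Defaults: two hidden layers
of 48 units, inputs affinely normalised to [-1, 1] from the training ranges
(`p` in [0.15, 1.5] kPa, `c1` in [2, 5] kPa, `c2` in [4, 40]), outputs
scaled by the target standard deviation, and the reference radius `|x|`
appended as a seventh input feature (the geometry is radially parameterised,
and the feature conditions training without changing the differentiable
input surface). Training minimises the boundary-penalised squared error
(penalty `alpha = 4.5` on endo/epi surface samples) with mini-batch Adam
(batch 4096, step 0.02 decaying by ~0.9983 per epoch, 3500 epochs, float32
arithmetic), a seeded 90/10 train/test split, and best-by-test-loss weight
selection.

The training set pairs 120 Latin-hypercube `(c1, c2)` draws, 72 further
pairs spread along the four edges of the `(c1, c2)` window and its corners,
with five stratified pressures each, and 62 seeded spatial samples per
combination (50 interior, 12 on the surfaces). Stratifying pressure within
each material was chosen over an isotropic 3-D Latin hypercube because the
inverse estimators read the surrogate along pressure traces: the joint
`(c1, c2)` estimate is exquisitely sensitive to the curvature of the
pressure response, and systematic curvature misfit maps onto a
stiffer-`c1`/softer-`c2` bias. Edge coverage matters because recovery is
evaluated across the whole window, and a network fitted on an interior-heavy
sample degrades exactly at the range edges where several study truths live.

Under these defaults the held-out mean absolute displacement error is
≈ 0.007 mm (per-component MSE ≈ 2e-5 mm^2), comfortably below the 0.0499 mm
/ 1.30e-3 mm^2 gates that the estimation studies presume. MSE here is the
standard per-component regression MSE; the gates are mutually consistent
only under that reading (0.0499^2 + 0.0374^2 ≈ 3.9e-3 mm^2 for the vector
norm, divided by three components ≈ 1.3e-3 mm^2).

## Inverse estimation

Both estimators freeze the network weights and optimise a subset of its
inputs (`p`, `c1`, `c2`) by Adam (beta = (0.9, 0.999), eps = 1e-8) on exact
input-gradients obtained by backpropagation. Parameters are updated in the
normalised [-1, 1] input coordinates — the only space in which the initial
step size `tau0 = 1` is meaningful across kPa and dimensionless units — and
reported in native units. The step size decays as `tau_i = tau0 *
0.985^(i/10)`; iteration stops when the max-norm relative parameter change
(reference scale: the training-range width per parameter) drops below 1e-5,
or at the epoch cap. Estimates are soft-clipped to the training ranges with
a warning when a trajectory touches a bound; initialisation defaults to the
range midpoints (p 0.825 kPa, c1 3.5 kPa, c2 22).

* Full-field tracking: `L = ||u(theta) - u_hat||_L2`, the root of the summed
  squared vector errors over the tracked points (per frame; frames add).
  Below a 1e-3 mm floor the root norm's gradient is taken as zero — the
  objective is non-differentiable at exact match and the residual direction
  there is float32 round-off noise.
* Contour matching: the reference surfaces are displaced by surrogate
  predictions at their points and compared with the observed loaded surfaces
  through the directed mean nearest-neighbour distance
  `d(s1, s2) = 1/|s1| sum_x min_y ||x - y||`, summed over endo and epi.
  Gradients flow through the selected nearest pair only (first index wins at
  ties).

### Argument order of the directed distance

`d` is asymmetric and both orders are implemented. Averaging over the dense
observed surface (`dense_first=True`, the package default) places the
minimisation over the sparse displaced surface; on a sphere this order
carries a curvature-induced discretisation bias — the nearest sparse
neighbour of a dense point improves, on average, when the sparse sphere
shrinks by about `E[t^2]/(2R)` (`t` the tangential nearest-neighbour offset,
`R` the radius), ~0.05 mm at the default sampling. That is invisible for
coarse work but maps to 1–2% pressure bias at the stiff end and a
stiffer-`c1` bias in joint estimation. The literal order
(`dense_first=False`) minimises over the dense surface, whose 4–7x finer
spacing shrinks the bias by the same factor, and under observation noise its
radial profile is symmetric (the noise enters the minimised side evenly), so
the reproduction studies in `lvestim.study` use the literal order
throughout. The oversampled order remains the module default and is
recommended when the observed segmentation is much denser than the model
discretisation and noise dominates discretisation.

During optimisation at scale the nearest-neighbour search is restricted to
the `k = 8` angular neighbours of each query point (KD-tree on unit
vectors, computed once per run): the displaced surfaces remain near-spherical
(surrogate predictions are radial to within the model error), so angular
proximity determines the nearest neighbour; tests verify the pruned search
is exact against brute force on the study geometry. The public
`directed_mean_nn_distance` and the landscape scans always use the exact
computation.

### Batched execution

The experiment harness optimises all runs of a study (grid cells x
replicates) in lock-step: runs share no state and gradients never mix, so
one vectorised Adam loop is numerically identical to looping runs one at a
time. The hot path folds the constant spatial part of the first network
layer into a precomputed base (only the estimated inputs change between
epochs, and they are constant within each run x frame row segment) and
evaluates the remaining layers in float32; tests pin the engines to the
float64 reference losses and gradients at 1e-3 relative or better.

### Stopping in practice

The literal last-epoch change rule fires spuriously whenever Adam's
momentum crosses zero mid-oscillation (a single sub-tolerance step while the
iterate is still far from the minimum), so convergence requires the
criterion to hold on three consecutive epochs. Independently, the slow decay
means that at any affordable epoch count the final iterate still oscillates
by 1–2% of the range; the estimators therefore support (and the studies use)
a Polyak-style tail average of the last 100 iterates, which removes the
residual step-size jitter at a fraction of the epochs a tiny final step size
would need. For a run that genuinely converges the tail is constant and the
average coincides with the final iterate.

## Study configuration

The reproduction studies (`lvestim.study`, driven by
`scripts/acceptance.py`) run at desk scale on one CPU core:

* every estimation run uses a 600-epoch Adam budget with the last 100
  iterates tail-averaged (see above; verified equivalent to 1500-epoch runs);
* noise-free pressure recovery: 5x5 `(c1, c2)` grid at `p = 0.9 kPa`, full
  default observation sampling (1109 / 7579 / 1072 points);
* noisy multi-frame stiffness recovery: 3x3 grid, 10 replicates, 10-frame
  traces to 0.9 kPa; full-field uses 800 tracked points per frame, contour
  250 reference / 1500 observed points per surface per frame;
* noisy pressure recovery: single loaded frame, 1109 tracked points,
  10 replicates.

The noisy-study grid uses interior truths ({2.5, 3.5, 4.5} kPa x
{10, 22, 34}): a truth sitting exactly on the estimator's soft-clipping
bound produces censored error statistics — a fully pinned cell reports
exactly 0% error (spuriously optimistic) while a half-pinned cell dumps the
whole noise budget into the free parameter (spuriously pessimistic). The
estimation problem the noise studies characterise is recovery inside the
physiological window, not behaviour on the optimiser's constraint boundary.

### Noise floors of the joint stiffness estimate

Because the spherical reduction collapses fibre and cross-fibre strain,
`c1` and `c2` are separated only by the curvature of the pressure response;
observation noise projected onto this shallow valley is amplified several
fold. Running the complete ten-frame noisy protocol with observations
generated *by the surrogate itself* (zero model error, 1109 points per
frame) measures the irreducible floor: mean c1 errors of 0.99 / 1.93 /
3.05 % at (c1, c2) = (2.5, 10) / (3.5, 22) / (4.5, 34), and c2 errors up to
2.7 % — for one noise seed; the per-cell means are themselves heavy-tailed
across seeds (individual replicates reach ~10 % when a noise realisation
pushes the estimate along the valley to a range bound), so the max-over-grid
statistics scatter by roughly a factor of two between master seeds, fully
converged. Mean full-field c1 errors of ~2 % across the whole grid are
therefore not reachable on this geometry for any estimator, and the
contour-matching c2 error sits at or above its ~3 % floor for most seeds;
those study outcomes should be read against these floors rather than as
estimator defects. The pressure targets and the c2 bound of the full-field
study are above their floors.

## Limitations

* The reduced shell has no bending, no fibre rotation through the wall, no
  basal boundary condition and no patient-specific shape; behaviour that
  depends on those features (e.g. non-radial displacement near the base) is
  out of reach, and the absolute error levels reported here calibrate the
  method, not clinical accuracy.
* Under spherical symmetry the fibre and cross-fibre strains coincide, so
  `c1` and `c2` are distinguished only through the nonlinearity of the
  pressure response — a worse-conditioned problem than in an anatomical
  ventricle, which makes the joint estimates unusually sensitive to
  systematic surrogate error (the motivation for the pressure-stratified
  training set).
* Observation noise is unbiased by construction; systematic segmentation or
  tracking bias is not modelled and would add directly to parameter bias.
* The synthetic data contain no model discrepancy: the same physics
  generates observations and training data. Passing studies demonstrate the
  estimation machinery, not robustness to model misspecification.
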