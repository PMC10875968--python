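# Methods

This note documents the models implemented in `mrmotion`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical choices that affect results.

## Geometry conventions

The internal world frame is LPS-flavoured and axis-aligned: world axis 0
is LR (+left), 1 is AP (+posterior), 2 is SI (+superior).  Voxel indices
are 0-based, positions refer to voxel centres, and `world = origin +
index·spacing`.  NIfTI files (RAS+) are reoriented and sign-flipped at the
I/O boundary; only orthogonal axis-aligned affines are supported.  The
handedness choice is a pure convention — any self-consistent frame gives
identical results — and is fixed here once so that acquisition,
reconstruction and evaluation can never drift by half a voxel relative to
each other.

## Transformation

The transformation is a cubic B-spline free-form deformation: a regular
control-point lattice of displacement vectors (in mm, not voxels — slices
and volume have different spacings) interpolated with the centred cubic
B-spline.  The lattice always covers the target field of view plus the
support margin, so every evaluated point has its full 4-point stencil per
axis; evaluating outside that region is an error rather than an
extrapolation.  The core is dimension-agnostic: the 2D registration used
for surrogate extraction runs through the same code as the 3D motion
model.

Image interpolation inside `T` is trilinear.  It is differentiable almost
everywhere, exact on locally linear intensities, and its adjoint is a
plain scatter with the same corner weights — `warp_pull`/`splat_push` are
exactly adjoint as linear maps, which the tests verify to rounding error.
Samples that leave the image domain are flagged invalid and excluded
downstream, not zero-filled; zero-filling would create artificial
gradients at the FOV edge exactly where slice data is scarcest.

Bending energy is the mean squared second derivative of the displacement
field (all six unique second-derivative tensors, mixed terms doubled)
over a regular sample lattice covering the FOV at two samples per control
spacing, with an analytic gradient.  Per-sample normalisation keeps the
penalty weight comparable across lattice resolutions; the sampling density
is a package choice (the penalty is quadratic, so moderately denser
sampling changes values only marginally).

Grid refinement is the classical dyadic B-spline subdivision
(1/8·(c₋₁+6c₀+c₊₁) and 1/2·(c₀+c₊₁)), which reproduces the continuous
field exactly (tested to 1e-9 mm).

## Acquisition operator

A thick slice is modelled as a Gaussian slice-selection profile along the
slice normal with FWHM equal to the slice thickness (10 mm by default).
The profile is truncated at 1.5× the thickness (≈3.5σ, >99.9% of the
mass) and renormalised over the quadrature samples that fall inside the
volume, giving the operator bounded support and bit-reproducible values.
Through-plane quadrature pitch equals the smallest voxel spacing: a
σ≈4.25 mm profile is already well resolved at 2 mm, and halving the pitch
changed the validation metrics by well under 0.1% at roughly twice the
cost (the factor is a module constant for anyone wanting the denser
rule).
The adjoint spreads pixel values along the same normalised weights, so
`A`/`A*` are exactly adjoint.  Where the model enters, `A_t∘T` is fused:
the reference image is sampled directly at the displaced quadrature
points, avoiding a double interpolation through an intermediate volume.

The schedule builder reproduces the interleaved pattern: sagittal motion
slices sweep LR across the (body-restricted) FOV, then axial slices sweep
inferior→superior; each motion slice is preceded by a surrogate slice at
a fixed sagittal plane through the tumour; the whole sweep repeats at
through-plane shifts 0, 2, 4, 6, 8 mm (a *repetition*), which provides the
overlapping slice grid that super-resolution needs — shifts exceeding the
thickness are rejected.  Frame interval defaults to 1/2.86 s (centre of
the 2.7–3 Hz cine range); both orientations cover the same cuboid FOV.

## Synthetic data

The generator is a procedural stand-in for an anthropomorphic torso at
the acquisition's scale (default 128 mm cube, 2 mm isotropic): a body
ellipsoid, two lung ellipsoids bounded below by a diaphragm dome, a
tumour sphere inside a lung, bright intra-lung vessel spheres (these
provide the image structure that drives registration and fitting inside
the otherwise dark lungs), heart and sub-diaphragm liver analogues, a
smooth intensity inhomogeneity and mild smoothed-noise soft-tissue
texture.  Tissue intensities sit on a 0–150 scale with soft tissue at 100.

**Breathing trace.**  Two driving signals: `a1` is built cycle by cycle
with period ~N(4 s, 0.5 s), amplitude ~N(1, 0.15) and a raised-cosine
within-cycle shape; `a2` is a scaled temporal derivative of `a1`
(`a2 = 0.4 s · da1/dt`), so the pair traces hysteresis loops.  The trace
is centred on its *vector median* state — the element of {(a1, a2)}
minimising summed distances — which is exactly the convention the
modelling pipeline uses for its zero-signal reference.  This matters: if
the generator's zero state differs from the pipeline's reference state by
Δa, the true t→reference field contains a composition term of order
|∇u|·|u(Δa)| that a linear no-intercept model cannot represent (measured
at ~0.3 mm body-mean before this alignment).  An optional linear drift is
off by default.

**Ground-truth motion.**  Two flavours share the same analytic driving
fields: SI-dominant displacement, flat over the diaphragm/abdominal
interior with a decisive lateral rolloff toward the chest wall (the body
surface barely moves in respiration — and, incidentally, edge motion is
also the part the slice geometry observes worst), decaying toward the
apex and the inferior FOV boundary; a smaller AP chest component; and a
hysteresis field concentrated around the diaphragm with AP/LR weight:

* `svf` — the displacement for state (a1, a2) is the scaling-and-squaring
  exponential of the stationary velocity field `a1·v_A + a2·v_B`;
  forward and backward fields are exponentials of ±the field and hence
  mutually inverse by construction (measured residual ~0.01 voxel mean,
  <0.05 voxel max over the body at extreme amplitudes).
* `span` — the backward (t→0) displacement is exactly the B-spline field
  `a1·W_A + a2·W_B` on a 16 mm control lattice, i.e. motion exactly
  representable by the fitted model.  This separates model
  *discretisation* error from *fitting* error: parameter-recovery
  experiments use `span`, realism-oriented runs use `svf`.

All field arithmetic (exponential, composition, inversion) runs on a
lattice padded 24 mm beyond the FOV so that composed sample paths stay
supported; results are cropped back.  Composition follows
`u_{ta→tb}(x) = u_{ta→0}(x) + u_{0→tb}(x + u_{ta→0}(x))`.
Peak SI displacement is configurable in the 5–20 mm range (default
10 mm); AP/LR components are smaller by construction; the hysteresis
fields produce loops of roughly 2–3 mm, mid-range for published lung
tumour hysteresis observations (~1–5 mm).  The default amplitude is a
deliberate compromise: the apparent 2D displacement of a 10 mm slab
responds *nonlinearly* to large through-plane-integrated motion, and
above ~12 mm peak the quadratic component of that response outgrows the
hysteresis signature in the surrogate registrations, so the second
principal component no longer tracks hysteresis.  At 10 mm the two-signal
premise holds cleanly; the resulting body-mean motion magnitude (~1.8 mm)
is gentler than a large-motion patient, which passing tests should be
read against.

**Slice simulation.**  Each scheduled slice deforms the phantom by the
backward ground-truth DVF of its frame, applies the Gaussian-profile
operator, and adds Rician noise (magnitude of the signal plus two
independent Gaussian channels), with σ given relative to soft tissue
(default 5%).

**What is not emulated.**  Sliding motion at pleural interfaces (the
B-spline transform could not represent it anyway and it is a known
failure mode of this model class), cardiac motion, sudden events
(coughs), k-space/readout physics, and receive-coil effects.  Passing
tests therefore demonstrate correctness of the estimation machinery under
smooth, invertible, two-signal-driven motion — not robustness to sliding
or to real-scanner artefacts.

## Surrogate signals

The reference slice is the candidate (first shift of the first
repetition) with minimal L1 distance to the voxelwise temporal median
image — an operationalisation of "closest to mid-position".  Every
surrogate slice is registered to it with a 2D cubic B-spline FFD: SSD on
p99-normalised intensities, bending weight 0.01, control spacing
40→20→10 mm with Gaussian image smoothing at the coarse levels,
Polak–Ribière conjugate gradient (≤80 iterations, gradient tolerance
3e-4 referenced to the zero-displacement gradient so warm starts converge
to the same accuracy).  Registrations are warm-started from the previous
frame (the stream is temporally coherent).

Two regularisation variants of the same registration serve different
purposes.  For *surrogate extraction* a small uniform displacement ridge
(weight 0.01) stabilises the control-point trajectories: regions without
image structure cannot be constrained by SSD, and without an anchor they
drift into the PCA as a spurious dominant mode.  The ridge shrinks
magnitudes slightly, which is irrelevant for PCA (only a consistent
linear response matters).  For *magnitude-faithful* registration
(residual-error evaluation) the ridge is applied only outside the dilated
image foreground, leaving in-body magnitudes unbiased.

PCA (scikit-learn, full SVD) is fitted on the building-phase rows only
and frozen before being applied to all rows — fitting on evaluation rows
would leak application-phase data into the model.  Rows are restricted to
control points whose B-spline support overlaps image content; air control
points carry only regularisation noise.  Component signs are fixed by
positive correlation with the mean SI control-point displacement (PCA
signs are otherwise arbitrary).  The first two components are the
signals; they are normalised to the building-phase vector median (the set
element minimising summed Euclidean distances, found exhaustively in
O(n²)), whose time point becomes `t_r` with `S(t_r) = 0` exactly.
Motion-slice signals are linear interpolants in time, clamped at the
boundaries.

## Model fitting

The similarity is the per-slice *mean* squared difference over valid
pixels on p99-normalised intensities — the mean (not the raw sum) so
sagittal and axial slices with different valid-pixel counts contribute
comparably, and the normalisation so the regularisation weights have an
image-independent meaning.  Two integrity details matter for large
motion: the per-slice normaliser is frozen at the zero-displacement
valid-pixel count (normalising by the current count would let the
optimiser lower the objective by pushing pixels out of the FOV rather
than explaining them), and a support-weighted displacement ridge
(`lambda_disp`, default 0.05) anchors control points whose B-spline
support sees no image content.  The bending term is summed over time
points inside the objective so the meaning of λ does not depend on slice
count; because `M_t` is linear in the signals, `Σ_t BE(M_t)` (and the
ridge) collapse to quadratic forms through the signal Gram matrix — the
penalty cost is independent of the number of slices.  The gradient
back-propagates the residual through the fused `A_t∘T` operator (profile
weights × exact trilinear gradient of the sampled reference) and scatters
it onto the component lattices through the B-spline weights, scaled by
each slice's signal; it matches central finite differences to ~1e-9 of
the gradient scale.

The bending weight deserves its own note.  The slice stream leaves a
*near-flat valley* of deformations that reproduce the data to within the
discretisation error — roughly half a millimetre of body-mean
displacement is data-invisible at these conditions — so the regulariser,
not the data, resolves that null space.  On synthetic ground truth the
deformation error falls monotonically with λ up to a knee beyond which
the data fidelity starts to degrade without further accuracy gain
(λ: 0.01 → 0.49 mm, 0.2 → 0.36 mm, 1.0 → 0.24 mm, 3.0 → 0.24 mm with
rising misfit); the default is the knee, λ = 1.0.

Optimisation: two resolution levels with control spacings 32→16 mm
(dyadic, so refinement is exact and, with knots snapped to integer
multiples of the spacing, phase-aligned across grids), a Gaussian image
pyramid at the coarse level (σ = 0.3 × spacing) for capture range, and
L-BFGS by default — it reaches a given deformation accuracy several
times faster here than Polak–Ribière conjugate gradient with Armijo
backtracking, which is retained as `optimizer="cg"` (with a
Gauss–Newton-diagonal preconditioner) and carries the provably
non-increasing objective contract.  No intercept component:
median-normalised signals make `s = 0` the reference state; a constant
component can be enabled for drifting data.  Warm-started refits (during
alternation) run only the finest level on raw images.

## Reconstruction

AVGI divides the accumulated back-projections `Σ_t T*_t A*_t P_t` by the
accumulated weights; voxels with weight below 1e-6 of the maximum are
flagged invalid and excluded from every statistic.  IBP starts from the
AVGI, simulates all slices from the current volume, back-projects the
residuals, and steps with α = 1 halved whenever the data fidelity would
increase (floor 1/16, best iterate returned) — fidelity is non-increasing
by construction.  The alternation runs IBP with the zero model first,
then repeats warm-started fit + IBP (5 iterations each, 5 alternations by
default, relative-objective tolerance 1e-3).

The ground-truth comparison image for reconstruction error is the phantom
deformed to the reference state, `I*_GT(x) = I_GT(x + u^GT_{t_r→0}(x))`:
the reconstruction targets the median position, not frame 0.

## Evaluation

DFE is the voxelwise l2 norm of (model − ground-truth) displacement, both
t→reference; the ground-truth field at each frame composes the frame's
backward field with the (precomputed) forward field of the reference
state.  Per-ROI summaries use the temporal mean, standard deviation, and
95th percentile (linear-interpolation order statistic) of the per-frame
spatial means; a voxelwise temporal-mean DFE map is also produced.

Residual-error registration simulates each motion slice from the MCSRI
through the model and `A_t`, registers the estimate to the acquired slice
in 2D (magnitude-faithful preset), and pools the absolute in-plane
displacements per anatomical direction within the body mask — sagittal
slices contribute SI and AP, axial slices AP and LR, AP pooled from both
orientations weighted by masked pixel count; sd and p95 summarise the
per-slice spatial means.  Means are reported as absolute values (signs
discarded).  The body-mask restriction is a package choice (a flag
exposes full-slice statistics).  In-plane registration cannot see
through-plane error, so the residual error is a lower-bound-style
estimate of the DFE.

## Validation experiment sizes

The experiment drivers (`mrmotion.experiments`, also run by
`scripts/acceptance.py`) use desk-scale versions of the study conditions:
a 64³ lattice at 2 mm with 10 mm slices and five 2 mm shifts; three
building repetitions plus one held-out evaluation repetition for the
parameter-recovery study (noise-free, span-mode motion — the setting in
which exact recovery is well defined); one repetition at 5% Rician noise
for surrogate recovery; fit budgets of 60 iterations per level, three
alternations and four IBP iterations; DFE summaries subsample
building-phase frames at stride 3 (the per-frame spatial means vary
slowly).  The determinism check runs a smaller 4 mm pipeline twice and
compares content hashes.

## Known limitations

* No sliding-interface transform; sliding regions would dominate the
  residual error on real data, as the model class predicts.
* The correspondence model is linear in two signals; motion outside that
  span (e.g. drift, cough) is unmodelled unless the constant component is
  enabled.
* Only axis-aligned geometry; oblique acquisitions are out of scope.
* The 2D surrogate registration measures apparent in-plane motion of a
  thick slab; through-plane content change leaves an irreducible residual
  that mildly biases the surrogate scores and the residual-error metric.
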