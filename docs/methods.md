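# Methods

## The reconstruction problem

A cone-beam CT scan of a breathing patient acquires a sequence of
projections `p_t`, one per gantry angle, over roughly a minute. Each
instantaneous anatomical state is seen by exactly one projection, so
reconstructing a volume per frame is hopelessly under-determined unless the
problem is restructured. `dyncbct` follows the joint
reconstruction-and-registration decomposition: a single reference volume
`I_ref(x)` is reconstructed once, and every frame is expressed as a warp of
it,

    I(x, t) = I_ref(x + d(x, t)),

with the deformation field factorized into a low-rank product of three
learnable spatial basis fields (motion basis components, MBCs) and
time-dependent coefficients,

    d(x, t) = sum_{i=1..3} w_i(t) * e_i(x).

All three ingredients — the reference volume, the coefficients, and the
basis — are learned from the projections of the single scan at hand, with no
prior anatomical model, no prior motion model, and no phase sorting.

## Representations

- **Reference volume** `I_ref`: a multiresolution hash encoding of the 3D
  coordinate (default 8 levels, 2 features per level, 2^16-entry tables,
  base resolution 8, growth 1.5) followed by a three-layer MLP (widths 32,
  32, 1) with periodic (SIREN) activations, `omega_0 = 30`. Coordinates are
  rescaled from the reconstruction bounding box to [-1, 1]^3; the field is
  defined as 0 outside the box. The output is unconstrained during training
  and clamped to nonnegative attenuation only at volume export.
- **Temporal coefficients** `w_{i,k}(t)`: a 1D hash encoding of the frame
  index (8 levels, 2 features, 2^12 tables, base resolution 4, growth 1.6)
  feeding nine small SIREN MLPs — one per Cartesian component of each of
  the three MBCs (one input layer, two hidden layers of width 32, scalar
  output). The representation is continuous in `t`.
- **Motion basis** `e_i(x)`: three uniform cubic B-spline control grids of
  increasing resolution (full-scale default 6^3 / 10^3 / 17^3 control
  points per axis, ~1.9e4 learnable values), evaluated by separable
  Cox-de Boor interpolation over the normalized [0, 1]^3 volume box.
  Basis fields are **dimensionless** (box units): a displacement value of 1
  spans half the reconstruction box, and the warp converts to mm. This
  makes the unit-norm orthonormality target and the natural output scale of
  the temporal heads mutually consistent — with mm-valued fields the
  coefficients would have to grow to the motion amplitude in mm (~13) from
  a ~0.04 initialization, which short training runs cannot reach.

## Projection operator

Measured projections are line integrals computed by a Joseph-style
ray-marching projector on the voxel grid (trilinear interpolation, trapezoid
weights, step = half the smallest voxel size, sample count fixed by the box
diagonal so the discretization does not depend on the ray subset). The
training losses evaluate the (warped) reference field **at the voxel centers
of the reconstruction grid** and push the resulting voxel array through the
*same* projector, made differentiable in the voxel values. Simulation and
training therefore share one discretized operator. This matters more than
it may appear: when the training DRRs were instead rendered by continuous
ray marching through the field, the small (~1 %) inter-voxel discrepancy
between the field and the trilinear measurement model integrated coherently
along rays into a residual an order of magnitude larger than the entire
motion signal, and motion recovery failed. A continuous-field projector is
still provided for DRR rendering at arbitrary resolution.

FDK filtered backprojection (cosine weighting, exact-kernel ramp filter with
optional Hann apodization, distance-weighted backprojection) provides the
motion-averaged initialization volume. Short scans use Parker redundancy
weights (generalized to over-scan arcs); offset-detector (half-fan) scans
use smooth lateral feathering of the doubly-measured band. The feathering
band should span at least ~10 detector columns; very narrow overlaps leave
visible residual error (measured: ~1 % mean interior error at a 16-column
overlap vs ~25 % at 5 columns for a water cylinder).

## Losses

- Projection fidelity: mean squared difference between rendered and measured
  line integrals (per-pixel normalization).
- Image fidelity (Stage I step 1 only): mean squared error to the FDK
  volume, fitted at *jittered* points with trilinearly interpolated targets
  so the field agrees with the measurement model between voxel centers too.
- Total variation of the reference (weight `lambda_TV = 1e-3`): isotropic
  magnitude of undivided forward differences on the sampled grid, averaged
  per voxel; a stride parameter subsamples the evaluation lattice for
  cheaper per-step regularization.
- MBC orthonormality (weight `lambda_MBC = 1`):
  `sum_i |<e_i, e_i> - 1| + sum_{i<j} |<e_i, e_j>|`, with the inner product
  taken between full 3-vector fields and discretized as the mean over a
  fixed 16^3 quadrature grid (mean rather than sum normalization keeps the
  unit target resolution-independent).
- Temporal smoothness (weight `lambda_temporal`, default 0): mean squared
  frame-to-frame difference of the nine coefficient traces. At full frame
  counts (hundreds of frames, ~6 frames per finest temporal-hash cell) the
  data itself averages adjacent frames and no penalty is needed; reduced
  desk-scale runs have ~1 frame per cell and set `lambda_temporal > 0` to
  stand in for that missing data density. Without it the coefficients fit
  ray batches as temporally incoherent noise (measured lag-1 autocorrelation
  ~0 against ~0.74 for true breathing).

## Training schedule

Stage I: (1) fit the reference field to the FDK volume in the image domain
(learning rate 4e-4); (2) refine against the measured projections with TV
regularization (learning rate 1e-7). Stage II freezes the reference field
and learns motion; Stage III unfreezes everything for joint training
(spatial rate 5e-9, i.e. the reference is essentially pinned — deliberately:
because every angle is observed only once, a static volume given a
meaningful learning rate can absorb the *entire* motion signal into
angle-correlated artifacts, which we verified destroys the solved motion).
Temporal/basis rates are 2e-3 (Stage II) and 2e-4 (Stage III). Epoch counts
default to the full-scale schedule (1000/600, 100 per basis scale + 50
fine-tune, 2000 joint) and shrink uniformly through `epoch_scale`.

Within Stage II the learning complexity increases progressively:

1. a *temporal-only* phase: the basis is frozen at its initialization and
   only the SI coefficient heads train, on motion-salient ray sets —
   effectively a per-frame rigid registration that anchors the breathing
   trace (salient rays are the per-frame detector pixels deviating most
   from the slow angular trend of their time series; concentrating the data
   term there counteracts the amplitude damping exerted by static anatomy);
2. the three basis resolutions unfreeze coarse-to-fine (with a x10 learning
   rate, since the basis gradient scales with the small coefficients), each
   followed by a short temporal refresh (block-coordinate descent; the
   factorization `w x e` is bilinear, and alternating updates are far more
   stable at small step counts than joint ones);
3. a joint finetune of all motion parameters at half the temporal rate.

The basis initializes as constant unit translation fields along SI, AP and
LR (coarse to fine) plus small jitter: the set is exactly orthonormal at
start, and the earliest gradients correspond to rigid motion, which avoids
the `w ~ 0, e` arbitrary dead point of a cold bilinear start. The SI
(dominant respiratory) coefficient heads train first; AP/LR heads join later
— with constant basis fields, free in-plane coefficient traces can otherwise
fit gantry-angle-correlated artifact residuals (a gauge degeneracy smooth in
time, which the temporal penalty cannot remove).

Each optimizer step accumulates the data term over a chunk of frames
(default 10) rather than a single frame: per-frame steps on the *shared*
temporal network fight each other and oscillate. Ray batches per frame are
drawn once per stage and reused across epochs (a re-drawn batch injects
sampling noise larger than the per-frame motion signal at small batch
sizes); with the voxel-grid operator the marginal cost of a ray is small, so
desk-scale runs simply use the full detector per frame. Adam (default
moments) is used throughout, with a fresh optimizer per phase.

## What desk-scale training does and does not recover

The full-scale schedule performs on the order of a million optimizer steps;
the shipped desk-scale studies perform on the order of a thousand. Within
that budget the pipeline recovers the reference volume (static scans:
relative error ~0.05 with projection-domain refinement; for static data
that refinement is plain iterative reconstruction and runs at a desk-scale
learning rate of 1e-4, since there is no motion to absorb), the dynamic
image sequence to RE ~0.18 / SSIM ~0.91, the tumor center of mass to
within one reconstruction voxel, and the *shape* of the breathing trace
(Pearson r ~0.6 against the programmed trajectory on the X1-analog
scenario). It does **not** reach the near-perfect trace correlation of the
full-scale method: with the reference pinned to its motion-blurred
initialization, the data term is nearly flat in the oscillating part of the
coefficients (measured: ~0.5 % of the residual), so the amplitude of the
solved motion remains damped and its correlation saturates. Growing it
further requires the mutual reference-sharpening/motion-refinement
staircase that the full-scale joint stage climbs over many epochs. A
motion-compensated FDK mode (`fdk_reconstruct(..., dvf_at_frame=...)`) is
provided for experimenting with explicit alternation.

## Synthetic data

The phantom is an analytic thorax: a soft-tissue body ellipsoid, two lung
ellipsoids, a spine cylinder, two hemispherical diaphragm domes and a
spherical lung tumor (default diameter 30 mm) placed at the isocenter — the
standard clinical setup, and important at desk scale: with the tumor far
from the axial mid-plane the moving anatomy can leave the projection field
of view entirely. Attenuations are 0.02 (soft tissue), 0.004 (lung), 0.035
(bone) mm^-1. The tumor and diaphragm domes follow the breathing trace
rigidly; the chest wall and spine are static, so the overall field to be
recovered is non-rigid. Volumes are rasterized with a ~0.7-voxel Gaussian
edge profile (partial-volume emulation); hard-edged volumes are nearly
impossible for a smooth neural field to match to the accuracy the projection
loss needs.

Breathing is an end-exhale-weighted `cos^4` waveform, peak-to-peak 13 mm SI
(AP = 0.3 x SI, LR = 0), period 5 s over a 60 s scan, with named scenario
presets: quasi-periodic with mild amplitude variation; a 5 mm baseline shift
at mid-scan; amplitude variation + shift; linear period and amplitude drift;
a single-cycle (slow breathing) scan; all combined; and an irregular mode
with strong cycle-to-cycle variation. All cycle randomness derives from the
scenario seed. The analytic tumor center of mass is bookkept exactly as
`COM(t) = COM_static + trace(t)`.

What the simulator does *not* emulate: real anatomy texture, scatter, beam
hardening, detector lag and noise correlations. Passing the recovery tests
therefore demonstrates the estimator's correctness and conditioning on
idealized data, not clinical performance.

## Problem sizes

Full-scale defaults mirror a clinical acquisition (660 frames / 60 s / 360
degrees, 256 x 192 detector at 1.6 mm, 128^3 x 64 volume at 4 mm). The
shipped test and reproduction configurations use a 32 x 32 x 16 grid at
12 mm, a 64 x 32 detector at 9 mm, and ~110 frames, with reduced epoch
counts; these sizes were chosen so a full study runs on a laptop-class CPU
in minutes while keeping the tumor several voxels across and the breathing
cycle sampled by ~9 frames.

## Known limitations

- The desk-scale recovery is validated on the analytic phantom only; the
  reference volume remains close to its motion-averaged initialization at
  reduced epoch counts, so image metrics (RE/SSIM) at desk scale understate
  what the full schedule achieves.
- The solved coefficient traces carry residual frame-to-frame noise that the
  temporal penalty does not fully remove; trace statistics (Pearson r) are
  reported on the mask-propagated center of mass, which averages the local
  field over the structure.
- Cone-beam artifacts at large cone angles are not specially treated (no
  short-scan cone weighting beyond Parker).
- The half-fan feathering assumes a full 360-degree rotation.
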