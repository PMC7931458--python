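# Methods

This note documents the models, algorithms and numerical choices behind
`munet`, in the order data flows through the pipeline.

## Scope and intent

The package studies MR-guided post-processing of low-count PET
reconstructions with a deliberately small ("micro") fully-3-D CNN, using
entirely synthetic data: procedurally generated brain-like phantoms, a
simplified slice-wise acquisition model, MLEM reconstruction with and
without resolution modeling (RM), and two classical reference filters
(Gaussian post-smoothing and T1-guided non-local means). Everything is
sized to run on a single CPU core; the sections below state the
desk-scale defaults and what they emulate.

## Synthetic phantoms (`munet.phantom`)

Real segmented-MR head phantoms are replaced by procedural ones so that
no external data set is required. A radial level function of a centered
ellipsoid, deformed by a smooth clamped random field, is thresholded
into nested compartments: scalp, skull, dura, a cortical gray-matter
ribbon and a white-matter core; a second smooth field folds additional
gray-matter sheets through the core so gray and white interdigitate in
3-D. The geometry parameters (semi-axis fractions, deformation
amplitude 0.05, fold threshold 0.45) were fixed once to give
plausible gray/white volume fractions at 2 mm voxels and are exposed in
the source rather than in config, since nothing downstream depends on
their exact values.

Activity follows FDG-like piecewise contrast — white matter 1.0
(reference), gray 4.0, dura 0.5, scalp 0.25, skull and background 0 —
with spherical lesions of diameter U[5, 15] mm at contrast U[6, 8]
against white matter, blurred by a per-lesion Gaussian edge
(U[0.4, 1.2] px) before alpha-compositing; centers are drawn uniformly
from voxels whose distance to the brain boundary exceeds the lesion
radius. Both the activity and the T1-like guide then receive
multiplicative randomized texture

    tau = phi o (1 + gamma [2 G_sigma(rho) - 1]),  rho ~ U[0,1),

with gamma = 1.5 for PET and gamma = 1 for MR, sigma = 1 px, and
*independent* random streams for the two modalities, so the voxel-wise
guide-to-activity mapping is not deterministic. For gamma = 1.5 the
factor can stray below zero in distribution tails; activity is clipped
at 0 (physical non-negativity). With gamma = 0 the operation is the
exact identity.

The attenuation map assigns 0.13 /cm to bone and 0.0975 /cm to every
other tissue; only object attenuation is modeled (no scanner hardware).

## Acquisition model and MLEM (`munet.petsim`)

The scanner-specific fully-3-D model is replaced by a slice-wise 2-D
parallel-beam projector: a Joseph (driven-axis, linear-interpolation)
ray tracer materialized once per geometry as a scipy CSR matrix. The
back projector is the matrix transpose, so adjointness holds to machine
precision — a property the MLEM fixed-point and count-conservation
checks rely on. Detector normalization is uniform.

Resolution degradation is simulated in image space with an isotropic
4.5 mm FWHM Gaussian. Expected trues are the attenuated projection of
the blurred activity, scaled so that trues, scatter and randoms total
the configured count level with 26 % randoms (uniform across bins) and
28 % scatter (wide Gaussian smoothing of the trues along the radial
axis, default sigma 5 bins). Prompts are Poisson draws; the expected
randoms+scatter background is stored with the sinogram and passed to
MLEM as known, matching a simulation study in which the background
model is exact.

MLEM uses the standard multiplicative update with an optional Gaussian
RM kernel H (4.5 mm FWHM, identical in forward and adjoint steps, so
H^T = H). Division guards: voxels with sensitivity below 1e-12 stay 0;
sinogram bins with near-zero predicted counts contribute ratio 0 (this
silently discards prompts on lines of response that miss the field of
view — at most the uniform-randoms tail). Defaults are 100 iterations
without RM and 300 with RM (RM converges more slowly); the desk-scale
study uses 50/150, preserving the 1:3 ratio at a tractable single-core
cost. The reconstruction loop runs in float32 by default for image
work; float64 is used wherever algebraic identities are asserted.

Count levels: the full-scale protocol spans 3 M-300 M counts. At 64^3
with 2 mm voxels the desk-scale analogues keep the 1:10:100 ratio at
30 k / 300 k / 3 M; the study's "low" level is 300 k. Reconstructions
are converted to activity units by dividing by the recorded
activity-to-counts scale, the simulation-study stand-in for a
well-counter calibration.

## Reference filters (`munet.filters`)

Gaussian post-smoothing (PS) shares the PSF-blur implementation. The
guided NLM weights each voxel's 5x5x5 neighborhood by a Gaussian in the
*guide* intensity difference, `w = exp(-((g_i-g_j)/Omega)^2 / 2)`, with
no patch comparison and no spatial weighting; boundaries truncate the
neighborhood. As printed in some descriptions the numerator of the
filter carries the center voxel rather than the neighbor, which would
reduce to the identity; the standard neighbor-weighted form is
implemented. The filter is a convex combination (local min/max bounds),
is invariant to guide offsets and to joint guide/Omega scaling, and
reduces to the box mean for constant guides or Omega -> infinity.

Both filter parameters are set by exhaustive NRMSE grid search against
the training target — full-grid defaults of 0.1 mm FWHM steps and 0.01
decade steps in Omega; the desk study coarsens Omega to 0.1-decade
steps over [1e-2, 1e2] (the optimum sits well inside) to keep the
search seconds-scale. Ties break toward the smaller parameter.

## Image-quality metrics (`munet.metrics`)

Bias, standard deviation and NRMSE across noise realizations are
normalized by the target's root energy rather than voxel-wise, and the
variance uses the population convention (divide by R) — the unique
choice under which eps^2 = b^2 + sigma^2 holds exactly, so
bias-versus-std curves can be read with NRMSE as distance from the
origin. With a single realization sigma is undefined (rejected) and
eps = b. An optional mask restricts the support.

## Networks (`munet.nets`)

The micro-net is three stride-1, zero-padded 3-D convolutions —
n = {32, 32, 1} kernels of width s = {5, 3, 1} — with sigmoid hidden
activations and a final ELU (alpha = 1), applied to four input
channels: low-count MLEM, low-count MLEM+RM, the T1 guide, and guided
NLM of the RM reconstruction. That is (4*125+1)*32 + (32*27+1)*32 +
(32+1)*1 = 43 745 parameters and a 7-voxel receptive field. Zero
padding is safe because the volumes are zero at all boundaries.

Normalization: the three reconstruction/guide channels are standardized
to zero mean, unit variance per input set; the NLM channel is computed
from the already-standardized RM and guide channels (Omega therefore
lives on the standardized-guide scale — the filter's joint-scaling
invariance makes this equivalent to filtering raw volumes) and is not
re-standardized. Targets are scaled to unit variance with the mean
untouched, which is what justifies the ELU's soft lower bound of -1.
Predictions are multiplied by a single constant so the total intensity
matches the pre-normalization primary PET channel; the non-RM MLEM
channel is taken as primary (the choice is a convention — any channel
with calibrated total intensity would serve — and is isolated in
`NormState`).

Weights are initialized He-style with the std written as sqrt(2 /
n_{j-1}), i.e. without the kernel volume in the fan-in; biases start at
zero. The conventional sqrt(2 / (n_{j-1} s^3)) is available via
`fan_in="standard"`. For the deep all-ELU U-net the volume-less
variant multiplies activation scale by ~s^{3/2} per layer and produces
astronomically scaled initial outputs; the U-net comparator is
therefore trained from the standard-fan-in init (see Design choices).

The U-net comparator: a four-level encoder of stride-2 3^3
convolutions (32, 64, 128, 256 kernels), a decoder of trilinear x2
upsampling + skip concatenation + stride-1 convolution (128, 64, 32, 1
kernels), ELU throughout, and a final residual layer adding the NLM
input channel to the single-channel decoder output (~2.9 M
parameters). Input spatial dimensions must be divisible by 16.

All forward/backward passes are numpy: convolutions are BLAS matrix
products over im2col blocks (numba-compiled gather/scatter, channels-
last layout, shift-wise sgemm for wide layers), verified against
finite differences in the test suite. Adam follows the standard
bias-corrected moments.

## Training and evaluation (`munet.train_eval`)

The l2 loss is the root-mean of per-realization squared error norms,
L = sqrt((1/R) sum_r ||T_r - pred_r||^2) — proportional to the sample
NRMSE of the prediction set (a typeset variant placing the sum under
the reciprocal decreases with error and is not used). The l1 variant is
the per-voxel mean absolute error. Training is full batch: one Adam
step (lr 1e-3) per epoch over all R realization input sets jointly;
validation loss on a different subject is evaluated after every step;
training stops when validation has not improved for the patience, and
the best-validation weights are restored. A NaN loss aborts with
diagnostics. Runs are bit-reproducible given the seed.

The experiment harness simulates one training subject (R noise
realizations), one validation subject, and held-out test subjects;
optimizes the PS and NLM parameters on the training subject only;
trains the micro-net (and optionally the U-net); and evaluates every
method on the test subjects against the ground truth, including MLEM
iterate bias-vs-std curves, PS/NLM parameter sweeps and the network
point. Channel ablations (zeroing named inputs and retraining) and an
architecture sweep (depth J, shared hidden-kernel count n_j, widths
{5, 3, ..., 3, 1}) are separate entry points sharing the prepared
study. Targets can be the ground truth or a standard-count
reconstruction.

### Desk-scale study (`desk_config`)

The bundled study runs 64^3 phantoms (2 mm voxels), 48 projection
angles, the 300 k "low" count level, 50/150 MLEM iterations, R = 3
training realizations, 1 validation subject and 2 test subjects with
10 realizations each.

The optimization schedule is compressed to the core-minutes the study
is given. The full-scale protocol performs on the order of 10^4
full-batch Adam steps at lr 1e-3 with a 10 000-epoch patience; on a
single CPU core each whole-volume step here costs seconds, so the desk
study performs ~65 steps for the micro-net at lr 5e-3 — the largest
step size that descends monotonically after the first few epochs
(1e-2 oscillates) — and uses the conventional He fan-in, since the
volume-less printed variant saturates the width-5 sigmoid layer at
initialization. The U-net comparator trains at its own largest stable
step size (1e-3; larger steps drive the all-ELU decoder into a dead
constant state) for a small number of epochs.

These budgets are enough for the micro-net to overtake Gaussian
post-smoothing on held-out subjects, but *not* to reach its converged
quality: in longer runs (a few hundred epochs, several-fold over the
bundled budget) its test NRMSE continues to fall below the optimized
guided-NLM baseline, and the U-net eventually drives its training loss
below the micro-net's — the compressed schedule reports both
comparisons honestly rather than emulating them. The micro-net's train
and validation curves stay within a 25 % relative gap
(`overfit_gap_threshold`), the quantitative form of "the validation
curve lies on top of the training curve".

## What the synthetic data does and does not show

The generator reproduces the *structure* of the original study — tissue
contrast, randomized texture breaking any T1-to-PET shortcut, lesions,
attenuation, count-dependent Poisson noise, RM ringing versus non-RM
noise trade-offs — but not real anatomy (cortical folding here is a
random field, not a brain atlas), not scanner-accurate geometry (2-D
parallel-beam versus fully-3-D span-11 sinograms), and not
registration error, motion or MR artefacts. Passing tests therefore
demonstrate the method ordering and overfitting behavior under
idealized conditions, not clinical performance; absolute NRMSE values
are higher than full-scale ones because the desk-scale count density
per voxel is lower.

## Design choices made where the design was open

- **Early-stopping budgets and step size.** The full protocol's
  10 000-epoch patience and lr 1e-3 are impractical per run here; the
  desk config compresses the schedule as described above. The full
  values remain the `TrainConfig` defaults.
- **Initialization convention.** `he_init` defaults to the volume-less
  std sqrt(2/n_{j-1}); the experiment harness trains both networks
  from the conventional fan-in (`init_fan_in="standard"`), which keeps
  the sigmoid layer unsaturated and the deep ELU network finite.
- **Which PS is "the" optimized PS.** Both PS-of-MLEM and PS-of-RM are
  optimized and reported; comparisons treat them separately.
- **NLM channel Omega** reuses the training-optimized value, rescaled
  by each input set's guide standard deviation (exact under the
  filter's invariance).
- **Degenerate inputs.** Constant channels cannot be standardized
  (rejected); an all-zero prediction cannot be rescaled (rejected);
  lesions that do not fit inside tissue are rejected at construction.

## Known limitations

- The projector is slice-wise 2-D; axial blur enters only through the
  image-space PSF.
- Scatter is a radial smoothing of the trues, not a physical
  single-scatter estimate, and is treated as known during MLEM.
- Networks run in float32; MLEM oracles requiring 1e-8 algebra run in
  float64.
- Listmode/real-data workflows (bootstrap resampling, registration)
  are out of scope.
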