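# Methods

## The problem

A diffusion-weighted volume is not acquired in an instant: its slices
(or multi-band groups) are excited one after another over several
seconds. If the subject moves during that window the slices are no
longer parallel planes of one rigid object — viewed sagittally or
coronally the brain acquires the tell-tale jagged edges of interleaved
acquisition, and any volume-to-volume ("volumetric") realignment can
only place the whole stack at a compromise position. This package
models, estimates and corrects that intra-volume movement.

## Movement model

Each of the six rigid-body parameters (three translations in mm, three
rotations in radians) is a truncated discrete-cosine series over the
volume's N excitation times:

    r_p(n) = sum_{k=0}^{M} B[k, p] cos(k n pi / (N - 1)),   n = 0..N-1

so `M = 0` reverts exactly to the volumetric model and `M + 1` is the
number of degrees of freedom per parameter ("dof"). A slice-timing
table Z maps each excitation time to the slice indices excited then;
all slices of a multi-band group share one rigid configuration.
Built-in orderings are sequential and odd/even two-pass interleaved
(0, 2, 4, ..., 1, 3, 5, ...); any scanner dialect can be supplied as an
explicit table.

Rigid conventions (the data are self-consistent under any fixed
convention; these are ours): extrinsic rotations about the world x,
then y, then z axis; rotation centre at the volume centre; points
transform translation-first, `x' = Rz Ry Rx (x + t)`.

Movement is regularised by the summed squared analytical second
temporal derivative of r(t) at the integer time points, a quadratic
form in B. In the estimation cost the penalty counts rotations in
degrees and is normalised per time point and by a fixed calibration
constant so that the weight `lam` is dimensionless with a useful range
of roughly 0.1–100: `lam = 1` is a mild constraint at typical b=0 SNR
and `lam = 100` forces slowly varying traces. The data term is
likewise normalised by the in-mask sum of squared observed intensities,
making the trade-off independent of scanner intensity scaling.

## Registration target: the q-space predictor

Volumes cannot be registered to each other directly — each has a
different diffusion contrast. Instead every volume is registered to a
prediction of what it should look like, produced by a Gaussian-process
interpolator over the diffusion descriptors. Within a shell the
covariance between two volumes with unit gradients g, g' is

    k(theta) = sf2 [ (1 - w) exp(-theta / ell) + w (0.3 + 0.7 P2(cos theta)) ],
    theta = arccos(|g . g'|)

— a mixture of an exponential angular kernel (full rank, so the
noise-free predictor interpolates its training data exactly) and a
degree-2 Legendre covariance, which is the angular structure of
single-tensor diffusion signals. The absolute dot product encodes
antipodal symmetry exactly. Shells are independent apart from their
own mean volume; b=0 volumes are predicted by their mean.
Hyperparameters are method-of-moments (signal variance from
across-volume residual variance; noise variance from half the minimum
nearest-neighbour mean squared difference) with the length-scale and
mixture weight chosen by a leave-one-out grid search; a relative jitter
of 1e-6 stabilises the factorisation.

During estimation each volume's target is its *leave-one-out*
prediction. With small shells this matters: a prediction containing
the volume's own data lets the volume "match" its own misalignment and
the estimator stalls.

## Forward and inverse spatial models

*Forward*: given a complete model-space volume, observation slice s is
predicted by sampling the volume with a cubic regular-grid spline at
the rigidly transformed coordinates of the slice's grid, using the
movement parameters of s's excitation time. Samples falling outside
the volume use constant edge extension and are excluded from
estimation costs. Optional static displacement fields (susceptibility
or eddy-current maps, supplied — never estimated) displace the
sampling points along the phase-encode axis before the rigid transform.

*Inverse*: the acquired slices are irregularly positioned along z.
For every in-plane target position (x, y) and slice s, the closed form

    z* = (s - RI31 x - RI32 y - RI34) / RI33

(with RI the inverse voxel-space transform of slice s) gives the
model-space through-plane coordinate of that slice's sample, and
substitution gives the matching in-plane point (x', y') at which the
slice is interpolated in 2D. A guard rejects |RI33| <= 1e-6 (slice
plane nearly parallel to the slice axis; unreachable below ~80 deg of
rotation). Each column's irregular samples (g_i, z*_i) are then
resampled onto the integer grid by a regularised least-squares cubic
B-spline fit over an extended knot range (-1..n_grid, so edge points
are representable). The 1D penalty is the squared second difference
of the spline coefficients (P-spline form): it annihilates affine
coefficient sequences — hence affine interpolants — and drives the fit
toward the best straight line as its weight grows.

Where out-of-plane movement leaves gaps, predictions fill them through
a weighted least-squares system stacking the irregular design on the
observations with the regular design on the predictions. The weights
implement "observations always take precedence": a grid point whose
bracketing observations are closer than one grid step gets weight 0;
a bracket of width 1 < dz < 2 containing one grid point gives it
dz - 1; with two points each gets its distance to the nearest
bracketing observation; with three or more, interior points are capped
at 1 — in every case the bracket total is dz - 1 for 1 < dz <= 3.
Grid points outside the outermost observations get weight 1 (pure
prediction), and a z* landing exactly on a grid point counts as an
observation there. During iterative estimation a fast piecewise-linear
column resampler (no predictions) replaces the spline machinery.

The final reconstruction uses the spline path with prediction weights
and a small penalty weight (1e-4): gaps are covered by the weighted
predictions, so the penalty only stabilises degenerate columns, and a
larger weight would shrink well-observed values measurably (the
regularised fit biases smooth profiles by about twice the penalty
weight in relative terms). Slices flagged as dropout are excluded
from the columns entirely, so predictions replace them.

## Estimation

Per volume, a Gauss-Newton step on the 6 x (M+1) coefficients: the
residual Jacobian with respect to the six per-time rigid parameters is
built by central finite differences on the forward model (0.2 mm /
0.2 degree steps, one simultaneous perturbation per parameter — 12
forward evaluations regardless of M) and mapped to coefficient space
through the exact chain rule over the DCT design. The regularised
normal equations are solved (an error advising larger `lam` is raised
above condition number 1e12) and a halving line search accepts only
non-increasing cost. Estimation runs on 0.8-voxel Gaussian-smoothed
copies of the observation and the prediction, suppressing noise-driven
parameter error; the reconstruction always uses the raw data.

The outer loop: (1) resample all volumes at current estimates —
fast-linear before predictions exist, prediction-filled spline
afterwards (this measurably removes a slow drift of rotation errors
across iterations); (2) refit the predictor; (3) two Gauss-Newton
steps per volume against its leave-one-out prediction; (4) pick a
shape-reference volume per group (b=0 and DWI) — the lowest prediction
residual among the half with the smallest within-volume rotation SD —
and subtract its non-constant coefficient rows from every volume of
the group, so the reference's shape anchors the group; (5) subtract
the first b=0 volume's constant row from all volumes, defining the
output space. Two volumetric (constant-only) warm-start iterations
precede the slice-to-volume iterations, the standard staging in which
volume-to-volume alignment runs before slice-level refinement; four refinement
iterations follow by default (the convergence history plateaus after
three to four). The brain mask is an Otsu threshold on the mean b=0
volume eroded by one voxel, and slices with under 2% in-plane brain
voxels are excluded from cost and reports.

## Synthetic data

The generator emulates the statistical structure of multi-shell DWI of
a moving subject: an ellipsoidal "brain" containing two crossing
prolate tract bundles (in-plane, along x and y), a bright CSF-like
blob (b=0 contrast that anchors rotations for unweighted volumes) and
isotropic tissue, with region masks smoothed by 0.8 voxels so boundary
voxels are partial-volume mixtures of the region signals. Signals
follow S = S0 exp(-b g^T D g) per compartment. Gradient schemes use
Coulomb-optimised half-sphere directions with random sign flips and
interspersed b=0 volumes (volume 0 is b=0, volume 1 diffusion
weighted). The reference FA map is fitted from the noise-free signals
by the same weighted-least-squares pipeline the evaluation uses.

Movement traces are integrated Gaussian-increment walks smoothed with
a 10-excitation kernel, windowed to zero over the first two volumes
(so motion-free shape-reference candidates exist in both volume
groups) and rescaled so each parameter's session peak is 1 mm / 1
degree at "normal" amplitude; "large" is exactly three times the
normal trace at equal seed. The smoothness is such that eight DCT
terms capture over 99% of within-volume trace variance. Multi-band
sessions run the same per-excitation process over correspondingly
fewer excitations per volume. Dropout multiplies whole
slices/MB-groups by a factor uniform on [0.1, 0.9], selected with
probability proportional to the trace's temporal-derivative magnitude
(uniform fallback for constant traces), normalised to an expected 3%
of slices. Noise is additive Gaussian with SD = mean in-brain b=0
intensity / SNR (defaults 40 "good" and 20 "poor"); at these SNRs the
difference from Rician noise is negligible for the b-values used.

What the generator does *not* emulate: k-space/Bloch physics (signals
are composed in image space), spin-history intensity modulation,
eddy-current or susceptibility corruption (static fields can be
*supplied* to the resampler but are never generated or estimated), and
the rotation of the effective encoding direction by head rotation —
simulated signals use the nominal gradient direction, so tests of the
estimator do not probe b-vector reorientation effects.

## Problem sizes and measured behaviour

The standard verification condition is a 48 x 48 x 30 phantom at
2.5 mm with 6 b=0 + 24 b=700 volumes — large enough for stable Otsu
masks and angular coverage, small enough that a full correction runs
in minutes on one CPU. At that scale, with large (3 mm / 3 degree)
movement and SNR 40, the estimator's slice-wise RMSE is limited not by
the Gauss-Newton machinery (which recovers movement against a known
target to ~0.01 mm / 0.01 degree noise-free and ~0.03 / 0.05 at SNR
40) but by the q-space predictor: with 24 directions per shell the
angular interpolation error of a prediction is partially
indistinguishable from a small in-plane rotation of this phantom's
in-plane tract geometry, leaving a per-volume orientation scatter of a
few tenths of a degree that no amount of iteration removes. Richer
direction sets shrink it; this is the main respect in which desk-scale
results understate what the method achieves on full acquisitions, and
it bounds what passing desk-scale tests can claim about real data.

## Degenerate inputs and numerical choices

Columns with no valid samples fall back to predictions (or zero);
columns with one sample are constant in fast mode. Ties of z* with
grid points count as observations. Non-positive signals are clamped
at a small floor before log-transform in tensor fitting. B-values
within 10% of a shell centre belong to that shell; anything else is
rejected with a clear error. All randomness flows from explicit seeds
and equal seeds give bit-identical outputs.

## Known limitations

* The slice axis must be the third voxel axis of the input NIfTI; no
  automatic reorientation is attempted.
* Susceptibility/eddy-current fields are consumed as known static maps
  only; their interaction with movement (the disjointed field problem)
  is not modelled.
* No outlier *detection*: dropout slices are handled via a supplied
  (or simulated) mask and replaced by predictions.
* The predictor's minimal kernel family is adequate for single-shell
  registration targets but is not a general multi-shell signal model;
  shells do not share covariance.
* Spin-history effects are neither simulated nor corrected.
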