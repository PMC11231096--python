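# Methods

`dynb0` simulates accelerated simultaneous-multi-slice (SMS) EPI
acquisitions of a brain-like digital phantom under dynamic, spatially linear
B0 field perturbations, implements a navigator-driven estimation and
correction of those perturbations based on GRAPPA shift operators, and runs
the downstream fMRI evaluation chain (bias/CoV/tSNR quality control, GLM
activation analysis, split-half reliability) comparing reconstructions with
and without the first-order correction.

## Field model and its k-space interpretation

The per-frame off-resonance field is spatially linear,

    df(x, y) = c0 + cx*x + cy*y        [Hz; x, y in FOV units, in [-0.5, 0.5)]

with x the readout and y the phase-encode direction. At echo time TE the
accrued phase `2*pi*df(x,y)*TE` factors into a global phase
`phi0 = 2*pi*c0*TE` and an image-domain linear ramp, i.e. a net translation
of k-space content by `(dkx, dky) = (cx, cy)*TE` grid units (grid unit =
1/FOV). The mapping `(c0, cx, cy) <-> (phi0, dkx, dky)` is linear and
invertible given TE; `FieldState` implements both directions.

Assumptions: the field is constant within a frame (body motion is slow
relative to one excitation), linear in-plane, and identical for the slices
of an SMS group. Frame 0 of every session is the zero-field reference.

## Acquisition simulation

Two field-effect modes:

* **physics** — EPI line n is the readout transform of the object modulated
  by `exp(i*2*pi*df(x,y)*t_n)`, with line times
  `t_n = TE + (n - N_lines/2)*esp` (esp = effective echo spacing between
  consecutive acquired lines, default 0.6 ms). The phase therefore accrues
  differently across the echo train, producing genuine EPI distortion
  (bulk phase-encode shift from `c0`, shear/stretch from `cx`, `cy`) on top
  of the net translation.
* **translate** — the estimator's idealized model: imaging lines carry
  exactly the TE-referenced translation and global phase; navigator lines
  carry the same translation scaled by `t_nav/TE` (linear-in-time accrual
  evaluated at the navigator time).

Both modes share: blipped-CAIPI slice encoding for MB=2 (phase alternating
per acquired line, i.e. `exp(i*2*pi*ky*s/(MB*R))` on the full grid — a FOV/2
inter-slice shift in the acquired, R-reduced FOV), in-plane undersampling of
every R-th phase-encode line, three non-phase-encoded navigator lines just
before the echo train (times `TE - (N_lines/2 + m)*esp`, m = 1..3,
alternating readout polarity), even/odd readout phase errors
`±(theta0 + theta1*x)/2` applied per line parity in projection space
(readout reversal is abstracted into this phase model), and i.i.d. complex
Gaussian noise of standard deviation sigma per k-space sample.

Calibration products are acquired at zero field with the same noise level:
fully sampled per-slice k-space (modeled as a clean, ghost-free segmented
acquisition), a single-band EPI reference per slice (R-undersampled,
ghost-corrected from its own navigators, GRAPPA-filled, RSS-combined), and
reference navigators per slice group.

## Calibration operators

* **In-plane GRAPPA**: a ky-interpolation kernel (sources: both ky
  neighbors, 3 readout taps, all coils) fitted on the fully sampled
  calibration by Tikhonov-regularized least squares (lambda relative to
  trace, default 1e-4).
* **Split-slice SMS kernels**: per slice of a group, a kernel mapping the
  CAIPI-collapsed k-space to that slice's (CAIPI-phased) k-space, with
  leak-block equations forcing the other slice's contribution to zero;
  sources 3 (ky, spaced R) x 3 (kx) x coils; default lambda 1e-5 (at 1e-4
  the noiseless separation error was 5-6%, at 1e-5 it is ~1%). The known
  CAIPI phase is divided out after separation. Standard (non-leak-block)
  slice-GRAPPA is available behind a flag.
* **GRAPPA shift operator**: the unit k-space shift `d(k+1) = W d(k)` as a
  coil-coupling relation. In the hybrid domain (image space along the fully
  sampled readout, k-space along phase-encode) the unit shift is an
  independent C x C matrix per readout position. The default fit is this
  per-position ridge regression over all adjacent line pairs of all
  calibration slices, with a regularization floor that pulls positions
  without signal toward the identity (no information -> no-op). A compact
  w-tap k-space convolution form is available (`w=` argument); the
  per-position fit is its w = N limit and is roughly an order of magnitude
  more accurate (translation error ~0.1-0.8% versus ~2-6% at w = 3-5 for
  shifts up to 0.4 grid units, noiseless).

  Fractional powers use the eigendecomposition per position,
  `W^delta = V Lambda^delta V^(-1)` with the principal branch of the
  logarithm, valid for |delta| <= 1.5. Eigenvalue moduli are clamped into
  [0.15, 1]: a k-space shift cannot gain energy, and unclamped small moduli
  amplify noise without bound for negative powers. Near-zero eigenvalues
  (< 1e-8) raise an error advising stronger regularization.

  Accuracy caveat: the operator needs genuine coil-phase structure. With a
  single uniform-sensitivity coil there is no coupling to exploit and the
  fractional shift fails (measured ~33% error at delta = 0.25); the
  synthetic coil maps therefore carry realistic receive-phase rolls of
  order one cycle across the FOV.

## Per-frame estimation and correction

Order (each step conditions the next):

1. **Nyquist ghost parameters** from the navigators: lines are transformed
   to projection space; the two even-polarity lines, whose times bracket the
   odd line, are averaged so that linear-in-time field phase cancels; the
   magnitude-weighted linear phase of odd x conj(even) yields
   (theta0, theta1).
2. **phi0 and dkx** from a magnitude-weighted least-squares fit of
   `phase(P_t * conj(P_ref)) = phi0 + 2*pi*dkx*x` over the navigator
   projections, against the ghost-corrected reference navigators (frame 0 by
   default; the calibration navigators behind a switch).
3. **dky** by a 1-D search: `argmin_delta || W^(-delta) nav_ref - nav_t ||^2`
   with a coarse grid (step 0.05) followed by golden-section refinement to
   0.005; separated near-global minima set an `ambiguous` flag. An exact
   zero of the objective short-circuits the refinement, so a frame identical
   to the reference returns exactly 0.

Navigators sense the field at their own time (~15 ms) rather than at TE
(25.4 ms), so all three quantities are fitted in navigator-time units and
rescaled by `TE / mean(t_nav)`; the search bound (default ±0.75 grid units)
is specified TE-referenced. This makes the estimator exact in translate mode
and gives a slope of ~1.00 between estimated and true `cy*TE` in physics
mode.

Correction: global phase `exp(-i*phi0)` and the readout translation `-dkx`
applied exactly as a projection-space linear phase (the readout is fully
sampled); the phase-encode translation `-dky` applied as the fractional
operator power to every acquired line and navigator. A perturbation of
exactly zero is a bit-exact no-op.

## Reconstruction

Per frame and slice group: ghost correction (per-frame navigator estimate)
-> corrected arm only: first-order correction -> dynamic zeroth-order (phi0)
correction on both arms -> split-slice SMS unaliasing -> in-plane GRAPPA
completion -> centered inverse FFT -> root-sum-of-squares coil combination.
The two arms share every step and every operator except the first-order
correction; forcing that step's estimates to zero makes the arms
bit-identical. Output is a 4-D magnitude series with NIfTI export (RAS
affine from voxel size only, TR in the time zoom).

## Quality control and activation analysis

* **bias**: per-voxel temporal mean minus the single-band reference,
  normalized by the mean reference intensity over the object.
* **CoV / tSNR**: per-voxel std/mean and mean/std over time; low-mean voxels
  masked; constant voxels flagged NaN.
* **ROI summaries** over the phantom's named tissue masks; paired per-ROI
  arm comparison across sessions by two-sided Wilcoxon signed-rank (t-test
  behind a flag) with Benjamini-Hochberg FDR across ROIs.
* **Residual slice-leakage energy**: mean squared reconstructed signal in
  the SMS partner slice's CAIPI-shifted support footprint outside the
  object, relative to mean squared object signal.
* **GLM**: five regressors (intercept; *offer* at trial onset;
  *action_onset* and the binary *motor_response* at the go-cue; *outcome*
  at reward delivery), each a 0.1-s boxcar convolved with a double-gamma HRF
  (default peak 3.0 s, undershoot 7.0 s, ratio 1/6 — a fast, primate-like
  response; no species-specific parameter set is assumed, so the shape is a
  knob). Preprocessing: in-plane Gaussian smoothing (3 mm FWHM via the voxel
  size; the 4-slice stack is too thin for through-slice smoothing) then
  DCT-basis high-pass filtering (cutoff 100 s), temporal mean re-added.
  Fitting: voxelwise OLS, AR(1) from the residuals (binned at 0.01),
  Cochrane-Orcutt whitening per bin, refit; z = beta/SE through the exact
  t -> z tail transform (capped at |z| = 8.2), T - p dof. Regressors are
  entered raw (no orthogonalization).
* **Cluster thresholding**: face-connected components above z = 3.1; the
  minimum extent can be calibrated by smoothing-matched null simulation
  (`calibrate_cluster_extent`) instead of Gaussian-random-field p-values.
* **Second level**: one-sample t across sessions per voxel, mapped to z;
  zero-variance voxels capped at ±8.2. A full mixed-effects engine is out
  of scope; the arm comparison uses identical inference on both arms.
* **Split-half reliability**: over 10 folds, sessions are randomly halved,
  a second-level z map computed per half; per ROI, r is the voxelwise
  Pearson correlation of the thresholded (below-threshold zeroed) z values
  within the ROI — so what must replicate is the activation *pattern* inside
  the ROI — and the baseline bias is the absolute difference of the
  unthresholded ROI-mean z. Per-ROI arm comparison across folds by Wilcoxon
  with BH FDR.

## Default study conditions

64 x 64 matrix, 4 slices in 2 SMS groups (MB=2), in-plane R=2, 8 coils,
TE/TR = 25.4/1282 ms, FOV 120 mm (1.875 mm in-plane voxels), effective echo
spacing 0.6 ms, ghost phases (0.1 rad, 0.05 rad/sample), coil-combined SNR
30, 2% peak BOLD amplitude in two disjoint regions (one posterior region
driven by *offer*, one in the motor strip driven by *motor_response*),
T = 200 frames (~256 s, ~20 trials), smooth body-motion-like field
timelines with amplitudes (c0, cx, cy) = (10, 15, 15) Hz / Hz-per-FOV, i.e.
max |dk| ~ 0.38 grid units at TE; 10 sessions sharing one phantom/coil
setup with independent events, timelines and noise. Trial timing: go-cue
3-4 s after the offer, response within 1 s, outcome 3.5-4.5 s after the
response, 3.5-4.5 s intertrial interval.

These sizes keep a full ten-session, two-arm study (simulation, estimation,
reconstruction, QC, GLM, reliability) within minutes on one CPU.

## What the simulation shows — and a negative result

The estimator itself validates cleanly: translate-mode corruptions are
undone exactly by the conjugate phase ramp (relative error ~1e-15 on the
fully sampled frame); injected (phi0, dkx, dky) are recovered to within a
few thousandths over the |dk| <= 0.5 range; the dky RMSE at SNR 30 is
~0.004 grid units; the fractional-power algebra (W^0 = I, semigroup
composition, inverse composition) holds to near machine precision; the
physics-mode estimate-versus-truth slope is 1.00 ± a few percent.

The arm comparison, however, exposes a structural property of this
idealized world: the quantity the correction removes — a net k-space
translation plus global phase — is exactly an image-domain phase ramp, and
root-sum-of-squares magnitude reconstruction is invariant to phase ramps.
Moreover, well-calibrated GRAPPA and slice-separation kernels are valid for
*any* image formed from the calibrated coils, including ramp-multiplied
ones, so a consistent translation passes through them essentially without
artifact (measured: < 0.1% added error at dky = 0.38, across kernel
geometries, ACS sizes, coil profiles and noise levels). The genuinely
visible corruption — EPI distortion from the phase accrual across the echo
train — is not a net translation and therefore remains in both arms alike.
Consequently the corrected arm differs from the uncorrected arm only by the
fractional-shift application error and its noise amplification, and on
in-object magnitude metrics (bias, CoV, tSNR, GLM z) it performs equally or
slightly worse, while it does reduce residual aliasing energy in the
background (the one place artifacts are not hidden under signal phase).
With real scanners the uncorrected comparator is an entirely separate
online reconstruction and the perturbations are larger and not exactly
linear, which is where the method's practical benefit lives; a synthetic
world built strictly from the linear-field model cannot reproduce it. The
package reports the comparison honestly rather than engineering an
artificial win; see the acceptance quantities for the measured values.

## What the generator does and does not emulate

Emulated: SMS+CAIPI encoding, in-plane undersampling, navigator lines with
alternating polarity, even/odd ghost phases, per-line off-resonance phase
accrual, thermal noise, a trial-structured BOLD signal with a fast HRF.
Not emulated: anatomy beyond piecewise-smooth ellipses, T2*/relaxation
across the echo train, ramp sampling and partial Fourier, physiological
noise, higher-order or through-slice field terms, within-frame field
changes, subject-to-subject variability (all sessions share one phantom),
and a vendor-distinct online reconstruction. Passing tests therefore
validate the estimator, the operator algebra and the analysis chain — not
in vivo effect sizes.

## Numerical choices

Centered FFT conventions with DC at index N/2; image coordinates in FOV
units, k-space in grid units. Ridge regularization relative to trace.
Golden-section tolerance 0.005 grid units. Wilcoxon exact p-values at the
study's sample sizes. The t -> z transform saturates numerically beyond
|z| ~ 8.2 and is capped there. Sessions are seeded through
`numpy.random.SeedSequence` spawns, so every result is bit-reproducible
from the study seed.
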