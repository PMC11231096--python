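# dynb0

Dynamic off-resonance correction for accelerated simultaneous-multi-slice
(SMS) EPI, with a fully synthetic test bench modeled on awake non-human-
primate fMRI.

Body and limb motion in awake, head-fixed animals produces strong,
time-varying B0 field perturbations. For accelerated EPI this not only
distorts images but breaks the correspondence between each frame's k-space
data and the calibration data used for parallel-imaging reconstruction.
`dynb0` implements a correction that needs no extra hardware or sequence
changes: the EPI phase-correction navigators acquired every frame are
compared against a reference frame to estimate the dynamic field state, and
the estimate is undone in k-space before reconstruction.

## Model and method

The per-frame field perturbation is spatially linear,
`df(x, y) = c0 + cx·x + cy·y` (Hz, x readout / y phase-encode in FOV
units). At echo time TE its effect is a global phase `φ0 = 2π·c0·TE` plus a
net translation of k-space content by `(Δkx, Δky) = (cx, cy)·TE` grid
units. Per frame:

1. Nyquist ghost parameters `(θ0, θ1)` from the alternating-polarity
   navigators;
2. `φ0` and `Δkx` from a weighted linear-phase fit of the navigator
   projections against the reference;
3. `Δky` by a 1-D search over fractional powers of a **GRAPPA shift
   operator** — a coil-coupling matrix `W` trained on the calibration scan
   with `d(k+1) = W d(k)`, whose eigendecomposition yields sub-grid shifts
   `W^δ = V Λ^δ V⁻¹`.

The correction applies `exp(-iφ0)`, an exact readout translation `-Δkx`,
and the operator power `W^{+Δky}` to every acquired line, restoring
consistency with the calibration before split-slice SMS unaliasing and
in-plane GRAPPA completion (MB = 2, R = 2, blipped CAIPI). Downstream, the
package reproduces the full evaluation chain: bias versus a single-band
reference, temporal CoV and tSNR with ROI summaries and paired
Wilcoxon/FDR statistics, a five-regressor decision-task GLM with AR(1)
prewhitening and cluster thresholding, a one-sample-t second level, and
10-fold split-half reliability.

No real data are involved: the `phantom`/`task`/`engine` modules generate
multi-coil k-space sessions of an ellipse-based brain phantom with smooth
coil maps, CAIPI-encoded SMS acquisition, navigators, even/odd ghost
phases, complex Gaussian noise, a trial-structured BOLD signal, and
body-motion-like field timelines (TE/TR = 25.4/1282 ms, matching the
emulated protocol).

## Worked example

`examples/estimate_perturbations.py` injects known perturbations into
single SMS frames and recovers them from the navigators:

```
  phi0    dkx    dky |  phi0_hat  dkx_hat  dky_hat
  0.30   0.25   0.40 |    0.2926   0.2490   0.3980
 -0.80  -0.10  -0.30 |   -0.7978  -0.0987  -0.3002
  1.00   0.50   0.15 |    0.9978   0.4995   0.1504
```

Each row is one frame: injected global phase (rad) and k-space translation
(grid units), followed by the navigator-based estimates — recovery to a few
thousandths of a grid unit, i.e. at the search tolerance.

`examples/reconstruct_and_compare.py` simulates a 60-frame perturbed run at
SNR 30 (max |Δky| ≈ 0.38) and reconstructs both arms:

```
         arm  median|bias|  median CoV   leakage
   corrected        0.0580      0.0792   0.00533
 uncorrected        0.0549      0.0773   0.00576
```

The corrected arm reduces residual slice-aliasing energy outside the object
(`leakage`), while the in-object bias/CoV medians are a near-tie: in this
idealized linear-field simulation the net translation the method removes is
an image-domain phase ramp that magnitude (RSS) reconstruction cannot see,
so in-object improvements cannot materialize by construction — see
`docs/methods.md` for the full analysis of this negative result and what it
does and does not say about real acquisitions.

Other examples: `examples/glm_activation.py` (task GLM and cluster tables
on one reconstructed run) and `examples/split_half_reliability.py`
(split-half reliability of second-level maps). A thin CLI wraps the same
pipeline: `dynb0 simulate / reconstruct / qc / glm / reliability / report`.

## Layout

```
src/dynb0/
  phantom.py   digital phantom, coil maps, field-state timelines
  task.py      decision-task events, HRF, BOLD timecourses
  engine.py    SMS-EPI acquisition simulation, HDF5 session container
  calib.py     GRAPPA kernels, split-slice kernels, shift operators
  correct.py   ghost + (φ0, Δkx, Δky) estimation and correction
  recon.py     unaliasing, GRAPPA fill, coil combination, NIfTI export
  qc.py        bias / CoV / tSNR, ROI stats, paired comparison with FDR
  glm.py       design, preprocessing, GLM, clusters, second level, reliability
  study.py     end-to-end simulation studies and validation experiments
  cli.py       thin command-line pipeline
```
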