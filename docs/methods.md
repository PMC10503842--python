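# Methods

## The measurement problem

Cerebrospinal fluid (CSF) in the basal cisterns moves slowly and
non-laminarly, too slowly for phase-contrast velocimetry and too far for spin
tagging, so its motion is quantified here from the *b*-value dependence of the
diffusion-weighted MRI signal.  Over b = 0–1000 s/mm² the magnitude signal of
a voxel follows, to good approximation, a monoexponential

    S(b) = S0 · exp(−b · D)

where `S0` is the signal without diffusion weighting and `D` (mm²/s) the
decay rate.  In parenchyma `D` is an apparent diffusion coefficient; in
freely circulating CSF it is dominated by incoherent fluid motion
(pseudo-diffusion), so a larger `D` means more vigorous neurofluid movement.
The suprasellar cistern — CSF around the circle of Willis — is the primary
region of interest; ventricular CSF, total gray matter (GM) and total white
matter (WM) are comparison regions.  Choroid plexus perfusion, a proxy for
CSF production activity, is measured with pseudo-continuous arterial spin
labeling (pCASL).

Because the cohort's raw images are not publicly deposited, the pipeline is
exercised end-to-end on digital phantoms whose ground truth is set to the
published group summaries.  Every acceptance-style result in this repository
is therefore a *parameter-recovery* or *calibration* statement, not a
re-analysis of patient data.

## Decay-rate mapping (`neurofluid.decay`)

1. **Bulk-motion correction.**  Each volume is rigidly aligned to the first
   b=0 volume by an integer-voxel translation chosen to maximize normalized
   cross-correlation over a ±3-voxel search window.  Shifts are circular
   (`np.roll`); under circular shifts the NCC denominator is shift-invariant,
   so the argmax is found from the FFT cross-correlation numerator alone,
   which makes the exhaustive search exact and cheap.  Sub-voxel and
   rotational motion are out of scope (phantom data share one grid).
2. **Direction combination.**  The six diffusion directions at each nonzero
   shell are combined by the voxelwise geometric mean — equivalent to
   averaging log-signals, i.e. a trace-style isotropic combination — because
   cisternal CSF motion is modeled as isotropic and the acquisition's
   direction handling is otherwise unspecified.  b=0 volumes are averaged
   arithmetically.  Shells enter the fit with equal weight.
3. **Voxelwise fit.**  Nonlinear least squares of `S0·exp(−b·D)` on the
   untransformed signal scale, initialized from ordinary least squares on
   log-signal and refined by a damped Gauss–Newton iteration (vectorized
   across voxels; backtracking step halving; convergence when parameter
   moves fall below 1e-14).  On noiseless input the initializer is already
   exact and the refinement does not move it, which is what makes
   machine-precision recovery testable.  Per voxel, shells with nonpositive
   signal are dropped (not clipped); a voxel needs ≥3 usable shells, and a
   fitted `D` at or below the positivity floor of 1e-8 mm²/s is flagged
   invalid rather than reported as 0.  `r²` is computed on the untransformed
   scale.
4. **ROI summary.**  Arithmetic mean of `D` over the valid voxels of an atlas
   region, with the voxel count reported.

## ASL quantification (`neurofluid.asl`)

Interleaved control/label pCASL volumes (controls at even indices) are
surround-subtracted: ΔM_k = (C_k + C_{k+1})/2 − L_k, the terminal label using
its single neighbor.  ΔM is averaged over pairs, normalized by the M0 volume,
and inverted through the post-bolus single-compartment kinetic model

    ΔM/M0 = CBF · 2 α T1b (1 − e^(−τ/T1b)) e^(−PLD_eff/T1b) / (6000 λ)

with λ = 0.9 mL/g, α = 0.8 (background-suppression losses folded in),
T1b = 1624 ms, τ = 1800 ms and PLD = 2000 ms by default.  All times are kept
in milliseconds internally; T1b enters the closed form in seconds and the
6000 factor converts mL/g/s to mL/100 g/min.  The model is linear in CBF, so
for a single post-label delay the inversion is a division; the forward form
doubles as the simulation and test oracle.  The slice-delay correction is
PLD_eff = PLD + slice_index × slice_readout_time, assuming ascending 2D
acquisition; the per-slice readout time has no universal default, must be
supplied in the config, and 0 disables the correction.

A noise floor of 10 mL/100 g/min is applied voxelwise *before* ROI
averaging: voxels below it are never reported as quantified perfusion, and
ROI summaries average above-floor voxels only.  (Applying the floor to ROI
means instead would be the other defensible reading; voxelwise-first is the
interpretation adopted here.)

## Digital phantom (`neurofluid.phantom`)

**Geometry.**  A blocky head on a 64×64×28 grid (echoing the 28-slice
acquisition at desk scale): WM ellipsoid core, GM shell, two lateral-ventricle
CSF blocks each containing a choroid-plexus sub-block, and a small midline
inferior suprasellar-cistern block.  The seed jitters region centers by ±1
voxel.  No folded cortex, partial-volume mixing or pulsatility is modeled, so
passing tests demonstrate correctness of the estimators, not robustness to
anatomy- or physiology-driven artifacts.

**Signal models.**  DWI voxels follow `S0·exp(−b·D)` with region-wise
constants; default decay rates are the healthy-group means (WM 0.00131,
GM 0.00138, ventricle 0.00241, suprasellar 0.00328 mm²/s) and the choroid
plexus carries 31.3 mL/100 g/min.  Magnitude DWI noise is Rician,
`sqrt((S+n1)² + n2²)` with n1, n2 ~ N(0, σ); ASL volumes get additive
Gaussian noise (subtraction-regime statistics).  In both cases
σ = S0(WM)/snr, so a single `snr` number controls the whole phantom.  The
source acquisitions' noise levels are not characterized anywhere, so `snr`
is a free simulation choice; the CLI logs it, and the tissue-contrast
replication suite uses snr = 50, a mid-range value for clinical EPI at this
voxel size.

**Cohort generator.**  Per-subject ROI values are Normal(mean, SD) per group
with the published summaries as defaults (32 healthy / 27 PD), floored at
1e-5 mm²/s (decay) and 0.1 mL/100 g/min (perfusion) to keep draws physical.
Within each group, suprasellar decay and choroid plexus perfusion are drawn
jointly from a Gaussian copula whose Pearson parameter is
ρ = 2 sin(π ρ_s / 6) for the target Spearman ρ_s — the exact bivariate-normal
rank-correlation inversion — with ρ_s = −0.51 in PD and 0 in healthy.  The
healthy 0 is an assumption: the published healthy association was a null
*test* result, not a zero estimate.  UPDRS (PD only) and MoCA are drawn from
their group Normals with no built-in decay correlation by default (the
published UPDRS trend was non-significant); an optional UPDRS–decay rank
correlation can be injected.  Sex is Bernoulli(0.5) per group because the
demographic table reports no sex split.  Ages use the table values
(healthy 67.6 ± 9.0, PD 66.0 ± 6.8 years).

## Cohort statistics (`neurofluid.stats`)

Continuous group contrasts use the Wilcoxon rank-sum test with midrank ties.
For combined samples of ≤12 observations the two-sided p is computed by exact
enumeration of all rank assignments (ties included, since the midranks
themselves are permuted); above that, the normal approximation with
tie-corrected variance and a 0.5 continuity correction.  The switch point
matters: the approximation's worst-case deviation from enumeration is ~0.09
at 2+2 and still ~0.03 at 4+4, but falls below 0.02 for the sizes just above
the switch — so the exact path covers exactly the regime where the
approximation is untrustworthy.  Categorical contrasts use Pearson's
chi-squared without continuity correction (1 df).  Associations use Spearman
rank-order correlation (Pearson of midranks, t-approximation p; constant
input yields a flagged, undefined result rather than an exception).
Covariate dependence (cohort, age, sex) is assessed by separate simple OLS
regressions with t-based p-values, with an optional joint model; sex enters
as a binary indicator.  Significance is two-sided p < 0.05 with no
multiplicity adjustment across the table rows, matching the study design
being emulated.

## Numerical and design choices

- Computation in float64 throughout; NIfTI output stored as float32 (and the
  NIfTI-1 affine fields are float32, so affines round-trip to that
  precision).
- bvec direction grouping tolerance 1e-6 on unit vectors, with antipodal
  vectors treated as the same direction (text files carry limited precision).
- b-values are taken as given per volume and never recomputed from gradient
  physics (γ, G, Δ, δ are deliberately not represented).
- Registration to standard space and learned choroid-plexus segmentation are
  out of scope: phantom masks are exact by construction and all data share
  one grid.
- Problem sizes in the test suite: the replicated tissue-contrast check runs
  100 noisy phantoms on the default 64×64×28 grid; statistical calibration
  uses 1000 null cohort replicates at the study's 32/27 group sizes; the
  copula calibration check uses 10⁵ pairs.

## Known limitations

- The monoexponential model ignores biexponential (IVIM-style) behavior at
  low b; with only seven shells this is the intended simplification.
- The motion model is integer-voxel translation only.
- The phantom's piecewise-constant regions make ROI recovery exact in ways
  real anatomy (partial volume, pulsatility) would not be; noise-robustness
  conclusions transfer, absolute-accuracy ones do not.
- The kinetic inversion assumes the post-bolus regime (PLD_eff ≥ τ); very
  long slice trains at short PLD would violate it.
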