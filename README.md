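# neurofluid

Quantification of cerebrospinal-fluid (CSF) motion from multi-b-value
diffusion MRI and of choroid plexus perfusion from pseudo-continuous arterial
spin labeling (pCASL), with digital phantoms and the cohort-level statistics
used to compare Parkinson's disease (PD) with healthy aging.

Slow, non-laminar CSF movement in the basal cisterns is invisible to
phase-contrast velocimetry, but it attenuates the diffusion-weighted signal:
a voxel's magnitude signal over diffusion weighting *b* follows

    S(b) = S0 · exp(−b · D)

and the decay rate `D` (mm²/s), fit over seven shells
(b = 0, 50, 100, 200, 300, 700, 1000 s/mm²), acts as a quantitative
neurofluid-motion readout in CSF spaces such as the suprasellar cistern.
Choroid plexus perfusion (CBF, mL/100 g/min) — a proxy for CSF production —
is quantified from surround-subtracted, M0-normalized pCASL through the
post-bolus single-compartment kinetic model

    ΔM/M0 = CBF · 2 α T1b (1 − e^(−τ/T1b)) e^(−PLD/T1b) / (6000 λ)

with λ = 0.9 mL/g, α = 0.8, T1b = 1624 ms, τ = 1800 ms, PLD = 2000 ms and a
10 mL/100 g/min noise floor.  The package is aimed at neuroimaging
researchers who want a tested, reusable implementation of this analysis; the
original cohort's images are not deposited, so a phantom module generates
image- and cohort-level synthetic data with the published statistical
structure, making every stage verifiable by parameter recovery.

## Modules

| module                  | what it does |
|-------------------------|--------------|
| `neurofluid.io_imaging` | NIfTI volume series, FSL bval/bvec parsing, ASL config, validation |
| `neurofluid.phantom`    | tissue atlas, DWI/ASL forward simulation (Rician / Gaussian noise), Gaussian-copula cohort generator |
| `neurofluid.decay`      | bulk-motion correction, direction combination, voxelwise exponential fitting, ROI summaries |
| `neurofluid.asl`        | surround subtraction, slice-delay correction, kinetic-model inversion, noise floor |
| `neurofluid.stats`      | Wilcoxon rank-sum (exact ≤12, tie-corrected normal above), chi-squared, Spearman, OLS regressions, full cohort analysis |

## Worked example

```bash
neurofluid simulate --out phantom/ --seed 1 --snr 50 --dims 32 32 16 --n-pairs 4
neurofluid fit-dwi --dwi phantom/dwi.nii.gz --bval phantom/dwi.bval \
    --bvec phantom/dwi.bvec --mask phantom/atlas.nii.gz \
    --atlas phantom/atlas.nii.gz --out dwi_fit/
cat dwi_fit/roi_decay.tsv
```

```
region              mean_D      n_voxels
white_matter        0.00130999  1892
gray_matter         0.00138015  4035
ventricle_csf       0.00240718  186
suprasellar_cistern 0.00328869  27
choroid_plexus      0.00139759  54
```

The fitted ROI means recover the phantom's ground-truth decay rates (WM
0.00131, GM 0.00138, ventricle 0.00241, suprasellar 0.00328 mm²/s) to within
the snr = 50 noise, and the expected tissue contrast — CSF spaces well above
GM above WM — is preserved.  The cohort-level analysis on the synthetic
per-subject table shows the injected structure:

```bash
neurofluid report --table phantom/cohort.tsv
```

```
== Group comparisons ==
 suprasellar_d: wilcoxon_rank_sum p = 0.0004533 *
  cp_perfusion: wilcoxon_rank_sum p = 0.2094
...
== Correlations (Spearman) ==
cp_perfusion vs suprasellar_d[healthy]: rho = 0.240, p = 0.1849, n = 32
cp_perfusion vs suprasellar_d[PD]: rho = -0.759, p = 4.479e-06, n = 27 *
```

i.e. reduced suprasellar decay in the PD group, no group difference in
perfusion itself, and an inverse perfusion–decay association present only in
PD — the pattern the generator is calibrated to.  (`*` marks two-sided
p < 0.05; with n = 27 the sample Spearman scatters widely around its −0.51
target.)

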