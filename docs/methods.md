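# Methods

`navein` quantifies how much cerebral venous blood contributes to brain
tissue sodium (²³Na) MRI measurements. Because no raw sodium MRI of this
kind is publicly deposited, the package pairs the analysis with a
synthetic-data generator that reproduces the statistical structure the
analysis assumes, so every step can be validated against known ground
truth. This note records the models, the parameters that matter, the
numerical choices, and what the synthetic validation does and does not
establish about real data.

## The analysis

Whole blood carries ~87 mM sodium against ~38–42 mM in brain tissue, so
the blood compartment inflates apparent tissue sodium concentration
wherever vessels share a voxel. The pipeline estimates that contribution
in five stages:

1. **Vein identification.** Veins are hypointense on T2\*-weighted
   (FLASH-like) ¹H images. A Gaussian high-pass filter of 3 mm FWHM
   (implemented as image minus Gaussian-smoothed image, σ = FWHM/2.3548
   per axis) suppresses contrast at scales larger than a vein; veins
   survive as negative excursions. A brain mask eroded once with a 7×7
   in-plane structuring element removes filter artifacts at the brain
   edge, and a minimum negative threshold yields a binary vein mask.
   Structures wider than the filter scale — notably the superior
   sagittal sinus (SSS) — do not survive the high-pass and are handled
   separately as a direct region-of-interest measurement.
2. **Partial volume maps.** The fine-grid vein mask and tissue maps are
   reduced to the sodium grid by taking the mean of each 7×7×7 block of
   sub-voxels. Block averaging involves no interpolation and therefore
   adds no spatial smoothing. On the synthetic grids one coarse voxel
   (3.2 × 3.2 × 6.4 mm) is exactly 343 fine voxels; the 131:1
   FLASH-to-sodium voxel-count ratio of a 0.5 × 0.5 × 2 mm acquisition
   grid is reproduced by `voxel_count_ratio`.
3. **Masking and referencing.** Voxels with CSF partial volume ≥ 0.01
   are excluded (CSF carries ~150 mM sodium and larger veins lie
   adjacent to CSF spaces); GM/WM regions use an inclusive 0.5 PVE
   threshold. Sodium signal is converted to concentration against the
   vitreous humor (VH) of the eyes, assumed 134 mM, measured as the
   mean over the VH region after one 3×3×3 erosion so the reference is
   free of partial volume bias.
4. **Regression.** Ordinary least squares of VH-normalized sodium
   signal on vein PVE over all brain-tissue voxels (and separately in
   GM-only and WM-only regions); the value extrapolated to vein PVE = 1
   is the apparent venous sodium concentration. The SSS is measured as
   the mean over voxels with SSS PVE ≥ 0.5. Cohort comparisons use
   paired two-tailed t-tests, Bonferroni-corrected for the four
   comparisons (all-tissue, GM, WM regressions and the SSS-vs-GM
   contrast).
5. **Blood-volume correction.** A two-compartment mixture,
   [Na]_vox = (1 − CBV)·[Na]_tissue + CBV·[Na]_blood, is inverted to
   remove the blood contribution from measured tissue values. With
   literature CBV of 2.7% (WM) and 5% (GM) and blood at 87 mM, measured
   39.1 / 41.9 mM correct to 37.8 / 39.5 mM — reductions of 3.4% and
   5.7%.

## The acquisition forward model

The sodium image is modelled as the true fine-grid concentration map
convolved with the point spread function (PSF) of a density-weighted
twisted projection imaging (TPI) readout, block-averaged to the coarse
grid, modulated by smooth B1 fields, and corrupted by Gaussian noise
(magnitude taken when noise is present; the noise-free path returns the
signed convolution so linearity and signal-conservation identities hold
exactly).

The k-space weighting is the product of

* a Hamming window, 0.54 + 0.46·cos(πk), k = |k|/k_max — the sampling
  density of the acquisition is designed to apply this apodization
  itself, suppressing Gibbs ringing from CSF; and
* biexponential transverse decay evaluated at TE + t(k) along the
  readout, with blood components T2fast = 2 ms and T2slow = 17 ms. The
  amplitude split defaults to 0.6 fast / 0.4 slow, the satellite/central
  transition partition of spin-3/2 quadrupolar relaxation, exposed as a
  parameter because the split is not fixed by any constraint available
  to the package.

The TPI time map is radial (linear in k) out to ρ = 0.2 of k_max, then
twisted with constant 3D sampling density, k ∝ t^(1/3), scaled so the
18 ms readout ends at k_max; the branches are continuous at ρ. This is
the simplest model consistent with a TPI trajectory; the exact
density-weighted time map of the original sequence is not public, so
the mapping is isolated behind `tpi_time_map` where it can be swapped.

Anisotropy enters only through the per-axis k_max = 1/(2·voxel): the
weighting is evaluated on the normalized radius, so the out-of-plane
PSF width is exactly the voxel ratio (2.0) times the in-plane width.

**PSF width.** With these defaults the simulated in-plane FWHM is
7.8 mm (15.5 mm out-of-plane). The published figure for this
acquisition is 7.1 mm in-plane; the difference traces to the two model
ingredients the literature does not pin down here — the amplitude split
of the biexponential decay (7.1 mm is reproduced near a fast fraction
of 0.2) and the exact trajectory time map. The default keeps the
principled 0.6 quadrupolar split rather than calibrating to the
published width. The checks that are insensitive to this assumption —
the out-of-plane/in-plane ratio of 2.0, the Hamming endpoints, and the
rectangular/no-decay limiting case (FWHM = (2x/π)·v ≈ 1.590·v per axis,
where 3(sin x − x cos x)/x³ = ½ at x ≈ 2.4983) — are asserted in the
test suite and pass.

**Numerics.** Convolution is performed in the transform domain with
periodic boundaries; the phantom's zero background makes wrap-around
negligible. The weighting is normalized to unit DC gain, so the kernel
sums to 1 and uniform volumes are reproduced at their own level.
Because the sampling stops dead at k_max, the real-space kernel rings
with an envelope decaying only quadratically in distance; `build_psf`
therefore accepts a boundary-tail tolerance (default 2×10⁻³ of peak,
reached on a ~128-voxel support) rather than demanding machine-precision
tail decay, which no practical support achieves. FWHM is measured on
axis profiles through the peak by linear interpolation at half maximum.

**B1.** Transmit and receive fields are smooth multiplicative random
fields centred on 1 with bounded amplitude. The actual flip angle is
recovered with the double-angle method, arccos(S₂α/2Sα), and the image
divided by the receive sensitivity and sin(actual)/sin(nominal). TR and
flip-angle saturation are treated as absorbed into the density-weighted
design; there is no T1 term.

## The phantom

One subject is an ellipsoidal brain (semi-axes 0.31/0.34/0.21 of the
field of view) containing, from outside in, a 2 mm CSF rim, a 6 mm
gray-matter shell, a white-matter core and ellipsoidal CSF ventricles.
Veins are piecewise-linear random-walk cylinders (segment length 4 mm,
radius drawn from 0.5–1.4 mm) added until they occupy the target
fraction of brain volume — default 3.1%, matched within ±0.005 on every
successful run, with an explicit error naming the achieved fraction
otherwise. The vein budget (default 120) caps the attempt. Per-voxel
coarse vein PVE reaches maxima in the tens of percent, matching the
regime the regression operates in. A single midline surface cylinder
(radius 3 mm, diameter wider than the 3 mm high-pass scale) stands in
for the SSS, and two 14 mm-radius VH spheres sit fully outside the
brain — large enough that the coarse VH region survives one 3×3×3
erosion on the anisotropic sodium grid. Default concentrations: WM
37.8, GM 39.5, CSF 150, blood 87, VH 134 mM.

The FLASH volume places all tissue at a constant level (100 a.u.),
darkens vein and SSS voxels by 50%, optionally dilates the darkened
support by a "bloom" radius to emulate fringe-field overestimation of
vein extent, and adds Gaussian noise (sd 2 a.u.). The automatic vein
threshold is 3.5 × 1.4826 × MAD of high-passed values inside the eroded
mask; this robust rule is undefined on noise-free data (MAD = 0 raises
an explicit error), where a manual threshold applies instead.

Cohorts (default 9 subjects) draw per-subject GM/WM concentrations with
sd 2.5 mM (≈3× the published between-subject SEM of tissue values) and
derive per-subject seeds from the master seed; identical (spec, seed)
always yields bit-identical volumes.

**Problem sizes.** The default fine grid is 224³ (coarse 32³); the full
9-subject cohort runs in about a minute on one CPU. The test suite uses
a 140×140×112 grid, the smallest on which both VH spheres fit outside
the brain with the coarse reference region surviving erosion.

## What the synthetic validation shows — and does not

On phantoms the pipeline recovers the 87 mM blood input within 2%
(mean over 20 seeds) when PSF and noise are disabled, demonstrating
that the regression machinery itself is unbiased under the mixture
assumption. With the acquisition PSF enabled the apparent venous
concentration falls strictly below the input on essentially every seed,
and dilating the FLASH vein darkening (PVE overestimation) depresses it
further — the two mechanisms proposed for why measured venous values
(55–71 mM in vivo) undershoot in vitro blood. These are qualitative
mechanisms reproduced under controlled conditions, not quantitative
predictions of in vivo values: the phantom brain is smaller than a real
head relative to the PSF, so CSF and vein smearing elevate synthetic
tissue means above in vivo tissue values, and the phantom has no
arteries, no microvasculature, no susceptibility field simulation, no
cortical folding and no registration error. Absolute cohort numbers
from the phantom therefore do not transfer to real data; the recovery
and monotonicity properties do.

## Degenerate inputs and tie-breaks

* GM/WM regions use inclusive ≥ at 0.5; on an exact 0.5/0.5 tie the
  voxel goes to GM so the regions stay disjoint.
* CSF exclusion is inclusive: CSF PVE exactly 0.01 is excluded.
* A constant vein-PVE predictor (e.g. a vein-free configuration) raises
  a degenerate-design error rather than returning an unidentified fit.
* Paired t-tests on zero-variance differences return the null result
  (t = 0, p = 1) for identical arrays and raise for a constant nonzero
  shift.
* Brain-mask erosion raises, naming the first affected axial slice,
  when a nonempty mask erodes to nothing.
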