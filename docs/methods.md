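# Methods

`cbctdose` implements a complete, testable analogue of the workflow used to
decide whether in-room cone-beam CTs (CBCTs), after correction, can replace a
repeat CT (rCT) for dose evaluation in breast radiotherapy. Because no image
data of this kind is publicly deposited, the package pairs the evaluation
chain with a synthetic-data generator whose corruptions are fully known, so
that every correction and every metric can be validated against ground truth.

## Synthetic study cases

A case is a triplet (pCT, rCT, CBCT) with structure sets on a shared grid.

**Anatomy.** A piecewise-constant thorax: an elliptical body cross-section
(semi-axes 140 x 88 mm) with a 12 mm subcutaneous adipose rim, two ellipsoidal
lungs, a spherical heart, rib cross-sections, and a hemispherical breast with
a glandular core on the treated side. Tissue HU defaults: air -1000, lung
-750, adipose -90, breast glandular 20, soft tissue 40, bone 700; all
configurable. Structures (BODY, whole-breast CTV, boost CTV, heart, lungs)
are emitted analytically; CTVs are contracted to stay >= 5 mm inside the BODY
contour. The default grid is 128 x 128 x 64 at 2.5 mm; the cohort analyses use
a scaled-down 72 x 72 x 40 grid at ~4.4 mm so a ten-case cohort runs in about
three minutes on one core.

**Deformation (pCT -> rCT).** The study population is patients whose breast
surface deformed by more than 5 mm, so the generator applies a smooth radial
bump centred on the breast: a Gaussian (sigma 32 mm) of the distance to the
breast apex, with compact support (96 mm) and a C1 taper near the breast
centre, scaled to a requested peak surface displacement (swelling or
shrinkage). The field is the pull-back displacement used for warping; a
fixed-point surface-tracking oracle confirms the realised peak matches the
request within 5%, and the Jacobian determinant of the map is checked to be
positive everywhere (no folding). The cohort draws peaks uniformly from
6-10 mm, always satisfying the > 5 mm inclusion criterion.

**CBCT corruption.** Artifacts are modelled phenomenologically as the three
corruption classes the correction methods address, not by scatter physics:

* a strictly monotone HU-scale distortion `g = a*HU + b` (defaults a = 0.9,
  b = -30 HU, optional mild tanh nonlinearity);
* a smooth low-frequency in-plane shading field: 70% systematic radial
  scatter *cupping* over the FOV (depressed centre, raised rim) plus 30%
  seeded Gaussian random field band-limited at 100 mm FWHM, scaled so its
  peak magnitude inside the FOV equals the configured amplitude (80 HU
  default);
* additive Gaussian noise (sigma 20 HU; CT images carry sigma 8 HU);
* a cylindrical field of view (radius 130 mm, length 140 mm) outside which
  the CBCT is air-filled.

The CBCT corrupts the (noisy) rCT voxel-for-voxel, so inside the FOV
`CBCT = distort(rCT) + shading + noise` holds by construction and every
corruption is returned as ground truth. All randomness is derived from one
case seed.

What the generator deliberately does **not** emulate: projection-domain
reconstruction artifacts (streaks, motion), anatomy change between CBCT and
rCT acquisition days, delineation variability, and registration error when
ground-truth alignment is injected. Passing the cohort tests therefore shows
that the evaluation chain orders the correction methods correctly under known
corruptions; it does not bound their accuracy on clinical scans.

## Correction methods

**HU-override (CBCT_HU).** Five thresholds are placed by multilevel Otsu on
the grey-level histogram inside BODY ∩ FOV, partitioning grey levels into six
classes assigned fixed mass densities (air 0.00121, lung 0.26, adipose 0.95,
tissue 1.05, cartilage/bone 1.6, other 3 g/cm^3). The implementation is an
exact dynamic program maximising between-class variance on a 1-HU-resolution
histogram (the commonly used library implementation is prohibitively slow at
six classes); ties at a threshold fall in the lower class. The raw grey
levels are kept unaltered next to the class map: HU-accuracy metrics for this
method are computed on the raw CBCT, only dosimetry uses the class densities.
This is why CBCT_HU shows both the worst MAE and a systematic dose error: the
six fixed densities overestimate the true density of every phantom tissue
(e.g. 1.05 vs ~1.02 g/cm^3 for soft tissue, 1.6 vs ~1.42 for rib bone),
producing a one-signed target underdosage.

**Analytical correction and conversion (CBCT_CC).** Iterates (default 3
rounds, early stop when the tracked MAE stops improving):

1. deformable registration of the reference CT onto the current corrected
   CBCT (or the injected ground-truth field);
2. grey-level conversion from a joint histogram of (CBCT grey, deformed-CT
   HU) pairs inside the **whole FOV** — including the air around the body,
   which anchors the low end of the map; without those anchors the clamped
   map mislabels exterior air by ~200 HU and the error bleeds through the
   low-pass filter into the body rim;
3. a difference map (deformed CT minus converted CBCT) restricted to the
   FOV, Gaussian low-pass filtered (25 mm FWHM, mask-normalised so the FOV
   edge does not ring), added to remove residual low-frequency shading.

Joint-histogram choices: 128 x 128 bins over the 0.05-99.95 percentile range
(wide enough to retain bone, which is ~0.2% of a breast FOV), a column
support threshold of 0.01% with an 8-voxel floor, per-column ridge = the
conditional **median** of the CT HU (the L1-optimal estimate under the
tissue-mixture distribution of a column; the modal-bin mean is available as
an option), monotonised by pool-adjacent-violators and evaluated by linear
interpolation with clamped extrapolation. The residual error of the
corrected image is bounded below by CBCT noise leaking through the
conversion (roughly `0.8 * sigma_noise / gain` where the map is locally
linear); flat segments at well-separated tissue plateaus suppress this,
adjacent plateaus (glandular 20 vs soft tissue 40 HU) cannot be disentangled
at sigma = 20 HU and trade a small quantisation error instead.

**Virtual CT (CT_V).** The reference CT warped onto the CBCT; only air
pockets are replaced with CBCT_CC values, so the output equals the warped CT
bit-exactly everywhere else. Pockets are connected components below -300 HU
inside the BODY, at least 0.5 cc, *internal* (not connected to the skin
partial-volume shell), not touching the lungs (which are legitimately
air-like anatomy), and, on the CBCT side, inside the FOV (outside it the
CBCT carries only padding).

## Registration

Rigid: multi-resolution mean-squared-difference optimisation
(regular-step gradient descent, shrink factors 4/2/1), 6 DOF by default with
a rotation-only `rot3` option, since the clinical phrasing of a "three
degree" registration is ambiguous and couch shifts require translations. The
result is never worse than the identity on the jointly valid domain.
Deformable: fast symmetric-forces demons, multi-resolution (4/2/1), Gaussian
field regularisation of 2 voxels (ITK specifies this in pixel units), 50
iterations per level. A focus mask fades the field to zero outside its
dilation — necessary because coarse-level aliasing of thin sharp structures
(ribs, skin) otherwise leaves spurious displacements far from the true
deformation. Both registrations accept an injected ground-truth transform so
every downstream analysis can be run with registration error excluded.

## Dose engine

A surrogate primary-fluence engine replaces the commercial collapsed-cone
algorithm: per control point, dose = weight x aperture transmission x
`exp(-mu_eff * r)` x inverse-square, with `mu_eff = 0.05 /cm` (~6 MV) and
`r` the water-equivalent depth from the source. There is no scatter kernel;
all dosimetric conclusions are *relative* comparisons between image sets
under this one engine, which is also how the clinical question is posed.
Radiological depth is computed per control point on a divergent
beam's-eye-view lattice (3 mm sampling, cumulative midpoint integration) and
interpolated to the voxels; an exact Siddon voxel traversal is provided as
the path-length primitive and agrees with dense sampling to < 0.5%, and the
central-axis attenuation law is reproduced to ~1e-5 relative.

The plan mirrors the clinical 70%/30% partial-VMAT breast technique: two
opposed tangential rectangular fields (70% weight) whose axes are derived
from the target geometry (offset 72 degrees from the breast's anterior
bearing so they graze the chest wall and exit without crossing the
mediastinum), plus four short conformal arcs of 40-80 degrees (30% weight)
discretised at 5 degrees (10 degrees in the cohort runs). Apertures are
fitted to the CTV's beam's-eye-view projection plus a 7 mm margin, with a
compact smoothstep penumbra (exactly zero outside, so the "dose > 0" gamma
inclusion rule is well posed). The plan is normalised once so the mean
whole-breast-CTV dose on the pCT equals the prescription (42.56 Gy default,
16 F x 2.66 Gy), and that scale is frozen for every other image set. Dose is
computed on the image grid. For dose calculation, CBCT_HU uses its class
densities and the other image sets a piecewise-linear HU-to-density table
(anchors -1000 -> 0.00121, 0 -> 1.0, 1000 -> 1.6, 3000 -> 3.0 g/cm^3);
densities inside the BODY but outside the CBCT FOV are overridden to
1 g/cm^3 on all corrected CBCTs.

DVH statistics D1/D2/D95/D98/D99 use the top-down percentile with linear
interpolation between order statistics; dose differences are reported
relative to the prescription.

## Gamma analysis

Global 3-D gamma with the dose criterion as a percentage of a fixed
normalisation dose (42.47 Gy default), distance criteria in mm, and
inclusion of reference voxels with dose strictly above 0. The evaluated
distribution is trilinearly refined 3x. The production search expands
neighbourhood shells in order of distance and terminates only when the
distance term alone exceeds the best gamma found, so it returns the exact
global minimum over the refined lattice; a dedicated exhaustive
implementation exists purely as the test oracle and the two agree to
machine precision on random fields. Criteria sweeps (2%/2 mm, 3%/3 mm,
5%/5 mm) are monotone by construction.

## ACE risk model

Acute-coronary-event risk is a function of mean heart dose only:
`risk = baseline * (1 + 0.074 * MHD_Gy)` per age bracket, linearly
interpolated between a minimum-risk bracket (> 70 years, baseline 1%) and a
maximum-risk bracket (< 40 years, baseline 10%) by a weight in [0, 1] and
clamped to [0, 100]%. The relative slope is the published linear
excess-rate-per-Gy figure for cardiac events after breast radiotherapy; the
baselines are illustrative configuration defaults, not cohort-derived
values, and all three parameters are configurable. Heart D1/D2 deviations
are reported in the DVH tables but deliberately do not enter the risk
number.

## Evaluation conventions

* MAE and ME are computed over an ROI with the sign convention
  reference (rCT) minus synthetic; hence a synthetic CT that reads too
  *bright* yields a negative ME.
* The CBCT-ROI is the FOV eroded by 2 cm — 3-D erosion by default, affecting
  both the radius and the axial ends; an in-plane-only flag is provided
  because the clinical definition does not state the cranio-caudal handling
  — intersected with the BODY contour, and shared across image sets so the
  compared volumes are identical.
* Erosion is computed on the world-space Euclidean distance transform
  because voxel spacing may be anisotropic.
* Structures are transferred rigidly for HU metrics and deformably for dose
  metrics (two distinct pipeline paths); after transfer they are clipped to
  the BODY automatically (replacing a visual check-and-fix step).
* Cohort comparisons vs the rCT use the two-tailed pooled-variance t-test;
  zero pooled variance with equal means returns p = 1 by convention.

## Recovery-test design

The method-recovery tests (conversion exactness, multilevel-threshold
classification, analytical-correction MAE reduction) run on a variant of the
phantom whose tissue plateaus are separated by at least 200 HU (air -1000,
lung -750, adipose -250, glandular -40, soft tissue 170, bone 700), so that
class membership and conversion targets are unambiguous by construction and
all plateaus sit on the correct side of the -300 HU air threshold. The
cohort analyses use the realistic close-plateau table, where the 20 HU
glandular/soft-tissue gap is intentionally unresolvable at the CBCT noise
level.

## Known limitations

* With ground-truth registration injected and the CBCT generated in the rCT
  frame, the CBCT_CC and CT_V dose deviations vs the rCT are small
  *deterministic* positives (~+0.1% and ~+0.03% of prescription). About a
  third of this is asymmetric rectification of CT air noise through the
  density clamp at -1000 HU; the remainder is the correction's residual. In
  clinical cohorts these deviations scatter around zero with ~1% spread
  driven by registration error and acquisition-day anatomy change — exactly
  the variability sources the ground-truth-injected synthetic conditions
  exclude — so the synthetic cohort reproduces the magnitude ordering of the
  methods but not the sign scatter of the two accurate ones.
* The surrogate engine has no scatter kernel or electron transport; absolute
  doses are not clinically meaningful, only differences between image sets.
* The demons implementation is a generic intensity-based registration; no
  equivalence with any commercial hybrid algorithm is claimed.
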