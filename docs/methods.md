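# Methods

## Overview

`datspect` models the quantitative reading of striatal dopamine-transporter
SPECT as a five-stage pipeline: synthetic subject generation → VOI
construction → six-index quantification → standardized linear-SVM
combination → statistical evaluation.  This note records the model, the
parameters that matter, the numerical choices, and what the synthetic data
can and cannot show.

## Phantom model

A subject is a 128×128×64 grid of 4.4 mm isotropic voxels.  A brain-shaped
ellipsoid (semi-axes 72×88×66 mm) carries a uniform background
concentration; six ellipsoidal striatal compartments (caudate, anterior and
posterior putamen per hemisphere, ≈11.1 mL per side — matching the 11.2 mL
striatal volume the large-VOI SBR method assumes) carry elevated
concentrations.  The geometry lives in a versioned YAML template
(`datspect/data/template_geometry.yaml`); phantoms are generated directly in
template space, so no registration stage exists.

Disease-like appearance is controlled by three parameters:

* `shape_erosion` ∈ [0, 1] attenuates putaminal contrast toward background,
  posterior first (factor 1 − min(2e, 1)) then anterior (1 − max(2e−1, 0)),
  so e = 1 leaves the caudate "dot".  The posterior/anterior specific-uptake
  retention ratio is monotone non-increasing in e (1 at e = 0, 0 from
  e = 0.5), which is the generator's invariant for "more dot-like".
* `asymmetry_factor` multiplies one hemisphere's compartment intensities.
  The cohort sampler converts a target asymmetry index into this factor
  analytically via (a·k − 1)/(k − 1) = (2 + AI)/(2 − AI), k being the mean
  concentration ratio.
* `psf_fwhm_mm` and `total_counts`: the rendered map is convolved with an
  isotropic Gaussian (a single post-reconstruction resolution parameter; a
  single-subject phantom defaults to 12 mm, a typical value for this kind of
  imaging) and Poisson-sampled after scaling to the requested total counts
  (default 2×10⁶, a realistic 30-min acquisition; `None` disables noise).

Voxelization uses 4× supersampled occupancy.  The six compartment masks are
*volume-preserving*: each compartment keeps its N highest-occupancy voxels
(N = fractional volume rounded), because a plain 50%-occupancy cut
understates the volume of bodies this small by up to ~10% at 4.4 mm.
Sub-voxel points inside two osculating ellipsoids are credited to the nearer
one, so compartments are pairwise disjoint; ties at the selection boundary
break on the distance of the voxel centre to the ellipsoid, which is
mirror-symmetric, so left/right masks are exact mirror images on the
symmetric grid — the basis of the left/right-swap tests.

## VOI schemes

**Fitted scheme ("Q")**: the six template compartments plus a bilateral
occipital reference (two ellipsoids placed deep in the posterior brain,
≥ 1.5 FWHM from the brain surface so edge partial-volume cannot bias the
reference mean).

**Pentagonal scheme ("V")**: per hemisphere, the striatal template is
dilated by 12 mm (one nominal PSF FWHM; exact Euclidean dilation via
distance transform), an axial "house" pentagon (rectangle + 15 mm anterior
apex) is circumscribed around the dilated mask, and the pentagon is extruded
across the dilated z-range.  Prisms are clipped at the midline so the two
sides stay disjoint; the dilated caudate crosses the midline slightly, so
containment is guaranteed for the full striatal template and for the dilated
template within each prism's own hemisphere.  The reference is the brain
mask eroded 18 mm inward minus the prism union dilated one voxel.  The
inward erosion is a deliberate design choice: the reference is a
*concentration*, and surface voxels blurred against the zero exterior would
otherwise depress it by several percent, destroying the blur invariance that
is the whole point of the total-count SBR formulation.

## Indices

* SBR-Q: per side, (mean of the three-compartment union − occipital mean) /
  occipital mean; sides averaged.
* SBR-V: per side, (C_t/C_r − V_voi)/V_str with C_t total prism counts, C_r
  reference concentration, V_voi prism volume, V_str = 11.2 mL default
  (config-exposed).  A plain background-subtracted concentration-ratio
  variant is available via `formulation="concentration"`.
* PCR-Q: per side, raw putamen-union mean / caudate mean (no background
  subtraction), sides averaged.
* AI: |L − R| / mean(L, R) on the per-side SBRs; reported as a fraction for
  the fitted scheme and ×100 for the large-VOI scheme, matching the
  magnitude conventions of the two software traditions the schemes emulate.
* FD-V: per side, voxels in the prism are compared against five threshold
  fractions of the in-prism maximum (default 0.35…0.55, config-exposed, a
  2-D single-slice mode available); FD = −slope of the least-squares line of
  ln N versus ln t, sides averaged.  Values are max-normalised *before*
  comparison so that threshold ties survive a global rescaling of the volume
  (scale equivariance).  Stages with zero surviving voxels are dropped with
  a warning; fewer than three surviving stages is an error.

All six indices are ratios or threshold-relative counts and therefore
invariant under multiplying the volume by a positive constant.  One caveat:
integer count data can tie a threshold exactly (e.g. 218/545 = 0.40), and
such ties cannot be preserved under arbitrary floating-point rescaling;
invariance is exact for continuous-valued volumes and for power-of-two
factors on integer data.

FD behaviour along the erosion path is deliberately documented rather than
idealised: the fully eroded dot scores clearly higher than the comma
(≈2.4 vs ≈2.1 noiseless at 14 mm FWHM), but mid-path values dip, because a
two-lobe body that loses one lobe temporarily becomes *more* compact.  The
diagnostic direction (dot > comma, PS > NPS at cohort level) is what the
tests assert.

## Cohort generators

**Tabular route** (default for classifier/evaluation work): six-index panels
drawn per class from independent normals truncated at zero with published
PS/NPS group means/SDs as location/scale (`REFERENCE_STATS`).  An optional
6×6 correlation matrix couples the marginals through a Gaussian copula;
the default is independence because no per-index correlation structure is
published.  Consequences to keep in mind: (1) truncation shifts the realized
mean upward for indices whose mean/SD ratio is small (AI-V in the PS class
by ~15%); (2) independent marginals make some indices *more* separable than
correlated clinical data (the asymmetry indices in particular), so single
tabular-cohort AUCs land near their binormal-implied values (SBR-Q ≈ 0.96)
rather than exactly at published clinical AUCs.

**Image route**: the cohort sampler draws, per subject, a global uptake
scalar (truncated normal, CV 0.27 NPS / 0.35 PS) multiplying fixed
caudate/putamen concentration ratios, an erosion level (0.05 ± 0.04 NPS,
0.60 ± 0.15 PS), an asymmetry target (0.03 ± 0.02 NPS, 0.09 ± 0.06 PS) and
a side.  The class ratios (7.60/6.45 NPS, 5.80/5.20 PS over background) and
the cohort PSF FWHM (14 mm) were calibrated once, by a fixed-point loop
against the published NPS group means, so that a rendered 40-subject NPS
cohort reproduces SBR-Q ≈ 2.3, SBR-V ≈ 5.7 and PCR-Q ≈ 0.86; the implied
fitted-VOI recovery coefficient (~0.41) is what selects the 14 mm figure.
The PS class keeps physiologic caudate-dominant uptake and is validated
directionally (lower SBRs, lower PCR, higher FD and AI than NPS).

What passing tests on these phantoms do **not** show: robustness to
anatomical variability, registration error, ventricular dilatation, scanner
and reconstruction differences, attenuation/scatter — none of which the
generator emulates.  The phantoms certify the *computational* pipeline
(definitions, invariances, statistics), not clinical performance.

## Classifier

`StandardizedLinearSVM` is a scikit-learn-compatible estimator: z-scoring
with training-set mean/SD (population SD, so transformed training columns
have exactly unit variance), soft-margin linear SVM (hinge loss + L2,
libsvm), regularization C selected from {0.01, 0.1, 1, 10, 100} by
stratified k-fold cross-validated accuracy (k = 10; ties → smallest C),
refit on the full training part.  Rows are canonically re-ordered (label,
then features) before folding and fitting, making the fit invariant to input
row order; all shuffling is seeded.  PS is encoded as the positive class, so
decision scores are positive on the disease side of the hyperplane.  The
stratified 75/25 split draws round(fraction × class size) test subjects per
class (71/40 → 18 + 10 = 28).  Standardization statistics are never
estimated on test data.

## Evaluation

ROC/AUC is computed from midrank placement values, which makes the AUC
identical to U/(n⁺·n⁻) (ties count ½) and yields the structural components
for the DeLong paired-AUC covariance test (z = ΔAUC/SE; self-comparison is
defined as z = 0, p = 1).  Mann-Whitney tests use the exact null
distribution for tie-free samples with n⁺·n⁻ ≤ 400, a full enumeration of
group assignments when ties are present and the assignment count is small
enough to list, and the tie-corrected normal approximation otherwise.
Cutoffs maximize Youden's J (criterion config-exposed; ties resolve toward
higher sensitivity; reported as the midpoint between adjacent observed
scores).  Confusion percentages are rounded half-up to one decimal, the
convention of the clinical tables this package mirrors; ratios with an empty
denominator are flagged undefined, never reported as 0.  Report direction
conventions: higher SBR/PCR → NPS, higher AI/FD/SVM score → PS.  Two-sided
tests, α = 0.05, no multiple-testing correction (noted in the report).
Single-index rows in the report are resubstitution results on the full
cohort; SVM rows are held-out test-split results — an asymmetry kept on
purpose because it mirrors how such analyses are commonly reported.

## Problem sizes and reproducibility

Tests exercise the image route at the full published cohort size (71 PS /
40 NPS rendered volumes, built once per session) and the tabular route at up
to 10⁴ subjects; cohort-recovery checks run 20 replicate seeds.  The
acceptance script averages tabular quantities over 10 replicates and renders
one image cohort.  Every stochastic stage takes an explicit integer seed and
derives child seeds through `numpy` generators; there is no global random
state, and rerunning any stage with the same configuration is bit-identical
up to float formatting.
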