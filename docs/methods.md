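# Methods

This note documents the models, parameter choices and numerical behavior
behind `acquant`, in the spirit of a methods section: what each procedure
assumes, which knobs matter, and what validation on synthetic data does
and does not demonstrate about real recordings.

## Coordinate and sampling conventions

Arrays are ordered `(z, y, x)`, or `(t, channel, z, y, x)` for time
series. The anteroposterior (AP) axis is `x` (anterior at low `x`); the
dorsoventral (DV) axis is `y` with ventral at high `y`, matching
laterally mounted animals viewed in the mid-sagittal plane. Voxel `i`
along an axis with spacing `d` has its center at `(i + 0.5)·d` µm.
Default voxel size is `(dz, dy, dx) = (0.25, 0.1, 0.1)` µm — the z
spacing of rapid AC-dynamics stacks and a lateral sampling typical of a
60×/NA 1.2–1.4 objective on an sCMOS camera.

## Synthetic scene model (`acquant.scenes`)

Each fixture renders two channels on the same grid:

- **Channel 0 (AC/actin reporter).** An ellipsoid (default semi-axes
  2.0 × 1.5 × 1.5 µm) centered dorsal of the BM, plus, when configured, an
  invasive protrusion: a vertical cylindrical stalk (default radius
  1.2 µm — the invasive protrusion is a chunky, micrometers-wide
  structure, not a needle) capped by a hemisphere. The *protrusion
  proper* is defined as the stalk+cap solid strictly ventral of the BM
  plane; a connecting neck above the BM joins it to the cell body but is
  not counted in the ground-truth volume, mirroring the measurement
  definition ("signal below the BM barrier"). The generator rejects
  configurations whose protrusion would cross an intact BM, whose stalk
  footprint exceeds the gap, or whose tip (including growth) would leave
  the grid — the last case would silently clip the ground truth.
- **Channel 1 (junction/BM reporter).** A flat BM sheet of thickness
  0.3 µm at DV depth `bm_y` (default 6.0 µm) with an optional rectangular
  gap in AP, plus Gaussian punctae (σ 0.15 µm lateral) at the five
  landmark positions. The default layout is physically stratified:
  AC-edge punctae dorsal of the sheet, vulA junctions just ventral of it,
  and the vulF apex well ventral (7.2 µm), as in the invaginating tissue.
  The default landmark set is perfectly symmetric, so the true `R_A` is
  exactly 0.5 and the true `Δ` is 0.

**Ground truth.** Per frame, the true protrusion volume is the count of
voxel centers inside the stalk+cap solid times the voxel volume —
i.e. the same voxelization the measurement chain can at best recover. A
fixture with any rendered gap is marked `true_breached`.

**Optics and noise.** Blur is a separable Gaussian PSF (default lateral
σ 0.15 µm, axial σ 0.4 µm; truncated at 4σ, unit-normalized) — no
depth-dependence or aberrations; adequate for estimator testing, not for
photorealism. Noise follows a gain-parameterized camera model:

```
observed = gain · Poisson(blurred / gain) + Normal(0, read_sd)
```

so a uniform patch has variance `gain·mean + read_sd²` (defaults:
gain 4.0 intensity units/photon, read_sd 2.0). Quadrupling the photon
flux (gain/4) halves the relative shot noise. Output is clipped and
rounded to uint16, with the saturated fraction logged. Intensities
(AC 600, BM 400, punctae 1500, background 5) put the default SNR in a
regime where all estimators work but noise is clearly visible.

**Dynamics.** Shape fluctuations perturb the ellipsoid boundary via a
smooth random field: coarse 4×6×8 Gaussian coefficients evolving as an
Ornstein–Uhlenbeck process with correlation time `deform_tau` (default
60 s), linearly upsampled to the grid; membership becomes
`q ≤ (1 + amplitude·field)²`. Stage jitter, when enabled, applies
integer-voxel *circular* shifts (borders carry only background, and the
translation stays exactly recoverable, which the registration recovery
test exploits). Protrusion growth elongates the stalk linearly in time.
All randomness derives from one seed via `SeedSequence` sub-streams (one
for the deformation/jitter process, one per frame for rendering), so
fixtures are bit-reproducible.

**What the generator does not emulate:** worm body and tissue context,
moving vulF cells, depth-dependent PSF, bleaching, sample drift other
than pure translation, and partially degraded (rather than absent) BM in
a breach. Passing recovery tests therefore demonstrates estimator
correctness under the stated forward model, not performance on real
micrographs.

## Preprocessing (`acquant.imgproc`)

**Richardson–Lucy.** The standard multiplicative update with the
symmetric Gaussian kernel, denominator floored at 1e-12, initialized
from the observed image, run in float32 (the photon-limited data carry
far less precision). Non-negativity holds at every iteration and total
intensity is conserved within ~1% for objects ≥ 4σ from borders. The
function default is 20 iterations — enough to sharpen structure for
dynamics and qualitative work. Low-threshold volumetry is the exception:
thresholding at 5% of the maximum probes the far tail of the edge
profile, where the residual blur after 20 iterations still adds a
~1-voxel shell around the object (~+35% volume on a 1.2 µm stalk).
Volumetry call sites therefore deconvolve with 400 iterations, where the
shell shrinks to ≲ 10% of the volume. An independent implementation
(scikit-image) initialized from a flat image converges to the same
trajectory; the two agree to ~1% near convergence.

**Registration** is translation-only (trapped animals translate but
barely rotate; rotation is a documented non-goal). Shifts are estimated
from the cross-correlation peak (`phase_cross_correlation` with
`normalization=None`; the default phase whitening amplifies noise and
mis-picks integer shifts on photon-limited frames), accumulated against
frame 0, and applied with zero-fill (linear interpolation for subpixel
mode). Shifts at or beyond half the frame size are rejected as ambiguous
wrap-around. The reported shift is the displacement of each frame
relative to frame 0, i.e. it matches the generator's `applied_shifts`
directly.

**Binarization** offers three modes: `fixed-normalized` (intensities
scaled by the stack maximum, threshold 0.05 by default — the constant
threshold used for protrusion segmentation; the normalization scale is a
package decision since a bare "0.05" is scale-ambiguous),
`otsu-first-frame` (default for dynamics series: one threshold from
frame 0 applied throughout, so threshold jitter cannot masquerade as
shape dynamics) and `otsu-per-frame`.

**Peak-centered crop** places the brightest pixel (row-major first on
ties) at `(h//2, w//2)` of a 90×144 window (the crop used for AC
dynamics), zero-padding out-of-bounds regions.

## Alignment (`acquant.alignment`)

`compute_alignment` evaluates the defining ratios along the AP axis
only; vulA1/vulA2 (and the AC edges) are canonically ordered by AP
position first, and a mid-point exactly equidistant from both vulA
junctions is measured against vulA1 (the value of `R_A` is unaffected).
Whenever the AC mid-point lies between the junctions, `R_A ∈ [0, 0.5]`
with 0.5 iff perfectly centered; `R_A` and `Δ` are invariant under AP
translation and reflection.

Automatic landmark detection takes the five brightest local maxima of
the z-projected junction channel (minimum separation 0.5 µm), refines
each to subpixel precision by a background-subtracted 5×5 intensity
centroid, and assigns roles by AP order (vulA1, ac_edge_1, vulF_mid,
ac_edge_2, vulA2). This assumes the standard layout; manually curated
landmark CSVs are authoritative in analysis workflows. On rendered
fixtures at default SNR the recovered `Δ` lands well within one lateral
voxel of truth.

`I_DV` splits the AC mask at its intensity-weighted DV centroid row and
ratios ventral-half to dorsal-half intensity (a row exactly at the
centroid counts toward neither). The originally cited polarity protocol
is published elsewhere and not reproduced here; this formulation is a
stated stand-in, not a verified replica.

## Invasion (`acquant.invasion`)

**BM surface.** Extraction works on the mid-sagittal slice. The DV
search band is auto-located at the row maximizing the across-column
*median* intensity (median rather than max, so bright punctae cannot
hijack the band), half-width 0.3 µm. Within the band, the per-column
height is the background-subtracted intensity centroid (sub-voxel, and
stable under ties when the sheet spans several rows) and the ridge
intensity is the band maximum. Columns whose ridge falls below
`drop_fraction` (0.2) of the median ridge have no sheet to locate;
their heights are linearly interpolated from the flanking intact
columns.

**Breach detection** calls a breach when the longest run of low-ridge
columns spans at least `min_gap` (1.0 µm). Both parameters are free
calibration knobs — the original scoring was by eye. At default SNR the
detector produces no false positives on intact sheets and detects ≥ 2 µm
gaps reliably; PSF blur erodes the apparent gap edges by ~0.15 µm per
side, so reported extents are slightly conservative.

**Protrusion volumetry.** Candidate voxels are binarized AC voxels
ventral of the per-column BM height; 26-connected components are formed
(thin diagonal stalks survive), and the measured component is chosen by
a seed voxel (preserving the manual per-frame workflow), as the largest
component (`seed="largest"`), or — the unattended default — as the
largest component whose AP extent intersects a detected gap. Volume is
`count × dz·dy·dx`. Volume is monotone under mask inclusion and
invariant to AP translation. The growth rate is the least-squares slope
of volume versus time over the 90-min post-breach window, undefined
(flagged, not faked) with fewer than three frames.

## Dynamics (`acquant.dynamics`)

The chain per series: Richardson–Lucy (20 iterations) → translation
registration → maximum-intensity projection → one common 90×144 crop
centered on the brightest point of the *time-averaged* registered
projection → binarization (Otsu from frame 0). A single common crop
center is used rather than per-frame recentering: per-frame centering
would partially undo registration and break the invariance of `C_I`
under a common translation of all frames. Pair correlations are Pearson
over pixels (the phi coefficient for binary frames); frames whose
correlation is undefined (empty/full masks — segmentation failures, not
dynamics) are dropped with a logged count, and `C_I` is the arithmetic
mean of the remaining consecutive-pair correlations. An option
correlates grayscale crops for sensitivity analysis. The exact estimator
of the original ImageJ correlation plugin is not published; pixelwise
Pearson is adopted as the standard definition.

At default SNR a static series yields `C_I = 1.0 ± 0.02` (residual noise
flicker at the mask boundary), and `C_I` decreases strictly with
deformation amplitude (0 → 0.05 → 0.2 across 10 seeds).

## Morphometry (`acquant.morphometry`)

vulA-to-vulA distance is the per-timepoint AP distance between the outer
junctions (NaN gaps for missing annotations); cohort trends use the
per-timepoint median. The dorsal-lumen expansion delay
`Δt = t_expansion − t_pre_fusion` consumes manual event annotations
(fusion = reporter diffusion into neighbors; expansion = junction-ring
growth); automated event detection is out of scope. Ring scoring
thresholds the ventral-view image, assigns annulus pixels to 36 angular
bins and reports the occupied-bin fraction; classes follow configurable
cut-offs (complete ≥ 0.9, semicircle ≥ 0.5, disorganized > 0,
absent = 0) — a quantitative proxy for by-eye classes, used only in the
automated path; cohort fractions enter via annotated tables.

## Statistics (`acquant.stats`)

Two-sided tests throughout. Welch's *t* with Welch–Satterthwaite degrees
of freedom; the *F*-test doubles the smaller tail of
`F = s_x²/s_y²`; Mann–Whitney *U* uses the exact distribution when both
samples have ≤ 8 observations without ties, otherwise a normal
approximation with tie-corrected variance and a signed continuity
correction (so identical samples give p = 1 exactly). Proportion CIs use
the Wilson score interval by default (Clopper–Pearson by flag) — the
interval always contains the point estimate and narrows with n. The
induction index is the mean induced-VPC count per animal, reported to
one decimal; percentages are reported rounded to integers with raw
fractions retained. Star codes: p < 0.05 (*), < 0.01 (**), < 0.001
(***), < 0.0001 (****). No multiple-testing correction is applied (none
is used in the workflows this mirrors).

## Validation problem sizes

The test battery uses the default 24×96×160-voxel scene (≈ 370k voxels)
unless stated: volumetry recovery over 10 seeds; growth-slope recovery
over 10 seeds of 4-frame series spanning 0–90 min on a deepened
(24×128×112) grid; dynamics monotonicity over 10 seeds × 3 amplitudes of
8-frame series; breach rates over 50 intact and 40 gapped fixtures.
These sizes were chosen as the smallest at which the estimators'
asymptotic behavior is already stable.

## Known limitations

- The Gaussian-PSF forward model and its inverse share the same kernel
  family; real PSFs are asymmetric and depth-dependent, so real-data
  volumetry will carry a larger systematic shell than the synthetic
  benchmarks show.
- Threshold-at-0.05 volumetry is intrinsically biased high for objects
  thin relative to the axial PSF; the bias shrinks with deconvolution
  depth and object size but never fully vanishes.
- Breach extents are biased low by edge blur (~1.5 voxels per side).
- Registration is translation-only; rotating or flexing animals violate
  the model.
- `I_DV` is a stand-in formulation; ring classes depend on configurable
  cut-offs; both should be calibrated before use in a new cohort.
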