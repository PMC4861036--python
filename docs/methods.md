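# Methods

`petresponse` quantifies the metabolic response of metastatic lesions between
serial FDG-PET scans and evaluates how well each read-out predicts a binary
gold-standard response label.  This note documents the models, the choices
made where the published methods leave room, and what the synthetic phantoms
do and do not establish.

## Measurement model

All volumes are body-weight SUV images on axis-aligned grids
(`physical = origin + index * spacing`).  SUV = tissue concentration /
(injected activity / body mass), with 1 g of tissue taken as 1 mL; injected
activity is assumed decay-corrected to scan start, so no decay model is
carried.  NIfTI-1 (float32) is the storage dialect.

## Lesion segmentation

The contrast-oriented adaptive threshold

    T = a * mSUV70 + b * BG,      a = 0.5, b = 1.0 by default

operates inside a working cube of half-width `max_region` (25 mm) around the
seed.  `mSUV70` is the mean of working-cube voxels at or above 70% of the
local SUVmax (ties included); `BG` is the mean of a shell 10–20 mm outside
the cube, excluding voxels above `0.4 * SUVmax` (so a neighbouring lesion
cannot masquerade as background) and excluding voxels invalidated by
resampling.  The final mask is the 26-connected component above `T`
containing the seed.  The coefficients are scanner-specific in practice;
`calibrate_coefficients` grid-searches them against phantoms with known
masks, minimising mean absolute relative volume error.

Failure modes are surfaced, not patched: a threshold above every voxel
raises `EmptyMaskError` (non-measurable lesion), and a 70%-isocontour mean
below `1.25 * BG` raises `NoFocalUptakeError`.  At low contrast the threshold
exceeds weakly avid lesions — the method's known low-SNR delineation
weakness — and the pipeline then falls back to measuring residual uptake
through the baseline mask transferred onto the registered follow-up (flagged
per lesion in the output table).

## Metabolic metrics

Per lesion and time point: SUVmax; SUVpeak (hottest mean over a 1 cm³ sphere
rasterised by voxel-center inclusion, centers restricted to mask voxels and
to positions where the sphere fits inside the volume); SUVmean over the
mask; MV = voxel count × voxel volume (mL); TLG = SUVmean × MV; and SAM, the
integral of SUV over the mask dilated by 8 mm minus the shell-background
mean times the dilated volume.  SAM's dilation margin must reach the PSF
footprint to capture smeared counts; beyond that it is insensitive to the
margin (<5% over 6–12 mm at FWHM 6 mm), which is its point: TLG from a tight
mask loses the blurred-out activity, SAM does not.  Note that SUVpeak can
exceed SUVmax when the lesion is smaller than the 1 cm³ sphere (the sphere
then averages in neighbours); the familiar ordering mean ≤ peak ≤ max holds
for lesions that contain the sphere.

## Rigid registration

Follow-up scans are aligned onto the baseline with a six-parameter rigid
transform estimated by iterated block matching: the highest-contrast 5³
blocks (top 256, stride 2, above 10% of the maximal block SD) are displaced
within a ±5-voxel search window to maximise normalised cross-correlation,
with parabolic sub-voxel refinement of the correlation peak per axis; a
rigid transform is fitted to the displacement field by least trimmed squares
(three reweighting rounds, worst 20% discarded) via the Kabsch solution; the
moving volume is resampled (trilinear) and the loop repeats until the
parameter motion falls below 0.1 mm.  The similarity measure, block size and
iteration limits are this implementation's choices; the originating clinical
workflow registers the CT channel and transfers the transform, whereas
phantoms register the PET channel itself.  Voxels resampled from outside the
source domain are zeroed and flagged in a validity mask which every
downstream stage respects.

On three-lesion phantoms with default noise, known transforms up to 8 mm /
5° are recovered to ~0.1 mm / ~0.2°; uniform images raise an error (no
matchable blocks) rather than returning a guess.

## Two-frame factor analysis (SULTAN)

A registered pair is modelled per voxel as

    S(v, t) = Ib(v) Cb(t) + Ie(v) Ce(t) + e(v, t),   t = 1, 2

with the factor count fixed at the number of scans (K = 2).  The fit is a
principal component analysis followed by an oblique rotation pinning the
first factor to the constant vector Cb; the evolution factor Ce is
initialised from the second principal component and re-estimated from the
residual structure of the voxels poorly explained by Cb alone (the
"evolving" set: Cb-only residuals above 3 robust-MAD units of the
frame-difference noise).  With two frames, the residual space orthogonal to
Cb is one-dimensional, so this re-estimation resolves Ce up to sign and
scale; the sign follows the dominant evolution of the evolving set and the
scale is fixed by normalising Ce (and Cb) to unit Euclidean norm.  Ib and Ie
then solve an exact per-voxel 2×2 system, so the factor images carry
SUV-scaled units and the reconstruction is exact wherever the system is
nonsingular.

Under this normalisation the significance cut |Ie| > 1 (the default)
corresponds to a between-scan change of √2 ≈ 1.4 SUV.  The SULTAN image
keeps Ie where |Ie| exceeds the cut and zeroes it elsewhere.  Degeneracy —
no energy orthogonal to the constant factor, or fewer than two evolving
voxels — yields an all-zero Ie with a flag; frames identical up to noise
land here or produce sub-threshold speckle only.

Classification: a lesion is a responder when its summed significant Ie
content tracks a decrease ((Ce decreasing ∧ ΣIe > 0) ∨ (Ce increasing ∧
ΣIe < 0)); all-zero content is a non-responder.  Sum aggregation (rather
than majority vote) lets large coherent changes dominate speckle in
heterogeneous lesions.  A patient is a responder iff every lesion is.

## Response rules and evaluation

Percent change is `100 (m2 − m1) / m1`; a PET responder is a decrease
strictly greater than the policy threshold (a decrease exactly at the
threshold is a non-responder).  The PERCIST preset is 30% for every metric
except 45% for TLG.  Target selection keeps at most five lesions, two per
organ, hottest baseline SUVmax first.  The per-patient change follows the
hottest lesion by the metric under evaluation at each time point
independently (the lesions may differ); ranking by SUVmax instead is
available by flag.  New-lesion-equals-progression is available as an option
but off by default, matching the literal hottest-lesion computation.

ROC analysis scores each case by the decrease `−change`, sweeps candidate
cuts at midpoints of adjacent unique scores (±∞ sentinels), computes AUC by
the tie-corrected Mann–Whitney rank formulation (identical to trapezoidal
integration of the empirical curve), and picks the Youden-optimal cut
(max sens + spec − 1), ties broken toward the smaller magnitude.  Confusion
statistics report sensitivity, specificity, PPV, NPV, accuracy and J, with
undefined ratios left as None rather than zero; serialised percentages are
rounded half-up to integers, J to two decimals.  Association uses Pearson's
chi-squared on the 2×2 table with 1 df and no continuity correction (a flag
enables Yates); a zero marginal is reported as undefined.  Paired AUC
comparison uses the DeLong estimator — the comparison method of the
MedCalc-era tooling this mirrors — with "groups" formed by transitive
closure of non-significant pairs.

## Synthetic phantoms

Phantoms emulate paired whole-body scans: uniform background (default
SUV 2), spherical lesions with configurable SUV at both time points,
isotropic Gaussian PSF (default FWHM 6 mm, typical clinical PET), additive
Gaussian noise in SUV units (default σ 0.15; Poisson count statistics are
not modelled because all downstream methods operate on SUV images), and a
known rigid misalignment of the follow-up frame, rendered analytically on
the misaligned grid so no interpolation enters the ground truth.  Lesions
are rasterised by voxel-center membership; partial-volume behaviour arises
from PSF plus voxelisation.  Overlapping or boundary-clipped lesions are
rejected.  The ground-truth rule labels a lesion responder when its true
mean-SUV change is ≤ −30% (configurable); the patient label is the
conjunction.

Cohort sampling: organ labels follow the 44:43:17:10:5:4
node/bone/liver/breast/lung/peritoneum frequencies; one or two lesions per
patient (p = 0.45/0.55), radii U(8, 12) mm, baseline SUV U(5, 9); response
classes responder / minor-decline / stable / progression with default mix
0.50/0.10/0.15/0.25 and true-change bands (−72, −34), (−26, −8), (−5, 5),
(+15, +60) percent.  The (−34, −26) guard band encodes the −30% adjudication
boundary: clinical gold standards do not label hairline evolutions, and the
band centre pins the recoverable optimal threshold at ≈30%.  Misalignments
draw translations U(−4, 4) mm per axis and rotations U(−2, 2)°.  Lesion
surfaces are kept ≥30 mm apart so each working region and background shell
is free of neighbours.

What the phantoms do not emulate: anatomical texture (registration leans on
lesion edges alone, which is the harder case for block matching), count-rate
dependent noise, respiratory motion, and heterogeneous intra-lesion uptake.
Passing the recovery studies therefore shows the estimators are correct and
well-conditioned under the stated model, not that clinical performance
figures transfer.

## Study sizes and numerical choices

End-to-end studies run at desk scale: 56³ voxels at 2 mm and ~200 lesion
evolutions (129 patients), low noise (σ 0.05) for parameter recovery;
`PhantomSpec` itself defaults to 96³.  Near the −30% boundary the adaptive
segmentation biases SUVmean changes by a few percentage points (contrast-
dependent mask size), so the recovered SUVmean threshold sits at ~26%, while
SUVmax — measured at the lesion core where the PSF bias cancels between
time points — recovers ~30% closely.  This echoes the clinical observation
that volume-dependent metrics are the fragile ones.

Other numerics: FADS tolerance 1e-6, at most 20 iterations (two suffice);
degeneracy ratio 1e-3; registration convergence 0.1 mm with rotation changes
measured at a half-extent lever arm; Youden ties toward the smaller cut
magnitude; segmentation seeds are snapped to the hottest immediate
neighbour so an off-peak seed still lands in the component.  All randomness
flows from explicit seeds; equal seeds give bit-identical volumes, catalogs
and reports.

## Known limitations

* The SAM construction dilates the PET segmentation rather than enlarging a
  CT-drawn VOI (no CT channel exists here); this is a stated deviation from
  the index method.
* MV and TLG inherit the segmentation's low-contrast fragility by design;
  their poor phantom AUCs are a property of the method, not a defect of the
  implementation.
* The |Ie| > 1 cut is meaningful only under the stated factor normalisation;
  other normalisations require rescaling the threshold.
* Per-patient hottest-lesion changes ignore lesions dropped at baseline as
  non-measurable; a cohort dominated by such lesions would need the
  fallback rules reconsidered.
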