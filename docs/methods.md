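# Methods

This package implements the analysis stages of an automated PSMA PET/CT
reading pipeline that sit *downstream* of anatomical organ segmentation:
reference-organ SUV quantification, candidate lesion detection, lesion
pre-segmentation, and SUV quantification, together with the agreement
statistics used to evaluate such pipelines and a synthetic phantom generator
that supplies inputs with known ground truth. Organ masks are an input — in
practice produced by a CT segmentation model, here by the phantom — and all
masks are assumed co-registered on the PET grid.

## Reference-organ quantification

**Blood pool.** The descending thoracic aorta mask is eroded by a sphere of
physical radius (default 4 mm, anisotropy-aware) so that partial-volume and
misalignment voxels at the vessel wall are excluded. The reference is the
mean of the SUVs lying within the interquartile range of the eroded-mask
values. Percentiles use linear interpolation between order statistics and
both bounds are inclusive; this is stated explicitly because IQR conventions
differ between implementations. The abdominal aorta is not used: its
segmentation is less reliable and the manual comparator for this measurement
is a VOI in the descending thoracic aorta.

**Liver.** Breathing motion attenuates part of the liver (typically near the
dome), producing a region of artifactually low uptake that would bias a
plain mean downward. The SUVs in the eroded liver (default 8 mm erosion) are
therefore modelled as a two-component 1D Gaussian mixture, fitted by EM with
a deterministic initialization (means at the 25th/75th data percentiles,
equal weights, pooled variance; tolerance 1e-6, at most 500 iterations,
variance floor (1e-3)^2). The reference is the mean of the component with
the larger mean — the low mode is the nuisance. Two guards apply: if the
component means are closer than 0.1 SUV the fit is declared unimodal and the
overall mean is returned (flagged); if the high-mean component's weight is
below 0.2 the heavier component is used instead (flagged), so the estimator
cannot latch onto a small bright tail. Because the initialization is
percentile-based, both reference statistics are exactly scale-equivariant.

**Manual-reader emulation.** For consistency experiments the package also
provides fixed-size spherical VOI means (1 cm in the aorta, 3 cm in the
liver) whose centers are jittered around nominal positions, standing in for
a human reader placing a VOI by eye.

## Lesion detection

Candidates are searched per tissue compartment:

- **bone** — the union of the five skeletal regions (femur, pelvic region,
  lumbar vertebrae, thoracic vertebrae, thorax; a fixed vocabulary collapses
  51 individual bones onto these), searched on the raw PET;
- **lymph** — the soft-tissue body volume (largest connected component above
  0.2x the blood-pool reference) minus all labelled organs and bones,
  searched on the suppression-subtracted PET;
- **prostate** — the prostate label when present (skipped with a warning
  post-prostatectomy), also on the suppressed PET.

**Physiological-uptake suppression.** The liver, kidneys and urinary bladder
dominate soft-tissue signal. For each of these organs a template is built —
the organ mask dilated by 3 mm and blurred by a 3 mm Gaussian, mimicking
spill-out — and its amplitude is fitted to the PET by least squares within
the dilated support. The summed, nonnegative field is subtracted (clamped at
zero) before the lymph and prostate searches. The model form is the simplest
one with a testable residual contract: on phantoms the suppressed kidney
mean falls below 10% of the original, while lesions 40 mm away change by
less than 5%.

**Blob operator.** The detector is the scale-normalized negated Laplacian of
Gaussian over a list of physical blob diameters, with the Gaussian scale
matched to diameter via d = 2*sigma*sqrt(3) (the diameter at which a solid
sphere maximizes the normalized response). Derivatives are taken per axis in
physical units, so the response is anisotropy-aware and has SUV units.
Candidates are local maxima over the joint (scale, space) neighborhood
(26-connectivity in space plus adjacent scales) above a response threshold,
inside the compartment mask, sorted by descending response with index
tie-breaks — fully deterministic.

Default scales are {9, 12, 16, 20, 25} mm. Scales below roughly three voxel
spacings are excluded by construction: a sampled Gaussian-derivative kernel
needs sigma of at least ~0.85 voxels, below which the response aliases
(inflations up to ~17x were measured at sigma = 0.39 voxels); the
implementation clamps sigma with a warning if such a scale is requested.
The default response threshold (0.6 SUV) was tuned on the packaged phantom
suite: conspicuous lesions respond at 1.9–3.2 while the noise-maximum floor
stays below ~0.35.

**Filtering.** After pre-segmentation, candidates pass rules in a fixed
order — location (seed not in the bladder/kidney labels), SUVmax (at least
max(2.0, 1.5x blood pool)), SUVmean, minimum volume (0.1 mL), maximum
volume — and every rejection records the first failed rule. A fixed-SUV
threshold detector (connected components above a cut, e.g. SUV 4.3 or 3.0)
is included as the baseline the blob detector is compared against.

## Lesion pre-segmentation

From each seed an Eikonal arrival-time field is solved (SimpleITK's
first-order upwind fast-marching solver on the anisotropic grid) with speed

    F(x) = clip((SUV(x) - floor) / (SUV_seed - floor), eps, 1)^q

where floor = 0.4x blood-pool reference, q = 2 and eps = 1e-3. Uptake at or
above the seed's level travels at unit speed; background travels ~0, so
low-uptake gaps are barriers. The lesion is {arrival <= T} within 40 mm of
the seed, with T = 18: since speed never exceeds 1, arrival time is bounded
below by physical distance and T is in mm. The triplet (q, floor, T) was
chosen by a grid search on two fixed phantom scenarios — isolated 10 mm
lesions at 5:1 contrast (overlap and volume accuracy) and a 2:1-contrast
lesion adjacent to the bladder (leak resistance) — before the acceptance
tests were written; at floor = 0.5x blood pool the low-contrast scenario
sits too close to the floor and no T satisfies both contracts. A
fixed-fraction region-growing comparator (50% of seed SUV) is kept to
demonstrate the failure mode that motivates fast marching: next to a hot
structure the blurred bridge exceeds the cut and the region floods.

First-order fast marching overestimates arrival times by up to ~15% along
diagonals; in the uniform-speed limit the segment is therefore a slightly
faceted ball inscribed in the exact arrival sphere. This is documented
behavior, not corrected.

## Quantification

Per lesion: SUVmax (max in mask), SUVmean (mean in mask), uptake volume
(voxel count x voxel volume), and SUVpeak — the maximum over spheres of
1 mL (radius 6.2 mm) centered on each in-mask voxel of the mean over the
sphere-mask intersection. Restricting the sphere to the mask keeps the
ordering SUVmean <= SUVpeak <= SUVmax meaningful next to hot neighbors;
lesions smaller than 1 mL fall back to SUVpeak = SUVmean and are flagged.

## Evaluation statistics

Dice overlap 2|A∩B|/(|A|+|B|) (two empty masks defined as 1, with a
warning); greedy one-to-one lesion matching by descending detection
response, where a detection matches a truth lesion if the true center lies
in the detected mask or the detected centroid is within max(true radius,
10 mm) of it; sensitivity as percent of truth lesions matched, with a
Wilson 95% CI; Pearson correlation with a Fisher-z CI; per-method sample SD
(n-1); and ICC(2,1) — two-way random effects, absolute agreement, single
measurement — computed from the two-way ANOVA mean squares. The matching
criterion is a package definition (clinically this matching is done by a
reader in a GUI) and is configurable.

## The phantom

A trunk-scale digital phantom on a 128x128x160 grid at 3 mm isotropic
spacing: an elliptic-cylinder body, ellipsoid/cylinder/box organs (liver,
two kidneys, bladder, prostate, two lungs, thoracic and abdominal aorta,
and the five skeletal regions), each with a constant mean uptake. Default
uptakes follow the PSMA-ligand biodistribution ordering the pipeline
assumes — background 0.8, lungs 0.4, bone 1.0, prostate 1.2, blood pool
1.8, liver 6, kidneys 30, bladder 60 — values chosen as typical for this
tracer class, not fitted to any data set. Lesions are uniform spheres
placed in the bone, lymph or prostate compartment. Degradation order:
liver artifact (a superior slab covering an exact fraction of liver voxels,
default 30%, at multiplier 0.5) -> Gaussian PSF (6 mm FWHM, typical PET)
-> voxelwise Gaussian noise with sigma = 0.1*sqrt(SUV), a variance-scaling
surrogate for Poisson counting noise. Clean organ means and lesion extents
are recorded before degradation; "realized" lesion SUVmax after, since that
is what detection sees. Generation is byte-deterministic given the spec and
seed.

The suite generator draws per-patient organ uptakes (blood pool
Normal(1.8, 0.2), liver Normal(6, 1), kidneys Normal(30, 4), bladder
Normal(60, 8), truncated at small positive floors) and random lesion
counts, sizes (10–16 mm), intensities (SUV 4–9 by default) and positions
within their compartments, with mutual separation constraints.

**What the phantom does not emulate** — and hence what passing tests do not
show about clinical data: intestinal and ureteral physiological uptake (the
dominant source of clinical false positives; phantom false-positive counts
are optimistic), organ texture and anatomical variability, attenuation and
scatter artifacts, respiratory motion beyond the liver slab, and
reconstruction-correlated noise. Detection thresholds tuned here transfer
to real data only as starting points.

## Experiment suites and problem sizes

Four packaged experiments mirror the evaluation designs: `reference_sd`
(automated vs jittered-sphere manual reference across a lesion-free suite),
`detection_sensitivity` (pooled matched sensitivity and false positives per
patient against ground truth), `threshold_comparison` (blob vs fixed SUV
4.3 cut on a suite whose lesion intensities straddle the cut), and
`reproducibility` (ICC(2,1) of SUVmax/SUVpeak/SUVmean across two identical
runs on one fixed 7-lesion phantom). Default suite sizes (20 patients for
detection experiments, 50 for reference consistency) keep a full run at
desk scale while leaving the binomial CIs informative.

## Known limitations

- Detection and fast-marching parameters are tuned on the phantom suite;
  the upstream clinical system's actual operating points are unpublished,
  so defaults are package choices, clearly configurable.
- The bone-label vocabulary is a faithful regrouping of the five standard
  skeletal regions, not a reproduction of any proprietary id scheme.
- Resampling CT-space masks onto the PET grid is the caller's concern;
  phantom outputs are pre-aligned.
- Sub-voxel lesion boundaries are rasterized at voxel-center resolution, so
  volume errors of a few voxels are intrinsic at 3 mm spacing.
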