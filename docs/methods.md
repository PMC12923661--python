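# Methods

`tractshift` implements a paired pre- vs intraoperative diffusion-MRI
tractometry analysis — deterministic FACT tracking, ROI-gated tract
segmentation, macro- and microstructural tract metrics, and a paired/grouped
statistical battery — together with a synthetic phantom cohort generator
that makes every stage testable end to end with known ground truth. This
note documents the models, the conventions, the tunable parameters, and the
choices made where the design was genuinely open.

## Coordinate and sampling conventions

Voxel indices are 0-based with axis order (x, y, z); z is the feet-head
axis. World coordinates are mm with the voxel-center convention
`world = (index + 0.5) * voxel_size`; all grids are isotropic. A vertex
"visits" the voxel that contains it (`floor(world / voxel_size)`); scalar
maps are sampled nearest-voxel, consistent with FACT's voxel-constant
philosophy. NIfTI affines written by the package encode exactly this
mapping.

## Acquisition model and phantom signal

The default scheme mirrors a 9-minute intraoperative two-shell protocol:
six b=0 volumes, 20 directions at b=1000 s/mm² and 32 at b=2000 s/mm², on
2.55-mm isotropic voxels. Gradient directions are a deterministic
generalized spiral on the sphere.

The signal model is single-tensor mono-exponential, `S = S0 exp(-b gᵀDg)`
with S0 = 100, chosen over multi-compartment models because every
downstream quantity (FA, MD, SNR, tracking substrate) is exercised by it
and it admits closed-form oracles. Noise is Rician: the magnitude of
`(S + N(0,σ), N(0,σ))` with `σ = S0/SNR`. Bundle voxels carry an axially
symmetric tensor with λ∥ = 1.7e-3 and λ⊥ = 0.3e-3 mm²/s (FA ≈ 0.72, MD ≈
0.767e-3 — typical coherent white matter); background white matter is
isotropic at MD 0.7e-3, gray matter 0.9e-3, CSF 3.0e-3, tumor 1.2e-3.

Fiber orientation is represented as a discrete per-voxel peak field (up to
3 peaks with amplitudes), not spherical-harmonic FODs: the tracker needs
only a direction and an amplitude for its 0.01 floor. Phantom bundle peaks
carry amplitude 0.5 and background 0, so the floor separates them by a wide
margin; the absolute amplitude scale is a convention of this package, not a
quantity with external meaning.

## Phantom geometry

A synthetic patient is a small "head" on a 24×24×32 grid (≈61×61×82 mm;
deliberately smaller than a real head so that replicated end-to-end runs
stay desk-scale). Six tube bundles follow cubic splines through fractional
control points mapped into the grid interior (6-mm margin): the decussating
dentato-rubro-thalamic tract (d-DRTT) runs from a cerebellar dentate region
across the midline through the contralateral thalamus to the contralateral
motor region; the non-decussating nd-DRTT stays ipsilateral; the arcuate
fasciculus (AF) arcs between temporal (Wernicke) and frontal (Broca)
regions. Left-sided bundles run in a y-lane at 0.44 of the grid depth and
right-sided ones, mirrored in x, at 0.56 — this keeps the two decussating
tracts from colliding at the midline. Tube radius defaults to 3.5 mm with
±10% between-subject variation, and control points receive 1.2-mm Gaussian
jitter per subject (clipped to the interior).

Each tube carries a one-voxel *orientation halo*: a partial-volume rim
(width `min(voxel, 0.7·radius)`) whose voxels hold the tube's tangent
direction at full amplitude, while the bundle mask and tensors stay
confined to the tube. Without the halo, voxel-quantized FACT propagation
drifts off a 2.55-mm rasterized tube and a substantial fraction of
in-bundle seeds dies mid-bundle; with it, ≥90% of in-bundle seeds traverse
an isolated bundle end to end. The rim width scales with the radius so that
an injected radius compression scales the *tracked* caliber by the same
factor. White matter is the tube union dilated twice (so it encloses the
halo), gray matter is a one-voxel shell around it, and tissue classes are
made disjoint by priority WM > GM > CSF > tumor. ROIs (dentate, thalamus,
motor cortex, Wernicke, Broca; corpus callosum and tumor as exclusion
masks) are spheres/boxes positioned so each endpoint ROI intersects its
bundle's terminal 10% of arc length.

## Injected surgical effects and study conditions

The intraoperative dataset of a pair regenerates the preoperative geometry
with: bundle radius scaled by `volume_scale` (default 0.7 on the d-DRTT,
0.95 on the AF, 1.0 on the nd-DRTT — compression strongest near the
resection site, mild on the distant control, absent on the stable tract);
an additive MD elevation `md_delta` (default 0.4e-3 mm²/s, scaled by a
per-subject severity factor uniform on [0.25, 1.75]) confined to the
arc-length window [0, 0.2] at the dentate end of the left d-DRTT; a global
SNR factor 0.906 (a ≈9.4% drop); and an emptied tumor mask. Preoperative
SNR is drawn from N(24.36, 4.6²) truncated at 10. The binary
speech-disturbance label is true when the applied left-sided `md_delta`
exceeds 0.3e-3 mm²/s, or with probability 0.05 at random; the rule and
every applied effect are recorded verbatim in the pair's truth record.
Ages are uniform on 1.75–17 years, sex is balanced. An optional
`ventricle_coupling` parameter links larger ventricles to stronger
compression, for exercising the change-vs-ventricle correlation analysis.

## Tensor fit, FA/MD, and SNR

The tensor is fit by ordinary (unweighted) least squares on the log-signal
using both shells — the reproducible baseline when the estimator is
otherwise unspecified; a mask restricts the fit, and voxels containing any
non-positive signal are marked invalid rather than imputed. Negative
eigenvalues are clamped to zero before FA/MD and the clamp count recorded.
MD is trace/3; FA is `sqrt(3/2)·‖λ − MD‖/‖λ‖` with FA of the all-zero
tensor defined as 0.

White-matter SNR is the per-voxel temporal mean of the b0 series divided by
its temporal standard deviation (sample SD, n−1), averaged over the WM
mask; zero-SD voxels are excluded and counted. With only six b0 volumes
this estimator is biased high by a factor E[s/σ]⁻¹ ≈ 1.19 (the 1/s moment
of the chi distribution at n = 6), so its absolute value overstates the
true SNR; the *relative* pre-to-intra change is unaffected, which is why
the phantom's 0.906 noise factor is recovered as a ≈9.4% drop. No bias
correction is applied — the statistic is reported as defined.

## Tracking

FACT propagation: from every seed, take the seed voxel's largest-amplitude
peak and propagate in both signs with fixed 1-mm steps, at each step using
the current voxel's peak best aligned with the incoming direction
(sign-resolved into the incoming hemisphere, no interpolation). Termination:
entering a voxel whose best amplitude is below 0.01 (that vertex is not
kept), a turn angle above 60° between successive steps, leaving the
white-matter mask (the exiting vertex *is* kept — the gray-white interface
rule), or 1000 steps. Seeds lie on a 1-mm lattice anchored at the
white-matter bounding-box corner; seeds outside the mask are skipped and
counted. Tracks shorter than two steps are dropped. Output order is
deterministic (lexicographic seed order), and mirroring the peak field
mirrors the streamlines exactly.

## Gating and tract segmentation

A streamline passes a gate when some vertex's voxel lies in every inclusion
mask and none in any exclusion mask — a vertex test, adequate at 1-mm steps
on 2.55-mm voxels. Kept streamlines are oriented so index 0 is nearest the
first endpoint ROI (dentate, or Wernicke). DRTT streamlines gated by
dentate + thalamus + motor cortex (callosum and tumor excluded) are split
by their motor-end vertex: contralateral motor cortex → d-DRTT, ipsilateral
→ nd-DRTT, neither → unclassified; side labels follow the dentate
hemisphere. Streamlines that cross between overlapping bundles (the d/nd
pair shares the dentate origin) are precisely what this classification
resolves.

The AF length filter is cohort-level: each subject's median AF streamline
length, normalized by brain height (feet-head extent of the brain mask), is
pooled across subjects and timepoints; the threshold is the first
percentile (linear interpolation between order statistics) of that
distribution, and every streamline whose own normalized length falls below
it is removed. The filter works because tracked tract lengths pile up at
the full bundle length with only a short-fragment tail; it is monotone in
the percentile.

## Tractometry

Tract volume is the count of voxels visited by at least one vertex times
the voxel volume, reported raw and as a percentage of supratentorial WM
volume (WM above a fixed tentorium plane at 22% of grid height). Diameter
treats the tract as a cylinder, `2·sqrt(volume/(π·length))`, with length
the mean streamline length. Whole-tract FA/MD are two-stage means —
per-streamline vertex means, then an unweighted mean across streamlines, so
every streamline counts equally. The along-tract profile resamples each
streamline to n+1 equal-arc-length points, averages them pointwise into a
centerline, assigns every vertex to the nearest segment midpoint (ties to
the lower index), and averages the map per segment; empty segments are
flagged NaN, never zero-filled. n = 55 for all tracts (the ceiling of the
cohort-typical 138-mm tract length over the 2.55-mm voxel — the helper
exposes the rule), with segment 1 at the dentate (or Wernicke) end.

## Statistics

Paired contrasts: Wilcoxon signed-rank (exact conditional distribution for
≤25 non-zero differences, ties included; normal approximation with
corrections above), and a linear mixed model with subject random intercept
and fixed timepoint (+ optionally SNR or age; both adjustments are computed
side by side since which covariate enters which model is an analysis
choice). With no covariate and balanced pairs the timepoint estimate equals
the mean paired difference. Paired Cohen's d is mean(Δ)/SD(Δ) (sample SD)
with bands negligible/small/moderate/large at 0.2/0.5/0.8, boundaries
left-closed (|d| = 0.5 is "moderate"). Group contrasts by speech label use
the Wilcoxon rank-sum test; logistic regression of the label on age and sex
flags complete separation instead of reporting runaway coefficients.
Correlations default to Pearson (Spearman available).

Along-tract testing: per segment, the statistic is z = mean(Δ)/SE across
subjects; the p-value references Student-t with n−1 df rather than the
normal — with ~30 subjects and 55 segments per family, the normal reference
roughly doubles the panel-level false-positive rate (measured 0.100 vs
0.050 over 120 null panels), and the package prioritizes calibration.
Segments observed in fewer than 3 subjects or missing in more than half are
excluded. Benjamini-Hochberg FDR is applied within one family = one metric
× one tract × one side (the 55 segments of one panel); the whole-tract
Wilcoxon battery is likewise BH-adjusted across its family.

## Validation experiments and problem sizes

`tractshift.experiments` hosts the replicated studies, run on a scaled-down
configuration chosen once: an 18×18×24 grid, d-DRTT + AF only, left
hemisphere (the analyzed panels), voxel-spaced (2.55-mm) seed lattice.
Cohort size stays at 30 paired subjects.

* **Compression power**: 100 replicate cohorts with the default injected
  effects; detection = mixed-model timepoint p < 0.05 with a negative
  volume estimate. Power is ≈1.0 at `volume_scale` 0.7 (the induced
  normalized-volume drop is ≈40–45%).
* **MD-window recovery**: one cohort; the across-subject variance of the
  per-segment ΔMD inside the injected window ±1 segment vs outside exceeds
  2 on the left d-DRTT (typically 6–9) and stays below 2 on the AF control.
* **Null calibration**: 200 effect-free replicate cohorts; the fraction of
  panels with any BH-significant segment stays within 2 Monte-Carlo SE of
  0.05.
* **Geometry**: the diameter formula recovers 2r on an analytically
  voxelized cylinder (axis through a voxel center; a corner-aligned axis is
  a degenerate rasterization) within 15%, and FACT traverses a
  40-mm-radius quarter-circle bundle (1.5-mm voxels, end caps trimmed to
  the exact angular quarter) within 5% of π·r/2.

## What the phantom does and does not show

Passing these tests demonstrates that the pipeline's operations are
individually correct against independent oracles and that, chained end to
end, they recover injected effects of realistic magnitude at realistic
noise with calibrated false-positive control. The phantom does not emulate
real anatomy (crossing-fiber FODs, partial-volume tissue mixtures,
susceptibility or motion artifacts, registration error between timepoints,
atlas-based ROI placement), so these results do not certify performance on
clinical data — they certify the analysis machinery.

## Known limitations

* Single-tensor signal: no multi-compartment or kurtosis behaviour; the
  two-shell scheme is reproduced for realism but carries no extra model
  information (a single-shell fit switch is provided).
* Overlapping bundles resolve tensor conflicts by last-writer-wins in the
  few shared voxels.
* The b0-series SNR statistic is biased high at 6 volumes (see above).
* The phantom's white matter is derived from the bundles themselves, so
  injected compression also shrinks the supratentorial WM normalizer and
  weakly couples the normalized volumes of untouched tracts (visible as
  small nd-DRTT "changes" in demo runs); in a real study WM volume comes
  from anatomical segmentation and is stable.
* The mixed model fits each metric separately; no multivariate or
  longitudinal (>2 timepoint) modelling.
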