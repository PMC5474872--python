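# Methods

`wmlquant` implements a desk-scale analogue of a semi-automated
white-matter-lesion (WML) quantification study: paired T1W/FLAIR brain
volumes are segmented into grey matter (GM), white matter (WM),
cerebrospinal fluid (CSF) and WML classes with a prior-weighted Gaussian
mixture; lesions drive a tissue-repair step; morphometry, volumetrics
and a permutation-based statistics layer complete the workflow.  Because
no imaging data ship with the package, a synthetic-cohort generator with
exact ground truth is a first-class component: every claim the test
suite makes is a property checked against that ground truth or against
an independent oracle.

## The phantom and cohort generator

A phantom head is a set of nested ellipsoids on a regular grid (default
48³ voxels at 2 mm isotropic, i.e. a 96 mm head — a deliberately
scaled-down geometry): an outer CSF shell, a cortical GM shell, a WM
core, and two lateral-ventricle cavities (CSF) inside the WM.  The
parenchyma radius is derived from a target CSF fraction f, so the
tissue volume ratio TVR = (GM+WM)/TIV equals 1 − f by construction and
atrophy can be planted exactly as a CSF-fraction shift.  A lobe atlas
(frontal, temporal, parietal, occipital, plus a single central deep-GM
label standing in for the thalamus/caudate/putamen/pallidum composite)
partitions the brain mask by position with deep-GM precedence.

Lesions are spheres planted in WM.  Default placement is
periventricular-weighted — sampling probability decays exponentially
(8 mm scale) with distance from the ventricle surface — mirroring the
periventricular "caps" and "bands" that dominate real WML spatial
distributions; a uniform-in-WM mode exists for unbiased tests.  Centres
are kept at least r₁ + r₂ + 4 mm apart so the planted count is
unambiguous under any standard connectivity; when a heavily lesioned
subject exhausts the admissible WM (possible at this scale), placement
stops with a warning and the ground truth records what was actually
planted.

Channel intensities are arbitrary units drawn as class mean + Gaussian
noise (default SD 5 on class separations of roughly 20–50), with the
defining contrast contract: lesions are hypo-intense relative to WM on
T1W (68 vs 90) and hyper-intense relative to everything on FLAIR (95 vs
WM 45), while CSF is FLAIR-suppressed (12).  An optional partial-volume
blur (off by default) smooths class boundaries.  There is no bias
field, motion or any other MRI-physics artefact — so passing tests
demonstrate correctness of the estimators under the stated noise model,
not robustness to scanner artefacts.  No quantitative intensity
distributions were available to calibrate against, so the intensity
model is free configuration with the above defaults.

Cohorts are two groups (control/patient) with age (means 65.9/67.6,
SDs 7.4/8.4 years), gender, pack-years and a cognitive-score covariate.
Per-subject lesion burden is Poisson in count (base rate 6, at least 1)
and log-normal in radius (median 3 mm, log-SD 0.3, clipped to
2–5.5 mm), with a mild age effect (+2 %/year on the log rate).  Planted
patient effects are multiplicative on expected total lesion volume
(via the rate) and on mean lesion size (via the radius distribution,
rate-compensated), plus the additive TVR shift above.  All randomness
derives from one seed; subject *i* uses the stream seeded
`(rng_seed, i)`, so cohorts are bit-reproducible and individual
subjects can be regenerated in isolation.

## Segmentation model

Each class k is a mixture of J_k Gaussians over the channel
intensities (defaults: GM 2, WM 2, CSF 2, WML 1, background 3).  The
voxel model is

    p(y_v) = Σ_k π_k(v)^α · τ_k · Σ_j w_kj N(y_v; μ_kj, Σ_kj)

where π_k(v) is a voxel-wise spatial prior (flat, or a population
tissue probability map), α ∈ [0,1] a prior-strength exponent
(default 1), and τ_k a learned global tissue proportion.  Learning τ_k
matters: without it every class is implicitly forced toward 1/K of the
image, which destroys rare classes such as WML (≈0.1 % of voxels).
EM runs to a relative log-likelihood change below 1e-6 or 200
iterations; because priors are fixed during the fit this is standard
EM, so the recorded log-likelihood trace is monotone non-decreasing (a
tested invariant, with 1e-9 relative slack for the small covariance
ridge added each M-step).  Singular covariances are ridge-regularised
(1e-6 × mean channel variance) with a warning; non-convergence returns
a flagged result rather than an error.

Initialisation is data-driven in all cases: k-means (20 000-voxel
subsample, fixed seed) seeds the normal-tissue classes, which are
mapped to class identities by the canonical contrast rules (background
darkest overall; CSF FLAIR-darkest; WM T1W-brightest; GM the
remainder).  The WML class is seeded from voxels whose FLAIR intensity
clearly exceeds the brightest normal-tissue cluster — a fixed
high quantile fails when lesions occupy less than that quantile's
tail, so the threshold is relative (halfway between the brightest
cluster centre and the robust FLAIR maximum).  Spatial priors
deliberately do **not** seed intensities: population lesion priors
average lesion and normal tissue at any one subject's non-lesion
locations, and seeding from that blend collapses the lesion class.
Channels are canonicalised to sorted name order internally, making
channel-relabelling invariance exact.

Population priors are the voxel-wise mean of subject TPMs, Gaussian
smoothed (default FWHM 4 mm in the pipeline stage) and renormalised by
the smoothed all-ones field so they still sum to one.  Because phantoms
share one grid, the "common space" is the grid itself; no registration
is performed anywhere in the package.  Skull stripping thresholds the
combined non-background probability at 0.1.

## Lesion quantification and volumetrics

Lesion probability maps are binarised at a threshold; the default is
Otsu's method over the map (a deterministic, reproducible stand-in for
a per-subject human rater), with a fixed manual override available.
Repair sets, inside the lesion mask, WM := 1 and every other class
(including WML) := 0, leaving other voxels untouched — idempotent and
sum-to-one preserving.  A lesion is a connected component under
26-connectivity by default (6/18 configurable; the choice is recorded
in the inventory because it changes counts for touching components).
Average lesion size is reported as total volume / count (the mean; the
choice is recorded in the summary metadata).  Lobe assignment takes the
maximally overlapping atlas label; exact ties break deterministically
by the fixed order frontal < temporal < parietal < occipital < deep-GM
and are flagged.

Volumes are partial-volume-aware probability sums: each class's
probability summed over supratentorial voxels where it exceeds 0.2,
times the voxel volume, in ml (a `count_mode` flag sums voxel counts
instead).  TIV = GM + WM + CSF; normalised volumes are % TIV; the
tissue volume ratio (GM+WM)/TIV is the atrophy index.  Per-lobe volumes
restrict the same computation to each atlas label, so they sum exactly
to whole-brain values over the partition.  For voxel-wise analysis,
binary lesion maps are downsampled ×2 in the axial plane by block
maximum (presence, not average — the point of downsampling is to
increase between-subject overlap) and a 6 mm FWHM Gaussian smoothing
utility is provided (zero-padded borders; σ = FWHM/2√(2 ln 2) per axis
in mm).

## Statistics layer

Tabulated measures route through a Gaussianity gate: Shapiro–Wilk
(α = 0.05) on the OLS residuals of the response against the covariates;
pass → ANCOVA; else, if strictly positive, the same check on log10 of
the response → ANCOVA on log10 data; else a permutation GLM.  Fewer
than 8 observations force the permutation route.  The group ANCOVA
statistic is the partial F (1 numerator df; for a binary group this is
the squared coefficient t, which the tests exploit as an oracle).

The permutation GLM uses the Freedman–Lane scheme: residuals of the
covariates-only model are permuted, added back to the reduced fit, and
the full model is refit; the two-sided p is (1 + #{|t*| ≥ |t|})/(1 + B).
When n! ≤ 50 000 the scheme switches to exhaustive enumeration of all
residual orderings and the p becomes the exact proportion (identity
included).  Default B is 10 000.  The repeated-measures design (two
within-levels, e.g. hemispheres) is decomposed exactly: the group
effect is the ANCOVA on subject sums; the hemisphere main effect and
hemisphere×group interaction are the intercept and group terms of the
difference-score model with effect-coded group and centred covariates —
verified against an independent mixed-ANOVA implementation.  Partial
Spearman correlations rank-transform both variables, residualise on the
covariates and use the t approximation with df = n − #covariates − 2.
Bonferroni correction (min(1, m·p)) handles the lobe families.  Missing
data are dropped listwise per model with a warning.

The voxel-wise lesion comparison uses the Liebermeister quasi-exact
2×2 test: with independent uniform-prior Beta posteriors for the two
group lesion probabilities, the one-sided p is Pr(π₁ ≤ π₂), computed in
closed form as the one-sided hypergeometric tail of the table with the
concordant diagonal incremented — verified to 1e-8 against numerical
Beta integration over all tables with margins ≤ 12.  Analysis is
restricted to voxels lesioned in at least ⌈0.10·N⌉ subjects (the
ceiling reading of "at least 10 % of subjects" is recorded in the mask
metadata).  Family-wise error is controlled by max-statistic
permutation: group labels are permuted, each permutation's smallest
voxel p recorded, and observed voxel p-values ranked against that null.
Random-field-theory FWE is a poor match for binary lesion data, which
is why the distribution-free max-statistic substitute is used and
labelled as such in outputs.  On binary data the procedure is mildly
conservative (discreteness of the statistic); calibration tests bound
the familywise error within the binomial 99 % band of 5 %.

## Pipeline and reproducibility

`run_pipeline` executes simulate (or ingest) → flat-prior segmentation
→ population priors → re-segmentation → binarise + repair →
volumetrics + morphometry → density map + voxel-wise test → group
statistics, writing NIfTI-1 volumes, TSV tables and a JSON manifest
with SHA-256 hashes of every output.  Population priors are built from
the cohort under analysis — faithful to the semi-automated protocol
this mirrors, and a known circularity for inference that is documented
rather than removed.  Every stochastic stage seeds from the single run
seed, and a rerun with the same config is bit-identical (a tested
property).  The report presents each measure as mean (SD) when the
gate chose ANCOVA on raw data and as median (IQR) otherwise.

## Problem sizes and limitations

Tests and the acceptance script run on 48³ (2 mm) and 32³ (3 mm)
phantoms, cohorts of 4–40 subjects, 200–1000 permutations and
100–2000 simulation replicates — sizes chosen so the whole suite runs
on a single CPU in minutes while leaving the Monte-Carlo bands tight
enough to be meaningful.  Known limitations: no registration (the
common space is the simulation grid), no bias-field or artefact
robustness, a single-sphere lesion shape model, the deep-GM label is a
geometric stand-in rather than an anatomical composite, and the power
analysis for the planted 2× lesion-volume effect uses the generator's
exact per-subject burdens with the pipeline's statistical stage — the
imaging measurement error (verified separately to be a few percent
relative) is not re-simulated inside that loop.
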