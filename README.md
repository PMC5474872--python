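# wmlquant

Quantification of white-matter lesions (WMLs) from paired T1W/FLAIR
brain MRI, packaged as a tested, reusable pipeline with synthetic
ground truth.  WMLs — FLAIR-hyperintense, T1W-hypointense focal
white-matter damage common in ageing and vascular disease — corrupt
ordinary T1-only tissue segmentation (lesions leak into the grey-matter
class) and thereby bias every downstream volumetric and morphometric
measure.  `wmlquant` implements the semi-automated workflow that fixes
this, for researchers who want lesion-aware brain volumetrics and
group statistics without a scanner-specific toolchain:

1. **Synthetic cohorts** (`wmlquant.phantom`) — parametric brain
   phantoms (nested ellipsoids, ventricles, lobe atlas) with spherical
   lesions planted periventricularly, two-group covariate structure and
   exact ground truth for every downstream quantity.
2. **Mixture segmentation** (`wmlquant.segment`) — one- and two-channel
   Gaussian-mixture EM over tissue classes k with voxel-wise spatial
   priors: p(y_v) = Σ_k π_k(v)^α τ_k Σ_j w_kj N(y_v; μ_kj, Σ_kj);
   population tissue probability maps; re-segmentation; skull stripping
   at combined tissue probability 0.1.
3. **Lesion quantification** (`wmlquant.lesions`) — Otsu or manual
   binarisation, tissue repair (lesion voxels: WM := 1, GM = CSF := 0),
   26-connected component morphometry, lobe assignment by maximal
   overlap, density maps, axial ×2 downsampling, 6 mm FWHM smoothing.
4. **Volumetrics** (`wmlquant.volumes`) — thresholded (>0.2)
   probability-sum volumes in ml, TIV = GM+WM+CSF, tissue volume ratio
   (GM+WM)/TIV, %TIV normalisation, per-lobe decomposition.
5. **Statistics** (`wmlquant.stats`) — Gaussianity-gated ANCOVA /
   log10-ANCOVA / Freedman–Lane permutation GLM, Bonferroni, partial
   Spearman correlations, two-way repeated-measures ANCOVA, and the
   voxel-wise Liebermeister test (presence mask ≥ 10 % of subjects)
   with max-statistic permutation family-wise error control.
6. **Pipeline** (`wmlquant.pipeline`) — the whole workflow from one
   YAML config, with seeded determinism and a SHA-256 output manifest.

See `docs/methods.md` for the model details and design rationale.

## Worked example (CLI)

```sh
wmlquant simulate --out sim --seed 3 --n-per-group 2
wmlquant segment --t1w sim/sub000_t1w.nii.gz --flair sim/sub000_flair.nii.gz \
                 --out segout --max-iter 60
wmlquant lesions --tpm segout/sub000_prob_wml.nii.gz \
                 --atlas sim/lobe_atlas.nii.gz \
                 --atlas-labels sim/lobe_labels.json --out lesout
wmlquant volumes --tpm-dir segout --stem sub000 --out vols.tsv
```

which prints

```
wrote 4 subjects to sim
segmented sub000: converged=True
9 lesions, total 728 mm^3 (threshold 0.350)
TIV 358.4 ml, tissue volume ratio 0.648
```

This subject was generated with 7 lesions totalling 712 mm³, a true TIV
of 360.8 ml and a true tissue volume ratio of 0.646: the single-subject
flat-prior fit recovers the lesion volume within ~2 % and TIV within
~0.7 %, at the cost of two spurious one-voxel components (the
population-prior re-segmentation inside `wmlquant run` removes these).
`lesout/lesions.tsv` lists each component with voxel count, volume and
assigned lobe; `vols.tsv` holds the volumetric row (GM/WM/CSF/WML in
ml and %TIV).

The full study pipeline — simulate, segment with flat priors, build
population priors, re-segment, binarise + repair, morphometry,
volumetrics, density map, voxel-wise test, group statistics — runs as

```sh
wmlquant run --out study --seed 7
```

and writes `volumes.tsv`, `lesions.tsv`, `lobe_summaries.tsv`,
`group_stats.tsv` (descriptives as mean (SD) or median (IQR) per the
Gaussianity gate, plus the test statistic, df, p and adjustment per
measure), NIfTI probability/density/p maps, and `manifest.json` with
hashes of every output.

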