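"""End-to-end study workflow with config, provenance and reporting.

Stage order follows the segmentation protocol the package implements:

1. simulate (or ingest) the cohort in a common space
2. first-pass segmentation of every subject with flat priors
3. population tissue probability maps from the first-pass TPMs
4. re-segmentation of every subject with the population priors
5. lesion-map binarisation and tissue repair
6. volumetrics (whole-brain and per-lobe) and lesion morphometry
7. lesion density map, axial downsampling, voxel-wise group test
8. group statistics on the tabulated measures, with reporting

Population priors are deliberately built from the cohort under analysis
(the protocol's own choice); the resulting circularity for inference is
documented rather than removed.  Every stochastic stage derives its seed
from the single run seed; the manifest records parameters and SHA-256
hashes of all outputs so a re-run can be checked for bit-identity.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from wmlquant import lesions as les
from wmlquant import phantom as ph
from wmlquant import segment as seg
from wmlquant import stats as st
from wmlquant import volumes as vol
from wmlquant.image import load_subject, load_volume, save_volume

#: whole-brain measures analysed by the stats stage
DEFAULT_MEASURES = ("gm_pct_tiv", "wm_pct_tiv", "tiv_ml", "tissue_volume_ratio",
                    "wml_number", "wml_pct_tiv", "wml_avg_size_mm3")
DEFAULT_COVARIATES = ("age", "gender")


@dataclass
class RunConfig:
    out_dir: str = "wmlquant_run"
    seed: int = 0
    # simulate stage (set simulate=False and input_dir to ingest real data)
    simulate: bool = True
    input_dir: str | None = None
    n_per_group: int = 3
    grid_shape: tuple = (48, 48, 48)
    voxel_size: tuple = (2.0, 2.0, 2.0)
    noise_sd: float = 5.0
    volume_effect: float = 1.0
    size_effect: float = 1.0
    atrophy_effect: float = 0.0
    # segmentation
    max_iter: int = 100
    alpha: float = 1.0
    prior_smoothing_fwhm_mm: float = 4.0
    # lesions
    lesion_threshold: float | str = "auto"
    connectivity: int = 26
    # volumetrics
    skull_threshold: float = 0.1
    volume_threshold: float = 0.2
    # statistics
    covariates: tuple = DEFAULT_COVARIATES
    n_permutations: int = 1000
    voxelwise: bool = True
    downsample_factor: int = 2
    presence_min: float = 0.10

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        for name in ("grid_shape", "voxel_size", "covariates"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


@dataclass
class RunManifest:
    config: dict
    stages: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def record(self, stage: str, params: dict, outputs: dict) -> None:
        self.stages[stage] = {"params": params, "outputs": outputs}

    def warn(self, stage: str, message: str) -> None:
        self.warnings.append({"stage": stage, "message": message})

    def output_hashes(self) -> dict:
        out = {}
        for stage in self.stages.values():
            out.update(stage["outputs"])
        return out

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"config": self.config, "stages": self.stages,
                       "warnings": self.warnings}, fh, indent=1, sort_keys=True)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _hash_outputs(paths, root) -> dict:
    return {str(Path(p).relative_to(root)): _sha256(p) for p in paths}


def group_test(table: pd.DataFrame, response: str, group: str = "group",
               covariates=DEFAULT_COVARIATES, n_permutations: int = 10_000,
               seed: int = 0):
    """The pipeline's group comparison for one tabulated measure.

    Routes through the Gaussianity gate: plain ANCOVA for Gaussian
    residuals, ANCOVA on log10-transformed data when that restores
    Gaussianity, otherwise a Freedman-Lane permutation GLM.  Returns
    ``(TestResult, gate_decision)``.
    """
    sub = table[[response, group, *covariates]].dropna()
    cov_mat = np.column_stack([st._as_numeric(sub[c]) for c in covariates]) \
        if covariates else None
    gate = st.gaussianity_gate(sub[response].to_numpy(float), cov_mat)
    if gate in ("none", "log10"):
        res = st.ancova(sub, response, group, covariates, transform=gate)
    else:
        res = st.permutation_glm(sub, response, group, covariates,
                                 n_permutations=n_permutations, seed=seed)
    return res, gate


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the full workflow; returns the provenance manifest."""
    root = Path(config.out_dir)
    root.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=dataclasses.asdict(config))
    config.to_yaml(root / "config.yaml")

    # -- stage 1: simulate or ingest -------------------------------------
    if config.simulate:
        spec = ph.PhantomSpec(grid_shape=tuple(config.grid_shape),
                              voxel_size=tuple(config.voxel_size),
                              noise_sd=config.noise_sd)
        cohort = ph.CohortSpec(n_per_group=config.n_per_group,
                               volume_effect=config.volume_effect,
                               size_effect=config.size_effect,
                               atrophy_effect=config.atrophy_effect,
                               rng_seed=config.seed)
        subjects, table, gts = ph.generate_cohort(cohort, spec)
        sim_dir = ph.save_cohort(subjects, table, gts, root / "cohort", spec)
        atlas_arr, lobe_names = spec.lobe_atlas()
        atlas = les.LobeAtlas(labels=atlas_arr, label_names=lobe_names,
                              voxel_size=tuple(spec.voxel_size))
        manifest.record("simulate",
                        {"n_per_group": config.n_per_group, "seed": config.seed},
                        _hash_outputs(sorted(sim_dir.glob("*")), root))
    else:
        if not config.input_dir:
            raise ValueError("input_dir required when simulate is disabled")
        in_dir = Path(config.input_dir)
        table = pd.read_csv(in_dir / "cohort.tsv", sep="\t")
        subjects = [load_subject(in_dir / f"{sid}_t1w.nii.gz",
                                 in_dir / f"{sid}_flair.nii.gz", subject_id=sid)
                    for sid in table["subject_id"]]
        atlas_arr, _ = load_volume(in_dir / "lobe_atlas.nii.gz")
        with open(in_dir / "lobe_labels.json") as fh:
            lobe_names = json.load(fh)
        atlas = les.LobeAtlas(labels=np.asarray(atlas_arr),
                              label_names=lobe_names,
                              voxel_size=subjects[0].voxel_size)
        manifest.record("ingest", {"input_dir": str(in_dir)}, {})

    channels = tuple(subjects[0].channels)
    classes = ("gm", "wm", "csf", "wml", "background") if "flair" in channels \
        else ("gm", "wm", "csf", "background")
    fit_cfg = seg.FitConfig(alpha=config.alpha, max_iter=config.max_iter,
                            seed=config.seed)

    # -- stage 2: first-pass segmentation (flat priors) -------------------
    first_pass = []
    for img in subjects:
        _, tpms = seg.fit_mixture(img, priors=None, channels=channels,
                                  classes=classes, config=fit_cfg)
        first_pass.append(tpms)
    manifest.record("first_pass_segmentation",
                    {"classes": list(classes), "alpha": config.alpha}, {})

    # -- stage 3: population priors ---------------------------------------
    priors = seg.build_population_tpm(first_pass,
                                      smoothing_fwhm_mm=config.prior_smoothing_fwhm_mm)
    prior_dir = root / "priors"
    prior_paths = priors.save(prior_dir, stem="population")
    manifest.record("population_priors",
                    {"smoothing_fwhm_mm": config.prior_smoothing_fwhm_mm,
                     "n_subjects": len(first_pass)},
                    _hash_outputs(prior_paths, root))

    # -- stages 4-6: per-subject re-segmentation, lesions, volumetrics ----
    seg_dir = root / "segmentation"
    vol_rows, lesion_tables, lobe_tables, binary_maps = [], [], [], []
    out_paths = []
    for img, sid in zip(subjects, table["subject_id"]):
        tpms = seg.resegment_with_priors(img, priors, config=fit_cfg,
                                         channels=channels)
        if "wml" in tpms.probs:
            lesion_tpm = tpms.probs["wml"]
            if config.lesion_threshold == "auto":
                try:
                    thr = les.auto_threshold(lesion_tpm)
                except ValueError:
                    thr = 0.5
                    manifest.warn("binarise", f"{sid}: constant lesion map, fell back to 0.5")
            else:
                thr = float(config.lesion_threshold)
            bmap = les.binarise_lesion_tpm(lesion_tpm, thr, tpms.voxel_size,
                                           tpms.affine)
            repaired = les.repair_tissues(tpms, bmap)
        else:
            bmap = les.BinaryLesionMap(np.zeros(tpms.shape, np.uint8),
                                       tpms.voxel_size, tpms.affine, None)
            repaired = tpms
        binary_maps.append(bmap)
        out_paths += repaired.save(seg_dir, stem=sid)
        p = seg_dir / f"{sid}_lesion_mask.nii.gz"
        save_volume(bmap.data, tpms.affine, p)
        out_paths.append(p)

        mask = seg.skull_strip(repaired, threshold=config.skull_threshold)
        row = vol.volume_report(repaired, mask, threshold=config.volume_threshold,
                                subject_id=sid)
        inv = les.label_lesions(bmap, connectivity=config.connectivity)
        summary = les.lesion_summary(inv, row["tiv_ml"])
        row["wml_number"] = summary["number"]
        row["wml_volume_pct_tiv"] = summary["volume_pct_tiv"]
        row["wml_avg_size_mm3"] = summary["average_size_mm3"]
        row["lesion_threshold"] = bmap.threshold
        vol_rows.append(row)

        inv_annot, per_lobe = les.assign_lobes(inv, atlas)
        t = inv_annot.table.copy()
        t.insert(0, "subject_id", sid)
        lesion_tables.append(t)
        pl = per_lobe.copy()
        pl.insert(0, "subject_id", sid)
        lobe_tables.append(pl)
        reg = vol.regional_volumes(repaired, atlas, threshold=config.volume_threshold,
                                   subject_id=sid)
        lobe_tables[-1] = pl.merge(reg, on=["subject_id", "lobe"], how="left")

    volumes_df = pd.DataFrame(vol_rows)
    # the tabulated wml %TIV is the lesion-mask-based burden
    volumes_df["wml_pct_tiv"] = volumes_df["wml_volume_pct_tiv"]
    measures_df = table.merge(volumes_df, on="subject_id")
    vol_path = root / "volumes.tsv"
    measures_df.to_csv(vol_path, sep="\t", index=False)
    lesion_path = root / "lesions.tsv"
    pd.concat(lesion_tables, ignore_index=True).to_csv(lesion_path, sep="\t", index=False)
    lobe_path = root / "lobe_summaries.tsv"
    pd.concat(lobe_tables, ignore_index=True).to_csv(lobe_path, sep="\t", index=False)
    out_paths += [vol_path, lesion_path, lobe_path]
    manifest.record("resegment_lesions_volumes",
                    {"lesion_threshold": str(config.lesion_threshold),
                     "connectivity": config.connectivity,
                     "volume_threshold": config.volume_threshold},
                    _hash_outputs(out_paths, root))

    # -- stage 7: density map and voxel-wise analysis ---------------------
    vox_paths = []
    density = les.density_map(binary_maps)
    density_ds = les.downsample_axial(density, config.downsample_factor, binary=False)
    p = root / "lesion_density.nii.gz"
    save_volume(density.astype(np.float32), subjects[0].affine, p)
    vox_paths.append(p)
    if config.voxelwise and table["group"].nunique() == 2:
        ds_maps = [les.downsample_axial(b.data, config.downsample_factor, binary=True)
                   for b in binary_maps]
        vres = st.voxelwise_lesion_test(ds_maps, table["group"].to_numpy(),
                                        presence_min=config.presence_min,
                                        n_permutations=config.n_permutations,
                                        seed=config.seed)
        if vres.n_in_mask == 0:
            manifest.warn("voxelwise", "empty analysis mask; no voxel-wise test run")
        for name, arr in (("voxelwise_p", vres.p_map), ("voxelwise_p_fwe", vres.p_fwe_map)):
            p = root / f"{name}.nii.gz"
            save_volume(arr.astype(np.float32), subjects[0].affine, p)
            vox_paths.append(p)
    manifest.record("voxelwise",
                    {"downsample_factor": config.downsample_factor,
                     "presence_min": config.presence_min,
                     "n_permutations": config.n_permutations},
                    _hash_outputs(vox_paths, root))

    # -- stage 8: group statistics and report -----------------------------
    results = {}
    if table["group"].nunique() == 2:
        for m in DEFAULT_MEASURES:
            if m not in measures_df:
                continue
            try:
                res, gate = group_test(measures_df, m,
                                       covariates=config.covariates,
                                       n_permutations=config.n_permutations,
                                       seed=config.seed)
            except ValueError as exc:
                manifest.warn("stats", f"{m}: {exc}")
                continue
            results[m] = (res, gate)

        # per-lobe lesion burden, Bonferroni-corrected across regions
        lobes_df = pd.concat(lobe_tables, ignore_index=True)
        lobe_results = []
        for lobe in atlas.label_names:
            sub = lobes_df[lobes_df["lobe"] == lobe][["subject_id",
                                                      "total_volume_mm3"]]
            merged = measures_df.merge(sub, on="subject_id")
            col = f"wml_volume_pct_tiv_{lobe}"
            merged[col] = 100 * merged["total_volume_mm3"] / (merged["tiv_ml"] * 1000)
            try:
                res, gate = group_test(merged, col, covariates=config.covariates,
                                       n_permutations=config.n_permutations,
                                       seed=config.seed)
            except ValueError as exc:
                manifest.warn("stats", f"{col}: {exc}")
                continue
            measures_df = measures_df.merge(merged[["subject_id", col]],
                                            on="subject_id")
            lobe_results.append((col, res, gate))
        if lobe_results:
            adj = st.bonferroni([r.p for _, r, _ in lobe_results],
                                m=len(atlas.label_names))
            for (col, res, gate), pa in zip(lobe_results, adj):
                res.p_adjusted = float(pa)
                res.adjustment = f"bonferroni_x{len(atlas.label_names)}"
                results[col] = (res, gate)
    report = make_report(measures_df, results, group="group")
    stats_path = root / "group_stats.tsv"
    report.to_csv(stats_path, sep="\t", index=False)
    manifest.record("group_stats",
                    {"covariates": list(config.covariates),
                     "n_permutations": config.n_permutations},
                    _hash_outputs([stats_path], root))

    manifest.save(root / "manifest.json")
    return manifest


def make_report(measures_df: pd.DataFrame, results: dict, group: str = "group") -> pd.DataFrame:
    """Per-measure descriptives plus test columns.

    Gaussian-gated measures are summarised as group mean (SD); measures
    that needed a transform or the permutation route as median (IQR) —
    the same rule used for presentation in two-group volumetric studies.
    Empty ``results`` yields an empty report.
    """
    rows = []
    if not results:
        return pd.DataFrame(columns=["measure", "gate", "method", "statistic",
                                     "df", "p", "p_adjusted", "adjustment"])
    levels = sorted(measures_df[group].dropna().unique()) if group in measures_df else []
    for measure, (res, gate) in results.items():
        row = {"measure": measure, "gate": gate}
        for lev in levels:
            vals = measures_df.loc[measures_df[group] == lev, measure].dropna() \
                if measure in measures_df else pd.Series(dtype=float)
            if gate == "none":
                row[f"{lev}_centre"] = vals.mean()
                row[f"{lev}_spread"] = vals.std()
                row[f"{lev}_summary"] = "mean (SD)"
            else:
                row[f"{lev}_centre"] = vals.median()
                row[f"{lev}_spread"] = (vals.quantile(0.75) - vals.quantile(0.25)
                                        if len(vals) else float("nan"))
                row[f"{lev}_summary"] = "median (IQR)"
        row.update(res.as_row())
        rows.append(row)
    return pd.DataFrame(rows)
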