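"""Synthetic brain phantoms and cohorts with exact ground truth.

The phantom is a parametric head: nested ellipsoidal compartments (outer
CSF shell, cortical GM shell, WM core) with two lateral-ventricle
cavities carved out of the WM, all on a regular grid that serves as the
cohort's common space.  White-matter lesions are planted as spheres that
are hypo-intense on the T1W channel and hyper-intense on the FLAIR
channel relative to normal WM — the contrast that makes them separable
by a two-channel mixture model.  Placement is periventricular-weighted
by default (probability decays with distance from the ventricle
surface), mirroring the "caps" and "bands" seen around the anterior and
posterior horns in vivo; a uniform-in-WM mode is kept for unbiased
tests.

Every quantity the downstream pipeline estimates (tissue volumes, lesion
count/volume/size, lobe membership, class intensity parameters) is
recorded exactly in :class:`GroundTruth` before noise is added.

Intensities are arbitrary units; there is no MRI physics simulation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from wmlquant.image import SubjectImage, affine_from_voxel_size, save_volume

# integer codes of the generative label field
LABEL_CODES = {"background": 0, "csf": 1, "gm": 2, "wm": 3, "wml": 4}
LOBE_LABELS = {"frontal": 1, "temporal": 2, "parietal": 3, "occipital": 4,
               "deep_gm": 5}

# default class intensity means (arbitrary units) per channel; WML is darker
# than WM on T1W and brighter than every other class on FLAIR
DEFAULT_MEANS = {
    "t1w": {"background": 5.0, "csf": 25.0, "gm": 60.0, "wm": 90.0, "wml": 68.0},
    "flair": {"background": 5.0, "csf": 12.0, "gm": 62.0, "wm": 45.0, "wml": 95.0},
}


class PlacementError(ValueError):
    """A planted lesion does not fit inside the WM compartment."""


class SpecError(ValueError):
    """Invalid phantom or cohort specification."""


@dataclass
class PhantomSpec:
    """Parametric description of one phantom head.

    Fractions are expressed in normalised grid coordinates (half-extent of
    the grid = 1).  ``csf_fraction`` is the target CSF share of the
    intracranial volume (outer shell plus ventricles); the parenchyma
    radius is derived from it, so atrophy can be dialled in directly as a
    CSF-fraction shift (tissue volume ratio = 1 - CSF fraction).
    """

    grid_shape: tuple[int, int, int] = (48, 48, 48)
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
    brain_radius_frac: float = 0.92
    csf_fraction: float = 0.35
    gm_fraction_of_parenchyma: float = 0.55
    ventricle_offset_frac: float = 0.18
    ventricle_semiaxes_frac: tuple[float, float, float] = (0.10, 0.28, 0.10)
    deep_gm_radius_frac: float = 0.32
    class_means: dict = field(default_factory=lambda: {c: dict(m) for c, m in DEFAULT_MEANS.items()})
    class_sds: dict = field(default_factory=dict)   # per channel per class, default 0
    noise_sd: float = 5.0
    smoothing_fwhm_mm: float = 0.0

    def __post_init__(self):
        if any(v <= 0 for v in self.voxel_size):
            raise SpecError(f"voxel size must be positive, got {self.voxel_size}")
        if any(n < 8 for n in self.grid_shape):
            raise SpecError("grid too small for a phantom head")
        if not (0 < self.csf_fraction < 1):
            raise SpecError("csf_fraction must be in (0,1)")
        if "flair" in self.class_means:
            if not self.class_means["flair"]["wml"] > self.class_means["flair"]["wm"]:
                raise SpecError("lesion FLAIR mean must exceed WM FLAIR mean")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size))

    # -- geometry ---------------------------------------------------------
    def _unit_coords(self):
        axes = [
            (np.arange(n) + 0.5 - n / 2) / (n / 2) for n in self.grid_shape
        ]
        return np.meshgrid(*axes, indexing="ij")

    def tissue_labels(self) -> np.ndarray:
        """Noiseless generative label field (no lesions)."""
        ux, uy, uz = self._unit_coords()
        r2 = ux ** 2 + uy ** 2 + uz ** 2
        rb = self.brain_radius_frac
        # ventricle share of the intracranial sphere (analytic, for radius calc)
        va, vb, vc = self.ventricle_semiaxes_frac
        vent_frac = 2.0 * va * vb * vc / rb ** 3
        shell_frac = np.clip(self.csf_fraction - vent_frac, 0.01, 0.95)
        r_par = rb * (1.0 - shell_frac) ** (1.0 / 3.0)
        r_wm = r_par * (1.0 - self.gm_fraction_of_parenchyma) ** (1.0 / 3.0)

        labels = np.zeros(self.grid_shape, dtype=np.int16)
        labels[r2 <= rb ** 2] = LABEL_CODES["csf"]
        labels[r2 <= r_par ** 2] = LABEL_CODES["gm"]
        labels[r2 <= r_wm ** 2] = LABEL_CODES["wm"]
        labels[self.ventricle_mask()] = LABEL_CODES["csf"]
        return labels

    def ventricle_mask(self) -> np.ndarray:
        ux, uy, uz = self._unit_coords()
        va, vb, vc = self.ventricle_semiaxes_frac
        off = self.ventricle_offset_frac
        left = ((ux - off) / va) ** 2 + (uy / vb) ** 2 + (uz / vc) ** 2 <= 1.0
        right = ((ux + off) / va) ** 2 + (uy / vb) ** 2 + (uz / vc) ** 2 <= 1.0
        return left | right

    def brain_mask(self) -> np.ndarray:
        return self.tissue_labels() > 0

    def lobe_atlas(self):
        """Lobe label field partitioning the supratentorial (= brain) mask.

        Precedence: deep_gm (central ellipsoid around the ventricles), then
        frontal (anterior), occipital (posterior), temporal (inferior band),
        parietal (remainder).  Returns the label volume and the label map.
        """
        ux, uy, uz = self._unit_coords()
        brain = self.brain_mask()
        atlas = np.zeros(self.grid_shape, dtype=np.int16)
        deep = (ux ** 2 + uy ** 2 + uz ** 2) <= self.deep_gm_radius_frac ** 2
        atlas[brain & deep] = LOBE_LABELS["deep_gm"]
        rest = brain & (atlas == 0)
        atlas[rest & (uy > 0.15)] = LOBE_LABELS["frontal"]
        rest = brain & (atlas == 0)
        atlas[rest & (uy < -0.55)] = LOBE_LABELS["occipital"]
        rest = brain & (atlas == 0)
        atlas[rest & (uz < -0.30)] = LOBE_LABELS["temporal"]
        atlas[brain & (atlas == 0)] = LOBE_LABELS["parietal"]
        return atlas, dict(LOBE_LABELS)


@dataclass
class LesionPlan:
    """Planted lesion geometry: per-lesion centre (voxel coords), radius
    in mm and intended lobe, plus the placement mode that produced it."""

    centres: list  # (i, j, k) integer voxel coords
    radii_mm: list
    lobes: list = None
    placement_mode: str = "periventricular"

    def __post_init__(self):
        if len(self.centres) != len(self.radii_mm):
            raise SpecError("centres and radii length mismatch")
        if self.lobes is None:
            self.lobes = [None] * len(self.centres)

    def __len__(self):
        return len(self.centres)


@dataclass
class GroundTruth:
    """Exact generative truth for one phantom subject."""

    label_volume: np.ndarray
    lesions: list                    # dicts: id, centre, radius_mm, n_voxels, volume_mm3, lobe
    volumes_ml: dict                 # gm, wm, csf, wml in ml (label counts x voxel volume)
    tiv_ml: float
    tissue_volume_ratio: float
    class_means: dict
    voxel_size: tuple

    @property
    def lesion_count(self):
        return len(self.lesions)

    @property
    def lesion_total_mm3(self):
        return float(sum(l["volume_mm3"] for l in self.lesions))

    @property
    def lesion_mean_size_mm3(self):
        if not self.lesions:
            return float("nan")
        return self.lesion_total_mm3 / len(self.lesions)

    def manifest(self) -> dict:
        return {
            "lesions": [
                {k: (list(v) if isinstance(v, tuple) else v) for k, v in l.items()}
                for l in self.lesions
            ],
            "volumes_ml": self.volumes_ml,
            "tiv_ml": self.tiv_ml,
            "tissue_volume_ratio": self.tissue_volume_ratio,
        }


def _sphere_mask(shape, centre, radius_mm, voxel_size):
    """Boolean mask of voxels whose centre lies within radius of the
    lesion centre (physical mm distance); evaluated only on a local box."""
    vs = np.asarray(voxel_size, float)
    half = np.ceil(radius_mm / vs).astype(int)
    lo = np.maximum(np.asarray(centre) - half, 0)
    hi = np.minimum(np.asarray(centre) + half + 1, shape)
    grids = np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)], indexing="ij")
    d2 = sum(((g - c) * s) ** 2 for g, c, s in zip(grids, centre, vs))
    box = d2 <= radius_mm ** 2
    mask = np.zeros(shape, dtype=bool)
    mask[tuple(slice(l, h) for l, h in zip(lo, hi))] = box
    return mask


def plan_lesions(spec: PhantomSpec, n_lesions: int, radii_mm, seed=0,
                 mode: str = "periventricular", min_separation_mm: float = 4.0,
                 decay_mm: float = 8.0, strict: bool = True) -> LesionPlan:
    """Sample lesion centres inside the WM compartment.

    ``min_separation_mm`` is the margin required *beyond touching*: two
    lesions of radii r1, r2 are kept at least r1 + r2 + margin apart, so
    planted components are unambiguous under any standard connectivity.
    With ``strict=False`` placement stops (with a warning) once the WM
    compartment cannot admit another lesion, instead of raising —
    the returned plan then simply holds fewer lesions and ground truth
    stays exact for what was actually planted.
    """
    rng = np.random.default_rng(seed)
    radii_mm = list(np.broadcast_to(np.asarray(radii_mm, float), (n_lesions,)))
    labels = spec.tissue_labels()
    wm = labels == LABEL_CODES["wm"]
    vs = np.asarray(spec.voxel_size, float)
    inside_dist = ndimage.distance_transform_edt(wm, sampling=vs)
    if mode == "periventricular":
        vent_dist = ndimage.distance_transform_edt(~spec.ventricle_mask(), sampling=vs)
        base_w = np.exp(-vent_dist / decay_mm)
    elif mode == "uniform":
        base_w = np.ones(spec.grid_shape)
    else:
        raise SpecError(f"unknown placement mode {mode!r}")

    atlas, lobe_labels = spec.lobe_atlas()
    inv_lobes = {v: k for k, v in lobe_labels.items()}
    coords_mm = None
    centres, lobes = [], []
    for i, r in enumerate(radii_mm):
        ok = inside_dist > (r + float(vs.max()))
        w = np.where(ok, base_w, 0.0)
        idx = np.flatnonzero(w)
        if idx.size == 0:
            if not strict:
                warnings.warn(f"phantom WM full after {len(centres)} lesions",
                              UserWarning)
                break
            raise PlacementError(
                f"no admissible centre for lesion {i} of radius {r} mm")
        if coords_mm is None:
            coords_mm = np.stack(np.meshgrid(*[np.arange(n) for n in spec.grid_shape],
                                             indexing="ij"), axis=-1) * vs
        flat_coords = coords_mm.reshape(-1, 3)
        # enforce separation from already-chosen centres
        keep = np.ones(idx.size, dtype=bool)
        for c_prev, r_prev in zip(centres, radii_mm[: len(centres)]):
            d = np.linalg.norm(flat_coords[idx] - np.asarray(c_prev) * vs, axis=1)
            keep &= d > (r + r_prev + min_separation_mm)
        idx = idx[keep]
        if idx.size == 0:
            if not strict:
                warnings.warn(f"phantom WM full after {len(centres)} lesions",
                              UserWarning)
                break
            raise PlacementError(
                f"no admissible centre for lesion {i} given separation constraint")
        p = w.reshape(-1)[idx]
        choice = rng.choice(idx, p=p / p.sum())
        centre = tuple(int(c) for c in np.unravel_index(choice, spec.grid_shape))
        centres.append(centre)
        lobes.append(inv_lobes.get(int(atlas[centre]), "unlabelled"))
    return LesionPlan(centres=centres, radii_mm=radii_mm[: len(centres)],
                      lobes=lobes, placement_mode=mode)


def generate_phantom(spec: PhantomSpec, plan: LesionPlan | None = None,
                     seed: int = 0) -> tuple[SubjectImage, GroundTruth]:
    """Render one phantom subject and its exact ground truth.

    The label field is built first (lesion spheres carved into WM), the
    ground truth recorded from it, and only then are channel intensities
    drawn — so the truth is exact by construction.
    """
    plan = plan if plan is not None else LesionPlan(centres=[], radii_mm=[])
    labels, gt = _generate_labels_only(spec, plan)

    rng = np.random.default_rng(seed)
    channels = {}
    for chan in sorted(spec.class_means):  # fixed order for determinism
        means = spec.class_means[chan]
        lut = np.zeros(max(LABEL_CODES.values()) + 1)
        for name, code in LABEL_CODES.items():
            lut[code] = means[name]
        vol = lut[labels]
        if spec.smoothing_fwhm_mm > 0:
            sigma_vox = (spec.smoothing_fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
                         / np.asarray(spec.voxel_size))
            vol = ndimage.gaussian_filter(vol, sigma=sigma_vox, mode="nearest")
        sds = spec.class_sds.get(chan, {})
        if sds:
            sd_lut = np.zeros(max(LABEL_CODES.values()) + 1)
            for name, code in LABEL_CODES.items():
                sd_lut[code] = sds.get(name, 0.0)
            vol = vol + rng.standard_normal(vol.shape) * sd_lut[labels]
        if spec.noise_sd > 0:
            vol = vol + rng.standard_normal(vol.shape) * spec.noise_sd
        channels[chan] = vol

    img = SubjectImage(channels=channels, voxel_size=tuple(spec.voxel_size))
    return img, gt


# --------------------------------------------------------------------------
# cohorts


@dataclass
class CohortSpec:
    """Two-group study design with covariate structure and planted effects.

    Effects are patient-vs-control multipliers: ``volume_effect`` scales the
    expected total lesion volume (via the lesion rate), ``size_effect``
    scales the mean lesion size (via the radius distribution; the rate is
    compensated so total volume tracks ``volume_effect`` alone).
    ``atrophy_effect`` is an additive shift of the patient tissue volume
    ratio, implemented exactly as the opposite shift of the CSF fraction.
    """

    n_per_group: int = 20
    groups: tuple[str, str] = ("control", "patient")
    age_mean: tuple[float, float] = (65.9, 67.6)
    age_sd: tuple[float, float] = (7.4, 8.4)
    male_prop: tuple[float, float] = (0.5, 0.6)
    lesion_rate: float = 6.0
    lesion_radius_mm: float = 3.0
    lesion_radius_sigma: float = 0.30
    lesion_radius_clip: tuple[float, float] = (2.0, 5.5)
    age_lesion_slope: float = 0.02          # per year, on log lesion rate
    volume_effect: float = 1.0
    size_effect: float = 1.0
    atrophy_effect: float = 0.0
    csf_fraction_sd: float = 0.015
    placement_mode: str = "periventricular"
    min_separation_mm: float = 4.0
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_per_group < 2:
            raise SpecError("n_per_group must be at least 2")
        for eff in (self.volume_effect, self.size_effect, self.atrophy_effect):
            if not np.isfinite(eff):
                raise SpecError("effect sizes must be finite")


def generate_cohort(cohort: CohortSpec, spec: PhantomSpec, render: bool = True):
    """Generate a two-group phantom cohort.

    Returns ``(subjects, table, ground_truths)``; ``subjects`` holds
    :class:`SubjectImage` objects (or ``None`` when ``render=False``, which
    still produces exact ground truth for design studies at much lower
    cost).  Identical spec + seed reproduce the cohort bit-for-bit;
    per-subject streams are derived from ``(rng_seed, subject_index)``.
    """
    rows, subjects, gts = [], [], []
    mean_age = float(np.mean(cohort.age_mean))
    idx = 0
    for g, gname in enumerate(cohort.groups):
        is_patient = g == 1
        for _ in range(cohort.n_per_group):
            rng = np.random.default_rng([cohort.rng_seed, idx])
            age = rng.normal(cohort.age_mean[g], cohort.age_sd[g])
            gender = "male" if rng.random() < cohort.male_prop[g] else "female"
            if is_patient:
                pack_years = max(0.0, rng.normal(54.0, 25.0))
            else:
                pack_years = 0.0 if rng.random() < 0.6 else rng.uniform(1.0, 30.0)
            cog = rng.normal(103.0 if is_patient else 110.0, 15.0)

            rate = cohort.lesion_rate * np.exp(cohort.age_lesion_slope * (age - mean_age))
            if is_patient:
                rate *= cohort.volume_effect / cohort.size_effect
            n_lesions = max(1, int(rng.poisson(rate)))
            mu = np.log(cohort.lesion_radius_mm)
            if is_patient:
                mu += np.log(cohort.size_effect) / 3.0
            radii = np.clip(rng.lognormal(mu, cohort.lesion_radius_sigma, n_lesions),
                            *cohort.lesion_radius_clip)

            csf_frac = rng.normal(spec.csf_fraction, cohort.csf_fraction_sd)
            if is_patient:
                # TVR = 1 - CSF fraction, so a TVR shift of atrophy_effect
                # is exactly the opposite CSF-fraction shift
                csf_frac -= cohort.atrophy_effect
            csf_frac = float(np.clip(csf_frac, 0.05, 0.9))
            sub_spec = replace(spec, csf_fraction=csf_frac)

            plan = plan_lesions(sub_spec, n_lesions, radii,
                                seed=rng.integers(2 ** 31),
                                mode=cohort.placement_mode,
                                min_separation_mm=cohort.min_separation_mm,
                                strict=False)
            render_seed = int(rng.integers(2 ** 31))
            if render:
                img, gt = generate_phantom(sub_spec, plan, seed=render_seed)
                img.subject_id = f"sub{idx:03d}"
            else:
                img, gt = None, _ground_truth_only(sub_spec, plan)
            subjects.append(img)
            gts.append(gt)
            rows.append({
                "subject_id": f"sub{idx:03d}",
                "group": gname,
                "age": round(float(age), 2),
                "gender": gender,
                "pack_years": round(float(pack_years), 1),
                "cog_score": round(float(cog), 1),
            })
            idx += 1
    table = pd.DataFrame(rows)
    return subjects, table, gts


def _ground_truth_only(spec: PhantomSpec, plan: LesionPlan) -> GroundTruth:
    """Ground truth without rendering intensity channels (cheap path)."""
    img, gt = _generate_labels_only(spec, plan)
    return gt


def _generate_labels_only(spec, plan):
    # reuse generate_phantom's label construction by rendering with no noise
    # on a single cheap channel is wasteful; build labels directly instead
    labels = spec.tissue_labels()
    wm_code, wml_code = LABEL_CODES["wm"], LABEL_CODES["wml"]
    atlas, lobe_labels = spec.lobe_atlas()
    inv_lobes = {v: k for k, v in lobe_labels.items()}
    lesion_rows = []
    for i, (centre, r) in enumerate(zip(plan.centres, plan.radii_mm)):
        sph = _sphere_mask(spec.grid_shape, centre, r, spec.voxel_size)
        if (sph & ~np.isin(labels, (wm_code, wml_code))).any():
            raise PlacementError(
                f"lesion {i} at {centre} (r={r} mm) extends outside the WM compartment")
        labels[sph] = wml_code
        n_vox = int(sph.sum())
        lesion_rows.append({
            "id": i + 1, "centre": tuple(centre), "radius_mm": float(r),
            "n_voxels": n_vox, "volume_mm3": n_vox * spec.voxel_volume_mm3,
            "lobe": inv_lobes.get(int(atlas[tuple(centre)]), "unlabelled"),
        })
    voxvol = spec.voxel_volume_mm3
    counts = {name: int((labels == code).sum()) for name, code in LABEL_CODES.items()}
    volumes_ml = {name: counts[name] * voxvol / 1000.0
                  for name in ("gm", "wm", "csf", "wml")}
    tiv_ml = sum(volumes_ml.values())
    tvr = (volumes_ml["gm"] + volumes_ml["wm"] + volumes_ml["wml"]) / tiv_ml
    gt = GroundTruth(label_volume=labels, lesions=lesion_rows,
                     volumes_ml=volumes_ml, tiv_ml=tiv_ml,
                     tissue_volume_ratio=tvr,
                     class_means={c: dict(m) for c, m in spec.class_means.items()},
                     voxel_size=tuple(spec.voxel_size))
    return labels, gt


def save_cohort(subjects, table, gts, out_dir, spec: PhantomSpec):
    """Write a cohort to disk: per-subject NIfTI channels + label volume +
    JSON lesion manifest, and the covariate table as TSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    affine = affine_from_voxel_size(spec.voxel_size)
    for img, gt, sid in zip(subjects, gts, table["subject_id"]):
        if img is not None:
            img.save(out_dir, stem=sid)
        save_volume(gt.label_volume.astype(np.int16), affine,
                    out_dir / f"{sid}_labels.nii.gz")
        with open(out_dir / f"{sid}_lesions.json", "w") as fh:
            json.dump(gt.manifest(), fh, indent=1)
    table.to_csv(out_dir / "cohort.tsv", sep="\t", index=False)
    atlas, labels = spec.lobe_atlas()
    save_volume(atlas.astype(np.int16), affine, out_dir / "lobe_atlas.nii.gz")
    with open(out_dir / "lobe_labels.json", "w") as fh:
        json.dump(labels, fh, indent=1)
    return out_dir
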