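"""In-memory containers for multi-channel volumes and tissue probability maps.

Geometry is carried explicitly (voxel size in mm and a 4x4 voxel-to-world
affine) so that volumes read from or written to NIfTI-1 round-trip without
loss.  All probability maps live on the same grid as their source image;
there is no resampling in this package — the phantom grid is the common
space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

#: canonical tissue class order used throughout
TISSUE_CLASSES = ("gm", "wm", "csf", "wml", "background")

SUM_TOL = 1e-6


def affine_from_voxel_size(voxel_size) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size
    return aff


def _check_geometry(shape, voxel_size):
    if len(shape) != 3:
        raise ValueError(f"expected a 3D volume, got shape {shape}")
    vs = np.asarray(voxel_size, dtype=float)
    if vs.shape != (3,) or np.any(vs <= 0):
        raise ValueError(f"voxel size must be three positive mm values, got {voxel_size}")
    return tuple(vs)


@dataclass
class SubjectImage:
    """One subject's co-registered channel volumes (t1w, flair, ...)."""

    channels: dict[str, np.ndarray]
    voxel_size: tuple[float, float, float]
    affine: np.ndarray = None
    subject_id: str = "subject"

    def __post_init__(self):
        if not self.channels:
            raise ValueError("SubjectImage needs at least one channel")
        shapes = {c: v.shape for c, v in self.channels.items()}
        if len(set(shapes.values())) != 1:
            raise ValueError(f"channels disagree on shape: {shapes}")
        self.voxel_size = _check_geometry(self.shape, self.voxel_size)
        if self.affine is None:
            self.affine = affine_from_voxel_size(self.voxel_size)
        for name, vol in self.channels.items():
            if not np.all(np.isfinite(vol)):
                raise ValueError(f"channel {name!r} contains non-finite intensities")

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size))

    def stacked(self, channel_names=None) -> np.ndarray:
        """Voxels x channels data matrix (flattened, C order)."""
        names = list(channel_names or self.channels)
        missing = [n for n in names if n not in self.channels]
        if missing:
            raise KeyError(f"channels not present: {missing}")
        return np.stack([self.channels[n].reshape(-1) for n in names], axis=1)

    def save(self, out_dir, stem=None) -> list[Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        stem = stem or self.subject_id
        paths = []
        for name, vol in self.channels.items():
            p = out_dir / f"{stem}_{name}.nii.gz"
            save_volume(vol.astype(np.float32), self.affine, p)
            paths.append(p)
        return paths


@dataclass
class TPMSet:
    """Per-voxel tissue probability maps on the source image grid.

    Probabilities are in [0, 1] and sum to one over classes at every voxel
    (within ``SUM_TOL``).  The class set always includes ``background``;
    ``wml`` is present only for two-channel (T1W+FLAIR) segmentations.
    """

    probs: dict[str, np.ndarray]
    voxel_size: tuple[float, float, float]
    affine: np.ndarray = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.probs:
            raise ValueError("TPMSet needs at least one class")
        shapes = {c: v.shape for c, v in self.probs.items()}
        if len(set(shapes.values())) != 1:
            raise ValueError(f"classes disagree on shape: {shapes}")
        self.voxel_size = _check_geometry(self.shape, self.voxel_size)
        if self.affine is None:
            self.affine = affine_from_voxel_size(self.voxel_size)

    @property
    def shape(self):
        return next(iter(self.probs.values())).shape

    @property
    def classes(self) -> tuple[str, ...]:
        return tuple(self.probs)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size))

    def validate(self, tol: float = SUM_TOL) -> None:
        total = np.zeros(self.shape)
        for name, vol in self.probs.items():
            if np.any(vol < -tol) or np.any(vol > 1 + tol):
                raise ValueError(f"class {name!r} has probabilities outside [0,1]")
            total += vol
        if np.max(np.abs(total - 1.0)) > tol:
            raise ValueError("per-voxel class probabilities do not sum to one")

    def copy(self) -> "TPMSet":
        return TPMSet(
            probs={c: v.copy() for c, v in self.probs.items()},
            voxel_size=self.voxel_size,
            affine=self.affine.copy(),
            meta=dict(self.meta),
        )

    def same_geometry(self, other) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.voxel_size, other.voxel_size)
            and np.allclose(self.affine, other.affine)
        )

    def save(self, out_dir, stem="subject") -> list[Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = []
        for name, vol in self.probs.items():
            p = out_dir / f"{stem}_prob_{name}.nii.gz"
            save_volume(vol.astype(np.float32), self.affine, p)
            paths.append(p)
        return paths


def save_volume(data: np.ndarray, affine: np.ndarray, path) -> Path:
    """Write a volume as NIfTI-1 (deterministic bytes for identical input)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(data), affine)
    img.to_filename(str(path))
    return path


def load_volume(path):
    img = nib.load(str(path))
    return np.asarray(img.dataobj), img.affine


def load_subject(t1w_path, flair_path=None, subject_id="subject") -> SubjectImage:
    t1w, affine = load_volume(t1w_path)
    channels = {"t1w": np.asarray(t1w, dtype=float)}
    if flair_path is not None:
        flair, aff2 = load_volume(flair_path)
        if not np.allclose(affine, aff2):
            raise ValueError("t1w and flair affines differ; co-registration required")
        channels["flair"] = np.asarray(flair, dtype=float)
    voxel_size = tuple(np.sqrt((affine[:3, :3] ** 2).sum(axis=0)))
    return SubjectImage(channels=channels, voxel_size=voxel_size, affine=affine,
                        subject_id=subject_id)
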