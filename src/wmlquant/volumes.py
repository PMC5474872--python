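"""Brain volumetrics: tissue volumes, TIV, tissue volume ratio, %TIV.

Volumes are probability sums (partial-volume aware): each class's
probability is summed over supratentorial voxels where it exceeds the
threshold (default 0.2), multiplied by the voxel volume and reported in
ml (cm^3).  A ``count_mode`` flag sums voxel counts instead.  TIV is the
sum of the GM, WM and CSF volumes; the tissue volume ratio
(GM + WM) / TIV is a global atrophy index — lower means more atrophy.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from wmlquant.image import TPMSet
from wmlquant.lesions import LobeAtlas


def _class_volume_ml(prob, mask, threshold, voxel_volume_mm3, count_mode):
    sel = mask & (prob > threshold)
    quantity = sel.sum() if count_mode else prob[sel].sum()
    return float(quantity) * voxel_volume_mm3 / 1000.0


def tissue_volumes(tpms: TPMSet, mask: np.ndarray, threshold: float = 0.2,
                   count_mode: bool = False) -> dict:
    """GM/WM/CSF (and WML, when present) volumes in ml over the mask."""
    if mask.shape != tpms.shape:
        raise ValueError("mask geometry does not match the TPMs")
    if not mask.any():
        raise ValueError("supratentorial mask is empty")
    voxvol = tpms.voxel_volume_mm3
    out = {}
    for cls in ("gm", "wm", "csf", "wml"):
        if cls in tpms.probs:
            out[f"{cls}_ml"] = _class_volume_ml(tpms.probs[cls], mask, threshold,
                                                voxvol, count_mode)
    return out


def tiv(gm_ml: float, wm_ml: float, csf_ml: float) -> float:
    """Total intracranial volume: the sum of GM, WM and CSF volumes."""
    vols = (gm_ml, wm_ml, csf_ml)
    if any(v < 0 for v in vols):
        raise ValueError("tissue volumes must be non-negative")
    total = float(sum(vols))
    if total == 0:
        raise ValueError("all tissue volumes are zero; TIV undefined")
    return total


def tissue_volume_ratio(gm_ml: float, wm_ml: float, tiv_ml: float) -> float:
    """(GM + WM) / TIV, in (0, 1] — equal to 1 only when CSF volume is 0."""
    if tiv_ml <= 0:
        raise ValueError("TIV must be positive")
    return (gm_ml + wm_ml) / tiv_ml


def normalise_pct_tiv(volume_ml: float, tiv_ml: float) -> float:
    """Volume as a percentage of total intracranial volume."""
    if tiv_ml <= 0:
        raise ValueError("TIV must be positive")
    return 100.0 * volume_ml / tiv_ml


def volume_report(tpms: TPMSet, mask: np.ndarray, threshold: float = 0.2,
                  count_mode: bool = False, subject_id: str = "subject") -> dict:
    """One subject's whole-brain volumetric row (repaired TPMs expected)."""
    vols = tissue_volumes(tpms, mask, threshold, count_mode)
    tiv_ml = tiv(vols["gm_ml"], vols["wm_ml"], vols["csf_ml"])
    row = {
        "subject_id": subject_id,
        **vols,
        "tiv_ml": tiv_ml,
        "tissue_volume_ratio": tissue_volume_ratio(vols["gm_ml"], vols["wm_ml"], tiv_ml),
        "gm_pct_tiv": normalise_pct_tiv(vols["gm_ml"], tiv_ml),
        "wm_pct_tiv": normalise_pct_tiv(vols["wm_ml"], tiv_ml),
        "threshold": threshold,
    }
    if "wml_ml" in vols:
        row["wml_pct_tiv"] = normalise_pct_tiv(vols["wml_ml"], tiv_ml)
    return row


def regional_volumes(tpms: TPMSet, atlas: LobeAtlas, threshold: float = 0.2,
                     count_mode: bool = False, subject_id: str = "subject") -> pd.DataFrame:
    """Per-lobe tissue volumes and tissue volume ratio.

    Each lobe's volumes are the whole-brain computation restricted to its
    atlas label; because the labels partition the supratentorial mask,
    per-lobe volumes sum exactly to the whole-brain values.  Missing
    labels yield empty rows (zero volumes, NaN ratio).
    """
    if atlas.labels.shape != tpms.shape:
        raise ValueError("atlas geometry does not match the TPMs")
    rows = []
    for name, code in atlas.label_names.items():
        mask = atlas.labels == code
        if not mask.any():
            rows.append({"subject_id": subject_id, "lobe": name, "gm_ml": 0.0,
                         "wm_ml": 0.0, "csf_ml": 0.0,
                         "tissue_volume_ratio": float("nan")})
            continue
        vols = tissue_volumes(tpms, mask, threshold, count_mode)
        gm, wm = vols["gm_ml"], vols["wm_ml"]
        denom = gm + wm + vols["csf_ml"]
        rows.append({
            "subject_id": subject_id,
            "lobe": name,
            **vols,
            "tissue_volume_ratio": (gm + wm) / denom if denom > 0 else float("nan"),
        })
    return pd.DataFrame(rows)
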