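"""Lesion ROI algebra, mirror metrics and cohort screening.

The longitudinal stroke analysis works on three regions derived from two
lesion masks: the initial diffusion lesion (IDL, DWI hyperintensity at
the first scan), the final infarct (FI, T2-FLAIR hyperintensity at the
second scan), the reversal region RR = IDL \\ FI, and the mismatch
FI \\ IDL when the infarct grew.  Metrics are reported relative to the
mirrored contralateral region (reflection about the midsagittal plane),
with voxels near the brain edge excluded by mask erosion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import binary_erosion

__all__ = [
    "ROISet",
    "derive_regions",
    "mirror_mask",
    "roi_mean",
    "relative_metric",
    "classify_case",
    "assign_phase",
    "apply_exclusions",
    "PHASE_LABELS",
]

PHASE_LABELS = ("acute", "early_subacute", "late_subacute", "chronic")

#: Exclusion reasons in reporting order; a record is tallied under the
#: first matching reason only.
EXCLUSION_REASONS = (
    "brainstem_cerebellum",
    "small_lesion",
    "hemorrhagic_transformation",
    "pre_mri_reperfusion_therapy",
    "other_disease",
    "motion_artifact",
)

MIN_LESION_VOLUME_MM3 = 250.0


@dataclass
class ROISet:
    """IDL/FI-derived masks with voxel geometry and midline."""

    idl: np.ndarray
    fi: np.ndarray
    rr: np.ndarray
    mismatch: np.ndarray
    brain: np.ndarray
    voxel_size_mm: float
    midline: float
    sinus: np.ndarray | None = None

    @classmethod
    def from_masks(cls, idl: np.ndarray, fi: np.ndarray, brain: np.ndarray,
                   voxel_size_mm: float, midline: float,
                   sinus: np.ndarray | None = None) -> "ROISet":
        idl = np.asarray(idl, dtype=bool)
        fi = np.asarray(fi, dtype=bool)
        brain = np.asarray(brain, dtype=bool)
        if idl.shape != fi.shape or idl.shape != brain.shape:
            raise ValueError("mask geometries differ")
        rr, mismatch = derive_regions(idl, fi)
        return cls(idl=idl, fi=fi, rr=rr, mismatch=mismatch, brain=brain,
                   voxel_size_mm=voxel_size_mm, midline=midline, sinus=sinus)

    def volume_ml(self, mask: np.ndarray) -> float:
        return float(mask.sum()) * self.voxel_size_mm ** 3 / 1000.0


def derive_regions(idl: np.ndarray, fi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(RR, mismatch) = (IDL \\ FI, FI \\ IDL); either may be empty."""
    idl = np.asarray(idl, dtype=bool)
    fi = np.asarray(fi, dtype=bool)
    if idl.shape != fi.shape:
        raise ValueError("mask geometries differ")
    return idl & ~fi, fi & ~idl


def mirror_mask(mask: np.ndarray, midline: float) -> np.ndarray:
    """Left-right reflection about the midsagittal plane index (axis 0).

    For the reflection to stay on the voxel grid, ``2*midline`` must be
    an integer (plane on a voxel center or halfway between two columns).
    """
    mask = np.asarray(mask)
    nx = mask.shape[0]
    if not 0 <= midline <= nx - 1:
        raise ValueError(f"midline {midline} outside grid of size {nx}")
    two_m = 2.0 * midline
    if abs(two_m - round(two_m)) > 1e-9:
        raise ValueError("2*midline must be integral for an index reflection")
    shift = int(round(two_m)) - (nx - 1)
    flipped = np.flip(mask, axis=0)
    out = np.zeros_like(mask)
    if shift >= 0:
        out[shift:] = flipped[: nx - shift]
    else:
        out[: nx + shift] = flipped[-shift:]
    return out


def roi_mean(volume: np.ndarray, mask: np.ndarray, brain: np.ndarray | None = None,
             edge_margin: int = 1) -> tuple[float, int]:
    """Mean of ``volume`` over ``mask``, away from the brain edge.

    The brain mask is eroded by ``edge_margin`` voxels and intersected
    with the ROI before averaging; NaN voxels are dropped.  Returns
    (mean, number of voxels excluded by the edge rule or NaN).
    """
    volume = np.asarray(volume, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    effective = mask
    if brain is not None and edge_margin > 0:
        core = binary_erosion(np.asarray(brain, dtype=bool), iterations=edge_margin)
        effective = mask & core
    vals = volume[effective]
    finite = np.isfinite(vals)
    excluded = int(mask.sum() - finite.sum())
    if not finite.any():
        raise ValueError("empty ROI after edge exclusion")
    return float(vals[finite].mean()), excluded


def relative_metric(volume: np.ndarray, mask: np.ndarray, midline: float,
                    brain: np.ndarray | None = None, edge_margin: int = 1) -> float:
    """ROI mean divided by the mean over the mirrored contralateral ROI."""
    ipsi, _ = roi_mean(volume, mask, brain, edge_margin)
    contra, _ = roi_mean(volume, mirror_mask(mask, midline), brain, edge_margin)
    if contra == 0:
        raise ZeroDivisionError("contralateral mean is zero")
    return ipsi / contra


def classify_case(vol_idl_mm3: float, vol_fi_mm3: float,
                  tol: float = 0.01) -> str:
    """Longitudinal class from lesion volumes.

    DR (diffusion reversal) when the final infarct is smaller than the
    initial diffusion lesion beyond the relative tolerance; NDR-enlarged
    when larger; NDR-equal otherwise.  Measured volumes are never
    bit-equal, hence the explicit tolerance.
    """
    if vol_idl_mm3 < 0 or vol_fi_mm3 < 0:
        raise ValueError("volumes must be nonnegative")
    if vol_fi_mm3 < vol_idl_mm3 * (1.0 - tol):
        return "DR"
    if vol_fi_mm3 > vol_idl_mm3 * (1.0 + tol):
        return "NDR-enlarged"
    return "NDR-equal"


def assign_phase(onset_to_scan_days: float) -> str:
    """Stroke phase from onset-to-scan time (days).

    acute: t <= 1; early subacute: 1 < t <= 7; late subacute: 7 < t <= 14;
    chronic: t > 14.  (The day-7/8 boundary is implemented as (7, 14] so
    continuous times partition cleanly.)
    """
    t = float(onset_to_scan_days)
    if t <= 0:
        raise ValueError("onset-to-scan time must be positive")
    if t <= 1:
        return "acute"
    if t <= 7:
        return "early_subacute"
    if t <= 14:
        return "late_subacute"
    return "chronic"


def apply_exclusions(roster: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Screen a roster: drop flagged records and small lesions.

    A record is excluded if any exclusion flag is set or its lesion
    volume is under 250 mm^3 (strict), and is tallied under the first
    matching reason in the reporting order.  Returns (included records,
    tally by reason).
    """
    if len(roster) == 0:
        raise ValueError("empty roster")
    tally = {reason: 0 for reason in EXCLUSION_REASONS}
    excluded = np.zeros(len(roster), dtype=bool)
    for i, (_, rec) in enumerate(roster.iterrows()):
        for reason in EXCLUSION_REASONS:
            hit = (rec["lesion_volume_mm3"] < MIN_LESION_VOLUME_MM3
                   if reason == "small_lesion"
                   else bool(rec.get(reason, False)))
            if hit:
                tally[reason] += 1
                excluded[i] = True
                break
    included = roster.loc[~excluded].copy()
    included["phase"] = included["onset_to_scan_days"].map(assign_phase)
    return included, {k: v for k, v in tally.items() if v > 0}
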