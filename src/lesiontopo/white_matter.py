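"""White-matter integrity: mean FA over paired tract ROIs and the
ipsilateral-vs-contralateral paired comparison."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import VolumeGrid
from .stats import TestResult, paired_t

__all__ = ["FAROIResult", "roi_mean_fa", "fa_roi_result", "fa_asymmetry_test"]


@dataclass
class FAROIResult:
    subject_id: str
    timepoint_day: float
    tract_name: str
    ipsi_mean_fa: float
    contra_mean_fa: float
    n_voxels_ipsi: int
    n_voxels_contra: int


def roi_mean_fa(fa_map: VolumeGrid, roi_mask: VolumeGrid) -> tuple[float, int, int]:
    """Arithmetic mean FA over ROI voxels.

    NaN voxels inside the ROI are excluded from the mean and counted.
    Returns ``(mean, n_used, n_nan)``.
    """
    if not fa_map.same_grid(roi_mask):
        raise ValueError("FA map and ROI mask are not on the same grid")
    roi = roi_mask.require_binary("ROI")
    if not roi.any():
        raise ValueError("ROI mask is empty")
    vals = np.asarray(fa_map.data, dtype=float)[roi]
    nan = np.isnan(vals)
    if nan.all():
        raise ValueError("ROI contains only NaN FA values")
    return float(vals[~nan].mean()), int((~nan).sum()), int(nan.sum())


def fa_roi_result(
    fa_map: VolumeGrid,
    roi_ipsi: VolumeGrid,
    roi_contra: VolumeGrid,
    subject_id: str = "",
    timepoint_day: float = 0.0,
    tract_name: str = "corpus_callosum",
    area_warn_fraction: float = 0.10,
) -> FAROIResult:
    """Paired ROI means for one subject; warns when the two ROI areas differ
    by more than ``area_warn_fraction`` (the equal-area ROI contract)."""
    ipsi_mean, n_ipsi, _ = roi_mean_fa(fa_map, roi_ipsi)
    contra_mean, n_contra, _ = roi_mean_fa(fa_map, roi_contra)
    if abs(n_ipsi - n_contra) > area_warn_fraction * max(n_ipsi, n_contra):
        warnings.warn(
            f"{subject_id}: ipsi/contra ROI voxel counts differ by >"
            f"{area_warn_fraction:.0%} ({n_ipsi} vs {n_contra})",
            stacklevel=2,
        )
    return FAROIResult(
        subject_id=subject_id,
        timepoint_day=timepoint_day,
        tract_name=tract_name,
        ipsi_mean_fa=ipsi_mean,
        contra_mean_fa=contra_mean,
        n_voxels_ipsi=n_ipsi,
        n_voxels_contra=n_contra,
    )


def fa_asymmetry_test(cohort: list[FAROIResult] | pd.DataFrame) -> TestResult:
    """Two-sided paired t-test of ipsi vs contra mean FA across subjects."""
    if isinstance(cohort, pd.DataFrame):
        ipsi = cohort["ipsi_mean_fa"].to_numpy(float)
        contra = cohort["contra_mean_fa"].to_numpy(float)
    else:
        ipsi = np.array([r.ipsi_mean_fa for r in cohort], dtype=float)
        contra = np.array([r.contra_mean_fa for r in cohort], dtype=float)
    if len(ipsi) < 2:
        raise ValueError("need at least 2 paired subjects for the asymmetry test")
    return paired_t(ipsi, contra)
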