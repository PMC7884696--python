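"""Canonical stroke MRI metrics from binary masks.

Lesion volume, ipsi/contra hemisphere volumes (ventricles subtracted,
cerebellum excluded), lesion as a percent of the ipsilateral hemisphere,
hemispheric swelling/atrophy, and landmark-based midline shift. Volumes are
voxel counts times voxel volume — on masks this is identical to summing
per-slice areas times slice thickness, the classical manual procedure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import VolumeGrid

__all__ = [
    "MidlineLandmarks",
    "VolumetricsResult",
    "mask_volume",
    "hemisphere_volumes",
    "lesion_percent_of_hemisphere",
    "hemispheric_change_percent",
    "midline_shift",
    "compute_volumetrics",
    "read_landmarks_csv",
]


@dataclass
class MidlineLandmarks:
    """Septum pellucidum point and the ideal (bony-landmark) midline plane.

    All coordinates in world mm. ``plane_normal`` must be unit length and
    point toward the contralateral hemisphere, so a positive shift means
    displacement toward the contralateral side.
    """

    septum_point: np.ndarray
    plane_point: np.ndarray
    plane_normal: np.ndarray

    def __post_init__(self) -> None:
        self.septum_point = np.asarray(self.septum_point, dtype=float)
        self.plane_point = np.asarray(self.plane_point, dtype=float)
        self.plane_normal = np.asarray(self.plane_normal, dtype=float)
        nrm = np.linalg.norm(self.plane_normal)
        if nrm < 1e-12:
            raise ValueError("degenerate midline plane: zero normal")
        if abs(nrm - 1.0) > 1e-6:
            raise ValueError("plane normal must be unit length")


@dataclass
class VolumetricsResult:
    subject_id: str
    timepoint_day: float
    lesion_volume_cm3: float
    ipsi_hemisphere_cm3: float
    contra_hemisphere_cm3: float
    lesion_percent_of_ipsi: float
    hemispheric_change_percent: float
    midline_shift_mm: float


def mask_volume(mask: VolumeGrid) -> float:
    """Volume of a binary mask in cm^3 (voxel count x voxel volume)."""
    m = mask.require_binary()
    return float(m.sum() * mask.voxel_volume_mm3 / 1000.0)


def hemisphere_volumes(
    ipsi_mask: VolumeGrid,
    contra_mask: VolumeGrid,
    ventricle_ipsi: VolumeGrid,
    ventricle_contra: VolumeGrid,
    cerebellum_mask: VolumeGrid | None = None,
) -> tuple[float, float]:
    """Hemisphere volumes (cm^3) with lateral ventricles subtracted and the
    cerebellum excluded from both sides."""
    ipsi = ipsi_mask.require_binary("ipsi hemisphere")
    contra = contra_mask.require_binary("contra hemisphere")
    for other in (contra_mask, ventricle_ipsi, ventricle_contra):
        if not ipsi_mask.same_grid(other):
            raise ValueError("all masks must share one grid")
    if (ipsi & contra).any():
        raise ValueError("ipsi and contra hemisphere masks overlap")
    cbm = (
        cerebellum_mask.require_binary("cerebellum")
        if cerebellum_mask is not None
        else np.zeros_like(ipsi)
    )
    vox_cm3 = ipsi_mask.voxel_volume_mm3 / 1000.0
    ipsi_net = ipsi & ~ventricle_ipsi.require_binary("ventricle") & ~cbm
    contra_net = contra & ~ventricle_contra.require_binary("ventricle") & ~cbm
    return float(ipsi_net.sum() * vox_cm3), float(contra_net.sum() * vox_cm3)


def lesion_percent_of_hemisphere(lesion_cm3: float, ipsi_cm3: float) -> float:
    """Lesion volume as a percent of the ipsilateral hemisphere volume."""
    if ipsi_cm3 <= 0:
        raise ZeroDivisionError("ipsilateral hemisphere volume must be > 0")
    return 100.0 * lesion_cm3 / ipsi_cm3


def hemispheric_change_percent(ipsi_cm3: float, contra_cm3: float) -> float:
    """Signed percent change of ipsi relative to contra hemisphere volume:
    positive = swelling, negative = atrophy."""
    if contra_cm3 <= 0:
        raise ZeroDivisionError("contralateral hemisphere volume must be > 0")
    return 100.0 * (ipsi_cm3 / contra_cm3 - 1.0)


def midline_shift(landmarks: MidlineLandmarks) -> float:
    """Signed perpendicular distance (mm) from the septum pellucidum to the
    ideal midline plane; positive = displaced toward the contralateral
    hemisphere."""
    return float(
        np.dot(landmarks.septum_point - landmarks.plane_point, landmarks.plane_normal)
    )


def compute_volumetrics(
    subject,
    subject_id: str = "",
    timepoint_day: float = 0.0,
) -> VolumetricsResult:
    """All canonical metrics for one subject x timepoint bundle.

    ``subject`` is any object exposing ``lesion``, ``hemisphere_ipsi``,
    ``hemisphere_contra``, ``ventricle_ipsi``, ``ventricle_contra``,
    ``cerebellum`` (VolumeGrids) and ``landmarks``.
    """
    lesion_cm3 = mask_volume(subject.lesion)
    ipsi_cm3, contra_cm3 = hemisphere_volumes(
        subject.hemisphere_ipsi,
        subject.hemisphere_contra,
        subject.ventricle_ipsi,
        subject.ventricle_contra,
        subject.cerebellum,
    )
    return VolumetricsResult(
        subject_id=subject_id,
        timepoint_day=timepoint_day,
        lesion_volume_cm3=lesion_cm3,
        ipsi_hemisphere_cm3=ipsi_cm3,
        contra_hemisphere_cm3=contra_cm3,
        lesion_percent_of_ipsi=lesion_percent_of_hemisphere(lesion_cm3, ipsi_cm3),
        hemispheric_change_percent=hemispheric_change_percent(ipsi_cm3, contra_cm3),
        midline_shift_mm=midline_shift(subject.landmarks),
    )


def read_landmarks_csv(path) -> dict[tuple[str, float], MidlineLandmarks]:
    """Load manually identified landmarks for real (non-phantom) data.

    Expected columns: ``subject_id, timepoint_day, septum_x_mm, septum_y_mm,
    septum_z_mm, plane_point_x_mm, plane_point_y_mm, plane_point_z_mm,
    plane_normal_x, plane_normal_y, plane_normal_z``. Normals are normalized
    to unit length on load. Returns a (subject, timepoint) -> landmarks map.
    """
    import pandas as pd

    df = pd.read_csv(path)
    out: dict[tuple[str, float], MidlineLandmarks] = {}
    for _, row in df.iterrows():
        normal = np.array(
            [row["plane_normal_x"], row["plane_normal_y"], row["plane_normal_z"]],
            dtype=float,
        )
        nrm = np.linalg.norm(normal)
        if nrm < 1e-12:
            raise ValueError(
                f"degenerate plane normal for {row['subject_id']}"
                f" at day {row['timepoint_day']}"
            )
        out[(str(row["subject_id"]), float(row["timepoint_day"]))] = MidlineLandmarks(
            septum_point=[row["septum_x_mm"], row["septum_y_mm"], row["septum_z_mm"]],
            plane_point=[
                row["plane_point_x_mm"], row["plane_point_y_mm"], row["plane_point_z_mm"],
            ],
            plane_normal=normal / nrm,
        )
    return out
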