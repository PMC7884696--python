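"""Synthetic porcine-style stroke phantom cohort with known ground truth.

Builds a mirrored ellipsoid parcellation (paired cortical/subcortical
structures, lateral ventricles, cerebellum) on a regular grid, then per
subject: an MCA-territory-style lesion covering stated fractions of chosen
structures, hemispheric swelling/atrophy with an exactly known
ipsi/contra volume ratio, a septum-pellucidum landmark displaced by a known
midline shift, FA maps with a stated ipsilateral tract decrement, and tidy
longitudinal outcome tables (gait, open field, mRS) driven by a linear
damage-to-deficit model.

Every stochastic element flows through one seeded generator per subject, so
a fixed seed reproduces the cohort byte for byte. The phantom exists to make
the downstream analysis testable: its ground-truth sidecar records the exact
quantities volumetrics and topology are expected to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .grid import VolumeGrid, LabelAtlas, LOOKUP_COLUMNS
from .volumetrics import MidlineLandmarks

__all__ = [
    "PhantomConfig",
    "LesionSpec",
    "SwellingSpec",
    "OutcomeModel",
    "SubjectImaging",
    "PhantomAtlas",
    "CoverageSampler",
    "generate_atlas",
    "generate_subject",
    "generate_fa_map",
    "generate_outcomes",
    "default_outcome_model",
    "default_coverage_sampler",
    "sample_cohort_pos",
    "STRUCTURE_CATALOG",
    "GAIT_PARAMETERS",
    "OPEN_FIELD_PARAMETERS",
]

# (name, region group) — motor/sensory structures of the MCA territory,
# ordered roughly by how heavily the territory lesions them.
STRUCTURE_CATALOG: list[tuple[str, str]] = [
    ("claustrum", "striate_system"),
    ("inferior_temporal_gyrus", "brodmann_area"),
    ("superior_temporal_gyrus", "brodmann_area"),
    ("insular_cortex", "brodmann_area"),
    ("middle_temporal_gyrus", "brodmann_area"),
    ("putamen", "striate_system"),
    ("somatosensory_association_cortex", "brodmann_area"),
    ("secondary_visual_cortex", "brodmann_area"),
    ("globus_pallidus", "striate_system"),
    ("primary_somatosensory_cortex", "brodmann_area"),
    ("caudate_nucleus", "striate_system"),
    ("hippocampus", "limbic_system"),
    ("amygdala", "limbic_system"),
    ("primary_motor_cortex", "brodmann_area"),
    ("primary_visual_cortex", "brodmann_area"),
    ("fusiform_gyrus", "brodmann_area"),
    ("prepiriform_area", "brodmann_area"),
    ("parahippocampal_cortex", "limbic_system"),
    ("pulvinar_nuclei", "thalamus"),
    ("fornix", "limbic_system"),
]

GAIT_PARAMETERS = [
    "velocity",
    "cadence",
    "stride_length",
    "step_length",
    "swing_percent",
    "stance_percent",
]
OPEN_FIELD_PARAMETERS = ["distance_traveled", "movement_duration"]


# --------------------------------------------------------------------------
# configuration dataclasses
# --------------------------------------------------------------------------


@dataclass
class PhantomConfig:
    """Geometry and content of the synthetic atlas.

    Defaults give a ~128x128x72 mm volume at 2x2x3 mm voxels (3 mm slices,
    as in axial T2-weighted stroke protocols) with 10 paired structures per
    hemisphere plus lateral ventricles and a cerebellum.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 24)
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 3.0)
    n_structures_per_hemisphere: int = 10
    ventricle_fraction: float = 0.05
    cerebellum_fraction: float = 0.12
    seed: int = 0

    def validate(self) -> None:
        if any(int(s) < 16 for s in self.grid_shape):
            raise ValueError("grid_shape components must be >= 16")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel_size_mm components must be > 0")
        if not (0 < self.ventricle_fraction < 0.2):
            raise ValueError("ventricle_fraction must lie in (0, 0.2)")
        if not (0 < self.cerebellum_fraction < 0.3):
            raise ValueError("cerebellum_fraction must lie in (0, 0.3)")
        if self.n_structures_per_hemisphere < 1:
            raise ValueError("need at least one structure per hemisphere")


@dataclass
class LesionSpec:
    """Which fraction of which (ipsilateral) structures the lesion covers.

    ``target_coverage`` maps structure label id -> fraction in [0, 1].
    ``extra_ellipsoids`` adds free-form lesion blobs: (center_mm, radii_mm)
    pairs, clipped to ipsilateral parenchyma. With
    ``ellipsoids_avoid_structures`` the blobs claim only unlabeled tissue,
    so per-structure coverage stays exactly at its target.
    """

    target_coverage: dict[int, float] = field(default_factory=dict)
    extra_ellipsoids: list[tuple[tuple[float, float, float], tuple[float, float, float]]] = field(
        default_factory=list
    )
    ellipsoids_avoid_structures: bool = False

    def validate(self) -> None:
        for sid, frac in self.target_coverage.items():
            if not (0.0 <= frac <= 1.0):
                raise ValueError(f"target coverage for structure {sid} must be in [0, 1], got {frac}")


@dataclass
class SwellingSpec:
    """Mass effect: signed midline shift (positive = toward the
    contralateral hemisphere) and signed percent change of the ipsilateral
    hemisphere volume (positive = swelling, negative = atrophy)."""

    midline_shift_mm: float = 0.0
    volume_change_percent: float = 0.0


@dataclass
class OutcomeModel:
    """Linear damage-to-deficit generator for longitudinal outcomes.

    value(param, subject, t) =
        baseline * (1 - sum_k beta[param, k] * PoS_k / 100 * 2^(-t / halflife))
        + Gaussian noise,                      for post-stroke days t >= 0;
    pre-stroke rows carry no deficit. mRS is produced by thresholding the
    same latent deficit onto the 0-6 integer scale.
    """

    baseline: dict[str, float] = field(default_factory=dict)  # param -> healthy mean
    units: dict[str, str] = field(default_factory=dict)  # param -> unit label
    limb: dict[str, str] = field(default_factory=dict)  # param -> limb tag
    beta: dict[tuple[str, str], float] = field(default_factory=dict)  # (param, structure) -> coeff
    noise_sd: dict[str, float] = field(default_factory=dict)  # param -> Gaussian SD
    recovery_halflife_days: dict[str, float] = field(default_factory=dict)
    mrs_thresholds: tuple[float, ...] = (0.08, 0.18, 0.30, 0.45, 0.62, 0.85)

    def validate(self, known_structures: set[str]) -> None:
        for (param, struct), _ in self.beta.items():
            if struct not in known_structures:
                raise ValueError(f"beta references unknown structure {struct!r}")
        for param, sd in self.noise_sd.items():
            if sd < 0:
                raise ValueError(f"noise_sd for {param!r} must be >= 0")


# --------------------------------------------------------------------------
# atlas geometry
# --------------------------------------------------------------------------


@dataclass
class _Geometry:
    """World-space (mm) layout of the phantom head; everything downstream
    re-derives masks from these few numbers."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    mid_x: float  # midline plane x (mm); left: x < mid_x, right (ipsi): x > mid_x
    cerebrum_center: tuple[float, float, float]
    cerebrum_semi: tuple[float, float, float]

    def world_coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        sx, sy, sz = self.spacing
        nx, ny, nz = self.shape
        return np.meshgrid(
            np.arange(nx) * sx,
            np.arange(ny) * sy,
            np.arange(nz) * sz,
            indexing="ij",
        )

    def cerebrum_mask(self) -> np.ndarray:
        X, Y, Z = self.world_coords()
        cx, cy, cz = self.cerebrum_center
        ax, ay, az = self.cerebrum_semi
        return ((X - cx) / ax) ** 2 + ((Y - cy) / ay) ** 2 + ((Z - cz) / az) ** 2 <= 1.0

    def right_half(self) -> np.ndarray:
        nx = self.shape[0]
        half = np.zeros(self.shape, dtype=bool)
        half[nx // 2 :, :, :] = True
        return half


@dataclass
class PhantomAtlas(LabelAtlas):
    """LabelAtlas plus the generator geometry needed to rebuild hemisphere
    envelopes and landmarks for synthetic subjects."""

    geometry: _Geometry = None  # type: ignore[assignment]


def _ellipsoid(X, Y, Z, center, semi) -> np.ndarray:
    cx, cy, cz = center
    ax, ay, az = semi
    return ((X - cx) / ax) ** 2 + ((Y - cy) / ay) ** 2 + ((Z - cz) / az) ** 2 <= 1.0


def generate_atlas(config: PhantomConfig) -> PhantomAtlas:
    """Build the mirrored parcellation.

    Paired structures are axis-aligned ellipsoids packed on a jittered
    lattice in the right hemisphere and mirrored voxel-exactly onto the
    left (the grid is symmetric about the midline plane, so a flip along
    the x axis is an exact reflection). Lateral ventricles sit beside the
    midline; the cerebellum occupies a posterior compartment outside the
    cerebral envelope.
    """
    config.validate()
    nx, ny, nz = (int(s) for s in config.grid_shape)
    sx, sy, sz = (float(v) for v in config.voxel_size_mm)
    Lx, Ly, Lz = nx * sx, ny * sy, nz * sz
    mid_x = (nx / 2 - 0.5) * sx

    # porcine-scale cerebrum: one net hemisphere ~35 cm^3
    geom = _Geometry(
        shape=(nx, ny, nz),
        spacing=(sx, sy, sz),
        mid_x=mid_x,
        cerebrum_center=(mid_x, 0.42 * Ly, 0.50 * Lz),
        cerebrum_semi=(0.27 * Lx, 0.25 * Ly, 0.23 * Lz),
    )
    X, Y, Z = geom.world_coords()
    cerebrum = geom.cerebrum_mask()
    right = geom.right_half()

    rng = np.random.default_rng(config.seed)
    n = config.n_structures_per_hemisphere
    labels = np.zeros((nx, ny, nz), dtype=np.int32)

    cx0, cy0, cz0 = geom.cerebrum_center
    ax, ay, az = geom.cerebrum_semi

    # cerebellum: posterior compartment, size set by cerebellum_fraction
    f_cbm = (config.cerebellum_fraction / 0.12) ** (1 / 3)
    cbm = _ellipsoid(
        X, Y, Z,
        center=(mid_x, cy0 + 1.40 * ay, cz0 - 0.30 * az),
        semi=(0.50 * ax * f_cbm, 0.40 * ay * f_cbm, 0.55 * az * f_cbm),
    ) & ~cerebrum

    # lateral ventricles beside the midline, mirrored exactly
    f_v = (config.ventricle_fraction / 0.05) ** (1 / 3)
    vent_r = _ellipsoid(
        X, Y, Z,
        center=(mid_x + 0.17 * ax, cy0, cz0),
        semi=(0.10 * ax * f_v, 0.35 * ay * f_v, 0.55 * az * f_v),
    ) & cerebrum & right
    vent_l = np.flip(vent_r, axis=0)

    # jittered lattice of paired structures in the right hemisphere,
    # lateral of the ventricle band
    box_lo = np.array([mid_x + 0.30 * ax, cy0 - 0.72 * ay, cz0 - 0.72 * az])
    box_hi = np.array([mid_x + 0.88 * ax, cy0 + 0.72 * ay, cz0 + 0.72 * az])
    extent = box_hi - box_lo
    # smallest lattice with >= n cells, splitting the widest cells first so
    # cells (and hence structures) stay as large as the box allows
    dims = np.ones(3, dtype=int)
    while dims.prod() < n:
        dims[np.argmax(extent / dims)] += 1
    cell = extent / dims
    centers = []
    for i in range(dims[0]):
        for j in range(dims[1]):
            for k in range(dims[2]):
                centers.append(box_lo + (np.array([i, j, k]) + 0.5) * cell)
    if n > len(centers):
        raise ValueError(
            f"grid too small: {len(centers)} lattice cells for {n} structures"
        )
    # prefer interior cells: ellipsoids near the envelope edge get clipped,
    # leaving structures too small to carry meaningful coverage fractions
    ctr = np.asarray(geom.cerebrum_center)
    semi = np.asarray(geom.cerebrum_semi)
    rho = np.array(
        [np.sqrt((((c - ctr) / semi) ** 2).sum()) for c in centers]
    )
    interior = np.argsort(rho, kind="stable")[:n]
    order = interior[rng.permutation(n)]

    struct_labels_right = np.zeros_like(labels)
    rows = []
    for j, ci in enumerate(order):
        center = np.asarray(centers[ci]) + rng.uniform(-0.08, 0.08, 3) * cell
        radii = rng.uniform(0.40, 0.48, 3) * cell
        mask = _ellipsoid(X, Y, Z, center, radii) & cerebrum & right & ~vent_r
        lid = 2 * j + 1
        struct_labels_right[mask & (struct_labels_right == 0)] = lid
        name, group = STRUCTURE_CATALOG[j % len(STRUCTURE_CATALOG)]
        if j >= len(STRUCTURE_CATALOG):
            name = f"{name}_{j // len(STRUCTURE_CATALOG)}"
        rows.append((lid, f"{name}_r", group, "right", lid + 1, False, False))
        rows.append((lid + 1, f"{name}_l", group, "left", lid, False, False))

    # mirror right-hemisphere structures onto the left with partner labels
    flipped = np.flip(struct_labels_right, axis=0)
    labels[:] = struct_labels_right
    labels[flipped > 0] = flipped[flipped > 0] + 1

    vid_r, vid_l, cid = 2 * n + 1, 2 * n + 2, 2 * n + 3
    labels[vent_r] = vid_r
    labels[vent_l] = vid_l
    labels[cbm] = cid
    rows.append((vid_r, "lateral_ventricle_r", "ventricular_system", "right", vid_l, True, False))
    rows.append((vid_l, "lateral_ventricle_l", "ventricular_system", "left", vid_r, True, False))
    rows.append((cid, "cerebellum", "cerebellum", "both", -1, False, True))

    lookup = pd.DataFrame(rows, columns=LOOKUP_COLUMNS)
    affine = np.diag([sx, sy, sz, 1.0])
    return PhantomAtlas(grid=VolumeGrid(labels, affine), lookup=lookup, geometry=geom)


# --------------------------------------------------------------------------
# subject imaging
# --------------------------------------------------------------------------


@dataclass
class SubjectImaging:
    """One subject x timepoint imaging bundle plus its ground truth."""

    lesion: VolumeGrid
    hemisphere_ipsi: VolumeGrid
    hemisphere_contra: VolumeGrid
    ventricle_ipsi: VolumeGrid
    ventricle_contra: VolumeGrid
    cerebellum: VolumeGrid
    landmarks: MidlineLandmarks
    ground_truth: dict


def _count_exact_sublevel(score: np.ndarray, candidates: np.ndarray, count: int) -> np.ndarray:
    """Boolean mask of exactly `count` candidate voxels with smallest score.

    Realizes a scaled-ellipsoid sublevel set at an exact voxel count, so
    discretization never erodes the ground-truth volume ratio. Ties broken
    by flat index (stable sort) for determinism.
    """
    idx = np.flatnonzero(candidates)
    order = np.argsort(score.ravel()[idx], kind="stable")
    keep = idx[order[:count]]
    out = np.zeros(score.shape, dtype=bool)
    out.ravel()[keep] = True
    return out


def generate_subject(
    atlas: PhantomAtlas,
    lesion: LesionSpec,
    swelling: SwellingSpec,
    seed: int = 0,
) -> SubjectImaging:
    """Realize one subject: lesion mask, swollen/atrophied hemisphere masks,
    ventricle and cerebellum masks, displaced septum landmark, sidecar truth.

    The lesion takes exactly ``round(fraction * n_structure_voxels)`` voxels
    of each targeted ipsilateral structure (those nearest the structure
    centroid, so each per-structure patch is compact), plus any free-form
    ellipsoid blobs clipped to ipsilateral parenchyma.
    """
    lesion.validate()
    geom = atlas.geometry
    nx, ny, nz = geom.shape
    sx, sy, sz = geom.spacing
    affine = atlas.grid.affine
    X, Y, Z = geom.world_coords()

    cerebrum = geom.cerebrum_mask()
    right = geom.right_half()
    lk = atlas.lookup
    vid_r = int(lk.loc[lk["is_ventricle"] & (lk["hemisphere"] == "right"), "label_id"].iloc[0])
    vid_l = int(lk.loc[lk["is_ventricle"] & (lk["hemisphere"] == "left"), "label_id"].iloc[0])
    cid = int(lk.loc[lk["is_cerebellum"], "label_id"].iloc[0])
    vent_r = atlas.mask_of(vid_r)
    vent_l = atlas.mask_of(vid_l)
    cbm = atlas.mask_of(cid)

    # ---- lesion ----
    lesion_mask = np.zeros(geom.shape, dtype=bool)
    achieved: dict[int, float] = {}
    right_ids = set(lk.loc[lk["hemisphere"] == "right", "label_id"]) - {vid_r}
    for sid, frac in lesion.target_coverage.items():
        if sid not in set(lk["label_id"]):
            raise ValueError(f"structure {sid} not in atlas")
        if sid not in right_ids:
            raise ValueError(
                f"structure {sid} is not an ipsilateral (right) parenchymal structure"
            )
        smask = atlas.mask_of(sid)
        n_vox = int(smask.sum())
        k = int(round(frac * n_vox))
        if k:
            coords = np.c_[X[smask], Y[smask], Z[smask]]
            centroid = coords.mean(axis=0)
            d2 = ((coords - centroid) ** 2).sum(axis=1)
            flat = np.flatnonzero(smask)
            take = flat[np.argsort(d2, kind="stable")[:k]]
            lesion_mask.ravel()[take] = True
        achieved[sid] = k / n_vox if n_vox else 0.0

    parenchyma_ipsi = cerebrum & right & ~vent_r
    if lesion.ellipsoids_avoid_structures:
        parenchyma_ipsi = parenchyma_ipsi & (atlas.grid.data == 0)
    for center, radii in lesion.extra_ellipsoids:
        lesion_mask |= _ellipsoid(X, Y, Z, center, radii) & parenchyma_ipsi

    # ---- hemisphere masks with count-exact swelling/atrophy ----
    # the stated ratio is honored on ventricle-subtracted (net) volumes,
    # because that is what hemispheric volumetrics reports
    contra = cerebrum & ~right
    n_vent = int(vent_r.sum())  # mirrored, so both sides count the same
    n_contra_net = int(contra.sum()) - int(vent_l.sum())
    scale = 1.0 + swelling.volume_change_percent / 100.0
    if scale <= 0:
        raise ValueError("volume_change_percent must leave a positive volume")
    target_net = int(round(n_contra_net * scale))
    cx0, cy0, cz0 = geom.cerebrum_center
    ax, ay, az = geom.cerebrum_semi
    score = (
        ((X - geom.mid_x) / (ax * scale)) ** 2
        + ((Y - cy0) / ay) ** 2
        + ((Z - cz0) / az) ** 2
    )
    ipsi = vent_r | _count_exact_sublevel(score, right & ~cbm & ~vent_r, target_net)

    # ---- septum landmark, snapped to the voxel grid ----
    # positive shift points toward the contralateral (left, -x) hemisphere
    normal = np.array([-1.0, 0.0, 0.0])
    plane_point = np.array([geom.mid_x, cy0, cz0])
    # septum localized at half-voxel precision in-plane (landmark lines are
    # drawn on magnified slices), full-voxel precision through-plane
    x_true = geom.mid_x - swelling.midline_shift_mm
    septum = np.array(
        [round(2 * x_true / sx) * sx / 2, round(cy0 / sy) * sy, round(cz0 / sz) * sz]
    )
    achieved_shift = float(np.dot(septum - plane_point, normal))
    landmarks = MidlineLandmarks(septum_point=septum, plane_point=plane_point, plane_normal=normal)

    vox_cm3 = atlas.grid.voxel_volume_mm3 / 1000.0
    truth = {
        "seed": seed,
        "lesion_voxels": int(lesion_mask.sum()),
        "lesion_volume_cm3": float(lesion_mask.sum() * vox_cm3),
        "target_coverage": {int(k): float(v) for k, v in lesion.target_coverage.items()},
        "achieved_coverage": {int(k): float(v) for k, v in achieved.items()},
        "midline_shift_mm": swelling.midline_shift_mm,
        "achieved_midline_shift_mm": achieved_shift,
        "volume_change_percent": swelling.volume_change_percent,
        "achieved_volume_change_percent": float(
            100.0 * ((int(ipsi.sum()) - n_vent) / n_contra_net - 1.0)
        ),
    }

    g = lambda a: VolumeGrid(a, affine)  # noqa: E731
    return SubjectImaging(
        lesion=g(lesion_mask),
        hemisphere_ipsi=g(ipsi),
        hemisphere_contra=g(contra),
        ventricle_ipsi=g(vent_r),
        ventricle_contra=g(vent_l),
        cerebellum=g(cbm),
        landmarks=landmarks,
        ground_truth=truth,
    )


def generate_fa_map(
    atlas: PhantomAtlas,
    tract_decrement: float,
    noise_sd: float,
    seed: int = 0,
    baseline_fa: float = 0.45,
    background_fa: float = 0.25,
) -> tuple[VolumeGrid, dict[str, VolumeGrid]]:
    """Scalar FA volume with mirrored corpus-callosum-style ROIs.

    The contralateral ROI carries ``baseline_fa``; the ipsilateral ROI
    carries ``baseline_fa * (1 - tract_decrement)``; independent Gaussian
    noise (SD ``noise_sd``) is added voxelwise and the map clipped to [0, 1].
    """
    if not (0.0 <= tract_decrement <= 1.0):
        raise ValueError("tract_decrement must lie in [0, 1]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    geom = atlas.geometry
    X, Y, Z = geom.world_coords()
    cx0, cy0, cz0 = geom.cerebrum_center
    ax, ay, az = geom.cerebrum_semi
    right = geom.right_half()
    cerebrum = geom.cerebrum_mask()

    roi_r = (
        (X > geom.mid_x)
        & (X <= geom.mid_x + 0.30 * ax)
        & (np.abs(Y - cy0) <= 0.45 * ay)
        & (np.abs(Z - cz0) <= 0.45 * az)
        & cerebrum & right
    )
    roi_l = np.flip(roi_r, axis=0)

    fa = np.full(geom.shape, background_fa, dtype=float)
    fa[roi_l] = baseline_fa
    fa[roi_r] = baseline_fa * (1.0 - tract_decrement)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        fa = fa + rng.normal(0.0, noise_sd, size=geom.shape)
    fa = np.clip(fa, 0.0, 1.0)

    affine = atlas.grid.affine
    return VolumeGrid(fa, affine), {
        "ipsi": VolumeGrid(roi_r, affine),
        "contra": VolumeGrid(roi_l, affine),
    }


# --------------------------------------------------------------------------
# outcome generation
# --------------------------------------------------------------------------


def default_outcome_model(noise_fraction: float = 0.10) -> OutcomeModel:
    """Study-condition outcome model.

    Healthy baselines use published porcine gait/behavior magnitudes
    (velocity ~199 cm/s, cadence ~133 strides/min, ...), deficits load on
    the motor-coordination structures (putamen, globus pallidus, primary
    somatosensory cortex), recovery halves per week, and noise defaults to
    10% of each baseline.
    """
    baseline = {
        "velocity": 198.78,
        "cadence": 133.01,
        "stride_length": 89.01,
        "step_length": 44.36,
        "swing_percent": 51.93,
        "stance_percent": 48.06,
        "distance_traveled": 75.70,
        "movement_duration": 230.55,
        "mRS": 0.0,
    }
    units = {
        "velocity": "cm/s",
        "cadence": "strides/min",
        "stride_length": "cm",
        "step_length": "cm",
        "swing_percent": "%",
        "stance_percent": "%",
        "distance_traveled": "m",
        "movement_duration": "s",
        "mRS": "score",
    }
    limb = {p: "LF" for p in GAIT_PARAMETERS}
    limb.update({p: "NA" for p in [*OPEN_FIELD_PARAMETERS, "mRS"]})

    # coefficients sized so each structure's damage is sign-recoverable in
    # correlation at small cohort sizes; the pallidum and somatosensory
    # cortex carry larger per-unit weights because they are lesioned in
    # fewer subjects (0.714 presence) than the putamen
    motor = {
        "putamen_r": 0.70,
        "globus_pallidus_r": 0.68,
        "primary_somatosensory_cortex_r": 0.72,
    }
    beta: dict[tuple[str, str], float] = {}
    for param in GAIT_PARAMETERS:
        sign = -1.0 if param == "stance_percent" else 1.0  # stance % rises post-stroke
        for s, b in motor.items():
            beta[(param, s)] = sign * b
    for param in OPEN_FIELD_PARAMETERS:
        for s, b in motor.items():
            beta[(param, s)] = 0.9 * b
    for s, b in motor.items():
        beta[("mRS", s)] = b  # latent deficit for thresholded mRS

    noise_sd = {p: noise_fraction * abs(v) if v else 0.0 for p, v in baseline.items()}
    noise_sd["mRS"] = 0.02
    halflife = {p: 7.0 for p in baseline}
    return OutcomeModel(
        baseline=baseline,
        units=units,
        limb=limb,
        beta=beta,
        noise_sd=noise_sd,
        recovery_halflife_days=halflife,
    )


def generate_outcomes(
    cohort_pos: pd.DataFrame,
    model: OutcomeModel,
    timepoints: Sequence[float],
    seed: int = 0,
) -> pd.DataFrame:
    """Tidy longitudinal outcome table from per-subject structure damage.

    ``cohort_pos`` is long-form with columns ``subject_id, group,
    structure_name, pos_percent``; non-stroked subjects simply carry zero
    (or no) PoS rows. Negative timepoints are pre-stroke and carry no
    deficit. Returns columns ``subject_id, group, timepoint_day, limb,
    parameter, value, units``.
    """
    required = {"subject_id", "group", "structure_name", "pos_percent"}
    if not required.issubset(cohort_pos.columns):
        raise ValueError(f"cohort_pos must have columns {sorted(required)}")
    catalog = {f"{n}_{side}" for n, _ in STRUCTURE_CATALOG for side in ("r", "l")}
    model.validate(known_structures=set(cohort_pos["structure_name"]) | catalog)

    pos_wide = (
        cohort_pos.pivot_table(
            index="subject_id", columns="structure_name", values="pos_percent", aggfunc="first"
        )
        .fillna(0.0)
    )
    groups = cohort_pos.drop_duplicates("subject_id").set_index("subject_id")["group"]

    records = []
    for si, subject in enumerate(sorted(pos_wide.index)):
        rng = np.random.default_rng([seed, si])  # one generator per subject
        pos = pos_wide.loc[subject]
        for param, base in model.baseline.items():
            D = sum(
                b * pos.get(s, 0.0) / 100.0
                for (p, s), b in model.beta.items()
                if p == param
            )
            half = model.recovery_halflife_days.get(param, 7.0)
            sd = model.noise_sd.get(param, 0.0)
            for t in timepoints:
                deficit = 0.0 if t < 0 else D * 2.0 ** (-t / half)
                eps = rng.normal(0.0, sd) if sd > 0 else 0.0
                if param == "mRS":
                    latent = deficit + eps
                    value = float(
                        np.clip(sum(latent > th for th in model.mrs_thresholds), 0, 6)
                    )
                else:
                    value = base * (1.0 - deficit) + eps
                records.append(
                    (
                        subject,
                        groups.loc[subject],
                        float(t),
                        model.limb.get(param, "NA"),
                        param,
                        value,
                        model.units.get(param, ""),
                    )
                )
    return pd.DataFrame(
        records,
        columns=["subject_id", "group", "timepoint_day", "limb", "parameter", "value", "units"],
    )


# --------------------------------------------------------------------------
# cohort-level damage sampler
# --------------------------------------------------------------------------


@dataclass
class CoverageSampler:
    """Per-structure lesion presence/extent sampler for stroked subjects.

    For each structure: presence ~ Bernoulli(presence_prob); if present,
    coverage ~ Beta with the stated mean and concentration. The joint
    distribution of damage across subjects is not published, so independent
    per-structure draws are used (documented model choice).
    """

    presence_prob: dict[str, float]
    mean_coverage: dict[str, float]
    concentration: float = 4.0

    def sample(self, rng: np.random.Generator) -> dict[str, float]:
        out = {}
        for name, p in self.presence_prob.items():
            if rng.uniform() < p:
                m = self.mean_coverage[name]
                a = m * self.concentration
                b = (1 - m) * self.concentration
                out[name] = float(np.clip(rng.beta(a, b), 0.0, 1.0))
            else:
                out[name] = 0.0
        return out


def default_coverage_sampler(atlas: PhantomAtlas) -> CoverageSampler:
    """MCA-territory-style damage profile over the atlas's ipsilateral
    structures: near-certain heavy damage in claustrum/insula/temporal
    cortex, frequent moderate damage in the striatum and somatosensory
    cortex, tapering off elsewhere."""
    profile = {
        "claustrum_r": (1.00, 0.66),
        "inferior_temporal_gyrus_r": (1.00, 0.62),
        "superior_temporal_gyrus_r": (1.00, 0.59),
        "insular_cortex_r": (1.00, 0.54),
        "middle_temporal_gyrus_r": (0.857, 0.44),
        "putamen_r": (1.00, 0.44),
        "somatosensory_association_cortex_r": (0.857, 0.43),
        "secondary_visual_cortex_r": (1.00, 0.41),
        "globus_pallidus_r": (0.714, 0.35),
        "primary_somatosensory_cortex_r": (0.714, 0.33),
    }
    names = set(atlas.lookup.loc[atlas.lookup["hemisphere"] == "right", "name"])
    names -= set(atlas.lookup.loc[atlas.lookup["is_ventricle"], "name"])
    presence, mean = {}, {}
    for i, name in enumerate(sorted(names)):
        if name in profile:
            presence[name], mean[name] = profile[name]
        else:
            presence[name], mean[name] = 0.5, 0.20
    return CoverageSampler(presence_prob=presence, mean_coverage=mean)


def sample_cohort_pos(
    atlas: PhantomAtlas,
    sampler: CoverageSampler,
    n_stroked: int,
    n_control: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a cohort's per-structure PoS table without voxelizing lesions.

    A sampled coverage fraction equals the PoS that the voxel pipeline
    would measure (up to one voxel of rounding), so this fast path is the
    right input for outcome-model and correlation calibration studies.
    """
    rows = []
    for i in range(n_stroked):
        rng = np.random.default_rng([seed, i])
        cov = sampler.sample(rng)
        for name, frac in cov.items():
            rows.append((f"mcao_{i:02d}", "MCAO", name, 100.0 * frac))
    for i in range(n_control):
        for name in sampler.presence_prob:
            rows.append((f"ctrl_{i:02d}", "control", name, 0.0))
    return pd.DataFrame(rows, columns=["subject_id", "group", "structure_name", "pos_percent"])
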