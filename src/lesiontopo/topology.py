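"""Per-structure lesion burden against a parcellation atlas.

The two lesion-topology scores are voxel-overlap ratios against the atlas:

    PoS(X) = 100 * |lesion ∩ X| / |X|        (percent of structure lesioned)
    PoL(X) = 100 * |lesion ∩ X| / |lesion|   (percent of lesion inside X)

Atlas labels are mutually exclusive, so summing PoL over all structures plus
the unlabeled-lesion fraction is exactly 100%. Incidence counts how many
subjects have at least a threshold number of lesion voxels in a structure.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .grid import LabelAtlas, VolumeGrid

__all__ = [
    "structure_overlap",
    "lesion_incidence",
    "rank_structures",
    "unlabeled_lesion_percent",
    "format_incidence_table",
]

OVERLAP_COLUMNS = [
    "structure_id",
    "structure_name",
    "n_lesion_overlap_voxels",
    "n_structure_voxels",
    "n_lesion_voxels",
    "pos_percent",
    "pol_percent",
]


def _pair_base_name(name: str) -> str:
    for suffix in ("_r", "_l"):
        if name.endswith(suffix):
            return name[: -len(suffix)]
    return name


def structure_overlap(
    atlas: LabelAtlas,
    lesion: VolumeGrid,
    merge_pairs: bool = False,
    include_special: bool = False,
) -> pd.DataFrame:
    """PoS/PoL record per structure for one lesion mask.

    With ``merge_pairs`` the bilateral partners share one record (denominator
    = both labels' voxels). Ventricle and cerebellum labels are skipped
    unless ``include_special``. Structures with zero voxels in the atlas are
    omitted with a warning.
    """
    if not atlas.grid.same_grid(lesion):
        raise ValueError("atlas and lesion mask are not on the same grid")
    lesion_arr = lesion.require_binary("lesion")
    labels = atlas.grid.data
    n_lesion = int(lesion_arr.sum())

    max_label = int(max(labels.max(), atlas.lookup["label_id"].max()))
    count_all = np.bincount(labels.ravel(), minlength=max_label + 1)
    count_overlap = np.bincount(labels[lesion_arr].ravel(), minlength=max_label + 1)

    lk = atlas.lookup
    if not include_special:
        lk = lk.loc[~(lk["is_ventricle"] | lk["is_cerebellum"])]

    rows = []
    if merge_pairs:
        seen: set[int] = set()
        for _, row in lk.iterrows():
            lid, pid = int(row["label_id"]), int(row["partner_id"])
            if lid in seen:
                continue
            ids = [lid] + ([pid] if pid > 0 and pid in set(lk["label_id"]) else [])
            seen.update(ids)
            n_struct = int(sum(count_all[i] for i in ids))
            n_over = int(sum(count_overlap[i] for i in ids))
            name = _pair_base_name(str(row["name"])) if len(ids) > 1 else str(row["name"])
            rows.append((min(ids), name, n_over, n_struct, n_lesion))
    else:
        for _, row in lk.iterrows():
            lid = int(row["label_id"])
            rows.append(
                (lid, str(row["name"]), int(count_overlap[lid]), int(count_all[lid]), n_lesion)
            )

    df = pd.DataFrame(
        rows,
        columns=["structure_id", "structure_name", "n_lesion_overlap_voxels",
                 "n_structure_voxels", "n_lesion_voxels"],
    )
    empty = df["n_structure_voxels"] == 0
    if empty.any():
        warnings.warn(
            f"omitting {int(empty.sum())} structure(s) with zero atlas voxels: "
            f"{df.loc[empty, 'structure_name'].tolist()}",
            stacklevel=2,
        )
        df = df.loc[~empty].reset_index(drop=True)
    df["pos_percent"] = 100.0 * df["n_lesion_overlap_voxels"] / df["n_structure_voxels"]
    df["pol_percent"] = np.where(
        df["n_lesion_voxels"] > 0,
        100.0 * df["n_lesion_overlap_voxels"] / df["n_lesion_voxels"].replace(0, 1),
        0.0,
    )
    return df[OVERLAP_COLUMNS]


def unlabeled_lesion_percent(overlap: pd.DataFrame) -> float:
    """Percent of lesion voxels falling outside every scored structure."""
    if overlap.empty or overlap["n_lesion_voxels"].iloc[0] == 0:
        return 0.0
    return 100.0 - float(overlap["pol_percent"].sum())


def lesion_incidence(
    cohort_overlap: pd.DataFrame,
    threshold_voxels: int = 1,
) -> pd.DataFrame:
    """Percent of subjects with lesion in each structure, per timepoint.

    ``cohort_overlap`` is a concatenation of per-subject overlap tables with
    ``subject_id`` and ``timepoint_day`` columns added. A subject counts as
    lesioned in a structure iff its overlap voxel count >= threshold.
    Incidence percents are rounded to one decimal for reporting.
    """
    if threshold_voxels < 1:
        raise ValueError("threshold_voxels must be >= 1")
    needed = {"subject_id", "timepoint_day", "structure_name", "n_lesion_overlap_voxels"}
    if not needed.issubset(cohort_overlap.columns):
        raise ValueError(f"cohort overlap table needs columns {sorted(needed)}")

    df = cohort_overlap.copy()
    df["lesioned"] = df["n_lesion_overlap_voxels"] >= threshold_voxels
    grp = df.groupby(["structure_name", "timepoint_day"], as_index=False).agg(
        n_subjects_lesioned=("lesioned", "sum"),
        n_subjects_total=("subject_id", "nunique"),
    )
    grp["incidence_percent"] = (
        100.0 * grp["n_subjects_lesioned"] / grp["n_subjects_total"]
    ).round(1)
    return grp


def format_incidence_table(
    incidence: pd.DataFrame,
    lookup: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Report-style wide incidence table: one row per structure, one column
    per timepoint, zero incidence rendered as an en dash, with a leading
    region-group column when an atlas lookup is supplied."""
    wide = incidence.pivot(
        index="structure_name", columns="timepoint_day", values="incidence_percent"
    )
    wide.columns = [f"incidence_{c:g}d_percent" for c in wide.columns]
    out = wide.map(lambda v: "–" if v == 0 else f"{v:.1f}").reset_index()
    if lookup is not None:
        groups = lookup.set_index("name")["region_group"]
        out.insert(0, "region_group", out["structure_name"].map(groups))
        out = out.sort_values(["region_group", "structure_name"]).reset_index(drop=True)
    return out


def rank_structures(
    cohort_overlap: pd.DataFrame,
    by: str = "pos",
    top_n: int | None = None,
) -> pd.DataFrame:
    """Structures ordered by descending cohort-mean PoS or PoL.

    Ties are broken alphabetically by structure name so the ranking is
    deterministic. Returns columns ``structure_name, mean, sd, n``.
    """
    col = {"pos": "pos_percent", "pol": "pol_percent"}.get(by)
    if col is None:
        raise ValueError("by must be 'pos' or 'pol'")
    if cohort_overlap.empty:
        return pd.DataFrame(columns=["structure_name", "mean", "sd", "n"])
    agg = (
        cohort_overlap.groupby("structure_name")[col]
        .agg(mean="mean", sd="std", n="count")
        .reset_index()
    )
    agg = agg.sort_values(
        ["mean", "structure_name"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    if top_n is not None:
        agg = agg.head(top_n)
    return agg
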