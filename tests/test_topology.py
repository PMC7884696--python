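"""PoS/PoL overlap scoring against brute-force voxel loops, plus incidence
and ranking behavior."""

import numpy as np
import pandas as pd
import pytest

from lesiontopo.grid import LabelAtlas, VolumeGrid
from lesiontopo.topology import (
    lesion_incidence,
    rank_structures,
    structure_overlap,
    unlabeled_lesion_percent,
)


def _toy_atlas(labels, spacing=(1.0, 1.0, 1.0)):
    ids = sorted(set(np.unique(labels)) - {0})
    lookup = pd.DataFrame(
        {
            "label_id": ids,
            "name": [f"s{i}" for i in ids],
            "region_group": "g",
            "hemisphere": "right",
            "partner_id": -1,
            "is_ventricle": False,
            "is_cerebellum": False,
        }
    )
    return LabelAtlas(VolumeGrid(np.asarray(labels, dtype=np.int32),
                                 np.diag([*spacing, 1.0])), lookup)


def _triple_loop_counts(labels, lesion, max_label):
    """Literal three-nested-loop voxel counting oracle."""
    n_struct = [0] * (max_label + 1)
    n_over = [0] * (max_label + 1)
    nx, ny, nz = labels.shape
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                lab = labels[i, j, k]
                n_struct[lab] += 1
                if lesion[i, j, k]:
                    n_over[lab] += 1
    return n_struct, n_over


def test_overlap_hand_example():
    """13 of 20 structure voxels lesioned, lesion 100 voxels total."""
    labels = np.zeros((10, 10, 10), dtype=np.int32)
    labels.ravel()[:20] = 1
    lesion = np.zeros((10, 10, 10), dtype=bool)
    lesion.ravel()[7:107] = True  # covers 13 structure voxels
    df = structure_overlap(_toy_atlas(labels), VolumeGrid(lesion, np.eye(4)))
    row = df.iloc[0]
    assert row["n_lesion_overlap_voxels"] == 13
    assert row["pos_percent"] == pytest.approx(65.0)
    assert row["pol_percent"] == pytest.approx(13.0)


def test_lesion_identical_to_structure():
    labels = np.zeros((6, 6, 6), dtype=np.int32)
    labels[2:4, 2:4, 2:4] = 1
    df = structure_overlap(_toy_atlas(labels), VolumeGrid(labels == 1, np.eye(4)))
    assert df["pos_percent"].iloc[0] == 100.0
    assert df["pol_percent"].iloc[0] == 100.0


def test_empty_lesion_all_zero(small_atlas):
    lesion = VolumeGrid(np.zeros(small_atlas.grid.shape, dtype=bool), small_atlas.grid.affine)
    df = structure_overlap(small_atlas, lesion)
    assert (df["pos_percent"] == 0).all()
    assert (df["pol_percent"] == 0).all()


def test_grid_mismatch_rejected(small_atlas):
    lesion = VolumeGrid(np.zeros((4, 4, 4), dtype=bool), np.eye(4))
    with pytest.raises(ValueError, match="same grid"):
        structure_overlap(small_atlas, lesion)


def test_overlap_matches_triple_loop_on_random_phantoms(rng):
    for _ in range(10):
        shape = tuple(rng.integers(8, 17, 3))
        labels = rng.integers(0, 5, shape).astype(np.int32)
        lesion = rng.random(shape) > 0.6
        df = structure_overlap(_toy_atlas(labels), VolumeGrid(lesion, np.eye(4)))
        n_struct, n_over = _triple_loop_counts(labels, lesion, 4)
        for _, row in df.iterrows():
            lid = int(row["structure_id"])
            assert row["n_structure_voxels"] == n_struct[lid]
            assert row["n_lesion_overlap_voxels"] == n_over[lid]


def test_pol_conservation_sums_to_100(rng):
    """Labels are exclusive, so sum(PoL) + unlabeled fraction = 100 exactly."""
    shape = (12, 12, 12)
    labels = rng.integers(0, 4, shape).astype(np.int32)
    lesion = rng.random(shape) > 0.5
    df = structure_overlap(_toy_atlas(labels), VolumeGrid(lesion, np.eye(4)))
    assert df["pol_percent"].sum() + unlabeled_lesion_percent(df) == pytest.approx(
        100.0, abs=1e-9
    )


def test_overlap_monotone_in_lesion_voxels(rng):
    """Adding a lesion voxel inside structure X never decreases PoS or PoL."""
    shape = (10, 10, 10)
    labels = np.zeros(shape, dtype=np.int32)
    labels[:5] = 1
    atlas = _toy_atlas(labels)
    lesion = rng.random(shape) > 0.7
    base = structure_overlap(atlas, VolumeGrid(lesion, np.eye(4))).iloc[0]
    inside = np.argwhere((labels == 1) & ~lesion)
    i, j, k = inside[0]
    lesion2 = lesion.copy()
    lesion2[i, j, k] = True
    new = structure_overlap(atlas, VolumeGrid(lesion2, np.eye(4))).iloc[0]
    assert new["pos_percent"] >= base["pos_percent"]
    assert new["pol_percent"] >= base["pol_percent"]


def test_merge_pairs_pools_bilateral_denominator(small_atlas):
    rid = int(
        small_atlas.lookup.loc[
            (small_atlas.lookup["hemisphere"] == "right")
            & ~small_atlas.lookup["is_ventricle"], "label_id"
        ].iloc[0]
    )
    pid = int(small_atlas.lookup.set_index("label_id").loc[rid, "partner_id"])
    lesion = VolumeGrid(small_atlas.mask_of(rid), small_atlas.grid.affine)
    uni = structure_overlap(small_atlas, lesion, merge_pairs=False)
    mrg = structure_overlap(small_atlas, lesion, merge_pairs=True)
    n_r = int(uni.set_index("structure_id").loc[rid, "n_structure_voxels"])
    n_l = int(uni.set_index("structure_id").loc[pid, "n_structure_voxels"])
    merged_row = mrg.loc[mrg["structure_id"] == min(rid, pid)].iloc[0]
    assert merged_row["n_structure_voxels"] == n_r + n_l
    assert merged_row["pos_percent"] == pytest.approx(100.0 * n_r / (n_r + n_l))


def test_zero_voxel_structures_omitted_with_warning():
    labels = np.zeros((6, 6, 6), dtype=np.int32)
    labels[0, 0, 0] = 1
    atlas = _toy_atlas(labels)
    atlas.lookup = pd.concat(
        [atlas.lookup, atlas.lookup.assign(label_id=9, name="ghost")],
        ignore_index=True,
    )
    with pytest.warns(UserWarning, match="zero atlas voxels"):
        df = structure_overlap(atlas, VolumeGrid(labels == 1, np.eye(4)))
    assert "ghost" not in set(df["structure_name"])


# ---------------------------------------------------------------- incidence


def _cohort_overlap(lesioned_counts: dict[str, int], n_subjects: int = 7):
    rows = []
    for s in range(n_subjects):
        for name, k in lesioned_counts.items():
            rows.append(
                {
                    "subject_id": f"p{s}",
                    "timepoint_day": 1.0,
                    "structure_name": name,
                    "n_lesion_overlap_voxels": 5 if s < k else 0,
                }
            )
    return pd.DataFrame(rows)


@pytest.mark.parametrize(
    "k,expected",
    [(1, 14.3), (2, 28.6), (3, 42.9), (4, 57.1), (5, 71.4), (6, 85.7), (7, 100.0)],
)
def test_incidence_k_of_seven_lattice(k, expected):
    inc = lesion_incidence(_cohort_overlap({"claustrum": k}))
    assert inc["incidence_percent"].iloc[0] == expected


def test_incidence_zero_of_seven():
    inc = lesion_incidence(_cohort_overlap({"claustrum": 0}))
    assert inc["incidence_percent"].iloc[0] == 0.0


def test_incidence_respects_voxel_threshold():
    df = _cohort_overlap({"claustrum": 7})  # all 7 have 5 voxels
    assert lesion_incidence(df, threshold_voxels=5)["incidence_percent"].iloc[0] == 100.0
    assert lesion_incidence(df, threshold_voxels=6)["incidence_percent"].iloc[0] == 0.0


# ---------------------------------------------------------------- ranking


def test_rank_structures_descending_with_name_ties():
    df = pd.DataFrame(
        {
            "structure_name": ["a", "b", "c", "a", "b", "c"],
            "pos_percent": [65.91, 62.15, 44.0, 65.91, 62.15, 44.0],
            "pol_percent": [1.0] * 6,
        }
    )
    top2 = rank_structures(df, by="pos", top_n=2)
    assert list(top2["structure_name"]) == ["a", "b"]
    full = rank_structures(df, by="pos", top_n=99)
    assert list(full["structure_name"]) == ["a", "b", "c"]


def test_rank_structures_matches_brute_force_sort(rng):
    names = [f"s{i}" for i in range(8)]
    df = pd.DataFrame(
        {
            "structure_name": names * 5,
            "pos_percent": rng.random(40) * 100,
            "pol_percent": rng.random(40) * 100,
        }
    )
    ranked = rank_structures(df, by="pol")
    means = {n: df.loc[df["structure_name"] == n, "pol_percent"].mean() for n in names}
    expected = sorted(names, key=lambda n: (-means[n], n))
    assert list(ranked["structure_name"]) == expected


def test_rank_structures_empty_and_bad_key():
    assert rank_structures(pd.DataFrame(columns=["structure_name", "pos_percent", "pol_percent"])).empty
    with pytest.raises(ValueError):
        rank_structures(pd.DataFrame(), by="volume")


def test_format_incidence_table_wide_layout():
    inc = lesion_incidence(
        pd.concat(
            [_cohort_overlap({"claustrum": 7, "fornix": 0}),
             _cohort_overlap({"claustrum": 2, "fornix": 0}).assign(timepoint_day=28.0)]
        )
    )
    lookup = pd.DataFrame(
        {"name": ["claustrum", "fornix"],
         "region_group": ["striate_system", "limbic_system"]}
    )
    from lesiontopo.topology import format_incidence_table

    wide = format_incidence_table(inc, lookup)
    assert list(wide.columns) == [
        "region_group", "structure_name", "incidence_1d_percent", "incidence_28d_percent",
    ]
    row = wide.set_index("structure_name")
    assert row.loc["claustrum", "incidence_1d_percent"] == "100.0"
    assert row.loc["claustrum", "incidence_28d_percent"] == "28.6"
    assert row.loc["fornix", "incidence_1d_percent"] == "–"
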