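"""Ground-truth properties of the synthetic phantom generator."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

from lesiontopo.phantom import (
    LesionSpec,
    OutcomeModel,
    PhantomConfig,
    SwellingSpec,
    default_coverage_sampler,
    default_outcome_model,
    generate_atlas,
    generate_fa_map,
    generate_outcomes,
    generate_subject,
    sample_cohort_pos,
)
from lesiontopo.volumetrics import midline_shift


# ---------------------------------------------------------------- atlas


def test_atlas_label_bookkeeping(atlas):
    lk = atlas.lookup
    n = 10
    paired = lk.loc[~(lk["is_ventricle"] | lk["is_cerebellum"])]
    assert len(paired) == 2 * n
    assert lk["is_ventricle"].sum() == 2
    assert lk["is_cerebellum"].sum() == 1
    # every paired structure's partner points back
    by_id = lk.set_index("label_id")
    for lid, row in by_id.iterrows():
        if row["partner_id"] > 0:
            assert by_id.loc[row["partner_id"], "partner_id"] == lid


def test_atlas_deterministic_for_fixed_seed():
    a = generate_atlas(PhantomConfig(seed=5))
    b = generate_atlas(PhantomConfig(seed=5))
    assert np.array_equal(a.grid.data, b.grid.data)
    pd.testing.assert_frame_equal(a.lookup, b.lookup)
    c = generate_atlas(PhantomConfig(seed=6))
    assert not np.array_equal(a.grid.data, c.grid.data)


def test_paired_structures_mirror_across_midline(atlas):
    """Brute-force reflection: flipping voxel i -> nx-1-i about the midline
    must carry each right label onto its left partner (>=95% of voxels)."""
    lab = atlas.grid.data
    flipped = lab[::-1, :, :]
    for _, row in atlas.lookup.iterrows():
        pid = row["partner_id"]
        if pid <= 0:
            continue
        mask = lab == row["label_id"]
        assert mask.sum() > 0
        frac = (flipped[mask] == pid).mean()
        assert frac >= 0.95


def test_all_labels_spatially_connected(atlas):
    lab = atlas.grid.data
    for lid in atlas.lookup["label_id"]:
        _, n_comp = ndimage.label(lab == lid)
        assert n_comp == 1, f"label {lid} split into {n_comp} components"


def test_labels_partition_voxels(atlas):
    """Every voxel carries exactly one label or background (by construction
    of a single integer volume), and all lookup labels are present."""
    present = set(np.unique(atlas.grid.data)) - {0}
    assert present == set(atlas.lookup["label_id"])


def test_config_validation():
    with pytest.raises(ValueError, match=">= 16"):
        PhantomConfig(grid_shape=(8, 32, 32)).validate()
    with pytest.raises(ValueError, match="ventricle_fraction"):
        PhantomConfig(ventricle_fraction=0.5).validate()


# ---------------------------------------------------------------- subject


def test_full_coverage_gives_full_structure_lesion(atlas):
    sid = int(atlas.lookup.loc[atlas.lookup["hemisphere"] == "right", "label_id"].iloc[0])
    subj = generate_subject(atlas, LesionSpec(target_coverage={sid: 1.0}), SwellingSpec())
    smask = atlas.mask_of(sid)
    assert (subj.lesion.data & smask).sum() == smask.sum()
    assert subj.ground_truth["achieved_coverage"][sid] == 1.0


def test_null_lesion_spec_gives_empty_mask(atlas):
    subj = generate_subject(atlas, LesionSpec(), SwellingSpec())
    assert subj.lesion.data.sum() == 0
    assert subj.ground_truth["lesion_volume_cm3"] == 0.0


def test_coverage_out_of_range_rejected(atlas):
    sid = int(atlas.lookup["label_id"].iloc[0])
    with pytest.raises(ValueError, match=r"\[0, 1\]"):
        generate_subject(atlas, LesionSpec(target_coverage={sid: 1.2}), SwellingSpec())


def test_contralateral_structure_rejected(atlas):
    left = int(atlas.lookup.loc[atlas.lookup["hemisphere"] == "left", "label_id"].iloc[0])
    with pytest.raises(ValueError, match="ipsilateral"):
        generate_subject(atlas, LesionSpec(target_coverage={left: 0.5}), SwellingSpec())


def test_lesion_confined_to_ipsilateral_hemisphere(atlas):
    rids = atlas.lookup.loc[
        (atlas.lookup["hemisphere"] == "right") & ~atlas.lookup["is_ventricle"], "label_id"
    ]
    spec = LesionSpec(target_coverage={int(i): 0.7 for i in rids})
    subj = generate_subject(atlas, spec, SwellingSpec())
    nx = atlas.grid.shape[0]
    assert not subj.lesion.data[: nx // 2].any()


@pytest.mark.parametrize("frac", [0.1, 0.33, 0.5, 0.77])
def test_achieved_coverage_within_one_voxel(atlas, frac):
    rows = atlas.lookup.loc[
        (atlas.lookup["hemisphere"] == "right") & ~atlas.lookup["is_ventricle"]
    ]
    spec = LesionSpec(target_coverage={int(i): frac for i in rows["label_id"]})
    subj = generate_subject(atlas, spec, SwellingSpec())
    for sid in spec.target_coverage:
        n = int(atlas.mask_of(sid).sum())
        got = (subj.lesion.data & atlas.mask_of(sid)).sum()
        assert abs(got - frac * n) <= 1.0


@pytest.mark.parametrize("pct", [15.0, -10.0, 0.0])
def test_swelling_gives_exact_volume_ratio(atlas, pct):
    subj = generate_subject(atlas, LesionSpec(), SwellingSpec(volume_change_percent=pct))
    ipsi = (subj.hemisphere_ipsi.data & ~subj.ventricle_ipsi.data).sum()
    contra = (subj.hemisphere_contra.data & ~subj.ventricle_contra.data).sum()
    # within one voxel-equivalent of the net contralateral volume
    assert abs(ipsi - contra * (1 + pct / 100)) <= 1.0


@pytest.mark.parametrize("shift", [-3.3, -1.99, 0.0, 1.57, 3.0])
def test_midline_shift_round_trip_within_in_plane_voxel(atlas, shift):
    subj = generate_subject(atlas, LesionSpec(), SwellingSpec(midline_shift_mm=shift))
    measured = midline_shift(subj.landmarks)
    assert abs(measured - shift) <= atlas.grid.spacing[0]


def test_subject_deterministic(atlas):
    sid = int(atlas.lookup.loc[atlas.lookup["hemisphere"] == "right", "label_id"].iloc[0])
    spec = LesionSpec(target_coverage={sid: 0.4})
    sw = SwellingSpec(midline_shift_mm=1.5, volume_change_percent=12.0)
    a = generate_subject(atlas, spec, sw, seed=3)
    b = generate_subject(atlas, spec, sw, seed=3)
    assert np.array_equal(a.lesion.data, b.lesion.data)
    assert np.array_equal(a.hemisphere_ipsi.data, b.hemisphere_ipsi.data)


# ---------------------------------------------------------------- FA


def test_fa_no_decrement_no_noise_symmetric(atlas):
    fa, rois = generate_fa_map(atlas, tract_decrement=0.0, noise_sd=0.0)
    ipsi = fa.data[rois["ipsi"].data.astype(bool)]
    contra = fa.data[rois["contra"].data.astype(bool)]
    assert ipsi.mean() == contra.mean()


def test_fa_decrement_arithmetic(atlas):
    fa, rois = generate_fa_map(
        atlas, tract_decrement=0.30, noise_sd=0.0, baseline_fa=0.45
    )
    ipsi = fa.data[rois["ipsi"].data.astype(bool)]
    assert ipsi.mean() == pytest.approx(0.315)


def test_fa_decrement_recovered_under_noise(atlas):
    """Monte-Carlo: the implied decrement from noisy ROI means averages to
    the specified value within 0.02 over 100 seeds."""
    est = []
    for seed in range(100):
        fa, rois = generate_fa_map(atlas, tract_decrement=0.30, noise_sd=0.05, seed=seed)
        ipsi = fa.data[rois["ipsi"].data.astype(bool)].mean()
        contra = fa.data[rois["contra"].data.astype(bool)].mean()
        est.append(1.0 - ipsi / contra)
    assert abs(np.mean(est) - 0.30) < 0.02


def test_fa_rejects_bad_decrement(atlas):
    with pytest.raises(ValueError):
        generate_fa_map(atlas, tract_decrement=1.5, noise_sd=0.0)


# ---------------------------------------------------------------- outcomes


def _pos_table():
    return pd.DataFrame(
        {
            "subject_id": ["s1", "s1", "s2"],
            "group": ["MCAO", "MCAO", "control"],
            "structure_name": ["putamen_r", "claustrum_r", "putamen_r"],
            "pos_percent": [40.0, 80.0, 0.0],
        }
    )


def test_outcomes_zero_beta_zero_noise_equal_baseline():
    model = default_outcome_model(noise_fraction=0.0)
    model.beta = {}
    model.noise_sd = {p: 0.0 for p in model.baseline}
    out = generate_outcomes(_pos_table(), model, [-1, 2, 8], seed=0)
    for param, base in model.baseline.items():
        vals = out.loc[out["parameter"] == param, "value"]
        assert np.allclose(vals, base if param != "mRS" else 0.0)


def test_outcome_deficit_arithmetic():
    """baseline 198.78 with total damage fraction 0.64 at t=0 -> 71.56."""
    model = OutcomeModel(
        baseline={"velocity": 198.78},
        units={"velocity": "cm/s"},
        limb={"velocity": "LF"},
        beta={("velocity", "putamen_r"): 0.8},
        noise_sd={"velocity": 0.0},
        recovery_halflife_days={"velocity": 7.0},
    )
    pos = pd.DataFrame(
        {"subject_id": ["s1"], "group": ["MCAO"],
         "structure_name": ["putamen_r"], "pos_percent": [80.0]}
    )
    out = generate_outcomes(pos, model, [0.0], seed=0)
    assert out["value"].iloc[0] == pytest.approx(198.78 * (1 - 0.64))


def test_outcome_deficit_halves_at_halflife():
    model = OutcomeModel(
        baseline={"velocity": 100.0}, units={}, limb={},
        beta={("velocity", "putamen_r"): 0.5},
        noise_sd={"velocity": 0.0},
        recovery_halflife_days={"velocity": 7.0},
    )
    pos = pd.DataFrame(
        {"subject_id": ["s1"], "group": ["MCAO"],
         "structure_name": ["putamen_r"], "pos_percent": [100.0]}
    )
    out = generate_outcomes(pos, model, [0.0, 7.0], seed=0).set_index("timepoint_day")
    d0 = 1 - out.loc[0.0, "value"] / 100.0
    d7 = 1 - out.loc[7.0, "value"] / 100.0
    assert d7 == pytest.approx(d0 / 2)


def test_outcomes_controls_and_prestroke_undamaged():
    model = default_outcome_model(noise_fraction=0.0)
    model.noise_sd = {p: 0.0 for p in model.baseline}
    out = generate_outcomes(_pos_table(), model, [-1.0, 2.0], seed=0)
    ctrl = out.loc[out["group"] == "control"]
    for param, base in model.baseline.items():
        expected = 0.0 if param == "mRS" else base
        assert np.allclose(ctrl.loc[ctrl["parameter"] == param, "value"], expected)
    pre = out.loc[(out["group"] == "MCAO") & (out["timepoint_day"] < 0)]
    assert np.allclose(
        pre.loc[pre["parameter"] == "velocity", "value"], model.baseline["velocity"]
    )


def test_outcomes_unknown_structure_in_beta_rejected():
    model = default_outcome_model()
    model.beta[("velocity", "not_a_structure")] = 1.0
    with pytest.raises(ValueError, match="unknown structure"):
        generate_outcomes(_pos_table(), model, [2.0], seed=0)


def test_outcomes_deterministic():
    model = default_outcome_model()
    a = generate_outcomes(_pos_table(), model, [-1, 2, 8], seed=9)
    b = generate_outcomes(_pos_table(), model, [-1, 2, 8], seed=9)
    pd.testing.assert_frame_equal(a, b)


def test_mrs_thresholding_scale():
    model = default_outcome_model(noise_fraction=0.0)
    model.noise_sd = {p: 0.0 for p in model.baseline}
    out = generate_outcomes(_pos_table(), model, [0.0, 27.0], seed=0)
    mrs = out.loc[out["parameter"] == "mRS"]
    assert mrs["value"].between(0, 6).all()
    assert (mrs["value"] % 1 == 0).all()
    s1 = mrs.loc[mrs["subject_id"] == "s1"].set_index("timepoint_day")["value"]
    assert s1.loc[0.0] >= s1.loc[27.0]  # disability recovers


# ---------------------------------------------------------------- sampler


def test_cohort_pos_sampler_shapes_and_determinism(atlas):
    sampler = default_coverage_sampler(atlas)
    a = sample_cohort_pos(atlas, sampler, n_stroked=4, n_control=2, seed=5)
    b = sample_cohort_pos(atlas, sampler, n_stroked=4, n_control=2, seed=5)
    pd.testing.assert_frame_equal(a, b)
    assert set(a["group"]) == {"MCAO", "control"}
    assert (a.loc[a["group"] == "control", "pos_percent"] == 0).all()
    assert a["pos_percent"].between(0, 100).all()
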