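"""End-to-end wiring: phantom cohort -> volumetrics -> topology -> white
matter -> outcome statistics -> correlation heatmaps.

``simulate_cohort`` realizes a study-like cohort (default 7 stroked + 5
control subjects, acute day-1 and chronic day-28 imaging) in memory;
``write_cohort`` serializes it (NIfTI volumes, lookup/outcome CSVs,
ground-truth JSON sidecars); ``analyze_cohort`` runs every analysis stage
and returns tidy tables; ``report`` condenses them into summary tables.
Each run can emit a manifest holding the seed, config and package version.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .correlation import build_feature_matrix, correlate, export_heatmap
from .phantom import (
    GAIT_PARAMETERS,
    LesionSpec,
    PhantomAtlas,
    PhantomConfig,
    SubjectImaging,
    SwellingSpec,
    default_coverage_sampler,
    default_outcome_model,
    generate_atlas,
    generate_fa_map,
    generate_outcomes,
    generate_subject,
)
from .stats import one_sample_t, paired_t, rm_anova_sidak
from .topology import lesion_incidence, rank_structures, structure_overlap
from .volumetrics import compute_volumetrics
from .white_matter import fa_asymmetry_test, fa_roi_result

__all__ = ["RunConfig", "Cohort", "simulate_cohort", "write_cohort", "analyze_cohort", "report"]


@dataclass
class RunConfig:
    """Study conditions for a simulated run; defaults mirror a small
    preclinical stroke cohort (7 stroked, 5 control, 3 mm slices)."""

    seed: int = 0
    n_stroked: int = 7
    n_control: int = 5
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    # imaging sessions: acute and chronic
    imaging_timepoint_days: tuple[float, ...] = (1.0, 28.0)
    # per-session pathology distributions: (mls_mean, mls_sd, swell_mean, swell_sd)
    pathology: dict[float, tuple[float, float, float, float]] = field(
        default_factory=lambda: {1.0: (1.57, 0.83, 15.17, 7.89), 28.0: (-1.99, 1.00, 3.2, 4.0)}
    )
    chronic_coverage_factor: float = 0.35  # lesion shrinkage by the chronic scan
    fa_decrement: dict[float, float] = field(default_factory=lambda: {1.0: 0.30, 28.0: 0.05})
    fa_decrement_sd: float = 0.08  # between-subject spread of the decrement
    fa_baseline_mean: float = 0.45
    fa_baseline_sd: float = 0.05
    fa_noise_sd: float = 0.05
    outcome_timepoints: tuple[float, ...] = (-1.0, 2.0, 8.0, 15.0, 27.0)
    outcome_noise_fraction: float = 0.10
    top_n_structures: int = 10
    min_lesioned: int = 3
    threshold_voxels: int = 1
    outcome_timepoint_days: tuple[float, ...] = (2.0, 8.0)
    limb: str = "LF"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["pathology"] = {str(k): list(v) for k, v in self.pathology.items()}
        d["fa_decrement"] = {str(k): v for k, v in self.fa_decrement.items()}
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "phantom" in raw:
            ph = dict(raw["phantom"])
            for key in ("grid_shape", "voxel_size_mm"):
                if key in ph:
                    ph[key] = tuple(ph[key])
            raw["phantom"] = PhantomConfig(**ph)
        for key in ("pathology", "fa_decrement"):
            if key in raw:
                raw[key] = {float(k): tuple(v) if isinstance(v, list) else v
                            for k, v in raw[key].items()}
        for key in ("imaging_timepoint_days", "outcome_timepoints", "outcome_timepoint_days"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class Cohort:
    config: RunConfig
    atlas: PhantomAtlas
    # subject_id -> timepoint_day -> imaging bundle
    imaging: dict[str, dict[float, SubjectImaging]]
    # subject_id -> timepoint_day -> (fa VolumeGrid, roi masks)
    fa: dict[str, dict[float, tuple]]
    cohort_pos: pd.DataFrame  # truth-level acute PoS per stroked subject
    outcomes: pd.DataFrame

    @property
    def stroked_subjects(self) -> list[str]:
        return sorted(self.imaging)


def simulate_cohort(config: RunConfig | None = None, seed: int | None = None) -> Cohort:
    """Generate the full synthetic cohort under the study conditions."""
    config = config or RunConfig()
    if seed is not None:
        config = dataclasses.replace(config, seed=seed)
    if config.n_stroked < 1:
        raise ValueError("n_stroked must be >= 1")
    phantom_cfg = dataclasses.replace(config.phantom, seed=config.seed)
    atlas = generate_atlas(phantom_cfg)
    sampler = default_coverage_sampler(atlas)
    name_to_id = dict(zip(atlas.lookup["name"], atlas.lookup["label_id"]))

    imaging: dict[str, dict[float, SubjectImaging]] = {}
    fa: dict[str, dict[float, tuple]] = {}
    pos_rows = []
    for i in range(config.n_stroked):
        sid = f"mcao_{i:02d}"
        rng = np.random.default_rng([config.seed, 1000 + i])
        coverage = sampler.sample(rng)
        imaging[sid] = {}
        fa[sid] = {}
        # MCA-territory blob centred mid-hemisphere; claims only unlabeled
        # tissue so per-structure coverage keeps its sampled ground truth
        geom = atlas.geometry
        cx0, cy0, cz0 = geom.cerebrum_center
        ax, ay, az = geom.cerebrum_semi
        blob_center = (
            geom.mid_x + 0.55 * ax + rng.normal(0, 0.03 * ax),
            cy0 + rng.normal(0, 0.05 * ay),
            cz0 + rng.normal(0, 0.05 * az),
        )
        size_jitter = float(np.clip(rng.normal(1.0, 0.12), 0.6, 1.4))
        blob_radii = tuple(
            r * size_jitter for r in (0.42 * ax, 0.72 * ay, 0.76 * az)
        )
        for tp in config.imaging_timepoint_days:
            acute_tp = tp == min(config.imaging_timepoint_days)
            factor = 1.0 if acute_tp else config.chronic_coverage_factor
            blob_scale = 1.0 if acute_tp else config.chronic_coverage_factor ** (1 / 3)
            spec = LesionSpec(
                target_coverage={
                    name_to_id[n]: f * factor for n, f in coverage.items() if f > 0
                },
                extra_ellipsoids=[
                    (blob_center, tuple(r * blob_scale for r in blob_radii))
                ],
                ellipsoids_avoid_structures=True,
            )
            mls_m, mls_sd, sw_m, sw_sd = config.pathology[tp]
            swelling = SwellingSpec(
                midline_shift_mm=float(rng.normal(mls_m, mls_sd)),
                volume_change_percent=float(rng.normal(sw_m, sw_sd)),
            )
            subj = generate_subject(atlas, spec, swelling, seed=config.seed)
            imaging[sid][tp] = subj
            fa[sid][tp] = generate_fa_map(
                atlas,
                tract_decrement=float(np.clip(
                    rng.normal(config.fa_decrement.get(tp, 0.0), config.fa_decrement_sd),
                    0.0, 0.9,
                )),
                noise_sd=config.fa_noise_sd,
                seed=int(rng.integers(2**31)),
                baseline_fa=float(np.clip(
                    rng.normal(config.fa_baseline_mean, config.fa_baseline_sd), 0.2, 0.8
                )),
            )
        acute = imaging[sid][min(config.imaging_timepoint_days)]
        for sid_struct, frac in acute.ground_truth["achieved_coverage"].items():
            pos_rows.append((sid, "MCAO", atlas.name_of(int(sid_struct)), 100.0 * frac))
    for i in range(config.n_control):
        for name in sampler.presence_prob:
            pos_rows.append((f"ctrl_{i:02d}", "control", name, 0.0))
    cohort_pos = pd.DataFrame(
        pos_rows, columns=["subject_id", "group", "structure_name", "pos_percent"]
    )
    outcomes = generate_outcomes(
        cohort_pos,
        default_outcome_model(config.outcome_noise_fraction),
        config.outcome_timepoints,
        seed=config.seed,
    )
    return Cohort(
        config=config, atlas=atlas, imaging=imaging, fa=fa,
        cohort_pos=cohort_pos, outcomes=outcomes,
    )


def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Serialize a cohort: atlas + per-subject NIfTI volumes, lookup CSV,
    outcomes CSV, and one ground-truth JSON sidecar per subject/timepoint."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.atlas.save(out / "atlas.nii.gz", out / "atlas_lookup.csv")
    cohort.outcomes.to_csv(out / "outcomes.csv", index=False)
    cohort.cohort_pos.to_csv(out / "cohort_pos_truth.csv", index=False)
    for sid, sessions in cohort.imaging.items():
        for tp, subj in sessions.items():
            base = out / f"{sid}_d{int(tp)}"
            subj.lesion.save(f"{base}_lesion.nii.gz")
            subj.hemisphere_ipsi.save(f"{base}_hemi_ipsi.nii.gz")
            subj.hemisphere_contra.save(f"{base}_hemi_contra.nii.gz")
            subj.ventricle_ipsi.save(f"{base}_vent_ipsi.nii.gz")
            subj.ventricle_contra.save(f"{base}_vent_contra.nii.gz")
            subj.cerebellum.save(f"{base}_cerebellum.nii.gz")
            fa_map, rois = cohort.fa[sid][tp]
            fa_map.save(f"{base}_fa.nii.gz")
            rois["ipsi"].save(f"{base}_cc_roi_ipsi.nii.gz")
            rois["contra"].save(f"{base}_cc_roi_contra.nii.gz")
            truth = dict(subj.ground_truth)
            truth["landmarks"] = {
                "septum_point": subj.landmarks.septum_point.tolist(),
                "plane_point": subj.landmarks.plane_point.tolist(),
                "plane_normal": subj.landmarks.plane_normal.tolist(),
            }
            with open(f"{base}_truth.json", "w") as fh:
                json.dump(truth, fh, indent=2)
    manifest = {
        "version": __version__,
        "seed": cohort.config.seed,
        "config": cohort.config.to_dict(),
    }
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(manifest["config"], sort_keys=True).encode()
    ).hexdigest()
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return out


def analyze_cohort(cohort: Cohort) -> dict:
    """Run every analysis stage on an in-memory cohort.

    Returns a dict of tidy DataFrames: ``volumetrics``, ``overlap``,
    ``incidence``, ``ranking_pos``/``ranking_pol`` (acute), ``fa_results``,
    ``fa_tests``, ``features`` and per-timepoint ``heatmap_cells``.
    """
    cfg = cohort.config
    vol_rows, ovl_tables, fa_rows = [], [], []
    for sid, sessions in cohort.imaging.items():
        for tp, subj in sessions.items():
            vol_rows.append(dataclasses.asdict(
                compute_volumetrics(subj, subject_id=sid, timepoint_day=tp)
            ))
            ovl = structure_overlap(cohort.atlas, subj.lesion)
            ovl.insert(0, "subject_id", sid)
            ovl.insert(1, "timepoint_day", tp)
            ovl_tables.append(ovl)
            fa_map, rois = cohort.fa[sid][tp]
            fa_rows.append(dataclasses.asdict(fa_roi_result(
                fa_map, rois["ipsi"], rois["contra"],
                subject_id=sid, timepoint_day=tp,
            )))
    volumetrics = pd.DataFrame(vol_rows)
    overlap = pd.concat(ovl_tables, ignore_index=True)
    fa_results = pd.DataFrame(fa_rows)

    acute = min(cfg.imaging_timepoint_days)
    incidence = lesion_incidence(overlap, threshold_voxels=cfg.threshold_voxels)
    ranking_pos = rank_structures(overlap.loc[overlap["timepoint_day"] == acute], by="pos")
    ranking_pol = rank_structures(overlap.loc[overlap["timepoint_day"] == acute], by="pol")

    fa_tests = []
    for tp, grp in fa_results.groupby("timepoint_day"):
        res = fa_asymmetry_test(grp)
        fa_tests.append({
            "timepoint_day": tp, "t": res.statistic, "df": res.df,
            "p_value": res.p_value, "mean_difference": res.estimate, "n": res.n,
        })
    fa_tests = pd.DataFrame(fa_tests)

    features = build_feature_matrix(
        volumetrics, overlap,
        top_n_structures=cfg.top_n_structures, imaging_timepoint_day=acute,
    )
    heatmaps = {}
    for tp in cfg.outcome_timepoint_days:
        heatmaps[tp] = correlate(
            features, cohort.outcomes, tp,
            outcome_parameters=GAIT_PARAMETERS, limb=cfg.limb,
            group="MCAO", min_lesioned=cfg.min_lesioned,
        )
    return {
        "volumetrics": volumetrics,
        "overlap": overlap,
        "incidence": incidence,
        "ranking_pos": ranking_pos,
        "ranking_pol": ranking_pol,
        "fa_results": fa_results,
        "fa_tests": fa_tests,
        "features": features,
        "heatmap_cells": heatmaps,
    }


def report(results: dict, cohort: Cohort) -> dict:
    """Summary tables: per-timepoint mean ± SD of the canonical metrics with
    the paired (acute vs chronic) and one-sample (vs no-pathology) tests,
    the incidence table, rankings, and the repeated-measures gait ANOVA."""
    vol = results["volumetrics"]
    if vol.empty:
        raise ValueError("empty cohort: nothing to report")
    metrics = [
        "lesion_volume_cm3", "lesion_percent_of_ipsi",
        "midline_shift_mm", "hemispheric_change_percent",
    ]
    tps = sorted(vol["timepoint_day"].unique())
    rows = []
    for m in metrics:
        for tp in tps:
            vals = vol.loc[vol["timepoint_day"] == tp, m].to_numpy(float)
            row = {
                "metric": m, "timepoint_day": tp,
                "mean": float(vals.mean()), "sd": float(vals.std(ddof=1)),
                "n": int(vals.size),
            }
            # pathology metrics: tested against the no-pathology value (0)
            if m in ("midline_shift_mm", "hemispheric_change_percent") and vals.size >= 2:
                row["p_vs_normal"] = one_sample_t(vals, 0.0).p_value
            rows.append(row)
        if len(tps) >= 2:
            wide = vol.pivot(index="subject_id", columns="timepoint_day", values=m)
            res = paired_t(wide[tps[0]], wide[tps[1]])
            rows.append({
                "metric": m, "timepoint_day": np.nan,
                "mean": res.estimate, "sd": np.nan, "n": res.n,
                "p_paired_acute_vs_chronic": res.p_value,
            })
    summary = pd.DataFrame(rows)

    anovas = {}
    for param in GAIT_PARAMETERS:
        try:
            anova, pairwise = rm_anova_sidak(
                cohort.outcomes, param, limb=cohort.config.limb
            )
            anovas[param] = {"anova": anova, "pairwise": pairwise}
        except ValueError:
            continue
    return {
        "canonical_summary": summary,
        "incidence": results["incidence"],
        "ranking_pos": results["ranking_pos"],
        "ranking_pol": results["ranking_pol"],
        "fa_tests": results["fa_tests"],
        "gait_anova": anovas,
    }
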