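"""Acute imaging features vs longitudinal functional outcomes.

Builds a subject x feature matrix (top structures by cohort-mean PoS plus
the four canonical MRI metrics), correlates each feature against each
outcome at a chosen post-stroke timepoint (Pearson), applies the
minimum-lesioned-subject filter, and controls the FDR over the included
cells (Benjamini-Hochberg, per heatmap by default). Exports the wide R
matrix and the long cell table the way correlation heatmaps are reported.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .stats import bh_fdr, pearson_r
from .topology import rank_structures

__all__ = [
    "CANONICAL_METRICS",
    "build_feature_matrix",
    "correlate",
    "export_heatmap",
    "read_heatmap_long",
]

CANONICAL_METRICS = [
    "lesion_volume_cm3",
    "lesion_percent_of_ipsi",
    "midline_shift_mm",
    "hemispheric_change_percent",
]


def build_feature_matrix(
    volumetrics: pd.DataFrame,
    cohort_overlap: pd.DataFrame,
    top_n_structures: int = 10,
    imaging_timepoint_day: float | None = None,
) -> pd.DataFrame:
    """Subject-indexed feature matrix: ``pos:<structure>`` columns for the
    ``top_n_structures`` structures by cohort-mean PoS, then the four
    canonical metrics. Both inputs may carry multiple timepoints; pass
    ``imaging_timepoint_day`` to fix the acute imaging session."""
    vol = volumetrics.copy()
    ovl = cohort_overlap.copy()
    if imaging_timepoint_day is not None:
        vol = vol.loc[vol["timepoint_day"] == imaging_timepoint_day]
        ovl = ovl.loc[ovl["timepoint_day"] == imaging_timepoint_day]
    if vol.empty or (ovl.empty and top_n_structures > 0):
        raise ValueError("no imaging rows at the requested timepoint")

    features = vol.set_index("subject_id")[CANONICAL_METRICS]
    if features.index.duplicated().any():
        raise ValueError("one volumetrics row per subject expected")

    if top_n_structures > 0:
        top = rank_structures(ovl, by="pos", top_n=top_n_structures)["structure_name"]
        pos_wide = ovl.pivot_table(
            index="subject_id", columns="structure_name",
            values="pos_percent", aggfunc="first",
        )
        missing = set(features.index) - set(pos_wide.index)
        if missing:
            raise ValueError(f"subjects missing overlap rows: {sorted(missing)}")
        pos_cols = pos_wide.loc[features.index, list(top)]
        pos_cols.columns = [f"pos:{c}" for c in pos_cols.columns]
        features = pd.concat([pos_cols, features], axis=1)
    return features


def correlate(
    features: pd.DataFrame,
    outcomes: pd.DataFrame,
    outcome_timepoint_day: float,
    outcome_parameters: list[str] | None = None,
    limb: str | None = "LF",
    group: str | None = "MCAO",
    min_lesioned: int = 3,
) -> pd.DataFrame:
    """Pearson r per (feature, outcome) cell with filtering and FDR.

    PoS features are excluded (``included = False``) when fewer than
    ``min_lesioned`` subjects have a nonzero PoS — correlations over
    structures lesioned in only one or two subjects are not interpretable.
    Degenerate (zero-variance) cells are likewise excluded. BH-FDR is
    applied over the included cells of this table only.
    """
    out = outcomes.loc[outcomes["timepoint_day"] == outcome_timepoint_day].copy()
    if group is not None:
        out = out.loc[out["group"] == group]
    if limb is not None:
        out = out.loc[out["limb"].isin([limb, "NA"])]
    if outcome_parameters is not None:
        out = out.loc[out["parameter"].isin(outcome_parameters)]
    if out.empty:
        raise ValueError("no outcome rows after filtering")
    out_wide = out.pivot_table(
        index="subject_id", columns="parameter", values="value", aggfunc="first"
    )
    subjects = features.index.intersection(out_wide.index)
    if len(subjects) < 3:
        raise ValueError(f"only {len(subjects)} subjects shared between features and outcomes")
    feats = features.loc[subjects]
    out_wide = out_wide.loc[subjects]

    rows = []
    for fname in feats.columns:
        fvals = feats[fname].to_numpy(float)
        n_lesioned = int((fvals > 0).sum()) if fname.startswith("pos:") else None
        pos_excluded = n_lesioned is not None and n_lesioned < min_lesioned
        for oname in out_wide.columns:
            ovals = out_wide[oname].to_numpy(float)
            ok = ~(np.isnan(fvals) | np.isnan(ovals))
            cell = {
                "feature": fname,
                "outcome": oname,
                "outcome_timepoint_day": outcome_timepoint_day,
                "r": np.nan,
                "n_used": int(ok.sum()),
                "p_raw": np.nan,
                "p_fdr": np.nan,
                "included": False,
                "exclude_reason": "",
            }
            if pos_excluded:
                cell["exclude_reason"] = f"lesioned in {n_lesioned} < {min_lesioned} subjects"
            elif ok.sum() < 3:
                cell["exclude_reason"] = "fewer than 3 complete pairs"
            else:
                res = pearson_r(fvals[ok], ovals[ok])
                if res.degenerate:
                    cell["exclude_reason"] = "zero variance"
                else:
                    cell.update(
                        r=res.estimate, p_raw=res.p_value, n_used=res.n, included=True
                    )
            rows.append(cell)
    cells = pd.DataFrame(rows)
    if not cells["included"].any():
        cells.attrs["empty_result"] = True
        return cells
    inc = cells["included"].to_numpy()
    adj = bh_fdr(cells.loc[inc, "p_raw"].to_numpy())
    cells.loc[inc, "p_fdr"] = adj
    return cells


def export_heatmap(
    cells: pd.DataFrame,
    out_dir: str | Path,
    prefix: str = "heatmap",
    render_png: bool = False,
) -> dict[str, Path]:
    """Write the wide R matrix (features x outcomes; excluded cells empty)
    and the long cell table; optionally render a PNG heatmap."""
    if cells.empty:
        raise ValueError("no heatmap cells to export")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    wide = cells.pivot(index="feature", columns="outcome", values="r")
    feature_order = cells["feature"].drop_duplicates()
    wide = wide.loc[feature_order]
    wide_path = out_dir / f"{prefix}_r_wide.csv"
    wide.to_csv(wide_path, na_rep="")

    long_path = out_dir / f"{prefix}_cells.csv"
    cells.to_csv(long_path, index=False)

    paths = {"wide": wide_path, "long": long_path}
    if render_png:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(
            figsize=(1.2 + 0.6 * wide.shape[1], 1.0 + 0.4 * wide.shape[0])
        )
        im = ax.imshow(wide.to_numpy(float), cmap="RdBu_r", vmin=-1, vmax=1)
        ax.set_xticks(range(wide.shape[1]), wide.columns, rotation=45, ha="right")
        ax.set_yticks(range(wide.shape[0]), wide.index)
        fig.colorbar(im, ax=ax, label="Pearson r")
        fig.tight_layout()
        png_path = out_dir / f"{prefix}.png"
        fig.savefig(png_path, dpi=120)
        plt.close(fig)
        paths["png"] = png_path
    return paths


def read_heatmap_long(path: str | Path) -> pd.DataFrame:
    """Round-trip reader for the long cell CSV written by export_heatmap."""
    df = pd.read_csv(path)
    df["included"] = df["included"].astype(bool)
    df["exclude_reason"] = df["exclude_reason"].fillna("")
    return df
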