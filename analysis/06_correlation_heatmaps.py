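#!/usr/bin/env python
"""Acute imaging features vs functional outcomes: correlation heatmaps.

Top-10 structures by acute cohort-mean PoS plus the four canonical MRI
metrics, correlated (Pearson) against the six contralateral-forelimb gait
parameters at days 2 and 8 post-stroke, within the stroked group, with the
minimum-three-lesioned-subjects filter and BH-FDR per heatmap.
"""

from pathlib import Path

from lesiontopo.correlation import export_heatmap
from lesiontopo.pipeline import RunConfig, analyze_cohort, simulate_cohort

ROOT = Path(__file__).resolve().parents[1]
SEED = 0


def main() -> None:
    cohort = simulate_cohort(RunConfig(seed=SEED))
    results = analyze_cohort(cohort)

    out = ROOT / "results"
    results["features"].to_csv(out / "features.csv")
    for tp, cells in results["heatmap_cells"].items():
        export_heatmap(cells, out, prefix=f"heatmap_d{int(tp)}", render_png=True)
        inc = cells[cells["included"]]
        strongest = inc.loc[inc["r"].abs().nlargest(3).index]
        print(f"day {tp:g} outcomes: {inc.shape[0]} included cells, "
              f"{(~cells['included']).sum()} excluded")
        for _, row in strongest.iterrows():
            print(f"  {row['feature']} vs {row['outcome']}: r = {row['r']:+.2f} "
                  f"(p = {row['p_raw']:.3f}, FDR {row['p_fdr']:.3f})")
    print(f"heatmap tables + PNGs -> {out}")


if __name__ == "__main__":
    main()
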