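#!/usr/bin/env python
"""Simulate the study cohort: 7 stroked + 5 control synthetic subjects.

Each stroked subject gets acute (day 1) and chronic (day 28) imaging with
an MCA-territory lesion, hemispheric swelling then atrophy, a displaced
septum landmark, FA maps with an ipsilateral corpus-callosum decrement, and
longitudinal gait/open-field/mRS outcomes from the damage->deficit model.

Writes the text tables to results/cohort/ and the NIfTI volumes (binary,
large) to scratch/cohort/.
"""

from pathlib import Path

from lesiontopo.pipeline import RunConfig, simulate_cohort, write_cohort

ROOT = Path(__file__).resolve().parents[1]
SEED = 0


def main() -> None:
    cfg = RunConfig(seed=SEED)
    cohort = simulate_cohort(cfg)

    out = ROOT / "results" / "cohort"
    out.mkdir(parents=True, exist_ok=True)
    cohort.outcomes.to_csv(out / "outcomes.csv", index=False)
    cohort.cohort_pos.to_csv(out / "cohort_pos_truth.csv", index=False)
    cohort.atlas.lookup.to_csv(out / "atlas_lookup.csv", index=False)

    write_cohort(cohort, ROOT / "scratch" / "cohort")

    n_img = sum(len(s) for s in cohort.imaging.values())
    print(f"simulated {cfg.n_stroked} stroked + {cfg.n_control} control subjects "
          f"(seed {SEED}); {n_img} imaging sessions")
    print(f"atlas: {len(cohort.atlas.lookup)} labels "
          f"({(~(cohort.atlas.lookup.is_ventricle | cohort.atlas.lookup.is_cerebellum)).sum()} "
          f"paired structures + ventricles + cerebellum)")
    print(f"outcome rows: {len(cohort.outcomes)}")
    print(f"text tables -> {out}")
    print(f"volumes + sidecars -> {ROOT / 'scratch' / 'cohort'}")


if __name__ == "__main__":
    main()
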