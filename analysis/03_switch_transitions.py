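#!/usr/bin/env python
"""Landscape-switching transitions between consecutive calibrated stages.

For every adjacent stage pair: clusters the pre-switch ensemble on aligned
RMSD, selects representatives from every cluster above 0.2% population,
swaps the stage potential, relaxes at constant temperature and collects
checkpoint ensembles.  Writes, per transition: the relaxation of the
ensemble contact map toward the target (MAE over checkpoints), the change in
coherent motions Delta M at each checkpoint, the (R_g, Delta) geometry
series, and PCA-quantified pathways (insulation and enhanced observables)
with their deviation from the linear-interpolation baseline.

Requires 02_calibrate_stages.py to have been run first.
"""

from pathlib import Path

from chromocycle.pipeline import (RunConfig, load_stage_result,
                                  run_transition_pipeline)

STAGE_LABELS = ["prometa", "anatelo", "earlyG1", "midG1", "lateG1"]
ROOT = Path("results/analysis/stages")
MAPS = Path("results/analysis/maps")


def main() -> None:
    results = {}
    stage_maps = []
    for label in STAGE_LABELS:
        stage_dir = ROOT / f"stage_{label}"
        if not stage_dir.is_dir():
            raise SystemExit(f"missing {stage_dir}; run 02_calibrate_stages.py first")
        results[label] = load_stage_result(stage_dir)
        stage_maps.append((label, str(MAPS / f"{label}.txt")))

    config = RunConfig(name="stages", scale="desk", base_seed=2024,
                       output_root="results/analysis", stage_maps=stage_maps,
                       overrides={"switch_duration": 200.0,
                                  "checkpoints": (1.0, 10.0, 100.0, 200.0)})
    transitions = run_transition_pipeline(config, results)

    print(f"\n{'transition':>20}  {'MAE(t=0)':>9}  {'MAE(end)':>9}  "
          f"{'dev(ins)':>9}  {'dev(enh)':>9}")
    for tag, tr in transitions.items():
        times = sorted(tr.checkpoint_mae)
        print(f"{tag:>20}  {tr.checkpoint_mae[times[0]]:9.4f}  "
              f"{tr.checkpoint_mae[times[-1]]:9.4f}  "
              f"{tr.deviation_insulation:9.4f}  {tr.deviation_enhanced:9.4f}")
    print("\neach switch pulls the ensemble map toward its target stage; "
          "pathway deviations quantify how far relaxation departs from the "
          "straight line between the endpoint maps")


if __name__ == "__main__":
    main()
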