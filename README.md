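# chromocycle

Data-driven polymer modelling of chromosome reorganization through the cell
cycle.  The package builds coarse-grained structural ensembles of a
chromosome segment whose simulated contact probabilities are calibrated to a
target Hi-C-like map by maximum-entropy biasing, drives non-equilibrium
transitions between cell-stage potentials by landscape switching, and
provides the analysis layer used to read those ensembles: insulation scores
and TAD boundaries, observed/expected enhanced contacts and A/B
compartments, gyration geometry (R_g, asphericity), fluctuation matrices of
coherent locus motion, and PCA-quantified transition pathways.

It is written for structural-genomics and biophysics researchers who want
the mitosis-to-G1 modelling workflow runnable end to end at desk scale:
every stage of the pipeline works on synthetic 40–120-locus maps with
planted ground truth, no downloads required.

## The model in brief

A chromosome segment is a chain of beads (one per 100 kb locus; the
reference segment, murine chr1 20.5–71.4 Mb, is 510 beads).  The stage
potential is

```
V(stage) = V_homopolymer + sum_{i<j} alpha_ij f(r_ij)
```

where `V_homopolymer` holds bonds, a straightness-favouring angle term, a
capped soft-core repulsion that lets chains cross (topoisomerase), and a
spherical confinement at 10% volume fraction; `f(r) = (1+tanh[eta(r_c-r)])/2`
is a smooth contact indicator whose ensemble mean is the simulated contact
probability `P_ij`.  The couplings `alpha_ij` are found iteratively —
annealed Langevin replicas, measure `P_sim`, update
`alpha += lr (P_sim - P_target)` — until the simulated map matches the
target.  A cell-stage transition swaps `V(stage1) -> V(stage2)`
instantaneously and records the relaxation trajectories on the new
landscape.  See `docs/methods.md` for the full account.

## Worked example

Calibrate a 24-locus synthetic two-TAD map and inspect the fit:

```python
import numpy as np
from chromocycle.synthetic import SyntheticSpec, make_interphase_map
from chromocycle.maxent import calibrate
from chromocycle.engine import AnnealingSchedule, LangevinSettings

spec = SyntheticSpec(n_loci=24, tad_blocks=[(0, 11, 3.0), (12, 23, 3.0)],
                     compartment_labels=np.array(["A"] * 12 + ["B"] * 12))
target, truth = make_interphase_map(spec)
state = calibrate(target,
                  settings=LangevinSettings(seed=7),
                  schedule=AnnealingSchedule(4.0, 1.0, 15.0, 60.0),
                  n_replicas=4, max_iter=6)
for it, (mae, pearson) in enumerate(state.error_history):
    print(f"round {it}: MAE {mae:.4f}  Pearson {pearson:.4f}")
```

prints

```
round 0: MAE 0.2772  Pearson 0.5821
round 1: MAE 0.0981  Pearson 0.9255
round 2: MAE 0.0951  Pearson 0.9361
round 3: MAE 0.0868  Pearson 0.9382
round 4: MAE 0.0778  Pearson 0.9611
round 5: MAE 0.0705  Pearson 0.9649
```

Round 0 is the unbiased homopolymer: its map correlates with the target
only through the generic distance decay (Pearson 0.58) and is off by 0.28
in mean absolute probability.  Each round then simulates under the updated
couplings; by round 5 the simulated ensemble reproduces the target map to
MAE 0.07 with Pearson 0.96 — the TAD blocks planted in the synthetic map
are now structural features of the 3D ensemble, and the remaining error is
mostly the sampling noise of this deliberately small run (4 replicas; the
60-locus acceptance run with more replicas reaches MAE < 0.05).
`state.bias` holds the
calibrated stage potential's couplings and `state.ensemble` the sampled
structures, ready for `chromocycle.metrics` (geometry, fluctuation
matrices) or `chromocycle.switching` (transitions to another stage).

## Analysis pipeline

The `analysis/` scripts chain the full study at desk scale (60 loci, five
stages) and write their tables under `results/analysis/`:

1. `01_synthesize_maps.py` — five-stage synthetic map series + ground truth.
2. `02_calibrate_stages.py` — max-ent calibration of every stage; per-stage
   ensembles, geometry, landscapes, fluctuation matrices, observables.
3. `03_switch_transitions.py` — landscape switching between consecutive
   stages; relaxation curves, Delta M at checkpoints, pathway PCA with
   linear-interpolation baselines.
4. `04_plot_summary.py` — summary figures from the saved tables.

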