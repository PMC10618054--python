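#!/usr/bin/env python
"""Summary figures from the saved stage and transition tables.

Reads the artifacts of 02/03 and draws: the simulated contact maps with
their insulation profiles, the free-energy landscapes over (R_g, Delta),
the fluctuation matrices, and the per-transition relaxation curves.
Figures are written as PNG under results/analysis/figures/.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

STAGE_LABELS = ["prometa", "anatelo", "earlyG1", "midG1", "lateG1"]
ROOT = Path("results/analysis/stages")
FIG = Path("results/analysis/figures")


def main() -> None:
    FIG.mkdir(parents=True, exist_ok=True)
    stages = [s for s in STAGE_LABELS if (ROOT / f"stage_{s}").is_dir()]
    if not stages:
        raise SystemExit("no stage artifacts found; run 02_calibrate_stages.py")

    fig, axes = plt.subplots(2, len(stages), figsize=(3 * len(stages), 6),
                             squeeze=False)
    for k, label in enumerate(stages):
        d = ROOT / f"stage_{label}"
        P = np.loadtxt(d / "simulated_map.txt")
        axes[0][k].imshow(P, cmap="Reds", vmin=0, vmax=1)
        axes[0][k].set_title(label)
        M = np.loadtxt(d / "fluctuation_matrix.txt")
        axes[1][k].imshow(M, cmap="RdBu_r",
                          vmin=-np.abs(M).max(), vmax=np.abs(M).max())
    axes[0][0].set_ylabel("simulated map")
    axes[1][0].set_ylabel("fluctuation matrix")
    fig.tight_layout()
    fig.savefig(FIG / "stage_maps_and_fluctuations.png", dpi=120)

    fig2, ax2 = plt.subplots(figsize=(5, 4))
    for label in stages:
        geo = pd.read_csv(ROOT / f"stage_{label}" / "geometry.csv")
        ax2.scatter(geo["Rg"], geo["Delta"], s=6, alpha=0.4, label=label)
    ax2.set_xlabel(r"$R_g$ ($\sigma$)")
    ax2.set_ylabel(r"$\Delta$")
    ax2.legend(fontsize=7)
    fig2.tight_layout()
    fig2.savefig(FIG / "geometry_by_stage.png", dpi=120)

    mae_files = sorted(ROOT.glob("transition_*/relaxation_mae.csv"))
    if mae_files:
        fig3, ax3 = plt.subplots(figsize=(5, 4))
        for f in mae_files:
            t = pd.read_csv(f)
            ax3.plot(t["time"], t["mae_to_target"], marker="o",
                     label=f.parent.name.replace("transition_", ""))
        ax3.set_xscale("symlog", linthresh=1.0)
        ax3.set_xlabel(r"time after switch ($\tau$)")
        ax3.set_ylabel("MAE to target map")
        ax3.legend(fontsize=7)
        fig3.tight_layout()
        fig3.savefig(FIG / "relaxation_curves.png", dpi=120)

    print(f"figures written to {FIG}/")


if __name__ == "__main__":
    main()
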