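#!/usr/bin/env python
"""Cost-effectiveness planes: per-draw (QALY gain, cost difference)
scatter for each QALY kind and training-cost variant.

Writes plane point CSVs with quadrant labels to results/ce_planes/ and
scatter plots (PNG) to scratch/figures/.  A draw in the south-east
quadrant is more effective and less costly (dominant).
"""
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from obpi_cea import TrainingVariant, default_config, run_psa
from obpi_cea.psa import ce_plane_points, quadrant_shares

OUT = Path("results/ce_planes")
FIG = Path("scratch/figures")
N_DRAWS = 1000
SEED = 0


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    FIG.mkdir(parents=True, exist_ok=True)
    config, coverage = default_config()
    for variant in TrainingVariant:
        res = run_psa(config, coverage, variant, n_draws=N_DRAWS, seed=SEED)
        for kind in ("adult", "parental", "dyadic"):
            points = ce_plane_points(res, kind)
            points.to_csv(OUT / f"ce_plane_{variant.value}_{kind}.csv", index=False)
            shares = quadrant_shares(points)
            print(
                f"{variant.value}/{kind}: quadrant shares "
                + ", ".join(f"{q}={v:.1%}" for q, v in shares.items() if v)
            )
            fig, ax = plt.subplots(figsize=(5, 4))
            ax.scatter(
                points["delta_qalys"], points["delta_cost"] / 1e9, s=6, alpha=0.4
            )
            ax.axhline(0, color="k", lw=0.6)
            ax.axvline(0, color="k", lw=0.6)
            ax.set_xlabel(f"incremental {kind} QALYs")
            ax.set_ylabel("incremental cost (GBP bn)")
            ax.set_title(f"{variant.value} vs current practice")
            fig.tight_layout()
            fig.savefig(FIG / f"ce_plane_{variant.value}_{kind}.png", dpi=150)
            plt.close(fig)
    print(f"Point sets in {OUT}/; figures in {FIG}/")


if __name__ == "__main__":
    main()
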