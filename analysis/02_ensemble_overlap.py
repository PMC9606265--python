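"""Ensemble overlap-over-chance across planted dependence levels.

For each generated map the observed double-positive fraction is compared
with the independence expectation (product of ensemble fractions): the
overlap-over-chance ratio should track the planted rho from 0 (mutually
exclusive ensembles) through 1 (independent) to 12 (the strong same-day
coupling regime). Writes results/overlap_by_rho.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from engram import overlap as ov
from engram import synthetic as sy
from engram.io import read_cellmap

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 20240901
N_REPLICATES = 50


def main() -> None:
    mask = sy.make_layer_mask(512, 512, 1.0, sy.BandParams(thickness_px=48), seed=1)
    rows = []
    for rho in (0.0, 1.0, 3.0, 12.0):
        # the deposited example section, plus replicate sections for the mean
        cm = read_cellmap(ROOT / "data" / f"map_rho{rho:g}.csv",
                          ROOT / "data" / "mask_512.png", pixel_size=1.0,
                          n_gc_true=5000)
        res = ov.compute_overlap(ov.counts_from_cellmap(cm))
        reps = []
        for i in range(N_REPLICATES):
            rep = sy.sample_cellmap(
                mask, sy.GeneratorSpec(n_cells=5000, rho=rho, seed=SEED + 1000 * i + int(rho))
            )
            reps.append(
                ov.compute_overlap(ov.counts_from_cellmap(rep)).overlap_over_chance
            )
        rows.append(
            {
                "rho_planted": rho,
                "n_tagged": res.counts.n_tagged,
                "n_cfos": res.counts.n_cfos,
                "n_double": res.counts.n_double,
                "overlap_over_chance_example": res.overlap_over_chance,
                "conditional_overlap_example": res.conditional_overlap,
                "overlap_over_chance_mean": float(np.mean(reps)),
                "overlap_over_chance_sem": float(np.std(reps) / np.sqrt(len(reps))),
            }
        )
    table = pd.DataFrame(rows)
    table.to_csv(ROOT / "overlap_by_rho.csv", index=False)
    print(table.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
    print(f"\nmean observed/expected overlap over {N_REPLICATES} sections tracks the"
          "\nplanted dependence level; rho = 1 sits at chance and rho = 0 yields no"
          "\ndouble positives. Single sections scatter widely (few double positives).")


if __name__ == "__main__":
    main()
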