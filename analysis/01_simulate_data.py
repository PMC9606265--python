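"""Generate the synthetic datasets used by the downstream analyses.

Emulates segmented two-blade dentate-gyrus sections with sparse labeled
ensembles at several overlap-over-chance levels, spatially clustered maps
whose cfos centers drift between days, intensity tables for three training
regimes (home cage, spaced, daily — increasing repressed fraction), and
CaMPARI tables for the trained vs novel-environment comparison.

Writes cell tables and masks under results/data/.
"""

from pathlib import Path

from engram import synthetic as sy
from engram.io import write_cellmap

SEED = 20240901
OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    mask = sy.make_layer_mask(512, 512, 1.0, sy.BandParams(thickness_px=48), seed=1)
    write_cellmap(
        sy.sample_cellmap(mask, sy.GeneratorSpec(n_cells=5000, seed=SEED)),
        OUT / "map_rho1.csv", OUT / "mask_512.png",
    )
    for rho in (0.0, 3.0, 12.0):
        cm = sy.sample_cellmap(
            mask, sy.GeneratorSpec(n_cells=5000, rho=rho, seed=SEED + int(rho))
        )
        write_cellmap(cm, OUT / f"map_rho{rho:g}.csv")

    big = sy.make_layer_mask(1024, 1024, 1.0, sy.BandParams(thickness_px=48), seed=1)
    for shift, name in ((0.0, "clustered_same_day"), (150.0, "clustered_next_day")):
        cm = sy.sample_cellmap(
            big,
            sy.GeneratorSpec(
                n_cells=1000, f_tagged=0.10, f_cfos=0.10, rho=1.0,
                cluster_model=sy.PlantedClusters(k=10, spread=50.0, min_separation=130.0),
                shift=shift, seed=SEED,
            ),
        )
        write_cellmap(cm, OUT / f"map_{name}.csv", OUT / "mask_1024.png")

    for i, (cond, frac_rep) in enumerate((("HC", 0.20), ("ST", 0.32), ("DT", 0.44))):
        frac_perm = 0.40
        tab = sy.simulate_intensity_table(
            2000, frac_rep, frac_perm, 1.0 - frac_rep - frac_perm,
            condition=cond, seed=SEED + 17 * (i + 1),
        )
        tab.to_csv(OUT / f"intensities_{cond}.csv", index=False)

    for name, frac in (("WM-WM", 0.23), ("WM-NE", 0.05)):
        sy.simulate_campari(1000, frac_reactivated=frac, seed=SEED).to_csv(
            OUT / f"campari_{name}.csv", index=False
        )
    print(f"wrote synthetic datasets to {OUT}")


if __name__ == "__main__":
    main()
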