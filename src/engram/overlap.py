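"""Ensemble sizes and overlap-over-chance statistics.

For one imaged section, two cFos ensembles are compared: the cFos-tagged
population (mKate2+, labeled during an earlier tagging window) and the
currently cFos+ population (shEGFP+). With N granule cells in the layer, the
key quantities are

    frac_tagged   = n_tagged / N
    frac_cfos     = n_cfos / N
    frac_double   = n_double / N
    expected      = frac_tagged * frac_cfos      (independence)
    over_chance   = frac_double / expected
    conditional   = n_double / n_tagged          (fraction of tagged cells
                                                  that are currently cFos+)

Both conventions are reported: figure-style percentages condition on the
tagged ensemble, while over-chance normalizes the double-positive fraction
of all granule cells by its independence expectation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .types import CellMap, ParameterError

__all__ = [
    "EnsembleCounts",
    "EnsembleOverlapResult",
    "estimate_total_gc",
    "match_double_positive",
    "compute_overlap",
    "counts_from_cellmap",
    "overlap_timecourse",
]

#: spot-matching radius in µm below which a tagged and a cfos spot are the
#: same cell (double positive)
DOUBLE_POSITIVE_RADIUS_UM = 5.0


@dataclass(frozen=True)
class EnsembleCounts:
    """Raw counts for one section."""

    n_gc: int
    n_tagged: int
    n_cfos: int
    n_double: int
    gc_source: str = "supplied"  # "supplied" | "density"

    def __post_init__(self) -> None:
        if min(self.n_gc, self.n_tagged, self.n_cfos, self.n_double) < 0:
            raise ParameterError("counts must be nonnegative")
        if self.n_double > min(self.n_tagged, self.n_cfos):
            raise ParameterError("n_double exceeds an ensemble size")
        if max(self.n_tagged, self.n_cfos) > self.n_gc:
            raise ParameterError("ensemble larger than the granule-cell count")


@dataclass(frozen=True)
class EnsembleOverlapResult:
    frac_tagged: float
    frac_cfos: float
    frac_double: float
    expected_overlap: float
    overlap_over_chance: float
    conditional_overlap: float  # NaN when n_tagged == 0
    counts: EnsembleCounts


def estimate_total_gc(layer_measure: float, density: float) -> int:
    """Total granule-cell count from layer measure x published density.

    Units are the caller's contract: pass a volume (µm³) with a volumetric
    density, or an area (µm²) with an areal density.
    """
    if layer_measure <= 0 or density <= 0:
        raise ParameterError("layer measure and density must be positive")
    return int(round(layer_measure * density))


def match_double_positive(
    points_a: np.ndarray,
    points_b: np.ndarray,
    radius: float = DOUBLE_POSITIVE_RADIUS_UM,
) -> list[tuple[int, int]]:
    """One-to-one spot matching: pairs closer than ``radius`` µm.

    Greedy closest-pair-first: candidate pairs with distance strictly below
    the radius are accepted in order of increasing distance (ties broken by
    lexicographic index order) and each spot is used at most once. Returns
    (index_a, index_b) pairs.
    """
    if radius <= 0:
        raise ParameterError("matching radius must be positive")
    a = np.asarray(points_a, dtype=float).reshape(-1, 2)
    b = np.asarray(points_b, dtype=float).reshape(-1, 2)
    if a.size == 0 or b.size == 0:
        return []
    tree = cKDTree(b)
    cand: list[tuple[float, int, int]] = []
    for i, neighbors in enumerate(tree.query_ball_point(a, r=radius)):
        for j in neighbors:
            d = float(np.hypot(*(a[i] - b[j])))
            if d < radius:
                cand.append((d, i, j))
    cand.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for _, i, j in cand:
        if i not in used_a and j not in used_b:
            pairs.append((i, j))
            used_a.add(i)
            used_b.add(j)
    return pairs


def compute_overlap(counts: EnsembleCounts) -> EnsembleOverlapResult:
    """Overlap fractions and overlap-over-chance from raw counts."""
    if counts.n_gc <= 0:
        raise ParameterError("n_gc must be positive")
    n = counts.n_gc
    ft = counts.n_tagged / n
    fc = counts.n_cfos / n
    fd = counts.n_double / n
    expected = ft * fc
    if expected == 0.0:
        if counts.n_double > 0:
            raise ParameterError(
                "inconsistent counts: double positives with an empty ensemble"
            )
        over = 0.0
    else:
        over = fd / expected
    conditional = counts.n_double / counts.n_tagged if counts.n_tagged else float("nan")
    return EnsembleOverlapResult(
        frac_tagged=ft,
        frac_cfos=fc,
        frac_double=fd,
        expected_overlap=expected,
        overlap_over_chance=over,
        conditional_overlap=conditional,
        counts=counts,
    )


def counts_from_cellmap(
    cellmap: CellMap,
    radius: float = DOUBLE_POSITIVE_RADIUS_UM,
    gc_density: float | None = None,
    double_method: str = "labels",
) -> EnsembleCounts:
    """Counts for one map.

    With ``double_method="labels"`` (default) a cell is double positive iff
    it carries both labels — appropriate when one segmentation produced a
    single cell table. ``"matching"`` instead pairs the tagged and cfos
    spot sets within ``radius`` µm, as when the two ensembles were detected
    independently. The granule-cell total is taken from the map's known
    ground truth when present, otherwise estimated from the mask area (µm²)
    times ``gc_density`` (GCs per µm²).
    """
    pos_t = cellmap.positions("tagged")
    pos_c = cellmap.positions("cfos")
    if double_method == "labels":
        n_double = len(cellmap.labeled("tagged") & cellmap.labeled("cfos"))
    elif double_method == "matching":
        n_double = len(match_double_positive(pos_t, pos_c, radius=radius))
    else:
        raise ParameterError("double_method must be 'labels' or 'matching'")
    if cellmap.n_gc_true is not None:
        n_gc, src = cellmap.n_gc_true, "supplied"
    elif gc_density is not None:
        area = float(cellmap.mask.grid.sum()) * cellmap.mask.pixel_size**2
        n_gc, src = estimate_total_gc(area, gc_density), "density"
    else:
        raise ParameterError("no granule-cell total: supply n_gc_true or gc_density")
    return EnsembleCounts(
        n_gc=n_gc,
        n_tagged=len(pos_t),
        n_cfos=len(pos_c),
        n_double=n_double,
        gc_source=src,
    )


def overlap_timecourse(
    maps: list[tuple[float, EnsembleOverlapResult]],
) -> pd.DataFrame:
    """Overlap statistics vs time since tagging, sorted by Δt (hours)."""
    dts = [dt for dt, _ in maps]
    if len(set(dts)) != len(dts):
        raise ParameterError("Δt values must be distinct")
    rows = [
        {
            "dt_hours": dt,
            "conditional_overlap": r.conditional_overlap,
            "overlap_over_chance": r.overlap_over_chance,
            "frac_tagged": r.frac_tagged,
            "frac_cfos": r.frac_cfos,
        }
        for dt, r in maps
    ]
    return pd.DataFrame(rows).sort_values("dt_hours", ignore_index=True)
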