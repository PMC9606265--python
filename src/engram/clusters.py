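"""Spatial cluster analysis of labeled ensembles with permutation nulls.

Each labeled ensemble (tagged or cfos, always including double-positive
cells) is clustered by connectivity-constrained agglomerative clustering
(Ward linkage) on its µm positions. Cluster quality is scored by the
clustering index

    C_c = < median_j-in-cluster(D_ij) / min_j-not-in-cluster(D_ij) >_i

averaged over clustered neurons i of the ensemble; smaller C_c means
stronger clustering. The cluster count n_c is chosen by comparing C_c
against artificial maps in which labeled cells are redistributed uniformly
within the layer mask (counts of tagged-only / cfos-only / double-positive
cells preserved): for each candidate n_c the proportion of artificial sets
that cluster more strongly than the data is computed, and the n_c with the
smallest proportion wins (largest n_c on ties).

Cluster footprints are convex hulls; the overlap of a tagged cluster with
the cfos ensemble is the largest Jaccard index (intersection area over
union area) against any cfos cluster hull. A second batch of artificial
maps provides the null distribution of these overlap indices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.spatial import ConvexHull, QhullError, cKDTree
from scipy.spatial.distance import cdist
from shapely.geometry import Polygon
from sklearn.cluster import ward_tree

from .synthetic import admissible_centers, sample_positions
from .types import CellMap, CellRecord, ParameterError

__all__ = [
    "ClusterConfig",
    "ClusterIndexResult",
    "HullOverlapResult",
    "ICNullResult",
    "connectivity_graph",
    "default_k",
    "ward_clusters",
    "clustering_index",
    "randomize_cellmap",
    "optimal_cluster_number",
    "hull_overlap_index",
    "ic_null_distribution",
]


@dataclass(frozen=True)
class ClusterConfig:
    """Parameters of the full cluster-analysis pipeline.

    Defaults follow the reference procedure: 16 candidate cluster counts in
    [5, 20], neighbor count one tenth of the ensemble size, Ward linkage,
    500 artificial maps for the n_c choice and 200 for the overlap null.
    ``recompute_nc_in_null`` re-runs the n_c optimization inside every
    null set instead of reusing the empirical n_c (much slower).
    """

    nc_min: int = 5
    nc_max: int = 20
    k_neighbors_fraction: float = 0.1
    linkage: str = "ward"
    n_artificial_opt: int = 500
    n_artificial_null: int = 200
    recompute_nc_in_null: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nc_min > self.nc_max or self.nc_min < 1:
            raise ParameterError("invalid n_c range")
        if not 0 < self.k_neighbors_fraction <= 1:
            raise ParameterError("k_neighbors_fraction must lie in (0, 1]")
        if self.linkage != "ward":
            raise ParameterError("only ward linkage is supported")

    @property
    def nc_values(self) -> list[int]:
        return list(range(self.nc_min, self.nc_max + 1))


@dataclass
class ClusterIndexResult:
    c_c: float
    per_point_ratio: dict[int, float]
    excluded_points: list[int]


@dataclass
class HullOverlapResult:
    """Best-overlap scores of tagged cluster hulls against cfos hulls."""

    best_ic: list[float]                  # one entry per tagged cluster
    matched_cfos_cluster: list[int]       # argmax cfos cluster id (-1 if none)
    degenerate_tagged: list[int]          # tagged cluster ids with <3-point hulls
    degenerate_cfos: list[int]


@dataclass
class ICNullResult:
    empirical_ics: list[float]
    empirical_median: float
    null_ics: np.ndarray        # pooled, sorted
    null_medians: np.ndarray    # one per artificial set
    percentile: float           # of the empirical median among null medians
    nc_tagged: int
    nc_cfos: int
    proportions_tagged: dict[int, float] = field(default_factory=dict)
    proportions_cfos: dict[int, float] = field(default_factory=dict)


# --------------------------------------------------------------------------
# clustering primitives
# --------------------------------------------------------------------------

def default_k(n_points: int, fraction: float = 0.1) -> int:
    """Neighbor count: one tenth of the ensemble size, floored, at least 1."""
    return max(1, int(np.floor(n_points * fraction)))


def connectivity_graph(points: np.ndarray, k: int):
    """Symmetrized k-nearest-neighbor graph (CSR) over µm positions.

    Built from a KD-tree query (ties broken by index order); an edge is
    present if either endpoint lists the other among its k nearest.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    if n < 2:
        raise ParameterError("need at least 2 points for a neighbor graph")
    if not 1 <= k < n:
        raise ParameterError("k must satisfy 1 <= k < n_points")
    _, nbr = cKDTree(points).query(points, k=k + 1)
    rows = np.repeat(np.arange(n), k)
    cols = nbr[:, 1:].ravel()  # drop self (always nearest at distance 0)
    g = sparse.csr_matrix((np.ones(n * k), (rows, cols)), shape=(n, n))
    return ((g + g.T) > 0).astype(float)


def _cut_tree(children: np.ndarray, n_leaves: int, n_c: int) -> np.ndarray:
    """Labels after undoing the last ``n_c - 1`` merges of a full tree."""
    parent = np.arange(n_leaves + len(children))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for m, (a, b) in enumerate(children[: n_leaves - n_c]):
        node = n_leaves + m
        parent[find(a)] = node
        parent[find(b)] = node
    roots = np.array([find(i) for i in range(n_leaves)])
    _, labels = np.unique(roots, return_inverse=True)
    return labels


def _ward_children(points: np.ndarray, graph) -> tuple[np.ndarray, int]:
    # a k-NN graph may be disconnected; the tree builder repairs it by
    # joining components last, which is exactly the convention we document
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message=".*connected components.*", category=UserWarning
        )
        children, _, n_leaves, _ = ward_tree(points, connectivity=graph)
    return children, n_leaves


def ward_clusters(points: np.ndarray, graph, n_c: int) -> np.ndarray:
    """Ward agglomeration restricted to graph-connected merges, cut at n_c.

    Disconnected mask components are joined last (standard connectivity
    repair), so the cut is always well defined. Returns one cluster label
    per point.
    """
    points = np.asarray(points, dtype=float)
    if n_c > len(points):
        raise ParameterError("n_c exceeds the number of points")
    children, n_leaves = _ward_children(points, graph)
    return _cut_tree(children, n_leaves, n_c)


def _cc_from_distances(d: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-point m_i/e_i ratios (NaN where undefined) from a distance matrix."""
    n = len(labels)
    same = labels[:, None] == labels[None, :]
    np.fill_diagonal(same, False)
    m = np.full(n, np.nan)
    # per-cluster row medians: sort each member row over its cluster mates
    # (self pushed to the end as +inf) and read the middle of the first m-1
    for cid in np.unique(labels):
        idx = np.nonzero(labels == cid)[0]
        if len(idx) < 2:
            continue
        sub = d[np.ix_(idx, idx)].copy()
        np.fill_diagonal(sub, np.inf)
        sub.sort(axis=1)
        k = len(idx) - 1  # mates per row
        if k % 2:
            m[idx] = sub[:, k // 2]
        else:
            m[idx] = 0.5 * (sub[:, k // 2 - 1] + sub[:, k // 2])
    extra = np.where(~same, d, np.inf)
    np.fill_diagonal(extra, np.inf)
    e = extra.min(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratios = np.where((e > 0) & np.isfinite(m), m / e, np.nan)
    return ratios, e


def clustering_index(
    points: np.ndarray, labels: np.ndarray, _distances: np.ndarray | None = None
) -> ClusterIndexResult:
    """Clustering index C_c: mean of median-intra / min-extra distance ratios.

    Points alone in their cluster have no intra-cluster median and are
    excluded (and listed), as are points whose nearest outside neighbor is
    coincident; the minimum extra-cluster distance is taken over all other
    points of the same ensemble.
    """
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ParameterError("clustering index needs at least 2 clusters")
    d = cdist(points, points) if _distances is None else _distances
    ratios, _ = _cc_from_distances(d, labels)
    defined = np.isfinite(ratios)
    if not defined.any():
        raise ParameterError("no point has a defined clustering ratio")
    return ClusterIndexResult(
        c_c=float(ratios[defined].mean()),
        per_point_ratio={int(i): float(ratios[i]) for i in np.nonzero(defined)[0]},
        excluded_points=[int(i) for i in np.nonzero(~defined)[0]],
    )


# --------------------------------------------------------------------------
# artificial (randomized) maps
# --------------------------------------------------------------------------

def _label_groups(cellmap: CellMap) -> tuple[list[CellRecord], list[CellRecord], list[CellRecord]]:
    t_only, c_only, double = [], [], []
    for c in cellmap.cells:
        if "tagged" in c.labels and "cfos" in c.labels:
            double.append(c)
        elif "tagged" in c.labels:
            t_only.append(c)
        elif "cfos" in c.labels:
            c_only.append(c)
    return t_only, c_only, double


def _randomized_positions(
    cellmap: CellMap, n_sets: int, seed: int
):
    """Yield (tagged_positions, cfos_positions) for each artificial map.

    Tagged-only, cfos-only and double-positive cells are redistributed as
    three types with their counts preserved; each ensemble is the union of
    its exclusive type with the doubles. Per-set substreams are spawned from
    the root seed, so earlier sets are identical when n_sets changes.
    """
    t_only, c_only, double = _label_groups(cellmap)
    n_t, n_c, n_d = len(t_only), len(c_only), len(double)
    adm = admissible_centers(cellmap.mask)
    root = np.random.SeedSequence(seed)
    for child in root.spawn(n_sets):
        rng = np.random.default_rng(child)
        pos = sample_positions(cellmap.mask, n_t + n_c + n_d, rng, adm=adm)
        p_t, p_c, p_d = pos[:n_t], pos[n_t : n_t + n_c], pos[n_t + n_c :]
        yield (
            np.vstack([p_t, p_d]) if n_t + n_d else np.empty((0, 2)),
            np.vstack([p_c, p_d]) if n_c + n_d else np.empty((0, 2)),
        )


def randomize_cellmap(
    cellmap: CellMap,
    which: tuple[str, ...] = ("tagged", "cfos"),
    n_sets: int = 500,
    seed: int = 0,
) -> list[CellMap]:
    """Artificial maps: labeled cells uniformly redistributed within the mask.

    Counts of tagged-only, cfos-only and double-positive cells are exactly
    preserved (doubles are a third type). Unlabeled cells are not carried
    over — the cluster analysis only uses labeled positions. Reproducible
    from ``seed`` via per-set substreams.
    """
    t_only, c_only, double = _label_groups(cellmap)
    keep_t = "tagged" in which
    keep_c = "cfos" in which
    groups = (
        (t_only if keep_t else []),
        (c_only if keep_c else []),
        (double if (keep_t or keep_c) else []),
    )
    records = [c for g in groups for c in g]
    root = np.random.SeedSequence(seed)
    out = []
    for child in root.spawn(n_sets):
        rng = np.random.default_rng(child)
        pos = sample_positions(cellmap.mask, len(records), rng)
        cells = [
            CellRecord(id=c.id, x=float(p[0]), y=float(p[1]), labels=c.labels,
                       intensities=dict(c.intensities), aux=dict(c.aux))
            for c, p in zip(records, pos)
        ]
        out.append(
            CellMap(cells=cells, mask=cellmap.mask, n_gc_true=cellmap.n_gc_true,
                    metadata={**cellmap.metadata, "artificial": True})
        )
    return out


# --------------------------------------------------------------------------
# optimal cluster number
# --------------------------------------------------------------------------

def _cc_profile(points: np.ndarray, nc_values: list[int], k_fraction: float) -> np.ndarray:
    """C_c for every candidate n_c, from a single Ward tree."""
    k = default_k(len(points), k_fraction)
    graph = connectivity_graph(points, k)
    children, n_leaves = _ward_children(points, graph)
    d = cdist(points, points)
    out = np.empty(len(nc_values))
    for i, n_c in enumerate(nc_values):
        labels = _cut_tree(children, n_leaves, n_c)
        out[i] = clustering_index(points, labels, _distances=d).c_c
    return out


def _ensemble_positions(cellmap: CellMap, ensemble: str) -> np.ndarray:
    # double positives carry both labels, so they are included automatically
    return cellmap.positions(ensemble)


def optimal_cluster_number(
    cellmap: CellMap,
    ensemble: str,
    config: ClusterConfig | None = None,
) -> tuple[int, dict[int, float]]:
    """Choose n_c by comparison against randomized artificial maps.

    For each n_c in the configured range, the proportion of artificial sets
    whose C_c is smaller than (clusters more strongly than) the empirical
    C_c is computed; the n_c with the smallest proportion wins and ties go
    to the largest n_c. Returns (n_c*, proportion per n_c).
    """
    config = config or ClusterConfig()
    points = _ensemble_positions(cellmap, ensemble)
    if len(points) <= config.nc_max:
        raise ParameterError(
            f"ensemble {ensemble!r} has {len(points)} cells; need more than "
            f"nc_max = {config.nc_max}"
        )
    nc_values = config.nc_values
    emp = _cc_profile(points, nc_values, config.k_neighbors_fraction)
    smaller = np.zeros(len(nc_values))
    n_sets = config.n_artificial_opt
    for pos_t, pos_c in _randomized_positions(cellmap, n_sets, config.seed):
        pos = pos_t if ensemble == "tagged" else pos_c
        art = _cc_profile(pos, nc_values, config.k_neighbors_fraction)
        smaller += art < emp
    proportions = {nc: float(s / n_sets) for nc, s in zip(nc_values, smaller)}
    best = min(proportions.values())
    n_c_star = max(nc for nc, p in proportions.items() if p == best)
    return n_c_star, proportions


# --------------------------------------------------------------------------
# convex-hull overlap
# --------------------------------------------------------------------------

def _cluster_polygons(points: np.ndarray, labels: np.ndarray) -> tuple[dict[int, Polygon], list[int]]:
    polys: dict[int, Polygon] = {}
    degenerate: list[int] = []
    for cid in np.unique(labels):
        pts = points[labels == cid]
        if len(pts) < 3:
            degenerate.append(int(cid))
            continue
        try:
            hull = ConvexHull(pts)
        except QhullError:  # collinear
            degenerate.append(int(cid))
            continue
        polys[int(cid)] = Polygon(pts[hull.vertices])
    return polys, degenerate


def hull_overlap_index(
    points_tagged: np.ndarray,
    labels_tagged: np.ndarray,
    points_cfos: np.ndarray,
    labels_cfos: np.ndarray,
) -> HullOverlapResult:
    """Best Jaccard overlap of each tagged cluster hull with any cfos hull.

    Degenerate hulls (fewer than 3 points, or collinear) score 0 and are
    flagged rather than raising, so sparse artificial sets stay analyzable.
    """
    polys_t, degen_t = _cluster_polygons(np.asarray(points_tagged, float), np.asarray(labels_tagged))
    polys_c, degen_c = _cluster_polygons(np.asarray(points_cfos, float), np.asarray(labels_cfos))
    best: list[float] = []
    matched: list[int] = []
    for cid in sorted(set(np.unique(labels_tagged).tolist())):
        if cid not in polys_t:
            best.append(0.0)
            matched.append(-1)
            continue
        pt = polys_t[cid]
        b, arg = 0.0, -1
        for cj, pc in polys_c.items():
            inter = pt.intersection(pc).area
            if inter == 0.0:
                continue
            union = pt.union(pc).area
            ic = inter / union
            if ic > b:
                b, arg = ic, cj
        best.append(float(b))
        matched.append(arg)
    return HullOverlapResult(
        best_ic=best, matched_cfos_cluster=matched,
        degenerate_tagged=degen_t, degenerate_cfos=degen_c,
    )


def _cluster_at(points: np.ndarray, n_c: int, k_fraction: float) -> np.ndarray:
    k = default_k(len(points), k_fraction)
    graph = connectivity_graph(points, k)
    return ward_clusters(points, graph, n_c)


def _best_ics(pos_t: np.ndarray, pos_c: np.ndarray, nc_t: int, nc_c: int, k_fraction: float) -> list[float]:
    lab_t = _cluster_at(pos_t, nc_t, k_fraction)
    lab_c = _cluster_at(pos_c, nc_c, k_fraction)
    return hull_overlap_index(pos_t, lab_t, pos_c, lab_c).best_ic


def ic_null_distribution(
    cellmap: CellMap,
    config: ClusterConfig | None = None,
) -> ICNullResult:
    """Overlap indices of the map against its randomized-position null.

    The empirical map is clustered at the optimal n_c per ensemble and each
    tagged cluster's best Jaccard overlap with the cfos hulls is scored.
    ``config.n_artificial_null`` artificial maps are then analyzed the same
    way (reusing the empirical n_c by default; set ``recompute_nc_in_null``
    to re-optimize inside each set). The empirical summary statistic is the
    median best-I_c; its percentile is the mid-rank of that median among the
    null sets' medians, on the uniform grid (r + 0.5) / (n + 1).
    """
    config = config or ClusterConfig()
    nc_t, prop_t = optimal_cluster_number(cellmap, "tagged", config)
    nc_c, prop_c = optimal_cluster_number(cellmap, "cfos", config)
    pos_t = _ensemble_positions(cellmap, "tagged")
    pos_c = _ensemble_positions(cellmap, "cfos")
    kf = config.k_neighbors_fraction
    emp_ics = _best_ics(pos_t, pos_c, nc_t, nc_c, kf)
    emp_median = float(np.median(emp_ics)) if emp_ics else 0.0

    null_seed = np.random.SeedSequence(config.seed).generate_state(2)[1] % (2**31)
    pooled: list[float] = []
    medians: list[float] = []
    for a_t, a_c in _randomized_positions(cellmap, config.n_artificial_null, int(null_seed)):
        if config.recompute_nc_in_null:
            art_map = _positions_to_map(a_t, a_c, cellmap)
            n_t = optimal_cluster_number(art_map, "tagged", config)[0]
            n_c = optimal_cluster_number(art_map, "cfos", config)[0]
        else:
            n_t, n_c = nc_t, nc_c
        ics = _best_ics(a_t, a_c, n_t, n_c, kf)
        pooled.extend(ics)
        medians.append(float(np.median(ics)) if ics else 0.0)
    medians_arr = np.array(medians)
    r = float((medians_arr < emp_median).sum() + 0.5 * (medians_arr == emp_median).sum())
    percentile = (r + 0.5) / (len(medians_arr) + 1)
    return ICNullResult(
        empirical_ics=emp_ics,
        empirical_median=emp_median,
        null_ics=np.sort(np.array(pooled)),
        null_medians=medians_arr,
        percentile=float(percentile),
        nc_tagged=nc_t,
        nc_cfos=nc_c,
        proportions_tagged=prop_t,
        proportions_cfos=prop_c,
    )


def _positions_to_map(pos_t: np.ndarray, pos_c: np.ndarray, template: CellMap) -> CellMap:
    """Wrap bare ensemble positions as a CellMap (artificial sets only).

    The doubles of the template occupy the tails of both arrays by
    construction of ``_randomized_positions``: the last n_double tagged
    positions coincide with the last n_double cfos positions.
    """
    t_only, c_only, double = _label_groups(template)
    n_d = len(double)
    cells = []
    next_id = 0
    for p in pos_t[: len(t_only)]:
        cells.append(CellRecord(next_id, float(p[0]), float(p[1]), frozenset({"tagged"})))
        next_id += 1
    for p in pos_c[: len(c_only)]:
        cells.append(CellRecord(next_id, float(p[0]), float(p[1]), frozenset({"cfos"})))
        next_id += 1
    for p in pos_t[len(t_only) :]:
        cells.append(CellRecord(next_id, float(p[0]), float(p[1]), frozenset({"tagged", "cfos"})))
        next_id += 1
    return CellMap(cells=cells, mask=template.mask, n_gc_true=template.n_gc_true,
                   metadata={"artificial": True})
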