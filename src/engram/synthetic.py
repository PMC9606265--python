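"""Synthetic cell maps, intensity tables and CaMPARI tables.

Real inputs to this pipeline are per-cell spot tables exported from segmented
confocal sections. This module generates tables with the same statistical
structure — sparse labels, tunable overlap-over-chance, planted spatial
clusters, bimodal anticorrelated (cFos, ΔFosB) intensities, bimodal
photoconversion ratios — so every downstream analysis can be exercised and
validated against known ground truth.

The generators are seeded and bit-reproducible. Cell footprints follow the
standardized 16x16-pixel convention: a position is admissible only when that
footprint lies fully inside the layer mask. Footprints may overlap; no
exclusion radius is enforced.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .types import CELL_FOOTPRINT_PX, CellMap, CellRecord, LayerMask, ParameterError

__all__ = [
    "BandParams",
    "PlantedClusters",
    "GeneratorSpec",
    "make_layer_mask",
    "admissible_centers",
    "sample_positions",
    "sample_cellmap",
    "simulate_intensity_table",
    "simulate_campari",
    "DEFAULT_COMPONENTS",
]


# --------------------------------------------------------------------------
# layer masks
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BandParams:
    """Geometry of the curved cell-body bands.

    ``thickness_px`` is the band thickness in pixels (>= 16 so a standard
    cell footprint fits); ``curvature_px`` the peak-to-edge vertical bow of
    each band; ``gap_px`` the minimum vertical clearance between the blades;
    ``wiggle_px`` the amplitude of a smooth seeded perturbation.
    """

    thickness_px: int = 40
    curvature_px: float = 30.0
    gap_px: int = 24
    wiggle_px: float = 4.0


def make_layer_mask(
    rows: int,
    cols: int,
    pixel_size: float,
    band_params: BandParams | None = None,
    seed: int = 0,
    region_tag: str = "DG",
) -> LayerMask:
    """Draw a two-blade (DG) or single-band (CA1) cell-body-layer mask.

    The DG granule-cell layer appears in coronal sections as two curved
    blades; they are modeled as two parabolic bands bowing toward each
    other, separated by the hilus. Deterministic for fixed arguments.
    """
    bp = band_params or BandParams()
    if rows < 64 or cols < 64:
        raise ParameterError("mask must be at least 64 x 64 pixels")
    if bp.thickness_px < CELL_FOOTPRINT_PX:
        raise ParameterError(
            f"band thickness {bp.thickness_px} px is thinner than the "
            f"{CELL_FOOTPRINT_PX} px cell footprint"
        )
    rng = np.random.default_rng(seed)
    u = np.linspace(-1.0, 1.0, cols)
    bow = bp.curvature_px * (1.0 - u**2)  # 0 at edges, max mid-section
    phase = rng.uniform(0, 2 * np.pi, size=2)
    wiggle = [bp.wiggle_px * np.sin(2 * np.pi * u + p) for p in phase]

    grid = np.zeros((rows, cols), dtype=bool)
    if region_tag == "CA1":
        center = rows / 2 + wiggle[0]
        rr = np.arange(rows)[:, None]
        grid |= np.abs(rr - center[None, :]) < bp.thickness_px / 2
        return LayerMask(grid, pixel_size, region_tag="CA1")

    # two blades bowing toward each other, clearance >= gap_px everywhere
    sep = bp.thickness_px + bp.gap_px
    upper = rows * 0.30 + bow + wiggle[0]
    lower = rows * 0.70 - bow + wiggle[1]
    lower = np.maximum(lower, upper + sep)
    rr = np.arange(rows)[:, None]
    grid |= np.abs(rr - upper[None, :]) < bp.thickness_px / 2
    grid |= np.abs(rr - lower[None, :]) < bp.thickness_px / 2
    mask = LayerMask(grid, pixel_size, region_tag="DG")
    n_comp = ndimage.label(grid)[1]
    if n_comp != 2:
        raise ParameterError(
            f"band parameters produce {n_comp} connected components, not 2"
        )
    return mask


def admissible_centers(mask: LayerMask) -> np.ndarray:
    """Boolean raster of pixels whose 16x16 footprint fits inside the mask.

    The footprint of the pixel ``(r, c)`` spans rows ``[r-8, r+8)`` and the
    matching columns, mirroring the standardized neuron size used when cell
    positions are randomized within the layer.
    """
    fp = CELL_FOOTPRINT_PX
    return ndimage.minimum_filter(
        mask.grid.astype(np.uint8), size=fp, mode="constant", cval=0
    ).astype(bool)


def sample_positions(
    mask: LayerMask,
    n: int,
    rng: np.random.Generator,
    adm: np.ndarray | None = None,
) -> np.ndarray:
    """Uniformly sample ``n`` µm positions over admissible pixels.

    A pixel is drawn uniformly among admissible ones, then the position is
    jittered uniformly within that pixel. Pass a precomputed
    ``admissible_centers(mask)`` raster as ``adm`` to avoid recomputation
    in tight loops.
    """
    if adm is None:
        adm = admissible_centers(mask)
    rows, cols = np.nonzero(adm)
    if rows.size == 0:
        raise ParameterError("mask too thin: no pixel admits the cell footprint")
    idx = rng.integers(0, rows.size, size=n)
    x = (cols[idx] + rng.random(n)) * mask.pixel_size
    y = (rows[idx] + rng.random(n)) * mask.pixel_size
    return np.column_stack([x, y])


# --------------------------------------------------------------------------
# cell maps with tunable overlap and planted clusters
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedClusters:
    """Planted spatial clustering of the labeled ensembles.

    ``k`` cluster centers are placed inside the layer with pairwise
    separation at least ``min_separation`` (µm; default ``6 * spread``) and
    labeled cells are scattered around them with isotropic Gaussian
    ``spread`` (µm).
    """

    k: int
    spread: float = 25.0
    min_separation: float | None = None

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ParameterError("planted cluster count k must be >= 1")
        if self.spread <= 0:
            raise ParameterError("cluster spread must be positive")


@dataclass(frozen=True)
class GeneratorSpec:
    """Configuration of one synthetic cell map.

    ``rho`` is the target overlap-over-chance: the expected double-positive
    count is ``rho * f_tagged * f_cfos * n_cells``; ``rho = 1`` reproduces
    independent labels and ``rho = 0`` forbids double positives.
    ``shift`` displaces the cfos ensemble's cluster centers (µm), emulating
    ensembles that drift between days.
    """

    n_cells: int
    f_tagged: float = 0.03
    f_cfos: float = 0.03
    rho: float = 1.0
    cluster_model: PlantedClusters | None = None
    shift: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ParameterError("n_cells must be >= 1")
        for name in ("f_tagged", "f_cfos"):
            f = getattr(self, name)
            if not 0.0 <= f <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1]")
        if self.rho < 0:
            raise ParameterError("rho must be >= 0")
        if self.f_tagged * self.rho > 1.0 + 1e-12 or self.f_cfos * self.rho > 1.0 + 1e-12:
            raise ParameterError(
                "infeasible overlap: rho * f exceeds 1 for one ensemble"
            )


def _label_assignment(spec: GeneratorSpec, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Draw boolean (tagged, cfos) label vectors with the target dependence.

    Two-stage scheme: the tagged set is a uniform subset of size
    ``round(f_tagged * n)``; the double-positive count is then binomial with
    per-tagged-cell probability ``rho * f_cfos`` (so its expectation is
    exactly ``rho * f_tagged * f_cfos * n``), and the remaining cfos labels
    fall uniformly on untagged cells to keep the cfos total exact.
    """
    n = spec.n_cells
    n_tagged = int(round(spec.f_tagged * n))
    n_cfos = int(round(spec.f_cfos * n))
    tagged = np.zeros(n, dtype=bool)
    cfos = np.zeros(n, dtype=bool)
    tagged_idx = rng.choice(n, size=n_tagged, replace=False)
    tagged[tagged_idx] = True

    p_double = min(spec.rho * spec.f_cfos, 1.0)
    n_double = rng.binomial(n_tagged, p_double) if n_tagged else 0
    n_double = min(n_double, n_cfos)
    # keep the cfos total feasible on the untagged side
    n_double = max(n_double, n_cfos - (n - n_tagged))
    double_idx = rng.choice(tagged_idx, size=n_double, replace=False) if n_double else np.empty(0, int)
    cfos[double_idx] = True
    untagged_idx = np.nonzero(~tagged)[0]
    rest = n_cfos - n_double
    if rest:
        cfos[rng.choice(untagged_idx, size=rest, replace=False)] = True
    return tagged, cfos


def _planted_centers(
    mask: LayerMask, model: PlantedClusters, rng: np.random.Generator
) -> np.ndarray:
    """Dart-throw ``k`` well-separated centers over admissible pixels.

    Greedy over batches of uniform candidates, restarting when a batch gets
    stuck; deterministic for a fixed generator state.
    """
    min_sep = model.min_separation if model.min_separation is not None else 6.0 * model.spread
    adm = admissible_centers(mask)
    for _ in range(40):
        cand = sample_positions(mask, 4000, rng, adm=adm)
        centers: list[np.ndarray] = []
        for c in cand:
            if all(np.hypot(*(c - p)) >= min_sep for p in centers):
                centers.append(c)
                if len(centers) == model.k:
                    return np.array(centers)
    raise ParameterError(
        f"could not place {model.k} cluster centers {min_sep:.0f} µm apart; "
        "reduce k, spread or min_separation"
    )


def _scatter_around(
    centers: np.ndarray,
    n: int,
    spread: float,
    mask: LayerMask,
    rng: np.random.Generator,
) -> np.ndarray:
    """Gaussian scatter around randomly chosen centers, rejected into the mask."""
    adm = admissible_centers(mask)
    out = np.empty((n, 2), dtype=float)
    for i in range(n):
        for _ in range(1000):
            c = centers[rng.integers(0, len(centers))]
            pos = c + rng.normal(0.0, spread, size=2)
            col = int(pos[0] // mask.pixel_size)
            row = int(pos[1] // mask.pixel_size)
            if 0 <= row < adm.shape[0] and 0 <= col < adm.shape[1] and adm[row, col]:
                out[i] = pos
                break
        else:  # pathological geometry: fall back to a uniform admissible draw
            out[i] = sample_positions(mask, 1, rng)[0]
    return out


def sample_cellmap(mask: LayerMask, spec: GeneratorSpec) -> CellMap:
    """Generate one synthetic cell map under ``spec``.

    Unlabeled cells are uniform over admissible pixels. With a planted
    cluster model, tagged cells (including double positives) scatter around
    the tagged centers and cfos-only cells around the same centers displaced
    by ``spec.shift`` µm in a seeded random direction per center.
    """
    rng = np.random.default_rng(spec.seed)
    tagged, cfos = _label_assignment(spec, rng)
    n = spec.n_cells
    pos = sample_positions(mask, n, rng)

    if spec.cluster_model is not None:
        centers_t = _planted_centers(mask, spec.cluster_model, rng)
        if spec.shift != 0.0:
            theta = rng.uniform(0, 2 * np.pi, size=len(centers_t))
            delta = spec.shift * np.column_stack([np.cos(theta), np.sin(theta)])
            centers_c = centers_t + delta
        else:
            centers_c = centers_t
        spread = spec.cluster_model.spread
        idx_t = np.nonzero(tagged)[0]
        idx_c_only = np.nonzero(cfos & ~tagged)[0]
        pos[idx_t] = _scatter_around(centers_t, idx_t.size, spread, mask, rng)
        pos[idx_c_only] = _scatter_around(centers_c, idx_c_only.size, spread, mask, rng)

    cells = []
    for i in range(n):
        labels = set()
        if tagged[i]:
            labels.add("tagged")
        if cfos[i]:
            labels.add("cfos")
        cells.append(CellRecord(id=i, x=float(pos[i, 0]), y=float(pos[i, 1]), labels=frozenset(labels)))
    meta = {
        "seed": spec.seed,
        "rho": spec.rho,
        "f_tagged": spec.f_tagged,
        "f_cfos": spec.f_cfos,
        "planted_k": spec.cluster_model.k if spec.cluster_model else 0,
        "shift_um": spec.shift,
    }
    return CellMap(cells=cells, mask=mask, n_gc_true=n, metadata=meta)


# --------------------------------------------------------------------------
# (cFos, ΔFosB) intensity tables
# --------------------------------------------------------------------------

#: Mixture components on the normalized (cfos, ΔFosB) plane, before scaling
#: to arbitrary fluorescence units. Repressed = low cFos / high ΔFosB,
#: permissive = high cFos / low ΔFosB, other = low both.
DEFAULT_COMPONENTS: dict[str, dict[str, tuple[float, float]]] = {
    "repressed": {"mean": (0.15, 0.70), "sd": (0.07, 0.10)},
    "permissive": {"mean": (0.70, 0.12), "sd": (0.12, 0.06)},
    "other": {"mean": (0.15, 0.12), "sd": (0.06, 0.05)},
}

#: raw fluorescence scale (arbitrary units) applied to normalized levels
_INTENSITY_SCALE = 1000.0


def simulate_intensity_table(
    n: int,
    frac_repressed: float = 0.44,
    frac_permissive: float = 0.40,
    frac_other: float = 0.16,
    component_params: dict[str, dict[str, tuple[float, float]]] | None = None,
    noise_sd: float = 0.02,
    condition: str = "DT",
    seed: int = 0,
) -> pd.DataFrame:
    """Per-cell (cfos, pan_fosb, fosb_cterm) intensities with planted states.

    Each cell belongs to one of three expression-state components drawn with
    the given probabilities (defaults mirror a heavily trained condition
    where the repressed state dominates). The C-terminal FosB channel
    carries a baseline unrelated to ΔFosB; the pan-FosB channel is that
    baseline plus the planted ΔFosB level, so the antibody difference
    pan − cterm recovers ΔFosB. ``noise_sd`` is measurement noise on the
    normalized scale, applied per channel.

    Returns a DataFrame with columns id, cfos, pan_fosb, fosb_cterm,
    condition and the ground-truth ``true_state``.
    """
    fracs = np.array([frac_repressed, frac_permissive, frac_other], dtype=float)
    if np.any(fracs < 0) or abs(fracs.sum() - 1.0) > 1e-9:
        raise ParameterError("state fractions must be nonnegative and sum to 1")
    comps = component_params or DEFAULT_COMPONENTS
    for name, p in comps.items():
        if min(p["sd"]) <= 0:
            raise ParameterError(f"component {name!r} has nonpositive SD")
    rng = np.random.default_rng(seed)
    names = ["repressed", "permissive", "other"]
    state = rng.choice(3, size=n, p=fracs)

    cfos_level = np.empty(n)
    dfosb_level = np.empty(n)
    for s, name in enumerate(names):
        m = state == s
        mu = comps[name]["mean"]
        sd = comps[name]["sd"]
        cfos_level[m] = rng.normal(mu[0], sd[0], m.sum())
        dfosb_level[m] = rng.normal(mu[1], sd[1], m.sum())
    cfos_level = np.clip(cfos_level, 0.0, None)
    dfosb_level = np.clip(dfosb_level, 0.0, None)

    # FosB proper: constitutive, ΔFosB-independent, spanning an order of
    # magnitude with a right tail so both FosB channels share their upper
    # percentile scale (which is what makes the antibody-difference
    # calibration by percentile normalization meaningful)
    cterm_base = np.exp(rng.normal(-1.4, 1.1, size=n))
    cfos = cfos_level + rng.normal(0, noise_sd, n) if noise_sd > 0 else cfos_level
    pan = cterm_base + dfosb_level + (rng.normal(0, noise_sd, n) if noise_sd > 0 else 0.0)
    cterm = cterm_base + (rng.normal(0, noise_sd, n) if noise_sd > 0 else 0.0)

    return pd.DataFrame(
        {
            "id": np.arange(n),
            "cfos": np.clip(cfos, 0, None) * _INTENSITY_SCALE,
            "pan_fosb": np.clip(pan, 0, None) * _INTENSITY_SCALE,
            "fosb_cterm": np.clip(cterm, 0, None) * _INTENSITY_SCALE,
            "condition": condition,
            "true_state": [names[s] for s in state],
            "true_dfosb": dfosb_level,
        }
    )


# --------------------------------------------------------------------------
# CaMPARI red/green tables
# --------------------------------------------------------------------------

def simulate_campari(
    n: int,
    frac_reactivated: float = 0.23,
    conversion_params: dict[str, float] | None = None,
    fiber_tip: tuple[float, float] = (0.0, 0.0),
    p_cfos_reactivated: float = 0.15,
    p_cfos_other: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Red/green channel pairs for CaMPARI2-expressing cells.

    Reactivated cells draw conversion ratios strictly above 0.3 and the rest
    strictly below, via scaled Beta distributions (``conversion_params`` keys
    ``a``/``b`` shape both). Distances to the fiber tip are synthetic
    scalars uniform in [0, 400] µm — double the analysis cutoff, so the
    distance filter is exercised. cFos positivity is more likely among
    reactivated cells (most photoconverted cells nevertheless stay cFos-).
    """
    if not 0.0 <= frac_reactivated <= 1.0:
        raise ParameterError("frac_reactivated must lie in [0, 1]")
    cp = {"a": 2.0, "b": 5.0}
    if conversion_params:
        cp.update(conversion_params)
    rng = np.random.default_rng(seed)
    reactivated = rng.random(n) < frac_reactivated
    beta = rng.beta(cp["a"], cp["b"], size=n)
    ratio = np.where(reactivated, 0.3 + 0.7 * beta, 0.3 * beta)
    total = rng.lognormal(mean=5.0, sigma=0.4, size=n)
    cfos_p = np.where(reactivated, p_cfos_reactivated, p_cfos_other)
    cfos_positive = rng.random(n) < cfos_p
    dist = rng.uniform(0.0, 400.0, size=n)
    return pd.DataFrame(
        {
            "id": np.arange(n),
            "red": ratio * total,
            "green": (1.0 - ratio) * total,
            "cfos_positive": cfos_positive.astype(int),
            "fiber_distance_um": dist,
            "true_reactivated": reactivated.astype(int),
            "fiber_tip_x_um": fiber_tip[0],
            "fiber_tip_y_um": fiber_tip[1],
        }
    )
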