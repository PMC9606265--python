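"""Single-cell cFos vs ΔFosB expression-state analysis.

ΔFosB, a long-lived FosB splice variant, lacks the C-terminal domain that a
C-terminus-specific FosB antibody recognizes. Its per-cell signal is
therefore obtained by antibody difference: each channel is normalized by
its own 99th percentile (robust to hot pixels) and the C-terminal signal is
subtracted from the pan-FosB signal, clipping at zero.

On the normalized (cFos, ΔFosB) plane the analysis builds a peak-scaled
Gaussian kernel density estimate of the data and compares it against 100
KDEs of scrambled data (ΔFosB values permuted against cFos values —
marginals preserved, pairing broken, i.e. the no-interaction null).
Per-gridpoint z-scores, (actual − null mean) / null SD, localize where
cells are over- or under-represented. Two overrepresented regions are
expected when ΔFosB represses cFos: low cFos / high ΔFosB (the repressed
state) and high cFos / low ΔFosB (the permissive state). Quadrant
thresholds split the plane and per-quadrant cell fractions are reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import ParameterError

__all__ = [
    "StateMapResult",
    "delta_fosb_signal",
    "rank_correlation",
    "peak_scaled_kde",
    "scrambled_zscore_map",
    "default_thresholds",
    "state_fractions",
    "state_analysis",
]

#: floor applied to the per-gridpoint null SD when forming z-scores
SD_FLOOR = 1e-6


@dataclass
class StateMapResult:
    grid_x: np.ndarray           # cfos axis of the evaluation lattice
    grid_y: np.ndarray           # dfosb axis
    kde_actual: np.ndarray       # (len(grid_y), len(grid_x)), peak = 1
    null_mean: np.ndarray
    null_sd: np.ndarray
    z: np.ndarray
    thresholds: tuple[float, float]          # (cfos_cut, dfosb_cut)
    fractions: dict[str, float]              # repressed / permissive / other
    spearman_rho: float
    spearman_p: float


def delta_fosb_signal(table: pd.DataFrame, normalization_percentile: float = 99.0) -> pd.DataFrame:
    """Fill the ``dfosb`` column by percentile-normalized antibody difference.

    Also adds ``cfos_norm``: the cFos channel normalized the same way, so
    downstream analyses operate on a common dimensionless scale.
    """
    for col in ("cfos", "pan_fosb", "fosb_cterm"):
        if col not in table.columns:
            raise ParameterError(f"missing intensity column {col!r}")
    out = table.copy()
    scales = {}
    for col in ("cfos", "pan_fosb", "fosb_cterm"):
        q = float(np.percentile(out[col].to_numpy(float), normalization_percentile))
        if q <= 0:
            raise ParameterError(f"channel {col!r} is degenerate (percentile <= 0)")
        scales[col] = q
    pan = out["pan_fosb"].to_numpy(float) / scales["pan_fosb"]
    cterm = out["fosb_cterm"].to_numpy(float) / scales["fosb_cterm"]
    out["dfosb"] = np.clip(pan - cterm, 0.0, None)
    out["cfos_norm"] = out["cfos"].to_numpy(float) / scales["cfos"]
    return out


def rank_correlation(
    x: np.ndarray,
    y: np.ndarray,
    n_permutations: int = 9999,
    seed: int = 0,
) -> tuple[float, float]:
    """Spearman rho (average ranks on ties) with a permutation p value.

    The two-sided p is the fraction of seeded label permutations whose
    |rho| is at least the observed |rho|, with the identity permutation
    included (add-one rule).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(x) != len(y):
        raise ParameterError("need n >= 3 paired values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ParameterError("constant input has no rank correlation")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = (rx - rx.mean()) / rx.std()
    ry = (ry - ry.mean()) / ry.std()
    rho = float(np.mean(rx * ry))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(len(ry))
        if abs(np.mean(rx * ry[perm])) >= abs(rho) - 1e-12:
            count += 1
    p = (count + 1) / (n_permutations + 1)
    return rho, float(p)


def _bandwidths(points: np.ndarray, bandwidth: float | str) -> tuple[float, float]:
    n = len(points)
    if isinstance(bandwidth, str):
        if bandwidth != "scott":
            raise ParameterError(f"unknown bandwidth rule {bandwidth!r}")
        factor = n ** (-1.0 / 6.0)  # Scott's rule for 2-D data
        hx = factor * float(np.std(points[:, 0]))
        hy = factor * float(np.std(points[:, 1]))
    else:
        hx = hy = float(bandwidth)
    if hx <= 0 or hy <= 0:
        raise ParameterError("bandwidth must be positive in both axes")
    return hx, hy


def peak_scaled_kde(
    points: np.ndarray,
    grid_x: np.ndarray,
    grid_y: np.ndarray,
    bandwidth: float | str = "scott",
) -> np.ndarray:
    """Peak-scaled Gaussian KDE evaluated on a regular lattice.

    Axis-aligned Gaussian kernels with per-axis Scott bandwidths (or one
    scalar bandwidth for both axes); the density is divided by its maximum
    over the lattice so the peak equals 1. Returns an array indexed
    [y, x].
    """
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(points) < 10:
        raise ParameterError("need at least 10 points for a density estimate")
    hx, hy = _bandwidths(points, bandwidth)
    dx = (np.asarray(grid_x)[:, None] - points[None, :, 0]) / hx
    dy = (np.asarray(grid_y)[:, None] - points[None, :, 1]) / hy
    kx = np.exp(-0.5 * dx**2)           # (nx, n)
    ky = np.exp(-0.5 * dy**2)           # (ny, n)
    dens = ky @ kx.T                    # (ny, nx) sum over points
    peak = dens.max()
    if peak <= 0:
        raise ParameterError("density is identically zero on the lattice")
    return dens / peak


def scrambled_zscore_map(
    points: np.ndarray,
    grid_x: np.ndarray,
    grid_y: np.ndarray,
    n_scrambles: int = 100,
    bandwidth: float | str = "scott",
    seed: int = 0,
    scale_before_average: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Z-score map of the actual KDE against the scrambled-pairing null.

    Each scramble permutes the ΔFosB values against the cFos values, the
    KDE of each scramble is peak-scaled (set ``scale_before_average`` False
    to scale only the aggregate), and per-gridpoint mean and SD over
    scrambles define z = (actual − mean) / max(SD, floor).

    Returns (z, null_mean, null_sd).
    """
    if n_scrambles < 2:
        raise ParameterError("need at least 2 scrambles to estimate an SD")
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    actual = peak_scaled_kde(points, grid_x, grid_y, bandwidth)
    rng = np.random.default_rng(seed)
    acc = np.zeros_like(actual)
    acc2 = np.zeros_like(actual)
    for _ in range(n_scrambles):
        scr = points.copy()
        scr[:, 1] = scr[rng.permutation(len(scr)), 1]
        k = peak_scaled_kde(scr, grid_x, grid_y, bandwidth)
        acc += k
        acc2 += k**2
    mean = acc / n_scrambles
    var = np.clip(acc2 / n_scrambles - mean**2, 0.0, None)
    sd = np.sqrt(var)
    if not scale_before_average:
        # rescale the aggregate so its peak is 1 instead of scaling each KDE
        factor = 1.0 / mean.max()
        mean = mean * factor
        sd = sd * factor
    z = (actual - mean) / np.maximum(sd, SD_FLOOR)
    return z, mean, sd


def default_thresholds(
    z: np.ndarray, grid_x: np.ndarray, grid_y: np.ndarray
) -> tuple[float, float]:
    """Quadrant cuts between the two largest positive-z local maxima.

    Local maxima of the z map (strictly positive, no larger 8-neighbor) are
    ranked by z. The first mode is the global positive maximum; the second
    is the strongest maximum displaced from it by at least 15% of the
    lattice span on *both* axes — the repressed and permissive modes sit in
    opposite quadrants, so two peaks of one overrepresented region never
    both qualify. The cuts are the per-axis midpoints between the two
    modes. Falls back to the strongest remaining maximum, then to the
    lattice midpoints, when no pair qualifies.
    """
    zp = np.pad(z, 1, constant_values=-np.inf)
    neigh = np.stack([
        zp[1 + di : zp.shape[0] - 1 + di, 1 + dj : zp.shape[1] - 1 + dj]
        for di in (-1, 0, 1) for dj in (-1, 0, 1) if (di, dj) != (0, 0)
    ])
    is_max = (z > 0) & (z >= neigh.max(axis=0))
    ys, xs = np.nonzero(is_max)
    if len(ys) < 2:
        return float(np.median(grid_x)), float(np.median(grid_y))
    order = np.argsort(z[ys, xs])[::-1]
    y1, x1 = ys[order[0]], xs[order[0]]
    min_dx = 0.15 * len(grid_x)
    min_dy = 0.15 * len(grid_y)
    second = None
    for idx in order[1:]:
        if abs(xs[idx] - x1) >= min_dx and abs(ys[idx] - y1) >= min_dy:
            second = idx
            break
    if second is None:
        second = order[1]
    y2, x2 = ys[second], xs[second]
    cfos_cut = float((grid_x[x1] + grid_x[x2]) / 2)
    dfosb_cut = float((grid_y[y1] + grid_y[y2]) / 2)
    return cfos_cut, dfosb_cut


def state_fractions(
    table: pd.DataFrame, thresholds: tuple[float, float]
) -> dict[str, float]:
    """Quadrant fractions on the normalized plane.

    Repressed: cfos below the cut and ΔFosB at or above its cut.
    Permissive: cfos at or above the cut and ΔFosB below its cut.
    Other: the remaining cells. Fractions are over the analyzed cells in
    the table (callers pre-filter to labeled cells).
    """
    if len(table) == 0:
        raise ParameterError("empty table")
    cfos_cut, dfosb_cut = thresholds
    cfos = table["cfos_norm"].to_numpy(float)
    dfosb = table["dfosb"].to_numpy(float)
    repressed = (cfos < cfos_cut) & (dfosb >= dfosb_cut)
    permissive = (cfos >= cfos_cut) & (dfosb < dfosb_cut)
    n = len(table)
    return {
        "repressed": float(repressed.sum() / n),
        "permissive": float(permissive.sum() / n),
        "other": float((~repressed & ~permissive).sum() / n),
    }


def state_analysis(
    table: pd.DataFrame,
    grid_size: int = 64,
    n_scrambles: int = 100,
    bandwidth: float | str = "scott",
    thresholds: tuple[float, float] | None = None,
    n_permutations: int = 9999,
    seed: int = 0,
) -> StateMapResult:
    """Full single-cell expression-state analysis of one intensity table."""
    table = delta_fosb_signal(table)
    pts = table[["cfos_norm", "dfosb"]].to_numpy(float)
    lo_x, hi_x = pts[:, 0].min(), pts[:, 0].max()
    lo_y, hi_y = pts[:, 1].min(), pts[:, 1].max()
    pad_x = 0.05 * (hi_x - lo_x + 1e-12)
    pad_y = 0.05 * (hi_y - lo_y + 1e-12)
    grid_x = np.linspace(lo_x - pad_x, hi_x + pad_x, grid_size)
    grid_y = np.linspace(lo_y - pad_y, hi_y + pad_y, grid_size)

    kde = peak_scaled_kde(pts, grid_x, grid_y, bandwidth)
    z, null_mean, null_sd = scrambled_zscore_map(
        pts, grid_x, grid_y, n_scrambles=n_scrambles, bandwidth=bandwidth, seed=seed
    )
    cuts = thresholds or default_thresholds(z, grid_x, grid_y)
    fractions = state_fractions(table, cuts)
    rho, p = rank_correlation(pts[:, 0], pts[:, 1], n_permutations=n_permutations, seed=seed)
    return StateMapResult(
        grid_x=grid_x, grid_y=grid_y, kde_actual=kde,
        null_mean=null_mean, null_sd=null_sd, z=z,
        thresholds=cuts, fractions=fractions,
        spearman_rho=rho, spearman_p=p,
    )
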