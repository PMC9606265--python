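"""Stochastic simulation of cFos turnover with slow negative feedback.

Each cell is an independent discrete-time unit (step ``dt`` hours). A cell
that is not currently expressing cFos inducts in a step with probability

    p_i = h0 * propensity_i * gate(S_i)

where ``propensity_i`` is a fixed per-cell lognormal activity factor and
``S_i`` a slowly decaying suppressor (ΔFosB-like): every induction adds
``suppressor_gain`` to S_i, which decays exponentially with
``suppressor_halflife``. The gate maps suppressor level to an induction
multiplier in [0, 1]: a hard gate blocks induction entirely above a
threshold; a soft gate attenuates it as exp(-S / slope). Once induced, a
cell counts as cFos+ (reporter visible) for ``reporter_lifetime`` hours;
when the reporter expires the cell may instead keep expressing for another
step with probability ``sustain_prob`` (persistent expression as seen in
CA1 pyramidal cells).

The tagged ensemble is every cell that expressed at any time during the
first ``tag_window`` hours. The similarity trajectory then tracks, at each
hour after the window closes, the fraction of tagged cells currently
expressing (overlap), the population expressing fraction, and their ratio —
the normalized ensemble overlap, 1 under independence.

Two documented presets bracket the biology:

* ``dg``: suppression on, no sustained expression. Tagged granule cells
  cannot re-induct while the suppressor persists, so overlap decays
  linearly as reporters expire and falls below chance within 24 h.
* ``ca1``: gate disabled, sustained expression plus per-cell heterogeneity.
  Re-expression of tagged cells is at least as likely as the population
  rate, so normalized overlap never drops below 1.

The presets are qualitative model configurations, not fits to data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .types import ParameterError

__all__ = [
    "FeedbackParams",
    "SimulationLog",
    "SimilarityTrajectory",
    "preset",
    "simulate_population",
    "similarity_curve",
    "fit_linear_decay",
]


@dataclass(frozen=True)
class FeedbackParams:
    n_cells: int = 10_000
    dt: float = 1.0                    # hours
    horizon: float = 48.0              # hours simulated in total
    h0: float = 0.002                  # baseline induction probability per step
    reporter_lifetime: float = 24.0    # hours a cell stays cFos+ after induction
    suppressor_gain: float = 1.0       # S increment per induction event
    suppressor_halflife: float = 200.0  # hours; long-lived like ΔFosB
    gate: str = "hard"                 # "hard" | "soft" | "none"
    gate_threshold: float = 0.5        # hard gate: block induction when S >= threshold
    gate_slope: float = 1.0            # soft gate: multiplier exp(-S / slope)
    heterogeneity_sd: float = 0.0      # SD of per-cell log propensity
    sustain_prob: float = 0.0          # per-step renewal after reporter expiry
    tag_window: float = 24.0           # hours of the tagging (Dox-off) window
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.horizon < self.tag_window:
            raise ParameterError("need dt > 0 and horizon >= tag_window")
        if not 0 <= self.h0 <= 1 or not 0 <= self.sustain_prob < 1:
            raise ParameterError("h0 in [0,1] and sustain_prob in [0,1) required")
        if self.gate not in ("hard", "soft", "none"):
            raise ParameterError("gate must be 'hard', 'soft' or 'none'")
        if self.reporter_lifetime < 0 or self.suppressor_halflife <= 0:
            raise ParameterError("invalid lifetime/halflife")
        if self.heterogeneity_sd < 0 or self.suppressor_gain < 0:
            raise ParameterError("negative heterogeneity or gain")


#: documented model configurations (see module docstring)
_PRESETS: dict[str, dict] = {
    "dg": dict(h0=0.0035, reporter_lifetime=24.0, gate="hard", gate_threshold=0.5,
               suppressor_gain=1.0, suppressor_halflife=200.0,
               heterogeneity_sd=0.0, sustain_prob=0.0),
    "ca1": dict(h0=0.01, reporter_lifetime=24.0, gate="none",
                suppressor_gain=0.0, heterogeneity_sd=1.0, sustain_prob=0.5),
    "independent": dict(h0=0.005, reporter_lifetime=6.0, gate="none",
                        suppressor_gain=0.0, heterogeneity_sd=0.0, sustain_prob=0.0),
}


def preset(name: str, **overrides) -> FeedbackParams:
    """Named parameter set (``dg``, ``ca1`` or ``independent``) with overrides."""
    if name not in _PRESETS:
        raise ParameterError(f"unknown preset {name!r}; choose from {sorted(_PRESETS)}")
    return replace(FeedbackParams(), **{**_PRESETS[name], **overrides})


@dataclass
class SimulationLog:
    """Per-step expression record of one simulated population."""

    params: FeedbackParams
    times: np.ndarray          # step start times, hours
    expressing: np.ndarray     # (n_steps, n_cells) bool
    inductions: np.ndarray     # (n_steps, n_cells) bool, True on induction steps
    propensity: np.ndarray     # per-cell activity factor


@dataclass
class SimilarityTrajectory:
    times: np.ndarray              # hours since tag-window close
    tagged_fraction: float
    overlap_fraction: np.ndarray   # fraction of tagged cells currently cFos+
    population_fraction: np.ndarray
    normalized: np.ndarray         # overlap / population (NaN where population = 0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "dt_hours": self.times,
                "overlap_fraction": self.overlap_fraction,
                "population_fraction": self.population_fraction,
                "normalized": self.normalized,
            }
        )


def _gate_multiplier(params: FeedbackParams, s: np.ndarray) -> np.ndarray:
    if params.gate == "none":
        return np.ones_like(s)
    if params.gate == "hard":
        return (s <= params.gate_threshold).astype(float)
    return np.exp(-s / params.gate_slope)


def simulate_population(params: FeedbackParams) -> SimulationLog:
    """Run the per-cell induction/suppression dynamics; fully seeded."""
    rng = np.random.default_rng(params.seed)
    n = params.n_cells
    n_steps = int(round(params.horizon / params.dt)) + 1
    decay = 0.5 ** (params.dt / params.suppressor_halflife)
    life_steps = int(round(params.reporter_lifetime / params.dt))

    propensity = (
        np.exp(rng.normal(-params.heterogeneity_sd**2 / 2, params.heterogeneity_sd, n))
        if params.heterogeneity_sd > 0
        else np.ones(n)
    )
    s = np.zeros(n)
    timer = np.zeros(n, dtype=int)  # remaining expressing steps; 0 = off
    expressing = np.zeros((n_steps, n), dtype=bool)
    inductions = np.zeros((n_steps, n), dtype=bool)
    times = np.arange(n_steps) * params.dt

    for step in range(n_steps):
        off = timer == 0
        p = np.clip(params.h0 * propensity * _gate_multiplier(params, s), 0.0, 1.0)
        induct = off & (rng.random(n) < p)
        timer[induct] = max(life_steps, 1)
        s[induct] += params.suppressor_gain
        inductions[step] = induct
        expressing[step] = timer > 0
        # advance: decrement reporters, renew persistent cells at expiry
        expiring = timer == 1
        timer[timer > 0] -= 1
        if params.sustain_prob > 0 and expiring.any():
            renew = expiring & (rng.random(n) < params.sustain_prob)
            timer[renew] = 1
        s *= decay

    return SimulationLog(params=params, times=times, expressing=expressing,
                         inductions=inductions, propensity=propensity)


def similarity_curve(log: SimulationLog, params: FeedbackParams | None = None) -> SimilarityTrajectory:
    """Normalized ensemble-overlap trajectory after the tag window closes."""
    params = params or log.params
    close = int(round(params.tag_window / params.dt))
    tagged = log.expressing[: close + 1].any(axis=0)
    n_tagged = int(tagged.sum())
    if n_tagged == 0:
        raise ParameterError("no cell was tagged during the tag window")
    post = log.expressing[close:]
    times = log.times[close:] - params.tag_window
    overlap = post[:, tagged].mean(axis=1)
    population = post.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        normalized = np.where(population > 0, overlap / population, np.nan)
    return SimilarityTrajectory(
        times=times,
        tagged_fraction=n_tagged / params.n_cells,
        overlap_fraction=overlap,
        population_fraction=population,
        normalized=normalized,
    )


def fit_linear_decay(
    trajectory: SimilarityTrajectory, window: float = 24.0
) -> tuple[float, float, float]:
    """OLS fit of normalized overlap vs Δt within [0, window] hours.

    Returns (slope per hour, intercept, r_squared).
    """
    m = (trajectory.times <= window) & np.isfinite(trajectory.normalized)
    if m.sum() < 3:
        raise ParameterError("need at least 3 defined points in the fit window")
    res = stats.linregress(trajectory.times[m], trajectory.normalized[m])
    return float(res.slope), float(res.intercept), float(res.rvalue**2)
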