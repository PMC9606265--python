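"""CaMPARI2 photoconversion scoring.

CaMPARI2 converts from green to red under 405 nm light only in cells with
high intracellular calcium, leaving a permanent record of activity. The
conversion ratio of a cell is R / (R + G); cells with ratio strictly above
0.3 count as photoconverted (reactivated). Because converting light reaches
a limited depth, the analysis is restricted to cells within 200 µm of the
fiber tip (inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import ParameterError

__all__ = ["CampariSummary", "conversion_ratio", "classify_and_summarize"]

RATIO_THRESHOLD = 0.3
MAX_FIBER_DISTANCE_UM = 200.0


@dataclass(frozen=True)
class CampariSummary:
    n_total: int            # rows in the input table
    n_retained: int         # within the distance filter, ratio defined
    n_undefined_ratio: int  # red + green == 0 among distance-filtered cells
    frac_photoconverted: float
    frac_cfos: float
    frac_both: float
    counts: dict[str, int]


def conversion_ratio(red: np.ndarray, green: np.ndarray) -> np.ndarray:
    """R / (R + G); NaN where both channels are zero."""
    red = np.asarray(red, dtype=float)
    green = np.asarray(green, dtype=float)
    if (red < 0).any() or (green < 0).any():
        raise ParameterError("fluorescence intensities must be nonnegative")
    total = red + green
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(total > 0, red / total, np.nan)
    return ratio


def classify_and_summarize(
    table: pd.DataFrame,
    ratio_threshold: float = RATIO_THRESHOLD,
    max_distance_um: float = MAX_FIBER_DISTANCE_UM,
) -> CampariSummary:
    """Photoconverted / cFos+ / both fractions over analyzable cells.

    Cells farther than ``max_distance_um`` from the fiber tip (strictly;
    the boundary is retained) and cells with an undefined ratio (both
    channels zero) are excluded from the denominator; the latter are
    reported in ``n_undefined_ratio``. Photoconversion requires ratio
    strictly above the threshold.
    """
    for col in ("red", "green", "cfos_positive", "fiber_distance_um"):
        if col not in table.columns:
            raise ParameterError(f"missing column {col!r}")
    near = table[table["fiber_distance_um"].to_numpy(float) <= max_distance_um]
    ratio = conversion_ratio(near["red"].to_numpy(), near["green"].to_numpy())
    defined = np.isfinite(ratio)
    n_undef = int((~defined).sum())
    kept = near[defined]
    ratio = ratio[defined]
    if len(kept) == 0:
        raise ParameterError(
            f"no analyzable cells: {len(table)} input, {len(near)} within "
            f"{max_distance_um} µm, {n_undef} with undefined ratio"
        )
    pc = ratio > ratio_threshold
    cfos = kept["cfos_positive"].to_numpy() > 0
    n = len(kept)
    counts = {
        "photoconverted": int(pc.sum()),
        "cfos": int(cfos.sum()),
        "both": int((pc & cfos).sum()),
    }
    return CampariSummary(
        n_total=len(table),
        n_retained=n,
        n_undefined_ratio=n_undef,
        frac_photoconverted=counts["photoconverted"] / n,
        frac_cfos=counts["cfos"] / n,
        frac_both=counts["both"] / n,
        counts=counts,
    )
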