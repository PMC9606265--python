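"""Core data containers shared across the analysis modules.

All spatial coordinates are in micrometres (µm), continuous, with the origin
at the top-left corner of the layer-mask raster: ``x`` runs along columns,
``y`` along rows, and mask pixel ``(row, col)`` covers the square
``[col*pixel_size, (col+1)*pixel_size) x [row*pixel_size, (row+1)*pixel_size)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np

#: side length, in pixels, of the standardized square footprint a cell body
#: occupies on the mask raster; a cell position is admissible only if this
#: footprint lies entirely inside the mask.
CELL_FOOTPRINT_PX = 16


class ParameterError(ValueError):
    """A parameter violates a documented precondition."""


@dataclass(frozen=True)
class LayerMask:
    """Binary raster of the cell-body layer of one imaged section.

    Parameters
    ----------
    grid
        Boolean array (rows x cols); ``True`` marks the layer.
    pixel_size
        Edge length of one pixel in µm; must be positive.
    region_tag
        Anatomical region the mask describes, ``"DG"`` (granule-cell layer,
        drawn as two blades) or ``"CA1"`` (single pyramidal band).
    """

    grid: np.ndarray
    pixel_size: float
    region_tag: str = "DG"

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=bool)
        object.__setattr__(self, "grid", grid)
        if self.pixel_size <= 0:
            raise ParameterError("pixel_size must be positive")
        if not grid.any():
            raise ParameterError("mask has no interior pixels")
        if self.region_tag not in ("DG", "CA1"):
            raise ParameterError(f"unknown region_tag {self.region_tag!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Vectorized membership test: is each (x, y) µm position inside?"""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor(x / self.pixel_size).astype(int)
        row = np.floor(y / self.pixel_size).astype(int)
        rows, cols = self.grid.shape
        ok = (row >= 0) & (row < rows) & (col >= 0) & (col < cols)
        inside = np.zeros(ok.shape, dtype=bool)
        inside[ok] = self.grid[row[ok], col[ok]]
        return inside


@dataclass
class CellRecord:
    """One segmented cell (an Imaris-style spot) from a section."""

    id: int
    x: float
    y: float
    labels: frozenset[str] = frozenset()
    intensities: dict[str, float] = field(default_factory=dict)
    aux: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = frozenset(self.labels)
        bad = self.labels - {"tagged", "cfos"}
        if bad:
            raise ParameterError(f"unknown labels {sorted(bad)}")
        for name, value in self.intensities.items():
            if value < 0:
                raise ParameterError(f"negative intensity in channel {name!r}")


@dataclass
class CellMap:
    """All cells of one imaged section plus its layer mask.

    ``n_gc_true`` carries a known total granule-cell count (synthetic maps
    have one by construction); when absent the count is estimated downstream
    from layer measure x published density.
    """

    cells: list[CellRecord]
    mask: LayerMask
    n_gc_true: int | None = None
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [c.id for c in self.cells]
        if len(set(ids)) != len(ids):
            raise ParameterError("cell ids are not unique")
        if self.cells:
            inside = self.mask.contains(
                np.array([c.x for c in self.cells]),
                np.array([c.y for c in self.cells]),
            )
            if not inside.all():
                n_out = int((~inside).sum())
                raise ParameterError(f"{n_out} cell(s) lie outside the mask")
        if self.n_gc_true is not None and self.n_gc_true < len(self.labeled("tagged") | self.labeled("cfos")):
            raise ParameterError("n_gc_true smaller than the number of labeled cells")

    def __len__(self) -> int:
        return len(self.cells)

    def positions(self, label: str | None = None) -> np.ndarray:
        """(n, 2) array of µm positions, optionally restricted to one label."""
        cells = self.cells if label is None else [c for c in self.cells if label in c.labels]
        if not cells:
            return np.empty((0, 2), dtype=float)
        return np.array([[c.x, c.y] for c in cells], dtype=float)

    def labeled(self, label: str) -> set[int]:
        return {c.id for c in self.cells if label in c.labels}


def as_dataframe(cellmap: CellMap) -> "pd.DataFrame":  # noqa: F821
    """Flat per-cell table (id, x_um, y_um, tagged, cfos, channels...)."""
    import pandas as pd

    channels: list[str] = sorted({ch for c in cellmap.cells for ch in c.intensities})
    rows = []
    for c in cellmap.cells:
        row: dict[str, Any] = {
            "id": c.id,
            "x_um": c.x,
            "y_um": c.y,
            "tagged": int("tagged" in c.labels),
            "cfos": int("cfos" in c.labels),
        }
        for ch in channels:
            row[ch] = c.intensities.get(ch, 0.0)
        for k, v in c.aux.items():
            row[k] = v
        rows.append(row)
    return pd.DataFrame(rows)
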