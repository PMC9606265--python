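"""Readers and writers for cell tables, layer masks and result files.

Cell tables are comma-separated UTF-8 CSV with a mandatory header and the
columns ``id, x_um, y_um, tagged, cfos`` (booleans as 0/1); any further
numeric column is carried as an intensity channel. Masks are 8-bit
grayscale PNG or TIFF (0 = outside, any nonzero = inside) or a plain-text
0/1 matrix; the pixel size travels in the run configuration, not the image.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .types import CellMap, CellRecord, LayerMask, ParameterError, as_dataframe

logger = logging.getLogger("engram")

REQUIRED_COLUMNS = ("id", "x_um", "y_um", "tagged", "cfos")
_NON_CHANNEL = set(REQUIRED_COLUMNS) | {"condition", "true_state"}


def write_mask(mask: LayerMask, path: str | Path) -> None:
    path = Path(path)
    arr = (mask.grid.astype(np.uint8)) * 255
    if path.suffix == ".txt":
        np.savetxt(path, mask.grid.astype(np.uint8), fmt="%d")
    elif path.suffix in (".png",):
        from PIL import Image

        Image.fromarray(arr).save(path)
    elif path.suffix in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, arr)
    else:
        raise ParameterError(f"unsupported mask format {path.suffix!r}")


def read_mask(path: str | Path, pixel_size: float, region_tag: str = "DG") -> LayerMask:
    path = Path(path)
    if path.suffix == ".txt":
        grid = np.loadtxt(path) != 0
    elif path.suffix == ".png":
        from PIL import Image

        grid = np.asarray(Image.open(path)) != 0
    elif path.suffix in (".tif", ".tiff"):
        import tifffile

        grid = tifffile.imread(path) != 0
    else:
        raise ParameterError(f"unsupported mask format {path.suffix!r}")
    return LayerMask(grid=grid, pixel_size=pixel_size, region_tag=region_tag)


def write_cellmap(cellmap: CellMap, table_path: str | Path, mask_path: str | Path | None = None) -> None:
    as_dataframe(cellmap).to_csv(table_path, index=False)
    if mask_path is not None:
        write_mask(cellmap.mask, mask_path)


def read_cellmap(
    table_path: str | Path,
    mask_path: str | Path,
    pixel_size: float,
    region_tag: str = "DG",
    n_gc_true: int | None = None,
) -> CellMap:
    """Load and validate a cell table against its layer mask.

    Cells outside the mask are rejected with a logged count, mirroring the
    masking step that restricts analysis to the cell-body layer.
    """
    table = pd.read_csv(table_path)
    for col in REQUIRED_COLUMNS:
        if col not in table.columns:
            raise ParameterError(f"cell table is missing required column {col!r}")
    mask = read_mask(mask_path, pixel_size=pixel_size, region_tag=region_tag)
    inside = mask.contains(table["x_um"].to_numpy(float), table["y_um"].to_numpy(float))
    n_rejected = int((~inside).sum())
    if n_rejected:
        logger.warning("rejected %d cell(s) outside the layer mask", n_rejected)
    table = table[inside]
    channels = [
        c for c in table.columns
        if c not in _NON_CHANNEL and pd.api.types.is_numeric_dtype(table[c])
    ]
    cells = []
    for row in table.itertuples(index=False):
        labels = set()
        if getattr(row, "tagged"):
            labels.add("tagged")
        if getattr(row, "cfos"):
            labels.add("cfos")
        cells.append(
            CellRecord(
                id=int(getattr(row, "id")),
                x=float(getattr(row, "x_um")),
                y=float(getattr(row, "y_um")),
                labels=frozenset(labels),
                intensities={c: float(getattr(row, c)) for c in channels},
            )
        )
    return CellMap(cells=cells, mask=mask, n_gc_true=n_gc_true,
                   metadata={"source": str(table_path), "n_rejected_outside_mask": n_rejected})


def write_json(obj: dict[str, Any], path: str | Path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=_default, sort_keys=True))
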