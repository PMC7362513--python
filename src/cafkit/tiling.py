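"""Tile grid construction and per-tile densitometry.

Registered marker images are divided into square tiles of a fixed
physical area (default 15 um x 15 um = 225 um^2, roughly one
fibroblast). Each full tile is either *stromal* (retained for
classification) or *masked* (majority-epithelial); partial tiles at the
image edge are discarded but still counted, so
stromal + masked + edge = total grid tiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = ["TileGrid", "tile_features"]


@dataclass(frozen=True)
class TileGrid:
    """Row-major grid of half-open pixel tiles over an image domain."""

    image_shape: tuple[int, int]  # (height, width) in pixels
    um_per_pixel: float
    tile_side_um: float = 15.0

    def __post_init__(self) -> None:
        if self.um_per_pixel is None or self.um_per_pixel <= 0:
            raise ValueError("um_per_pixel must be a positive number")
        if self.tile_side_um <= 0:
            raise ValueError("tile side must be positive")
        side = self.tile_side_um / self.um_per_pixel
        if abs(side - round(side)) > 1e-9 or round(side) < 1:
            raise ValueError(
                f"tile side of {self.tile_side_um} um is not a whole number of "
                f"pixels at {self.um_per_pixel} um/px"
            )

    @property
    def tile_side_px(self) -> int:
        return int(round(self.tile_side_um / self.um_per_pixel))

    @property
    def tile_area_um2(self) -> float:
        return self.tile_side_um**2

    @property
    def shape(self) -> tuple[int, int]:
        """(rows, cols) counting all tiles, including partial edge tiles."""
        h, w = self.image_shape
        s = self.tile_side_px
        return (-(-h // s), -(-w // s))

    @property
    def n_tiles(self) -> int:
        r, c = self.shape
        return r * c

    def tile_extent(self, row: int, col: int) -> tuple[int, int, int, int]:
        """Half-open pixel extent (y0, y1, x0, x1), clipped to the image."""
        s = self.tile_side_px
        h, w = self.image_shape
        return (row * s, min((row + 1) * s, h), col * s, min((col + 1) * s, w))

    def is_full(self, row: int, col: int) -> bool:
        y0, y1, x0, x1 = self.tile_extent(row, col)
        s = self.tile_side_px
        return (y1 - y0) == s and (x1 - x0) == s


def tile_features(
    od_images: Mapping[str, np.ndarray],
    grid: TileGrid,
    epithelium_mask: np.ndarray | None = None,
    coverage_threshold: float = 0.5,
) -> pd.DataFrame:
    """Mean DAB optical density per tile per marker.

    ``od_images`` maps marker name -> 2D OD image, all co-registered and
    of the grid's image shape. ``epithelium_mask`` is boolean (True =
    epithelium); a full tile whose epithelial pixel fraction is >=
    ``coverage_threshold`` is flagged ``masked``, otherwise ``stromal``.
    Partial edge tiles are flagged ``edge`` and carry no features.

    Returns a tidy frame with one row per grid tile: ``tile_id``,
    ``row``, ``col``, ``flag`` and one ``od_<marker>`` column per marker
    (NaN for edge tiles).
    """
    if not od_images:
        raise ValueError("at least one marker OD image is required")
    markers = list(od_images)
    for m, img in od_images.items():
        if img.shape[:2] != grid.image_shape:
            raise ValueError(
                f"marker {m}: image shape {img.shape[:2]} does not match "
                f"grid {grid.image_shape}"
            )
    if epithelium_mask is not None and epithelium_mask.shape != grid.image_shape:
        raise ValueError("epithelium mask shape does not match the grid")

    rows = []
    nrows, ncols = grid.shape
    for r in range(nrows):
        for c in range(ncols):
            rec: dict = {"tile_id": r * ncols + c, "row": r, "col": c}
            if not grid.is_full(r, c):
                rec["flag"] = "edge"
                for m in markers:
                    rec[f"od_{m}"] = np.nan
                rows.append(rec)
                continue
            y0, y1, x0, x1 = grid.tile_extent(r, c)
            if epithelium_mask is not None:
                frac = float(np.mean(epithelium_mask[y0:y1, x0:x1]))
                rec["flag"] = "masked" if frac >= coverage_threshold else "stromal"
            else:
                rec["flag"] = "stromal"
            for m in markers:
                rec[f"od_{m}"] = float(np.mean(od_images[m][y0:y1, x0:x1]))
            rows.append(rec)
    df = pd.DataFrame(rows)
    for m in markers:
        stromal = df.loc[df["flag"] == "stromal", f"od_{m}"]
        if (stromal < 0).any():
            raise ValueError(f"marker {m}: negative optical densities in tiles")
    return df
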