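"""Tile-wise CAF subset maps: classification and rendering.

Stromal tiles of a registered serial-section set are classified with
the same quartile decision tree used at tumor level, with thresholds
fitted on the section set's own stromal tiles (the tile-scale analogue
of cohort-relative quartiles). Masked (epithelial) tiles are painted
gray and discarded edge tiles black in the rendered map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .subtyping import (
    SUBSET_COLORS,
    SUBSETS,
    DecisionTreeSpec,
    MarkerPanel,
    QuantileThresholds,
    classify_subset,
    fit_quantile_thresholds,
)
from .tiling import TileGrid

__all__ = ["SubsetMap", "classify_tiles", "render_map"]


def _hex_to_rgb(h: str) -> tuple[int, int, int]:
    h = h.lstrip("#")
    return tuple(int(h[i : i + 2], 16) for i in (0, 2, 4))  # type: ignore[return-value]


@dataclass(frozen=True)
class SubsetMap:
    """Per-tile subset labels plus the thresholds they were called with."""

    tiles: pd.DataFrame  # tile_id, row, col, flag, od_*, label
    grid: TileGrid
    thresholds: QuantileThresholds

    @property
    def labels(self) -> pd.Series:
        return self.tiles.set_index("tile_id")["label"]

    @property
    def proportions(self) -> pd.Series:
        """Subset proportions over stromal tiles, in percent (sums to 100)."""
        stromal = self.tiles[self.tiles["flag"] == "stromal"]
        counts = stromal["label"].value_counts()
        return counts.reindex(SUBSETS, fill_value=0) / len(stromal) * 100.0

    def accuracy_vs(self, truth_labels: pd.Series) -> float:
        """Fraction of stromal tiles whose label matches a truth labeling."""
        stromal = self.tiles[self.tiles["flag"] == "stromal"]
        truth = truth_labels.reindex(stromal["tile_id"])
        return float(np.mean(stromal["label"].to_numpy() == truth.to_numpy()))


def classify_tiles(
    features: pd.DataFrame,
    grid: TileGrid,
    tree: DecisionTreeSpec | None = None,
    thresholds: QuantileThresholds | None = None,
) -> SubsetMap:
    """Label every stromal tile with a CAF subset.

    Quartile thresholds are fitted per marker over the stromal tiles of
    this section set unless supplied. Masked tiles get the label
    ``masked`` and edge tiles ``edge``; at least 4 stromal tiles are
    required for the quantiles to be defined.
    """
    markers = [c[3:] for c in features.columns if c.startswith("od_")]
    if not markers:
        raise ValueError("feature table has no od_<marker> columns")
    stromal = features[features["flag"] == "stromal"]
    if len(stromal) < 4:
        raise ValueError(
            f"need >= 4 stromal tiles to fit quartile thresholds, "
            f"got {len(stromal)}"
        )
    if thresholds is None:
        thresholds = fit_quantile_thresholds(
            {m: stromal[f"od_{m}"].to_numpy() for m in markers}
        )

    labels = []
    for _, rec in features.iterrows():
        if rec["flag"] != "stromal":
            labels.append(rec["flag"])
            continue
        panel = MarkerPanel(**{m: rec[f"od_{m}"] for m in markers})
        labels.append(classify_subset(panel, thresholds, tree=tree, mode="tree"))
    tiles = features.copy()
    tiles["label"] = labels
    return SubsetMap(tiles=tiles, grid=grid, thresholds=thresholds)


def render_map(
    subset_map: SubsetMap, colors: dict[str, str] | None = None
) -> np.ndarray:
    """Paint each tile its subset color; masked tiles gray, edge black.

    Returns an RGB uint8 image of the grid's pixel domain whose colors
    come exactly from the six-color palette.
    """
    colors = colors or SUBSET_COLORS
    grid = subset_map.grid
    h, w = grid.image_shape
    out = np.zeros((h, w, 3), dtype=np.uint8)
    for _, rec in subset_map.tiles.iterrows():
        label = rec["label"]
        if label not in colors:
            raise ValueError(f"no rendering color for label {label!r}")
        y0, y1, x0, x1 = grid.tile_extent(int(rec["row"]), int(rec["col"]))
        out[y0:y1, x0:x1] = _hex_to_rgb(colors[label])
    return out
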