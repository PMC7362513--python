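"""Synthetic serial-section IHC stacks with ground-truth subset layout.

Each simulated tumor region is a mosaic of CAF-subset territories laid
out on the analysis tile lattice (so every full tile is pure), stained
for one marker per section under a Beer-Lambert H-DAB model, deformed
by a known smooth warp per non-reference section, and annotated with
the landmark pairs that encode that warp plus a tile-aligned
epithelium mask.

Two generator choices make the noise-free stacks exactly analyzable:

* subset territory areas are balanced up to a rounding that places the
  stromal-tile quartiles of every marker in the gaps between the
  subsets' mean OD levels, so cohort-relative thresholds recover the
  generating bands;
* the warp (translation + rotation + low-frequency sinusoid) is
  tapered to zero at the image boundary, so deformed sections never
  sample outside the frame.

Measurement noise is added as ``od_noise_sd`` times a unit-variance
noise field drawn independently of the noise SD, so stacks generated
from the same seed at increasing noise levels share their noise
pattern (common random numbers).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

from ..registration import LandmarkSet
from ..stains import StainModel, mix_stains
from ..subtyping import SUBSETS
from ..tiling import TileGrid

__all__ = ["SectionSimParams", "SerialSectionSet", "generate_serial_sections"]

#: Mean DAB OD per marker per subset. Values sit at distinct levels per
#: marker so that with near-balanced areas the fitted tile quartiles
#: fall between levels (see _quartile_aligned_quotas).
DEFAULT_MEAN_OD = {
    "fap": {"CAF-S1": 0.875, "CAF-S2": 0.10, "CAF-S3": 0.14, "CAF-S4": 0.30},
    "sma": {"CAF-S1": 0.85, "CAF-S2": 0.10, "CAF-S3": 0.28, "CAF-S4": 0.90},
    "cd29": {"CAF-S1": 0.55, "CAF-S2": 0.30, "CAF-S3": 0.70, "CAF-S4": 0.875},
    "fsp1": {"CAF-S1": 0.55, "CAF-S2": 0.15, "CAF-S3": 0.75, "CAF-S4": 0.40},
}

_EPITHELIUM_MARKER_OD = 0.04  # faint nonspecific DAB in epithelium
_HEMATOXYLIN_STROMA_OD = 0.30
_HEMATOXYLIN_EPITHELIUM_OD = 0.80


@dataclass(frozen=True)
class SectionSimParams:
    """Study conditions for one synthetic serial-section stack."""

    image_size: int = 256
    um_per_pixel: float = 1.0
    markers: tuple[str, ...] = ("cd29", "fap", "sma", "fsp1")
    blob_count: int = 8
    mean_od_table: dict = dc_field(default_factory=lambda: DEFAULT_MEAN_OD)
    od_noise_sd: float = 0.0
    warp_amplitude: float = 3.0  # pixels
    n_landmarks: int = 16
    epithelium_fraction: float = 0.12
    tile_side_um: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size < 2 * self.tile_side_um / self.um_per_pixel:
            raise ValueError("image too small for the tile size")
        if self.warp_amplitude < 0 or self.od_noise_sd < 0:
            raise ValueError("warp amplitude and noise SD must be >= 0")
        if not 0 <= self.epithelium_fraction < 1:
            raise ValueError("epithelium fraction must lie in [0, 1)")
        if self.n_landmarks < 4:
            raise ValueError("need at least 4 landmarks")
        for m in self.markers:
            table = self.mean_od_table.get(m)
            if table is None:
                raise ValueError(f"mean OD table is missing marker {m!r}")
            for s, v in table.items():
                if s not in SUBSETS:
                    raise ValueError(f"unknown subset label {s!r} in OD table")
                if v < 0:
                    raise ValueError("mean ODs must be nonnegative")


@dataclass(frozen=True)
class SerialSectionSet:
    """One multi-marker stack: images, landmarks, mask, grid and truth."""

    images: dict[str, np.ndarray]  # marker -> RGB uint8, each in its own frame
    landmarks: dict[str, LandmarkSet]  # marker -> pairs (ref frame <-> marker frame)
    epithelium_mask: np.ndarray  # bool, reference frame, True = epithelium
    grid: TileGrid
    stain: StainModel
    reference_marker: str
    truth: pd.DataFrame | None = None  # tile_id, row, col, label

    def save(self, out_dir) -> None:
        """Write PNG images, landmark TSVs, mask PNG and metadata JSON."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for m, img in self.images.items():
            Image.fromarray(img).save(out / f"section_{m}.png")
            self.landmarks[m].to_tsv(out / f"landmarks_{m}.tsv")
        Image.fromarray(
            np.where(self.epithelium_mask, 255, 0).astype(np.uint8)
        ).save(out / "epithelium_mask.png")
        meta = {
            "markers": list(self.images),
            "reference_marker": self.reference_marker,
            "um_per_pixel": self.grid.um_per_pixel,
            "tile_side_um": self.grid.tile_side_um,
        }
        (out / "sections.json").write_text(json.dumps(meta, indent=2))
        if self.truth is not None:
            self.truth.to_csv(out / "truth_tiles.tsv", sep="\t", index=False)

    @classmethod
    def load(cls, in_dir, stain: StainModel | None = None) -> "SerialSectionSet":
        src = Path(in_dir)
        meta = json.loads((src / "sections.json").read_text())
        images, landmarks = {}, {}
        for m in meta["markers"]:
            images[m] = np.asarray(Image.open(src / f"section_{m}.png"))
            landmarks[m] = LandmarkSet.from_tsv(src / f"landmarks_{m}.tsv")
        mask = np.asarray(Image.open(src / "epithelium_mask.png")) > 127
        grid = TileGrid(
            image_shape=mask.shape,
            um_per_pixel=float(meta["um_per_pixel"]),
            tile_side_um=float(meta["tile_side_um"]),
        )
        truth_path = src / "truth_tiles.tsv"
        truth = pd.read_csv(truth_path, sep="\t") if truth_path.exists() else None
        return cls(
            images=images,
            landmarks=landmarks,
            epithelium_mask=mask,
            grid=grid,
            stain=stain or StainModel(),
            reference_marker=meta["reference_marker"],
            truth=truth,
        )


def _quartile_aligned_quotas(n_stromal: int) -> dict[str, int]:
    """Subset tile quotas whose cumulative counts sit on quartile seams.

    With the default OD table the below-gap tile count of each decision
    threshold is S2+S3+S4 (FAP Q3), S2+S3 (SMA median) and S2+S1 (CD29
    median). Linear-interpolation quantiles land inside the gap between
    OD levels exactly when the below-gap count k satisfies
    k - 1 < (n - 1) * p <= k, so the quotas are rounded onto those seams.
    """
    t = n_stromal
    if t < 8:
        raise ValueError("need at least 8 stromal tiles for a 4-subset layout")

    def seam(p: float) -> int:
        pos = (t - 1) * p
        return int(np.ceil(pos)) if pos != int(pos) else int(pos)

    c75, c50 = seam(0.75), seam(0.5)
    n1 = t - c75
    n2 = c50 - n1
    n3 = n1
    n4 = t - n1 - n2 - n3
    quotas = {"CAF-S1": n1, "CAF-S2": n2, "CAF-S3": n3, "CAF-S4": n4}
    if any(v <= 0 for v in quotas.values()):
        raise ValueError("too few stromal tiles for balanced subset quotas")
    return quotas


def _layout_tiles(
    rng: np.random.Generator,
    n_rows: int,
    n_cols: int,
    blob_count: int,
    epithelium_fraction: float,
) -> np.ndarray:
    """Tile-resolution label field: subset territories + epithelium.

    Returns an (n_rows, n_cols) object array with values in SUBSETS or
    ``"epithelium"``. Territories are compact (nearest-seed growth)
    with exact subset quotas; the epithelium is a disk of tiles.
    """
    total = n_rows * n_cols
    coords = np.array([(r, c) for r in range(n_rows) for c in range(n_cols)])

    labels = np.empty(total, dtype=object)
    # Tile-aligned epithelial disk.
    n_epi = int(round(epithelium_fraction * total))
    if n_epi > 0:
        center = rng.uniform([1, 1], [n_rows - 1, n_cols - 1])
        d_epi = np.linalg.norm(coords - center, axis=1)
        epi_idx = np.argsort(d_epi)[:n_epi]
        labels[epi_idx] = "epithelium"
    stromal_idx = np.flatnonzero(labels == None)  # noqa: E711

    quotas = _quartile_aligned_quotas(stromal_idx.size)
    seeds = coords[rng.choice(stromal_idx, size=blob_count, replace=False)]
    seed_subsets = [SUBSETS[i % 4] for i in range(blob_count)]
    order = rng.permutation(blob_count)
    seed_subsets = [seed_subsets[i] for i in order]

    # Grow territories: visit stromal tiles by distance to their nearest
    # seed; take that seed's subset while its quota lasts, else the
    # nearest seed of a subset with remaining quota.
    d = np.linalg.norm(
        coords[stromal_idx][:, None, :] - seeds[None, :, :], axis=2
    )
    remaining = dict(quotas)
    visit = np.argsort(d.min(axis=1))
    for i in visit:
        for j in np.argsort(d[i]):
            s = seed_subsets[j]
            if remaining[s] > 0:
                labels[stromal_idx[i]] = s
                remaining[s] -= 1
                break
    assert all(v == 0 for v in remaining.values())
    return labels.reshape(n_rows, n_cols)


def _taper_window(h: int, w: int) -> np.ndarray:
    """Smooth window equal to 0 on the boundary and ~1 in the interior."""
    wy = np.sin(np.pi * np.arange(h) / (h - 1))
    wx = np.sin(np.pi * np.arange(w) / (w - 1))
    return np.minimum.outer(np.sqrt(wy * (2 - wy)), np.sqrt(wx * (2 - wx)))


def _make_warp(
    rng: np.random.Generator, h: int, w: int, amplitude: float
) -> tuple[np.ndarray, np.ndarray]:
    """Displacement field (dy, dx): section frame -> reference frame.

    Rigid motion (translation + small rotation) plus a one-period
    sinusoid, jointly tapered to zero at the boundary and normalized so
    the peak displacement magnitude equals ``amplitude`` pixels.
    """
    ys, xs = np.mgrid[0:h, 0:w].astype(float)
    if amplitude == 0:
        return np.zeros((h, w)), np.zeros((h, w))
    ty, tx = rng.uniform(-1, 1, size=2)
    theta = rng.uniform(-1, 1) * 2.0 / max(h, w)
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    dy = ty + theta * (xs - cx)
    dx = tx - theta * (ys - cy)
    phy, phx = rng.uniform(0, 2 * np.pi, size=2)
    dy = dy + np.sin(2 * np.pi * xs / w + phy)
    dx = dx + np.sin(2 * np.pi * ys / h + phx)
    win = _taper_window(h, w)
    dy, dx = dy * win, dx * win
    peak = np.sqrt(dy**2 + dx**2).max()
    scale = amplitude / peak if peak > 0 else 0.0
    return dy * scale, dx * scale


def _landmark_positions(
    rng: np.random.Generator, h: int, w: int, n: int
) -> np.ndarray:
    """Jittered-grid landmark (x, y) positions covering the frame."""
    grid_n = int(np.ceil(np.sqrt(n)))
    fr = (np.arange(grid_n) + 0.5) / grid_n
    pts = np.array([(x * (w - 1), y * (h - 1)) for y in fr for x in fr])
    idx = rng.permutation(len(pts))[:n]
    pts = pts[idx]
    pts += rng.uniform(-0.02, 0.02, size=pts.shape) * min(h, w)
    return np.clip(pts, 0, [w - 1, h - 1])


def generate_serial_sections(
    params: SectionSimParams, stain: StainModel | None = None
) -> SerialSectionSet:
    """Simulate one registered-by-construction serial-section stack.

    The first marker is the reference section (identity geometry); each
    further marker carries its own smooth warp, encoded exactly in its
    landmark pairs. Deterministic per seed. Raises if a warp would push
    a landmark out of frame.
    """
    stain = stain or StainModel()
    rng = np.random.default_rng(params.seed)
    h = w = params.image_size
    grid = TileGrid(
        image_shape=(h, w),
        um_per_pixel=params.um_per_pixel,
        tile_side_um=params.tile_side_um,
    )
    side = grid.tile_side_px
    n_rows, n_cols = h // side, w // side  # full tiles only

    tile_labels = _layout_tiles(
        rng, n_rows, n_cols, params.blob_count, params.epithelium_fraction
    )

    # Pixel-level truth in the reference frame: upsample tile labels and
    # extend the last row/column over the partial edge strip.
    pixel_labels = np.repeat(np.repeat(tile_labels, side, 0), side, 1)
    pad_y, pad_x = h - pixel_labels.shape[0], w - pixel_labels.shape[1]
    pixel_labels = np.pad(pixel_labels, ((0, pad_y), (0, pad_x)), mode="edge")
    epithelium_mask = pixel_labels == "epithelium"

    # Noise-free DAB OD field per marker (reference frame).
    od_fields = {}
    for m in params.markers:
        od = np.full((h, w), _EPITHELIUM_MARKER_OD)
        for s in SUBSETS:
            od[pixel_labels == s] = params.mean_od_table[m][s]
        od_fields[m] = od

    # Unit noise fields drawn regardless of the noise SD, so stacks at
    # different SDs from one seed share their noise pattern.
    noise = {m: rng.standard_normal((h, w)) for m in params.markers}
    hema = np.where(
        epithelium_mask, _HEMATOXYLIN_EPITHELIUM_OD, _HEMATOXYLIN_STROMA_OD
    )
    hema_noise = rng.standard_normal((h, w))

    images: dict[str, np.ndarray] = {}
    landmark_sets: dict[str, LandmarkSet] = {}
    lm_xy = _landmark_positions(rng, h, w, params.n_landmarks)

    ys, xs = np.mgrid[0:h, 0:w].astype(float)
    for k, m in enumerate(params.markers):
        if k == 0:
            dy = dx = None
        else:
            dy, dx = _make_warp(rng, h, w, params.warp_amplitude)

        dab = np.clip(od_fields[m] + params.od_noise_sd * noise[m], 0, None)
        hm = np.clip(hema + params.od_noise_sd * hema_noise, 0, None)
        if dy is None:
            dab_sec, hema_sec = dab, hm
            ref_pts = lm_xy.copy()
        else:
            # Section pixel (y, x) shows reference material at (y+dy, x+dx).
            coords = np.vstack([(ys + dy).ravel(), (xs + dx).ravel()])
            dab_sec = ndimage.map_coordinates(
                dab, coords, order=1, mode="nearest"
            ).reshape(h, w)
            hema_sec = ndimage.map_coordinates(
                hm, coords, order=1, mode="nearest"
            ).reshape(h, w)
            # Landmark in the section frame at (x, y) corresponds to the
            # reference position (x + dx, y + dy) evaluated there.
            lm_coords = np.vstack([lm_xy[:, 1], lm_xy[:, 0]])  # (row, col)
            lm_dx = ndimage.map_coordinates(dx, lm_coords, order=1, mode="nearest")
            lm_dy = ndimage.map_coordinates(dy, lm_coords, order=1, mode="nearest")
            ref_pts = lm_xy + np.column_stack([lm_dx, lm_dy])
            if (
                (ref_pts[:, 0] < 0).any()
                or (ref_pts[:, 0] > w - 1).any()
                or (ref_pts[:, 1] < 0).any()
                or (ref_pts[:, 1] > h - 1).any()
            ):
                raise ValueError(
                    f"marker {m}: warp amplitude pushes landmarks out of frame"
                )
        od_stack = np.stack([hema_sec, dab_sec, np.zeros((h, w))], axis=-1)
        images[m] = mix_stains(od_stack, stain, dtype=np.uint8)
        landmark_sets[m] = LandmarkSet(ref=ref_pts, mov=lm_xy.copy())

    truth_rows = []
    for r in range(grid.shape[0]):
        for c in range(grid.shape[1]):
            tid = r * grid.shape[1] + c
            if not grid.is_full(r, c):
                label = "edge"
            else:
                label = str(tile_labels[r, c])
                if label == "epithelium":
                    label = "masked"
            truth_rows.append({"tile_id": tid, "row": r, "col": c, "label": label})

    return SerialSectionSet(
        images=images,
        landmarks=landmark_sets,
        epithelium_mask=epithelium_mask,
        grid=grid,
        stain=stain,
        reference_marker=params.markers[0],
        truth=pd.DataFrame(truth_rows),
    )
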