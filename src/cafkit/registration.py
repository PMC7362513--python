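"""Landmark-driven registration of serial histology sections.

Serial sections are aligned from manually placed landmark pairs
(reference section vs moving section, 0-based pixel coordinates).
The fitted transform is the backward map reference -> moving: applying
it to the moving image resamples that image into the reference frame.
Two transform families are supported: affine (least squares) and
thin-plate spline with smoothing parameter lambda (lambda = 0
interpolates the landmarks exactly).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.interpolate import RBFInterpolator

__all__ = ["LandmarkSet", "WarpTransform", "fit_landmark_warp", "warp_image"]


@dataclass(frozen=True)
class LandmarkSet:
    """Paired landmarks: ``ref`` and ``mov`` are (n, 2) arrays of (x, y)."""

    ref: np.ndarray
    mov: np.ndarray

    def __post_init__(self) -> None:
        ref = np.atleast_2d(np.asarray(self.ref, dtype=float))
        mov = np.atleast_2d(np.asarray(self.mov, dtype=float))
        if ref.shape != mov.shape or ref.ndim != 2 or ref.shape[1] != 2:
            raise ValueError("ref and mov must both be (n, 2) coordinate arrays")
        if not (np.all(np.isfinite(ref)) and np.all(np.isfinite(mov))):
            raise ValueError("landmark coordinates must be finite")
        object.__setattr__(self, "ref", ref)
        object.__setattr__(self, "mov", mov)

    def __len__(self) -> int:
        return self.ref.shape[0]

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {
                "x_ref": self.ref[:, 0],
                "y_ref": self.ref[:, 1],
                "x_mov": self.mov[:, 0],
                "y_mov": self.mov[:, 1],
            }
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "LandmarkSet":
        df = pd.read_csv(path, sep="\t")
        return cls(
            ref=df[["x_ref", "y_ref"]].to_numpy(),
            mov=df[["x_mov", "y_mov"]].to_numpy(),
        )


def _collinear(pts: np.ndarray) -> bool:
    if pts.shape[0] < 3:
        return True
    centered = pts - pts.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    return s[1] < 1e-9 * max(s[0], 1.0)


@dataclass(frozen=True)
class WarpTransform:
    """Backward map reference -> moving, with its landmark RMS residual."""

    kind: str  # "affine" | "tps"
    residual: float
    _affine: np.ndarray | None = None  # 3x2, rows for (x, y, 1)
    _rbf: RBFInterpolator | None = None
    smoothing: float = 0.0

    def map(self, points: np.ndarray) -> np.ndarray:
        """Map (n, 2) reference-frame (x, y) points into the moving frame."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if self.kind == "affine":
            ones = np.ones((pts.shape[0], 1))
            return np.hstack([pts, ones]) @ self._affine
        return self._rbf(pts)


def fit_landmark_warp(
    landmarks: LandmarkSet, kind: str = "tps", smoothing: float = 0.1
) -> WarpTransform:
    """Fit the reference -> moving backward map from landmark pairs.

    ``kind="affine"`` needs >= 3 non-collinear pairs; ``kind="tps"``
    (thin-plate spline) needs >= 4, and with ``smoothing=0``
    interpolates the landmarks exactly. The RMS distance between the
    mapped reference landmarks and the true moving positions is stored
    as the residual.
    """
    ref, mov = landmarks.ref, landmarks.mov
    if kind == "affine":
        if len(landmarks) < 3 or _collinear(ref):
            raise ValueError("affine fit needs >= 3 non-collinear landmark pairs")
        ones = np.ones((ref.shape[0], 1))
        A, *_ = np.linalg.lstsq(np.hstack([ref, ones]), mov, rcond=None)
        pred = np.hstack([ref, ones]) @ A
        res = float(np.sqrt(np.mean(np.sum((pred - mov) ** 2, axis=1))))
        return WarpTransform(kind="affine", residual=res, _affine=A)
    if kind == "tps":
        if len(landmarks) < 4 or _collinear(ref):
            raise ValueError("TPS fit needs >= 4 non-collinear landmark pairs")
        if smoothing < 0:
            raise ValueError("smoothing must be >= 0")
        rbf = RBFInterpolator(
            ref, mov, kernel="thin_plate_spline", smoothing=smoothing
        )
        pred = rbf(ref)
        res = float(np.sqrt(np.mean(np.sum((pred - mov) ** 2, axis=1))))
        return WarpTransform(
            kind="tps", residual=res, _rbf=rbf, smoothing=smoothing
        )
    raise ValueError(f"unknown transform kind {kind!r}")


def warp_image(
    image: np.ndarray,
    transform: WarpTransform,
    fill: float = 0.0,
    order: int = 1,
) -> np.ndarray:
    """Resample a moving-frame image into the reference frame.

    Backward mapping with bilinear interpolation (``order=1``);
    reference pixels whose mapped position falls outside the moving
    image get the ``fill`` value. Integer inputs are returned in their
    own dtype (an identity transform reproduces the input bitwise).
    """
    img = np.asarray(image)
    h, w = img.shape[:2]
    ys, xs = np.mgrid[0:h, 0:w]
    pts = np.column_stack([xs.ravel(), ys.ravel()]).astype(float)
    mapped = transform.map(pts)
    # snap float fuzz so exact integer maps (identity, integer shifts)
    # reproduce pixel values bitwise
    nearest = np.rint(mapped)
    mapped = np.where(np.abs(mapped - nearest) < 1e-6, nearest, mapped)
    # map_coordinates wants (row, col) = (y, x)
    coords = np.vstack([mapped[:, 1], mapped[:, 0]])

    def _one(channel: np.ndarray) -> np.ndarray:
        out = ndimage.map_coordinates(
            channel.astype(float), coords, order=order, mode="constant", cval=fill
        )
        return out.reshape(h, w)

    if img.ndim == 2:
        out = _one(img)
    elif img.ndim == 3:
        out = np.stack([_one(img[..., c]) for c in range(img.shape[2])], axis=-1)
    else:
        raise ValueError("expected a 2D image or a 2D image with channels")
    if np.issubdtype(img.dtype, np.integer):
        info = np.iinfo(img.dtype)
        out = np.clip(np.rint(out), info.min, info.max).astype(img.dtype)
    return out
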