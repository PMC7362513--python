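"""Beer-Lambert stain mixing and color deconvolution (unmixing).

A chromogen at optical density ``OD`` attenuates light as
``I = I0 * 10**(-OD)`` per RGB channel, with the per-channel attenuation
direction given by the stain's unit vector in RGB-OD space. Mixing is
the forward model (per-stain OD fields -> RGB image); unmixing inverts
it with the stain matrix (Ruifrok-Johnston color deconvolution).

The default matrix is the standard H-DAB pair (hematoxylin, DAB) with
the residual channel as their normalized cross product.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

__all__ = ["StainModel", "mix_stains", "unmix_stains", "UnmixResult"]

_HEMATOXYLIN = (0.650, 0.704, 0.286)
_DAB = (0.269, 0.568, 0.778)


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


@dataclass(frozen=True)
class StainModel:
    """Stain matrix (rows = unit stain vectors in RGB-OD space) + background.

    Row order is (hematoxylin, DAB, residual). ``background_intensity``
    is the per-channel intensity I0 of unstained glass.
    """

    stain_matrix: np.ndarray = field(default=None)  # type: ignore[assignment]
    background_intensity: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        m = self.stain_matrix
        if m is None:
            h = _unit(np.array(_HEMATOXYLIN))
            d = _unit(np.array(_DAB))
            r = _unit(np.cross(h, d))
            m = np.vstack([h, d, r])
        m = np.asarray(m, dtype=float)
        if m.shape != (3, 3):
            raise ValueError(f"stain matrix must be 3x3, got {m.shape}")
        norms = np.linalg.norm(m, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("stain matrix rows must be unit vectors")
        if np.linalg.cond(m) > 1e6:
            raise ValueError("stain matrix is singular or near-singular")
        bg = self.background_intensity
        if bg is None:
            bg = np.full(3, 255.0)
        bg = np.asarray(bg, dtype=float)
        if bg.shape != (3,) or np.any(bg <= 0):
            raise ValueError("background intensity must be 3 positive values")
        object.__setattr__(self, "stain_matrix", m)
        object.__setattr__(self, "background_intensity", bg)

    @property
    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.stain_matrix)


class UnmixResult(NamedTuple):
    """Per-stain OD images (..., 3, stain axis last) and clamping diagnostics."""

    od: np.ndarray
    clamp_rate: float


def mix_stains(
    od_channels: np.ndarray,
    stain: StainModel | None = None,
    dtype: np.dtype | None = None,
) -> np.ndarray:
    """Forward Beer-Lambert model: per-stain OD fields -> RGB image.

    ``od_channels`` has the stain axis last, ordered as the stain-matrix
    rows. With ``dtype=None`` the float image is returned unquantized
    (the exact inverse of :func:`unmix_stains`); an integer dtype
    rounds to the stored bit depth.
    """
    stain = stain or StainModel()
    od = np.asarray(od_channels, dtype=float)
    if od.shape[-1] != stain.stain_matrix.shape[0]:
        raise ValueError("stain axis length must match the stain matrix rows")
    if np.any(od < 0):
        raise ValueError("optical densities must be nonnegative")
    od_rgb = od @ stain.stain_matrix
    rgb = stain.background_intensity * np.power(10.0, -od_rgb)
    if dtype is None:
        return rgb
    info = np.iinfo(dtype)
    return np.clip(np.rint(rgb), info.min, info.max).astype(dtype)


def unmix_stains(
    rgb: np.ndarray, stain: StainModel | None = None, clamp: bool = True
) -> UnmixResult:
    """Color deconvolution: RGB image -> per-stain OD images.

    Per channel ``OD = -log10(max(I, 1) / I0)``; the RGB-OD vector is
    then projected onto the stains with the inverse stain matrix.
    Negative unmixed values (physically meaningless) are clamped to 0
    and the clamp rate over all pixels and stains is reported.
    """
    stain = stain or StainModel()
    img = np.asarray(rgb, dtype=float)
    if img.shape[-1] != 3:
        raise ValueError("expected an RGB image with channel axis last")
    od_rgb = -np.log10(np.maximum(img, 1.0) / stain.background_intensity)
    od = od_rgb @ stain.inverse
    neg = od < 0
    clamp_rate = float(np.mean(neg)) if od.size else 0.0
    if clamp:
        od = np.where(neg, 0.0, od)
    return UnmixResult(od=od, clamp_rate=clamp_rate)
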