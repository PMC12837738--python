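"""Color indices for sighting-image segmentation.

Sighting images of marine animals contain three broad region types —
land, sea with the animal, and sky — whose red/green/blue balance
differs systematically.  Two per-pixel channel differences capture
this:

* ``GMR = G - R`` (green minus red), originally a vegetation index,
  separates land (red/green dominant) from sea and sky;
* ``BMG = B - G`` (blue minus green) separates blue-dominant sky from
  the blue-green sea and the low-chroma animal body.

Both raw indices live in ``[-255, 255]`` for 8-bit input.  Because
distance-based thresholds weight large-range features more, each index
is linearly rescaled to the unit interval,

    NGMR = (GMR + L) / (2 L),   NBMG = (BMG + L) / (2 L),

with ``L = 255`` the maximum channel intensity.  The normalized images
are the input to morphological smoothing and three-class thresholding
(:mod:`seasight.segmentation`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np

L_MAX = 255


class IndexKind(str, Enum):
    """Which channel-difference map an :class:`IndexImage` holds."""

    GMR = "gmr"
    BMG = "bmg"
    NGMR = "ngmr"
    NBMG = "nbmg"

    @property
    def is_normalized(self) -> bool:
        return self in (IndexKind.NGMR, IndexKind.NBMG)

    @property
    def normalized(self) -> "IndexKind":
        return {IndexKind.GMR: IndexKind.NGMR, IndexKind.BMG: IndexKind.NBMG}[self]


@dataclass(frozen=True)
class IndexImage:
    """A single-channel color-index map.

    Parameters
    ----------
    values
        2-D float array.  Raw kinds (GMR/BMG) lie in ``[-L, L]``;
        normalized kinds (NGMR/NBMG) lie in ``[0, 1]``.
    kind
        Which index the values represent.
    """

    values: np.ndarray
    kind: IndexKind

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2:
            raise ValueError(f"index image must be 2-D, got shape {v.shape}")
        object.__setattr__(self, "values", v)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def as_rgb_array(img: np.ndarray) -> np.ndarray:
    """Validate and coerce an input image to an 8-bit-range RGB float array.

    Accepts ``(H, W, 3)`` arrays of integer or float dtype.  An alpha
    channel is dropped with a warning; grayscale input is rejected
    because channel differences are undefined on it.  16-bit input is
    rescaled to the ``[0, 255]`` range (``L`` stays 255).
    """
    a = np.asarray(img)
    if a.ndim != 3 or a.shape[2] not in (3, 4):
        raise ValueError(
            f"expected an (H, W, 3) RGB image, got shape {a.shape}; "
            "grayscale input is not supported (color indices are undefined)"
        )
    if a.shape[0] < 1 or a.shape[1] < 1:
        raise ValueError("image must have at least one pixel")
    if a.shape[2] == 4:
        warnings.warn("alpha channel dropped", stacklevel=3)
        a = a[:, :, :3]
    a = a.astype(np.float64)
    if a.max() > 255:  # 16-bit input
        a = a * (255.0 / 65535.0)
    if a.min() < 0:
        raise ValueError("negative channel intensities are invalid")
    return a


def compute_gmr(img: np.ndarray) -> IndexImage:
    """Green-minus-red index, ``GMR = G - R``, per pixel."""
    a = as_rgb_array(img)
    return IndexImage(a[:, :, 1] - a[:, :, 0], IndexKind.GMR)


def compute_bmg(img: np.ndarray) -> IndexImage:
    """Blue-minus-green index, ``BMG = B - G``, per pixel."""
    a = as_rgb_array(img)
    return IndexImage(a[:, :, 2] - a[:, :, 1], IndexKind.BMG)


def normalize_index(raw: IndexImage, L: int = L_MAX) -> IndexImage:
    """Rescale a raw index linearly from ``[-L, L]`` onto ``[0, 1]``.

    ``value' = (value + L) / (2 L)`` — strictly monotone, so thresholds
    on the normalized scale are equivalent to thresholds on the raw one.
    """
    if raw.kind.is_normalized:
        raise ValueError(f"index of kind {raw.kind.value!r} is already normalized")
    v = raw.values
    if v.min() < -L or v.max() > L:
        raise ValueError(f"raw index values outside [-{L}, {L}]")
    return IndexImage((v + L) / (2.0 * L), raw.kind.normalized)


def compute_index(img: np.ndarray, kind: IndexKind | str) -> IndexImage:
    """Compute a (possibly normalized) index directly from an RGB image."""
    kind = IndexKind(kind)
    raw = compute_gmr(img) if kind in (IndexKind.GMR, IndexKind.NGMR) else compute_bmg(img)
    return normalize_index(raw) if kind.is_normalized else raw


def export_index_png(idx: IndexImage, path) -> None:
    """Write a normalized index image as 16-bit PNG (value * 65535)."""
    import imageio.v3 as iio

    if not idx.kind.is_normalized:
        raise ValueError("only normalized indices are exported as 16-bit PNG")
    iio.imwrite(path, np.round(idx.values * 65535).astype(np.uint16))


def export_index_text(idx: IndexImage, path) -> None:
    """Write an index image as a plain-text matrix (debugging aid)."""
    np.savetxt(path, idx.values, fmt="%.6f")
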