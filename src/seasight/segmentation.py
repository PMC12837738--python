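"""Three-class thresholding segmentation and candidate-region extraction.

A normalized index image is first smoothed with a grayscale
morphological closing (dilation then erosion, square structuring
element, default 11x11) so that each scene region becomes near-uniform
in index value.  Pixels are then assigned to LAND / ANIMAL / SKY by
comparing the smoothed value against four calibrated thresholds:

    value <= t_c1            -> LAND
    t_c2a <= value <= t_c2b  -> MARINE ANIMAL (sea and animal share
                                this band; they reflect each other)
    value >= t_c3            -> SKY

Values are quantized to 4 decimals before comparison; adjacent
thresholds differ by exactly 0.0001 at that precision, so the three
intervals tile [0, 1] with no gaps and every pixel receives exactly
one label.

Candidate animal regions are the 8-connected components of the ANIMAL
label; the largest surviving component is the localization candidate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
from scipy import ndimage

from .color_index import IndexImage, IndexKind

DEFAULT_WINDOW = 11
QUANT_DECIMALS = 4


class PixelClass(IntEnum):
    LAND = 0
    ANIMAL = 1
    SKY = 2


@dataclass(frozen=True)
class ThresholdSet:
    """The four class-boundary thresholds for one normalized index.

    ``t_c1`` is the land upper bound, ``t_c2a``/``t_c2b`` bound the
    marine-animal (sea + animal) band, ``t_c3`` is the sky lower bound.
    After 4-decimal quantization ``t_c2a = t_c1 + 0.0001`` and
    ``t_c3 = t_c2b + 0.0001`` (adjacent representable values).
    """

    t_c1: float
    t_c2a: float
    t_c2b: float
    t_c3: float
    index_kind: IndexKind = IndexKind.NGMR

    def __post_init__(self) -> None:
        if not (self.t_c1 < self.t_c2a <= self.t_c2b < self.t_c3):
            raise ValueError(
                f"thresholds must satisfy t_c1 < t_c2a <= t_c2b < t_c3, got "
                f"({self.t_c1}, {self.t_c2a}, {self.t_c2b}, {self.t_c3})"
            )
        gap = 10.0 ** (-QUANT_DECIMALS)
        if abs((self.t_c2a - self.t_c1) - gap) > gap * 1e-6 or abs(
            (self.t_c3 - self.t_c2b) - gap
        ) > gap * 1e-6:
            raise ValueError(
                "class bands must be adjacent at 4-decimal precision "
                "(t_c2a - t_c1 = t_c3 - t_c2b = 0.0001)"
            )
        object.__setattr__(self, "index_kind", IndexKind(self.index_kind))

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.t_c1, self.t_c2a, self.t_c2b, self.t_c3)


# Shipped defaults: thresholds obtained from 100 land / marine-animal /
# sky training images each (the overall defaults), plus the full
# training-size sweep.  These are configuration constants.
NGMR_DEFAULT = ThresholdSet(0.4608, 0.4609, 0.5781, 0.5782, IndexKind.NGMR)
NBMG_DEFAULT = ThresholdSet(0.4491, 0.4492, 0.5898, 0.5899, IndexKind.NBMG)

THRESHOLDS_BY_TRAINING_SIZE: dict[int, dict[IndexKind, ThresholdSet]] = {
    n: {
        IndexKind.NGMR: ThresholdSet(*g, IndexKind.NGMR),
        IndexKind.NBMG: ThresholdSet(*b, IndexKind.NBMG),
    }
    for n, g, b in [
        (5, (0.3905, 0.3906, 0.6211, 0.6212), (0.4022, 0.4023, 0.6172, 0.6173)),
        (10, (0.4335, 0.4336, 0.5977, 0.5978), (0.4101, 0.4102, 0.6211, 0.6212)),
        (20, (0.4413, 0.4414, 0.5977, 0.5978), (0.4101, 0.4102, 0.6133, 0.6134)),
        (40, (0.4374, 0.4375, 0.5820, 0.5821), (0.4687, 0.4688, 0.6016, 0.6017)),
        (60, (0.4491, 0.4492, 0.6016, 0.6017), (0.4452, 0.4453, 0.5898, 0.5899)),
        (80, (0.4257, 0.4258, 0.5781, 0.5782), (0.4608, 0.4609, 0.5820, 0.5821)),
        (100, (0.4608, 0.4609, 0.5781, 0.5782), (0.4491, 0.4492, 0.5898, 0.5899)),
    ]
}


def morphological_close(idx: IndexImage, window: int = DEFAULT_WINDOW) -> IndexImage:
    """Grayscale closing: dilation then erosion with a square window.

    Border handling is replicate (edge-value extension), so flat fields
    map to themselves exactly.  Closing fills dark details smaller than
    the structuring element and never decreases any pixel value.
    """
    if not idx.kind.is_normalized:
        raise ValueError("morphology operates on normalized index images")
    if window < 3 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 3, got {window}")
    size = (window, window)
    dilated = ndimage.grey_dilation(idx.values, size=size, mode="nearest")
    closed = ndimage.grey_erosion(dilated, size=size, mode="nearest")
    return IndexImage(np.clip(closed, 0.0, 1.0), idx.kind)


def classify_pixels(morph: IndexImage, thr: ThresholdSet) -> np.ndarray:
    """Assign every pixel to LAND / ANIMAL / SKY by threshold bands.

    Returns an integer label map (:class:`PixelClass` values).  Values
    are rounded to 4 decimals before comparison so that the three bands
    form a total partition of [0, 1].
    """
    if morph.kind != thr.index_kind:
        raise ValueError(
            f"index kind {morph.kind.value!r} does not match threshold "
            f"kind {thr.index_kind.value!r}"
        )
    v = np.round(morph.values, QUANT_DECIMALS)
    labels = np.full(v.shape, PixelClass.ANIMAL, dtype=np.int8)
    labels[v <= thr.t_c1] = PixelClass.LAND
    labels[v >= thr.t_c3] = PixelClass.SKY
    return labels


def fuse_label_maps(
    seg_ngmr: np.ndarray, seg_nbmg: np.ndarray, rule: str = "union"
) -> np.ndarray:
    """Combine NGMR and NBMG label maps into one decision.

    ``"union"`` (default): where the maps agree, keep the label; on
    disagreement ANIMAL wins if either map says ANIMAL, otherwise the
    NGMR label wins.  Maximizes animal-pixel recall.

    ``"and"``: a pixel is ANIMAL only when both maps say ANIMAL; other
    disagreements fall back to the NGMR label (or to the NBMG label
    when NGMR's lone ANIMAL claim was vetoed).  Precision-oriented.
    """
    a = np.asarray(seg_ngmr)
    b = np.asarray(seg_nbmg)
    if a.shape != b.shape:
        raise ValueError(f"label map shapes differ: {a.shape} vs {b.shape}")
    if rule == "union":
        fused = a.copy()
        either_animal = (a == PixelClass.ANIMAL) | (b == PixelClass.ANIMAL)
        fused[either_animal] = PixelClass.ANIMAL
        return fused
    if rule == "and":
        fused = a.copy()
        lone_ngmr_animal = (a == PixelClass.ANIMAL) & (b != PixelClass.ANIMAL)
        fused[lone_ngmr_animal] = b[lone_ngmr_animal]
        return fused
    raise ValueError(f"unknown fusion rule {rule!r} (expected 'union' or 'and')")


@dataclass(frozen=True)
class Region:
    """A connected component of same-class pixels.

    ``bbox`` is half-open ``(top, left, bottom, right)``; ``centroid``
    is ``(x, y)`` in pixel units with the origin at the image's top
    left corner (x along columns, y along rows).
    """

    pixels: np.ndarray  # (n, 2) array of (row, col), lexicographically sorted
    size: int
    bbox: tuple[int, int, int, int]
    centroid: tuple[float, float]
    label_value: int = field(default=int(PixelClass.ANIMAL))

    @classmethod
    def from_pixels(cls, rows: np.ndarray, cols: np.ndarray, label_value: int) -> "Region":
        order = np.lexsort((cols, rows))
        pix = np.column_stack([rows[order], cols[order]])
        bbox = (int(rows.min()), int(cols.min()), int(rows.max()) + 1, int(cols.max()) + 1)
        centroid = (float(cols.mean()), float(rows.mean()))
        return cls(pix, int(len(rows)), bbox, centroid, int(label_value))

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[self.pixels[:, 0], self.pixels[:, 1]] = True
        return m

    def to_dict(self) -> dict:
        return {
            "size": self.size,
            "bbox": list(self.bbox),
            "centroid": list(self.centroid),
            "class": PixelClass(self.label_value).name,
        }


_STRUCT_8 = np.ones((3, 3), dtype=bool)
_STRUCT_4 = ndimage.generate_binary_structure(2, 1)


def extract_regions(
    labels: np.ndarray,
    target_class: PixelClass = PixelClass.ANIMAL,
    connectivity: int = 8,
    min_size: int | None = None,
) -> list[Region]:
    """Connected components of ``target_class``, largest first.

    ``min_size`` defaults to 0.1% of the image area (speckle
    suppression); pass 0 to keep everything.  Ties in size are broken
    by the smaller ``(top, left)`` bbox corner.
    """
    labels = np.asarray(labels)
    if connectivity not in (4, 8):
        raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")
    if min_size is None:
        min_size = max(1, int(0.001 * labels.size))
    mask = labels == target_class
    struct = _STRUCT_8 if connectivity == 8 else _STRUCT_4
    comp, n = ndimage.label(mask, structure=struct)
    regions = []
    for rows, cols in _component_indices(comp, n):
        if len(rows) >= min_size:
            regions.append(Region.from_pixels(rows, cols, int(target_class)))
    regions.sort(key=lambda r: (-r.size, r.bbox[0], r.bbox[1]))
    return regions


def _component_indices(comp: np.ndarray, n: int):
    if n == 0:
        return
    rr, cc = np.nonzero(comp)
    ids = comp[rr, cc]
    order = np.argsort(ids, kind="stable")
    rr, cc, ids = rr[order], cc[order], ids[order]
    bounds = np.searchsorted(ids, np.arange(1, n + 1), side="right")
    for k in range(n):
        lo, hi = (bounds[k - 1] if k else 0), bounds[k]
        yield rr[lo:hi], cc[lo:hi]


def select_candidate(regions: list[Region]) -> Region | None:
    """The largest candidate region, or ``None`` when there is none.

    A ``None`` result propagates to an absent animal location
    downstream ("location is not provided").
    """
    return regions[0] if regions else None


def export_label_png(labels: np.ndarray, path, overlay_rgb: np.ndarray | None = None) -> None:
    """Write a label map as PNG: integer mask {0,1,2}, or a green
    animal-overlay when ``overlay_rgb`` is given."""
    import imageio.v3 as iio

    labels = np.asarray(labels)
    if overlay_rgb is None:
        iio.imwrite(path, labels.astype(np.uint8))
        return
    out = np.asarray(overlay_rgb, dtype=np.uint8).copy()
    animal = labels == PixelClass.ANIMAL
    out[animal] = (0.4 * out[animal] + 0.6 * np.array([0, 255, 0])).astype(np.uint8)
    iio.imwrite(path, out)
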