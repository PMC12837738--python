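"""Threshold calibration from class-labeled training images.

The segmentation thresholds are learned from three sets of class-pure
training images (land, marine animal, sky).  For each training image
the normalized index is computed, smoothed by morphological closing,
and summarized by the mode of its 256-bin histogram on [0, 1] (refined
to the mean of the values inside the modal bin).  Class statistics are
averaged, and the class boundaries are the midpoints between adjacent
class means, rounded to 4 decimals; the inner band bounds sit one
representable step (0.0001) inside the boundaries, so the three bands
tile [0, 1].

Per-image Otsu thresholds are available as an alternative statistic
(``statistic="otsu"``); the default is the histogram mode, which is
robust when one class fills most of a training image.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .color_index import IndexImage, IndexKind, compute_index
from .segmentation import DEFAULT_WINDOW, QUANT_DECIMALS, ThresholdSet, morphological_close

HIST_BINS = 256


@dataclass(frozen=True)
class TrainingSet:
    """Class-pure training images for one class."""

    class_name: str  # "land", "animal" or "sky"
    images: list  # list of (H, W, 3) arrays

    def __post_init__(self) -> None:
        if len(self.images) < 1:
            raise ValueError(f"training set {self.class_name!r} is empty")

    @property
    def n(self) -> int:
        return len(self.images)


@dataclass
class CalibrationReport:
    """Thresholds and per-class statistics from one calibration run."""

    thresholds: dict  # IndexKind -> ThresholdSet
    class_stats: dict  # (kind, class_name) -> list of per-image statistics
    n_per_class: dict = field(default_factory=dict)
    window: int = DEFAULT_WINDOW

    def to_dict(self) -> dict:
        return {
            "window": self.window,
            "n_per_class": self.n_per_class,
            "thresholds": {
                k.value: list(t.as_tuple()) for k, t in self.thresholds.items()
            },
            "class_stats": {
                f"{k.value}:{c}": [float(x) for x in v]
                for (k, c), v in self.class_stats.items()
            },
        }


def _image_statistic(idx: IndexImage, statistic: str) -> float:
    v = idx.values.ravel()
    if statistic == "mode":
        counts, edges = np.histogram(v, bins=HIST_BINS, range=(0.0, 1.0))
        b = int(np.argmax(counts))
        lo, hi = edges[b], edges[b + 1]
        in_bin = v[(v >= lo) & (v < hi)] if b < HIST_BINS - 1 else v[(v >= lo) & (v <= hi)]
        return float(in_bin.mean()) if in_bin.size else float((lo + hi) / 2)
    if statistic == "otsu":
        from skimage.filters import threshold_otsu

        try:
            return float(threshold_otsu(v, nbins=HIST_BINS))
        except ValueError:  # constant image: Otsu undefined, fall back to the value
            return float(v[0])
    raise ValueError(f"unknown statistic {statistic!r} (expected 'mode' or 'otsu')")


def class_index_statistic(
    training: TrainingSet,
    kind: IndexKind | str,
    window: int = DEFAULT_WINDOW,
    statistic: str = "mode",
) -> list[float]:
    """Per-image index statistic for one class: index -> closing -> mode."""
    kind = IndexKind(kind)
    if not kind.is_normalized:
        raise ValueError("calibration operates on normalized indices (NGMR/NBMG)")
    out = []
    for img in training.images:
        idx = morphological_close(compute_index(img, kind), window)
        out.append(_image_statistic(idx, statistic))
    return out


def derive_thresholds(
    stats_land: list[float],
    stats_animal: list[float],
    stats_sky: list[float],
    kind: IndexKind | str = IndexKind.NGMR,
) -> ThresholdSet:
    """Class boundaries as midpoints between averaged class statistics.

    Requires the class means to be separated in the expected order
    (land < animal < sky on the normalized index scale); otherwise the
    classes are not distinguishable by a single-band rule and
    calibration fails with a diagnostic.
    """
    kind = IndexKind(kind)
    for name, s in (("land", stats_land), ("animal", stats_animal), ("sky", stats_sky)):
        if len(s) < 1:
            raise ValueError(f"no statistics for class {name!r}")
    m1, m2, m3 = (float(np.mean(s)) for s in (stats_land, stats_animal, stats_sky))
    if not (m1 < m2 < m3):
        raise ValueError(
            "class means are not separated in the order land < animal < sky: "
            f"land={m1:.4f}, animal={m2:.4f}, sky={m3:.4f}"
        )
    step = 10.0 ** (-QUANT_DECIMALS)
    t_c1 = round((m1 + m2) / 2.0, QUANT_DECIMALS)
    t_c2b = round((m2 + m3) / 2.0, QUANT_DECIMALS)
    t_c2a = round(t_c1 + step, QUANT_DECIMALS)
    t_c3 = round(t_c2b + step, QUANT_DECIMALS)
    if not t_c2a <= t_c2b:
        raise ValueError(
            f"degenerate marine-animal band: boundaries {t_c1:.4f} and {t_c2b:.4f} collide"
        )
    return ThresholdSet(t_c1, t_c2a, t_c2b, t_c3, kind)


def calibrate(
    land: TrainingSet,
    animal: TrainingSet,
    sky: TrainingSet,
    kinds: tuple = (IndexKind.NGMR, IndexKind.NBMG),
    window: int = DEFAULT_WINDOW,
    statistic: str = "mode",
) -> CalibrationReport:
    """Full calibration over one or both normalized indices."""
    thresholds: dict = {}
    class_stats: dict = {}
    for kind in (IndexKind(k) for k in kinds):
        per_class = {}
        for ts in (land, animal, sky):
            stats = class_index_statistic(ts, kind, window, statistic)
            per_class[ts.class_name] = stats
            class_stats[(kind, ts.class_name)] = stats
        thresholds[kind] = derive_thresholds(
            per_class[land.class_name],
            per_class[animal.class_name],
            per_class[sky.class_name],
            kind,
        )
    return CalibrationReport(
        thresholds=thresholds,
        class_stats=class_stats,
        n_per_class={ts.class_name: ts.n for ts in (land, animal, sky)},
        window=window,
    )


def calibration_stability(
    land: TrainingSet,
    animal: TrainingSet,
    sky: TrainingSet,
    sizes: list[int],
    seed: int = 0,
    kinds: tuple = (IndexKind.NGMR, IndexKind.NBMG),
    window: int = DEFAULT_WINDOW,
):
    """Thresholds versus training-set size (seeded random subsampling).

    For each requested size, that many images per class are sampled
    without replacement and calibration is re-run; the result is a
    tidy table with one row per (size, index) pair.  The same seed
    reproduces the same table exactly.
    """
    import pandas as pd

    n_min = min(land.n, animal.n, sky.n)
    for s in sizes:
        if s < 1 or s > n_min:
            raise ValueError(f"size {s} exceeds the corpus ({n_min} images per class)")
    rng = np.random.default_rng(seed)
    rows = []
    for size in sizes:
        sets = []
        for ts in (land, animal, sky):
            pick = rng.choice(ts.n, size=size, replace=False)
            sets.append(TrainingSet(ts.class_name, [ts.images[i] for i in pick]))
        report = calibrate(*sets, kinds=kinds, window=window)
        for kind, thr in report.thresholds.items():
            rows.append(
                {
                    "n_images": size,
                    "index": kind.value,
                    "t_c1": thr.t_c1,
                    "t_c2a": thr.t_c2a,
                    "t_c2b": thr.t_c2b,
                    "t_c3": thr.t_c3,
                }
            )
    return pd.DataFrame(rows)
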