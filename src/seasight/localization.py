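"""Region classification and animal localization.

The segmentation stage proposes one candidate region per image (the
largest 8-connected component in the marine-animal band).  A simple
supervised classifier then decides whether that region actually is a
marine animal, by comparing its aggregated local-feature descriptor
against three per-class prototypes learned from labeled training
images:

* per training image, the mean of its 64-d descriptors is the image
  aggregate;
* the class prototype ``P_c`` is the mean of those aggregates and the
  class weight ``W_c`` is the sum of their Euclidean norms (the summed
  descriptor mass of the class);
* for a query region with aggregate ``p``, the squared Euclidean
  distance ``M_c = ||p - P_c||^2`` is turned into a similarity
  ``S_c = 1 / (1 + M_c)``, weight-normalized to a score
  ``R_c = (S_c / W_c) / sum_k (S_k / W_k)``, and the region is
  assigned to the class with maximal ``R_c``.

A literal minimum-distance mode (``decision_mode="distance"``:
smallest ``M_c / W_c`` wins) is available for comparison.  When the
region yields no descriptors, or when it is classified as sky or land,
the animal location is reported as absent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .calibration import TrainingSet
from .color_index import IndexKind, compute_index
from .features import DESCRIPTOR_SIZE, DescriptorSet, extract_descriptors
from .segmentation import (
    DEFAULT_WINDOW,
    PixelClass,
    Region,
    ThresholdSet,
    classify_pixels,
    extract_regions,
    fuse_label_maps,
    morphological_close,
    select_candidate,
)

CLASS_ORDER = ("land", "animal", "sky")


@dataclass(frozen=True)
class ClassModel:
    """Per-class descriptor prototypes and weights."""

    prototypes: dict  # class name -> (64,) array
    weights: dict  # class name -> positive float
    n_per_class: dict

    def __post_init__(self) -> None:
        if set(self.prototypes) != set(CLASS_ORDER):
            raise ValueError(f"model must cover classes {CLASS_ORDER}")
        for c, w in self.weights.items():
            if not w > 0:
                raise ValueError(f"class weight for {c!r} must be positive, got {w}")
            if np.asarray(self.prototypes[c]).shape != (DESCRIPTOR_SIZE,):
                raise ValueError(f"prototype for {c!r} must have length {DESCRIPTOR_SIZE}")

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "prototypes": {c: list(map(float, p)) for c, p in self.prototypes.items()},
                    "weights": {c: float(w) for c, w in self.weights.items()},
                    "n_per_class": self.n_per_class,
                },
                fh,
            )

    @classmethod
    def load(cls, path) -> "ClassModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            {c: np.asarray(p) for c, p in d["prototypes"].items()},
            d["weights"],
            d.get("n_per_class", {}),
        )


@dataclass(frozen=True)
class DetectionResult:
    """Outcome of classifying (and possibly locating) one candidate region.

    ``decision`` is the winning class name, or ``None`` when the region
    produced no descriptors.  ``located`` is true only for a
    marine-animal decision; only then are ``bbox`` and ``centroid``
    (x, y; origin at the image's top-left corner) populated.
    """

    decision: str | None
    scores: dict = field(default_factory=dict)  # class -> R_c
    distances: dict = field(default_factory=dict)  # class -> M_c
    region: Region | None = None
    bbox: tuple | None = None
    centroid: tuple | None = None

    @property
    def located(self) -> bool:
        return self.decision == "animal" and self.centroid is not None

    def to_dict(self) -> dict:
        return {
            "decision": self.decision,
            "located": self.located,
            "scores": {c: float(v) for c, v in self.scores.items()},
            "distances": {c: float(v) for c, v in self.distances.items()},
            "bbox": list(self.bbox) if self.bbox else None,
            "centroid": list(self.centroid) if self.centroid else None,
        }


def train_class_model(
    land: TrainingSet, animal: TrainingSet, sky: TrainingSet, **detector_params
) -> ClassModel:
    """Learn per-class prototypes and weights from labeled image sets."""
    prototypes, weights, n_per_class = {}, {}, {}
    for ts in (land, animal, sky):
        aggregates = []
        for i, img in enumerate(ts.images):
            ds = extract_descriptors(img, source=f"{ts.class_name}[{i}]", **detector_params)
            agg = ds.aggregate()
            if agg is not None:
                aggregates.append(agg)
        if not aggregates:
            raise ValueError(
                f"training failure: no image of class {ts.class_name!r} "
                "yielded any descriptors"
            )
        aggregates = np.array(aggregates)
        prototypes[ts.class_name] = aggregates.mean(axis=0)
        weights[ts.class_name] = float(np.linalg.norm(aggregates, axis=1).sum())
        n_per_class[ts.class_name] = ts.n
    return ClassModel(prototypes, weights, n_per_class)


def _decide(scores: dict) -> str:
    # argmax with ties resolved in favor of the animal class (the
    # method's purpose is detection), then by class order
    best = max(scores.values())
    tied = [c for c in ("animal",) + tuple(CLASS_ORDER) if c in scores and scores[c] == best]
    return tied[0]


def classify_region(
    region_img: np.ndarray,
    model: ClassModel,
    decision_mode: str = "similarity",
    **detector_params,
) -> DetectionResult:
    """Classify a candidate-region image against the class prototypes."""
    ds = extract_descriptors(region_img, source="region", **detector_params)
    agg = ds.aggregate()
    if agg is None:
        return DetectionResult(decision=None)
    distances = {
        c: float(np.sum((agg - np.asarray(model.prototypes[c])) ** 2)) for c in CLASS_ORDER
    }
    if decision_mode == "similarity":
        raw = {c: (1.0 / (1.0 + distances[c])) / model.weights[c] for c in CLASS_ORDER}
        total = sum(raw.values())
        scores = {c: v / total for c, v in raw.items()}
        decision = _decide(scores)
    elif decision_mode == "distance":
        scores = {c: distances[c] / model.weights[c] for c in CLASS_ORDER}
        decision = min(
            CLASS_ORDER, key=lambda c: (scores[c], c != "animal", CLASS_ORDER.index(c))
        )
    else:
        raise ValueError(f"unknown decision_mode {decision_mode!r}")
    return DetectionResult(decision=decision, scores=scores, distances=distances)


ROI_PAD = 12


def region_roi(
    img: np.ndarray, region: Region, roi_mode: str = "masked", pad: int = ROI_PAD
) -> np.ndarray:
    """Crop the candidate region from the original image.

    ``"masked"`` (default): the bounding-box crop with pixels outside
    the region zeroed, so only the segmented object carries structure.
    ``"bbox"``: the plain bounding-box crop.
    ``"binary"``: the region's binary mask itself (a literal reading in
    which features come from the segmented image rather than the RGB
    data; binary masks carry little scale-space structure).

    Masked and binary crops get a ``pad``-pixel zero margin so that
    interest points on the object boundary keep their full sampling
    neighborhood instead of being clipped at the crop edge.
    """
    t, l, b, r = region.bbox
    if roi_mode == "binary":
        crop = region.mask(np.asarray(img).shape[:2])[t:b, l:r].astype(np.float64)
        return np.pad(crop, pad)
    crop = np.asarray(img)[t:b, l:r].copy()
    if roi_mode == "masked":
        m = region.mask(np.asarray(img).shape[:2])[t:b, l:r]
        crop[~m] = 0
        pad_width = ((pad, pad), (pad, pad)) + ((0, 0),) * (crop.ndim - 2)
        crop = np.pad(crop, pad_width)
    elif roi_mode != "bbox":
        raise ValueError(f"unknown roi_mode {roi_mode!r}")
    return crop


def segment_image(
    img: np.ndarray,
    thr_ngmr: ThresholdSet | None,
    thr_nbmg: ThresholdSet | None,
    fusion: str = "union",
    window: int = DEFAULT_WINDOW,
) -> np.ndarray:
    """Index -> closing -> per-index label map -> (optional) fusion."""
    if thr_ngmr is None and thr_nbmg is None:
        raise ValueError("at least one ThresholdSet is required")
    maps = []
    for thr, kind in ((thr_ngmr, IndexKind.NGMR), (thr_nbmg, IndexKind.NBMG)):
        if thr is None:
            continue
        if thr.index_kind != kind:
            raise ValueError(f"threshold set of kind {thr.index_kind} passed for {kind}")
        idx = morphological_close(compute_index(img, kind), window)
        maps.append(classify_pixels(idx, thr))
    return maps[0] if len(maps) == 1 else fuse_label_maps(maps[0], maps[1], fusion)


def locate(
    img: np.ndarray,
    thr_ngmr: ThresholdSet | None,
    thr_nbmg: ThresholdSet | None,
    model: ClassModel,
    fusion: str = "union",
    window: int = DEFAULT_WINDOW,
    min_size: int | None = None,
    roi_mode: str = "masked",
    decision_mode: str = "similarity",
    **detector_params,
) -> DetectionResult:
    """Full chain: segment, pick the largest candidate, classify, locate.

    The location (bbox and centroid) is emitted only when the candidate
    is classified as a marine animal; otherwise the decision is
    recorded and the location is absent.
    """
    labels = segment_image(img, thr_ngmr, thr_nbmg, fusion, window)
    regions = extract_regions(labels, PixelClass.ANIMAL, connectivity=8, min_size=min_size)
    cand = select_candidate(regions)
    if cand is None:
        return DetectionResult(decision=None)
    roi = region_roi(img, cand, roi_mode)
    res = classify_region(roi, model, decision_mode, **detector_params)
    if res.decision == "animal":
        return DetectionResult(
            decision=res.decision,
            scores=res.scores,
            distances=res.distances,
            region=cand,
            bbox=cand.bbox,
            centroid=cand.centroid,
        )
    return DetectionResult(
        decision=res.decision, scores=res.scores, distances=res.distances, region=cand
    )


def track_sequence(frames, *args, **kwargs) -> list[tuple[int, float | None, float | None]]:
    """Per-frame localization of a video sequence.

    Frames are processed independently — no temporal information from
    neighboring frames is used — so the result is exactly the map of
    :func:`locate` over the frames.  Returns ``(frame_index, x, y)``
    with ``None`` coordinates where the location is absent.
    """
    if len(frames) == 0:
        raise ValueError("frame sequence is empty")
    out = []
    for i, frame in enumerate(frames):
        res = locate(frame, *args, **kwargs)
        if res.located:
            out.append((i, res.centroid[0], res.centroid[1]))
        else:
            out.append((i, None, None))
    return out


def annotate_image(
    img: np.ndarray, result: DetectionResult, style: str = "box"
) -> np.ndarray:
    """Draw the detection on a copy of the image.

    ``"box"``: red bounding rectangle; ``"cross"``: red '+' mark at the
    centroid (the tracking-figure style).
    """
    out = np.asarray(img, dtype=np.uint8).copy()
    if not result.located:
        return out
    red = np.array([255, 0, 0], dtype=np.uint8)
    h, w = out.shape[:2]
    if style == "box":
        t, l, b, r = result.bbox
        b, r = min(b, h) - 1, min(r, w) - 1
        out[t, l : r + 1] = red
        out[b, l : r + 1] = red
        out[t : b + 1, l] = red
        out[t : b + 1, r] = red
    elif style == "cross":
        x, y = int(round(result.centroid[0])), int(round(result.centroid[1]))
        arm = max(3, min(h, w) // 40)
        out[max(0, y - arm) : min(h, y + arm + 1), x] = red
        out[y, max(0, x - arm) : min(w, x + arm + 1)] = red
    else:
        raise ValueError(f"unknown style {style!r}")
    return out
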