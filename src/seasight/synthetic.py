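"""Seeded synthetic sighting scenes with ground truth.

A sighting image is emulated as horizontal bands — blue-dominant sky
at the top, an optional red/green-dominant land strip at the horizon,
blue-green sea below — with a low-chroma gray animal ellipse on the
sea.  Band colors are chosen so that, on the normalized color-index
scale, land < animal < sky in that order while the sea falls between
the animal body and the sky (sea and animal reflect each other in real
sightings, but the sea's blue-green excess keeps its index above the
animal band once thresholds are calibrated on the three classes).

Texture is luminance-only mottling (equal in R, G and B), so it gives
local features structure to latch onto without moving the color
indices at all; chroma-perturbing effects are explicit knobs
(illumination shift, Gaussian blur, per-channel noise).  A distractor
mode adds small bird-like gray blobs in the sky.

All randomness derives from a single integer seed split into
independent substreams (background, animal, distractors, noise), so
changing one knob does not reshuffle unrelated randomness.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .calibration import TrainingSet
from .color_index import L_MAX
from .segmentation import PixelClass

# Default band colors (R, G, B).  On the unit index scale these give
# NGMR land 0.441 / animal 0.504 / sea 0.598 / sky 0.618 and
# NBMG land 0.441 / animal 0.508 / sea 0.588 / sky 0.637.
SKY_RGB = (100, 160, 230)
SEA_RGB = (60, 110, 155)
LAND_RGB = (120, 90, 60)
ANIMAL_RGB = (90, 92, 96)

# luminance-mottling amplitude per class (gray levels)
TEXTURE_AMP = {"sky": 4.0, "sea": 7.0, "land": 14.0, "animal": 6.0}
TEXTURE_SCALE = 5.0  # Gaussian correlation length of the mottling, px


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic sighting scene."""

    height: int = 160
    width: int = 200
    sky_frac: float = 0.35
    land_frac: float = 0.15  # 0 removes the land strip
    sky_rgb: tuple = SKY_RGB
    sea_rgb: tuple = SEA_RGB
    land_rgb: tuple = LAND_RGB
    animal_rgb: tuple = ANIMAL_RGB
    animal: bool = True
    animal_center: tuple | None = None  # (x, y); default: center of the sea band
    animal_axes: tuple = (22.0, 12.0)  # semi-axes (along-x, along-y) before rotation
    animal_rotation_deg: float = 20.0
    illumination_shift: tuple = (0, 0, 0)
    blur_sigma: float = 0.5
    noise_sigma: float = 2.0
    n_distractors: int = 0
    distractor_radius: float = 2.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.sky_frac <= 1 and 0 <= self.land_frac <= 1):
            raise ValueError("band fractions must lie in [0, 1]")
        if self.sky_frac + self.land_frac > 1:
            raise ValueError("sky and land fractions must leave room for the sea")
        if self.animal and min(self.animal_axes) <= 0:
            raise ValueError("animal axes must be positive")

    @property
    def sky_rows(self) -> tuple[int, int]:
        return (0, int(round(self.sky_frac * self.height)))

    @property
    def land_rows(self) -> tuple[int, int]:
        top = self.sky_rows[1]
        return (top, top + int(round(self.land_frac * self.height)))

    @property
    def sea_rows(self) -> tuple[int, int]:
        return (self.land_rows[1], self.height)


@dataclass(frozen=True)
class GroundTruth:
    """Per-pixel truth for a generated scene."""

    class_mask: np.ndarray  # PixelClass values; sea and animal share ANIMAL-band truth? no:
    # class_mask holds the scene-content classes LAND / ANIMAL(sea+animal) / SKY,
    # mirroring the three-class labeling the segmenter produces.
    animal_mask: np.ndarray  # the animal instance alone
    centroid: tuple | None  # (x, y), top-left origin
    bbox: tuple | None  # (top, left, bottom, right), half-open

    def __post_init__(self) -> None:
        if self.animal_mask.any():
            if self.centroid is None or self.bbox is None:
                raise ValueError("animal present but centroid/bbox missing")


def _mottling(shape, rng, scale: float = TEXTURE_SCALE) -> np.ndarray:
    field2d = ndimage.gaussian_filter(rng.standard_normal(shape), scale, mode="wrap")
    sd = field2d.std()
    return field2d / sd if sd > 0 else field2d


def _ellipse_mask(shape, center, axes, rotation_deg) -> np.ndarray:
    h, w = shape
    cx, cy = center
    a, b = axes
    th = np.deg2rad(rotation_deg)
    yy, xx = np.mgrid[0:h, 0:w]
    u = (xx - cx) * np.cos(th) + (yy - cy) * np.sin(th)
    v = -(xx - cx) * np.sin(th) + (yy - cy) * np.cos(th)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _band_masks(spec: SceneSpec):
    h, w = spec.height, spec.width
    rows = np.arange(h)[:, None] * np.ones((1, w), dtype=int)
    sky = rows < spec.sky_rows[1]
    land = (rows >= spec.land_rows[0]) & (rows < spec.land_rows[1])
    sea = rows >= spec.sea_rows[0]
    return sky, land, sea


def _animal_geometry(spec: SceneSpec):
    sea_top, sea_bot = spec.sea_rows
    if sea_bot - sea_top < 3:
        raise ValueError("sea band too thin to hold an animal")
    center = spec.animal_center
    if center is None:
        center = (spec.width / 2.0, (sea_top + sea_bot) / 2.0)
    a, b = spec.animal_axes
    reach = max(a, b)
    if not (sea_top <= center[1] - reach and center[1] + reach <= sea_bot):
        raise ValueError(
            f"animal at y={center[1]:.1f} with reach {reach:.1f} leaves the sea "
            f"band rows [{sea_top}, {sea_bot})"
        )
    if not (0 <= center[0] - reach and center[0] + reach <= spec.width):
        raise ValueError("animal leaves the image horizontally")
    return center, (a, b)


def _render(spec: SceneSpec, animal_center=None, streams=None):
    """Render one frame; ``streams`` lets sequences share substreams."""
    if streams is None:
        streams = [np.random.default_rng(s) for s in np.random.SeedSequence(spec.seed).spawn(4)]
    rng_bg, rng_animal, rng_distr, rng_noise = streams
    h, w = spec.height, spec.width
    sky, land, sea = _band_masks(spec)

    img = np.zeros((h, w, 3), dtype=np.float64)
    for mask, rgb in ((sky, spec.sky_rgb), (land, spec.land_rgb), (sea, spec.sea_rgb)):
        img[mask] = rgb

    tex = _mottling((h, w), rng_bg)
    amp = np.zeros((h, w))
    amp[sky] = TEXTURE_AMP["sky"]
    amp[land] = TEXTURE_AMP["land"]
    amp[sea] = TEXTURE_AMP["sea"]

    animal_mask = np.zeros((h, w), dtype=bool)
    if spec.animal:
        center, axes = _animal_geometry(
            spec if animal_center is None else replace(spec, animal_center=animal_center)
        )
        animal_mask = _ellipse_mask((h, w), center, axes, spec.animal_rotation_deg)
        img[animal_mask] = spec.animal_rgb
        amp[animal_mask] = TEXTURE_AMP["animal"]

    img += (tex * amp)[..., None]

    if spec.n_distractors > 0:
        r0, r1 = spec.sky_rows
        for _ in range(spec.n_distractors):
            cx = rng_distr.uniform(spec.distractor_radius, w - spec.distractor_radius)
            cy = rng_distr.uniform(
                r0 + spec.distractor_radius, max(r0 + spec.distractor_radius + 1, r1 - spec.distractor_radius)
            )
            blob = _ellipse_mask((h, w), (cx, cy), (spec.distractor_radius,) * 2, 0.0)
            img[blob] = spec.animal_rgb

    img += np.asarray(spec.illumination_shift, dtype=np.float64)
    if spec.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, (spec.blur_sigma, spec.blur_sigma, 0))
    if spec.noise_sigma > 0:
        img += rng_noise.normal(0.0, spec.noise_sigma, img.shape)
    img = np.clip(np.round(img), 0, L_MAX).astype(np.uint8)

    class_mask = np.full((h, w), PixelClass.ANIMAL, dtype=np.int8)
    class_mask[sky] = PixelClass.SKY
    class_mask[land] = PixelClass.LAND
    class_mask[animal_mask] = PixelClass.ANIMAL

    if animal_mask.any():
        rr, cc = np.nonzero(animal_mask)
        centroid = (float(cc.mean()), float(rr.mean()))
        bbox = (int(rr.min()), int(cc.min()), int(rr.max()) + 1, int(cc.max()) + 1)
    else:
        centroid = bbox = None
    return img, GroundTruth(class_mask, animal_mask, centroid, bbox)


def generate_scene(spec: SceneSpec) -> tuple[np.ndarray, GroundTruth]:
    """One seeded scene and its ground truth (deterministic per seed)."""
    return _render(spec)


def class_index_means(spec: SceneSpec = SceneSpec()) -> dict:
    """The true per-class normalized-index means implied by the colors."""
    out = {}
    for name, rgb in (
        ("land", spec.land_rgb),
        ("animal", spec.animal_rgb),
        ("sea", spec.sea_rgb),
        ("sky", spec.sky_rgb),
    ):
        r, g, b = (float(c) for c in rgb)
        out[name] = {
            "ngmr": (g - r + L_MAX) / (2 * L_MAX),
            "nbmg": (b - g + L_MAX) / (2 * L_MAX),
        }
    return out


def _patch_spec(spec: SceneSpec, class_id: str, size) -> SceneSpec:
    h, w = size
    if class_id == "sky":
        return replace(spec, height=h, width=w, sky_frac=1.0, land_frac=0.0, animal=False)
    if class_id == "land":
        return replace(spec, height=h, width=w, sky_frac=0.0, land_frac=1.0, animal=False)
    if class_id == "animal":
        return replace(spec, height=h, width=w, sky_frac=0.0, land_frac=0.0, animal=False)
    raise ValueError(f"unknown class {class_id!r}")


def generate_class_patches(
    class_id: str,
    n: int,
    spec: SceneSpec = SceneSpec(),
    seed: int = 0,
    size: tuple[int, int] = (64, 64),
    style: str = "flat",
) -> TrainingSet:
    """Class-pure training patches.

    ``style="flat"``: a uniform patch of the class color plus its
    luminance mottling — the calibration-style training crop.
    ``style="roi"``: for the animal class, an ellipse of animal color
    on a black background, emulating the masked region-of-interest
    crops the localization classifier sees; other classes fall back to
    the flat style.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    h, w = size
    base = _patch_spec(spec, class_id, size)
    images = []
    for k, ss in enumerate(np.random.SeedSequence(seed).spawn(n)):
        streams = [np.random.default_rng(s) for s in ss.spawn(4)]
        if style == "roi" and class_id == "animal":
            rng = streams[1]
            axes = (rng.uniform(0.28, 0.42) * w, rng.uniform(0.16, 0.24) * h)
            rot = rng.uniform(0.0, 180.0)
            ps = replace(
                base,
                animal=True,
                animal_center=(w / 2.0, h / 2.0),
                animal_axes=axes,
                animal_rotation_deg=rot,
                sea_rgb=(0, 0, 0),
            )
            # a masked ROI has zero background: drop sea texture
            img, _ = _render(ps, streams=streams)
            img = img.copy()
        elif style in ("flat", "roi"):
            if class_id == "animal":
                ps = replace(base, sea_rgb=base.animal_rgb)
                img, _ = _render(ps, streams=streams)
            else:
                img, _ = _render(base, streams=streams)
        else:
            raise ValueError(f"unknown style {style!r}")
        images.append(img)
    return TrainingSet(class_id, images)


def generate_sequence(
    spec: SceneSpec, n_frames: int, trajectory
) -> tuple[list[np.ndarray], list[tuple[float, float]]]:
    """A moving-animal frame sequence over a shared background.

    ``trajectory`` is a list of ``(x, y)`` animal centers, one per
    frame, all inside the sea band.  Returns the frames and the
    ground-truth track — exactly the requested trajectory (the
    rasterized ellipse centroid agrees with it to sub-pixel accuracy).
    """
    trajectory = [tuple(map(float, p)) for p in trajectory]
    if len(trajectory) != n_frames:
        raise ValueError(f"trajectory length {len(trajectory)} != n_frames {n_frames}")
    root = np.random.SeedSequence(spec.seed)
    bg_stream, *frame_streams = root.spawn(n_frames + 1)
    bg_rngs_state = bg_stream.spawn(3)  # shared background/animal/distractor entropy
    frames, track = [], []
    for i, center in enumerate(trajectory):
        streams = [np.random.default_rng(s) for s in bg_rngs_state] + [
            np.random.default_rng(frame_streams[i])  # per-frame noise
        ]
        img, gt = _render(spec, animal_center=center, streams=streams)
        if gt.centroid is None:
            raise ValueError(f"frame {i}: animal absent (spec.animal is False?)")
        frames.append(img)
        track.append(center)
    return frames, track
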