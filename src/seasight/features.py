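"""Scale- and rotation-invariant local features (SURF-style).

Interest points are the scale-space maxima of the determinant of the
Hessian (the detector used by SURF and by determinant-of-Hessian blob
detection); detection is delegated to scikit-image's ``blob_doh``.
Each keypoint then receives

* a dominant orientation, from a sliding pi/3 window over
  Gaussian-weighted gradient responses in a circular neighborhood of
  radius 6 s, and
* a 64-dimensional descriptor: a 20 s x 20 s patch aligned to the
  orientation is divided into a 4 x 4 grid of subregions, and each
  subregion contributes the four sums (sum dx, sum dy, sum |dx|,
  sum |dy|) of Gaussian-weighted first-derivative responses, measured
  in the rotated frame.  The vector is L2-normalized, which gives
  invariance to affine illumination change.

Everything is deterministic: the same image and parameters always
produce the same keypoints and descriptors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.feature import blob_doh

DESCRIPTOR_SIZE = 64

# Detector defaults (the Hessian-threshold / octave layout knobs).
DEFAULT_DETECTOR = {
    "min_sigma": 2.0,
    "max_sigma": 32.0,
    "num_sigma": 15,
    "threshold": 0.001,
    "max_keypoints": 200,
}


@dataclass(frozen=True)
class DescriptorSet:
    """Keypoints with their 64-d descriptors for one image or region."""

    keypoints: np.ndarray  # (n, 3): x, y, scale
    descriptors: np.ndarray  # (n, 64)
    source: str = ""

    def __post_init__(self) -> None:
        kp = np.atleast_2d(np.asarray(self.keypoints, dtype=np.float64))
        d = np.atleast_2d(np.asarray(self.descriptors, dtype=np.float64))
        if kp.size == 0:
            kp = kp.reshape(0, 3)
            d = d.reshape(0, DESCRIPTOR_SIZE)
        if kp.shape[0] != d.shape[0]:
            raise ValueError("one descriptor per keypoint required")
        if d.shape[0] and d.shape[1] != DESCRIPTOR_SIZE:
            raise ValueError(f"descriptors must be {DESCRIPTOR_SIZE}-dimensional")
        if d.size and not np.all(np.isfinite(d)):
            raise ValueError("descriptors must be finite")
        object.__setattr__(self, "keypoints", kp)
        object.__setattr__(self, "descriptors", d)

    def __len__(self) -> int:
        return self.keypoints.shape[0]

    @property
    def is_empty(self) -> bool:
        return len(self) == 0

    def aggregate(self) -> np.ndarray | None:
        """Mean descriptor vector, or ``None`` for an empty set."""
        if self.is_empty:
            return None
        return self.descriptors.mean(axis=0)


def _to_gray(image: np.ndarray) -> np.ndarray:
    a = np.asarray(image, dtype=np.float64)
    if a.ndim == 3:
        a = a[..., :3] @ np.array([0.2125, 0.7154, 0.0721])
    if a.max() > 1.0:
        a = a / 255.0
    return a


def _gradients_at_scale(gray: np.ndarray, sigma: float):
    """First-derivative-of-Gaussian responses (the Haar-response analogue)."""
    gx = ndimage.gaussian_filter(gray, sigma, order=(0, 1), mode="nearest")
    gy = ndimage.gaussian_filter(gray, sigma, order=(1, 0), mode="nearest")
    return gx, gy


def _sample(field2d: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    return ndimage.map_coordinates(
        field2d, [rows, cols], order=1, mode="nearest"
    )


# Orientation: sample offsets on the disc of radius 6 (keypoint-scale units).
_ORI_IJ = np.array(
    [(i, j) for i in range(-6, 7) for j in range(-6, 7) if i * i + j * j <= 36],
    dtype=np.float64,
)
_ORI_W = np.exp(-(np.sum(_ORI_IJ**2, axis=1)) / (2 * 2.5**2))
_N_ORI_BINS = 60  # pi/3 sliding window stepped by pi/30


def _dominant_orientation(gx, gy, x: float, y: float, s: float) -> float:
    rows = y + _ORI_IJ[:, 1] * s
    cols = x + _ORI_IJ[:, 0] * s
    rx = _sample(gx, rows, cols) * _ORI_W
    ry = _sample(gy, rows, cols) * _ORI_W
    ang = np.arctan2(ry, rx)
    best_norm, best_theta = -1.0, 0.0
    centers = np.linspace(-np.pi, np.pi, _N_ORI_BINS, endpoint=False)
    for c in centers:
        d = np.abs((ang - c + np.pi) % (2 * np.pi) - np.pi)
        m = d <= np.pi / 6
        if not m.any():
            continue
        sx, sy = rx[m].sum(), ry[m].sum()
        n = sx * sx + sy * sy
        if n > best_norm:
            best_norm, best_theta = n, float(np.arctan2(sy, sx))
    return best_theta


# Descriptor sampling grid: 20x20 points, 4x4 subregions of 5x5 samples.
_GRID = np.linspace(-9.5, 9.5, 20)
_GU, _GV = np.meshgrid(_GRID, _GRID, indexing="xy")  # u along x, v along y
_DESC_W = np.exp(-((_GU**2 + _GV**2)) / (2 * 3.3**2))


def _descriptor(gx, gy, x: float, y: float, s: float, theta: float) -> np.ndarray:
    ct, st = np.cos(theta), np.sin(theta)
    # rotated sample positions in image coordinates
    sx = x + s * (_GU * ct - _GV * st)
    sy = y + s * (_GU * st + _GV * ct)
    rx = _sample(gx, sy, sx)
    ry = _sample(gy, sy, sx)
    # gradient responses expressed in the keypoint frame
    du = (rx * ct + ry * st) * _DESC_W
    dv = (-rx * st + ry * ct) * _DESC_W
    vec = np.empty(DESCRIPTOR_SIZE)
    k = 0
    for bi in range(4):
        for bj in range(4):
            blk = (slice(5 * bi, 5 * bi + 5), slice(5 * bj, 5 * bj + 5))
            u, v = du[blk], dv[blk]
            vec[k : k + 4] = (u.sum(), v.sum(), np.abs(u).sum(), np.abs(v).sum())
            k += 4
    n = np.linalg.norm(vec)
    return vec / n if n > 1e-12 else vec


def extract_descriptors(
    image: np.ndarray,
    source: str = "",
    **detector_params,
) -> DescriptorSet:
    """Detect Hessian-determinant interest points and describe them.

    Accepts a single- or three-channel image (converted to grayscale
    internally).  Images too small or too flat to carry scale-space
    extrema yield an empty set, not an error.
    """
    params = {**DEFAULT_DETECTOR, **detector_params}
    max_kp = params.pop("max_keypoints")
    gray = _to_gray(image)
    if min(gray.shape) < 8 or np.ptp(gray) < 1e-12:
        return DescriptorSet(np.empty((0, 3)), np.empty((0, DESCRIPTOR_SIZE)), source)
    blobs = blob_doh(gray, **params)
    if blobs.shape[0] == 0:
        return DescriptorSet(np.empty((0, 3)), np.empty((0, DESCRIPTOR_SIZE)), source)
    # deterministic order: by scale, then y, then x; keep the strongest
    # (largest-scale-first is not meaningful here, use stable spatial order)
    order = np.lexsort((blobs[:, 1], blobs[:, 0], blobs[:, 2]))
    blobs = blobs[order][:max_kp]

    grads: dict[float, tuple] = {}
    kps, descs = [], []
    for yy, xx, s in blobs:
        s = max(float(s), 1.0)
        if s not in grads:
            grads[s] = _gradients_at_scale(gray, s)
        gx, gy = grads[s]
        theta = _dominant_orientation(gx, gy, xx, yy, s)
        descs.append(_descriptor(gx, gy, xx, yy, s, theta))
        kps.append((xx, yy, s))
    return DescriptorSet(np.array(kps), np.array(descs), source)


def match_descriptors_sets(a: DescriptorSet, b: DescriptorSet) -> np.ndarray:
    """Nearest-neighbor distances from each descriptor of ``a`` to ``b``."""
    if a.is_empty or b.is_empty:
        return np.empty(0)
    d2 = (
        np.sum(a.descriptors**2, axis=1)[:, None]
        + np.sum(b.descriptors**2, axis=1)[None, :]
        - 2 * a.descriptors @ b.descriptors.T
    )
    return np.sqrt(np.maximum(d2.min(axis=1), 0.0))
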