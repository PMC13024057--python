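"""Deterministic preprocessing and stochastic training augmentation.

The preprocessing chain mirrors a standard radiograph pipeline: adaptive
histogram equalization, proportional rescale so the longer side hits the
target, asymmetric zero-padding to a square canvas, and (training only)
minor random affine transforms plus random horizontal flipping.  Every
geometric step is captured in a :class:`GeometryRecord` so ROI masks and
saliency maps can be mapped into — and back out of — the preprocessed image
frame.

Coordinate convention throughout: row-major, 0-based, origin top-left,
half-open pixel boxes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage
from skimage import exposure, transform

from .phantom import STANDARD, MIRRORED


@dataclass(frozen=True)
class GeometryRecord:
    """Invertible record of the resize + pad (+ flip) geometry.

    ``scale`` maps source pixels to resized pixels; pads are in target
    pixels.  ``flip_applied`` records a final horizontal mirror.
    """

    scale: float
    pad_top: int
    pad_left: int
    pad_bottom: int
    pad_right: int
    source_dims: tuple[int, int]
    target_dims: tuple[int, int]
    flip_applied: bool = False

    def __post_init__(self):
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    @property
    def content_dims(self) -> tuple[int, int]:
        return (self.target_dims[0] - self.pad_top - self.pad_bottom,
                self.target_dims[1] - self.pad_left - self.pad_right)

    def map_point(self, row: float, col: float) -> tuple[float, float]:
        """Source-frame point -> target-frame point."""
        r = row * self.scale + self.pad_top
        c = col * self.scale + self.pad_left
        if self.flip_applied:
            c = self.target_dims[1] - 1 - c
        return r, c

    def unmap_point(self, row: float, col: float) -> tuple[float, float]:
        """Target-frame point -> source-frame point."""
        c = col
        if self.flip_applied:
            c = self.target_dims[1] - 1 - c
        return (row - self.pad_top) / self.scale, (c - self.pad_left) / self.scale

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "GeometryRecord":
        d = json.loads(s)
        d["source_dims"] = tuple(d["source_dims"])
        d["target_dims"] = tuple(d["target_dims"])
        return cls(**d)

    @classmethod
    def identity(cls, dims: tuple[int, int]) -> "GeometryRecord":
        return cls(1.0, 0, 0, 0, 0, tuple(dims), tuple(dims))


@dataclass(frozen=True)
class AugmentParams:
    """Ranges for the random training augmentation.

    rotation in degrees (± range), translation as a fraction of the image
    side (± range), scale sampled uniformly in ``scale_range``, horizontal
    flip with probability ``flip_prob``.
    """

    rotation_range: float = 5.0
    translation_range: float = 0.03
    scale_range: tuple[float, float] = (0.95, 1.05)
    flip_prob: float = 0.5

    def __post_init__(self):
        if self.rotation_range < 0 or self.translation_range < 0:
            raise ValueError("ranges must be non-negative")
        if not (0.0 <= self.flip_prob <= 1.0):
            raise ValueError("flip_prob must be in [0, 1]")


def equalize_contrast(image: np.ndarray, clip_limit: float = 0.02,
                      tile_grid: tuple[int, int] = (8, 8)) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization (CLAHE).

    ``clip_limit`` follows the scikit-image convention (fraction of the
    tile histogram, default 0.02); ``tile_grid`` is the number of contextual
    tiles per axis.  Output is float in [0, 1] with the input's dimensions.
    """
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty image")
    if not np.isfinite(image).all():
        raise ValueError("image contains non-finite values")
    if image.max() == image.min():
        # no contrast to redistribute
        return np.asarray(image, dtype=np.float32).copy()
    kernel = (max(image.shape[0] // tile_grid[0], 1),
              max(image.shape[1] // tile_grid[1], 1))
    out = exposure.equalize_adapthist(image, kernel_size=kernel,
                                      clip_limit=clip_limit)
    return out.astype(np.float32)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def resize_and_pad(image: np.ndarray, target_side: int
                   ) -> tuple[np.ndarray, GeometryRecord]:
    """Scale the longer side to ``target_side`` and zero-pad to a square.

    Aspect ratio is preserved; the short side rounds half-up.  Padding is
    split as evenly as possible with the extra pixel on the bottom/right.
    """
    if target_side < 2:
        raise ValueError("target_side must be >= 2")
    image = np.asarray(image)
    h, w = image.shape[:2]
    if h == 0 or w == 0:
        raise ValueError("degenerate image dimensions")
    scale = target_side / max(h, w)
    nh = target_side if h >= w else _round_half_up(h * scale)
    nw = target_side if w >= h else _round_half_up(w * scale)
    if (nh, nw) == (h, w):
        resized = image.astype(np.float32, copy=True)
    else:
        resized = transform.resize(image.astype(np.float32), (nh, nw),
                                   order=1, mode="edge",
                                   anti_aliasing=scale < 1.0,
                                   preserve_range=True).astype(np.float32)
    pad_v = target_side - nh
    pad_h = target_side - nw
    pads = (pad_v // 2, pad_h // 2, pad_v - pad_v // 2, pad_h - pad_h // 2)
    out = np.zeros((target_side, target_side), dtype=np.float32)
    out[pads[0]:pads[0] + nh, pads[1]:pads[1] + nw] = resized
    rec = GeometryRecord(scale=scale, pad_top=pads[0], pad_left=pads[1],
                         pad_bottom=pads[2], pad_right=pads[3],
                         source_dims=(h, w),
                         target_dims=(target_side, target_side))
    return out, rec


def transform_mask(mask: np.ndarray, record: GeometryRecord) -> np.ndarray:
    """Map a binary mask through a GeometryRecord (nearest-neighbor)."""
    mask = np.asarray(mask)
    if mask.shape != tuple(record.source_dims):
        raise ValueError(f"mask dims {mask.shape} do not match record source "
                         f"dims {record.source_dims}")
    nh, nw = record.content_dims
    if (nh, nw) == mask.shape:
        resized = mask.astype(bool, copy=True)
    else:
        resized = transform.resize(mask.astype(np.float32), (nh, nw), order=0,
                                   anti_aliasing=False,
                                   preserve_range=True) > 0.5
    out = np.zeros(record.target_dims, dtype=bool)
    out[record.pad_top:record.pad_top + nh,
        record.pad_left:record.pad_left + nw] = resized
    if record.flip_applied:
        out = out[:, ::-1]
    return out


def inverse_transform_mask(mask: np.ndarray, record: GeometryRecord) -> np.ndarray:
    """Map a target-frame binary mask back to the source frame."""
    mask = np.asarray(mask)
    if mask.shape != tuple(record.target_dims):
        raise ValueError("mask dims do not match record target dims")
    if record.flip_applied:
        mask = mask[:, ::-1]
    nh, nw = record.content_dims
    content = mask[record.pad_top:record.pad_top + nh,
                   record.pad_left:record.pad_left + nw]
    if (nh, nw) == tuple(record.source_dims):
        return content.astype(bool, copy=True)
    return transform.resize(content.astype(np.float32), record.source_dims,
                            order=0, anti_aliasing=False,
                            preserve_range=True) > 0.5


def apply_augmentation(image: np.ndarray, params: AugmentParams,
                       rng: np.random.Generator | int) -> np.ndarray:
    """One random affine (rotation/translation/scale about the center) plus
    a Bernoulli horizontal flip.  Deterministic given the generator state."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    image = np.asarray(image, dtype=np.float32)
    h, w = image.shape
    angle = rng.uniform(-params.rotation_range, params.rotation_range)
    dr = rng.uniform(-params.translation_range, params.translation_range) * h
    dc = rng.uniform(-params.translation_range, params.translation_range) * w
    lo, hi = params.scale_range
    scale = rng.uniform(lo, hi)
    do_flip = rng.random() < params.flip_prob

    if angle != 0.0 or dr != 0.0 or dc != 0.0 or scale != 1.0:
        theta = np.deg2rad(angle)
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]]) * scale
        inv = np.linalg.inv(rot)
        cen = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
        offset = cen - inv @ (cen + np.array([dr, dc]))
        image = ndimage.affine_transform(image, inv, offset=offset, order=1,
                                         mode="constant", cval=0.0)
    if do_flip:
        image = image[:, ::-1].copy()
    return image.astype(np.float32)


def align_orientation(arr: np.ndarray, orientation: str) -> np.ndarray:
    """Bring an image/mask/saliency map into the standard lateral orientation.

    Mirrored inputs are flipped horizontally; standard inputs are returned
    unchanged.  Idempotent in the sense that re-aligning the returned array
    (which is now standard) is a no-op.
    """
    if orientation == STANDARD:
        return np.asarray(arr)
    if orientation == MIRRORED:
        return np.asarray(arr)[..., ::-1].copy()
    raise ValueError(f"unknown orientation {orientation!r}")


def preprocess(image: np.ndarray, target_side: int,
               clip_limit: float = 0.02, tile_grid=(8, 8)
               ) -> tuple[np.ndarray, GeometryRecord]:
    """Full deterministic chain: equalize -> resize -> pad."""
    eq = equalize_contrast(image, clip_limit=clip_limit, tile_grid=tile_grid)
    return resize_and_pad(eq, target_side)
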