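"""Grad-CAM saliency for the regression and classification heads, and
population-average maps.

For a model output target (the predicted age, or one sex logit) and the
last convolutional feature stack F^r (r = 1..R), the channel weight is the
global average of the gradient over the N_p feature pixels,

    alpha_r = (1/N_p) * sum_ij  d target / d F^r_ij ,

the raw map is the weighted sum  M = sum_r alpha_r F^r,  and the saliency
map is its rectification  M* = ReLU(M).  Maps are bilinearly upsampled to
the preprocessed-image frame and aligned to the standard lateral
orientation before any averaging or regional indexing.  Saliency values
are kept raw (unnormalized) everywhere except in overlays.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .nets import Model
from .pretreat import align_orientation
from .phantom import STANDARD


@dataclass
class SaliencyMap:
    """One subject's attribution map.

    ``alpha`` are the channel weights, ``raw`` the pre-ReLU weighted sum,
    ``rect`` the rectified map (both at feature resolution); ``image_rect``
    is the rectified map upsampled to the image frame and aligned to the
    standard orientation (filled by :func:`upsample_align`).
    """

    subject_id: str
    task: str  # "age" | "sex"
    alpha: np.ndarray
    raw: np.ndarray
    rect: np.ndarray
    image_rect: np.ndarray | None = None
    group_key: tuple | None = None


@dataclass
class AverageSaliencyMap:
    """Pixelwise mean of member maps for one group."""

    group_key: tuple
    mean: np.ndarray
    n_members: int


def gradcam_map(model: Model, image: np.ndarray, subject_id: str = "",
                task: str | None = None, class_index: int | None = None
                ) -> SaliencyMap:
    """Grad-CAM at feature resolution for one image.

    For the age head the target is the scalar age output; for the sex head
    it is the logit of ``class_index`` (0 = male, 1 = female), which the
    caller usually sets to the subject's true class.
    """
    head = model.config.head
    task = task or ("age" if head == "age_regression" else "sex")
    x = np.asarray(image, dtype=np.float32)[None]
    feats = model.features(x, train=False)  # (1, R, h, w)
    out_dim = model.config.out_dim
    dout = np.zeros((1, out_dim), dtype=np.float32)
    if head == "age_regression":
        dout[0, 0] = 1.0
    else:
        if class_index is None:
            raise ValueError("class_index required for the sex head")
        dout[0, class_index] = 1.0
    grads = model.head_input_gradient(feats, dout)[0]  # (R, h, w)
    alpha = grads.mean(axis=(1, 2))
    raw = np.einsum("r,rhw->hw", alpha, feats[0], optimize=True)
    rect = np.maximum(raw, 0.0)
    return SaliencyMap(subject_id=subject_id, task=task, alpha=alpha,
                       raw=raw, rect=rect)


def bilinear_upsample(arr: np.ndarray, target_shape: tuple[int, int]
                      ) -> np.ndarray:
    """Bilinear interpolation with the half-pixel center convention.

    Output pixel centers map to input coordinates
    ``(i + 0.5) * H_in / H_out - 0.5``; coordinates beyond the border clamp
    to the edge value.
    """
    H, W = arr.shape
    Ht, Wt = target_shape
    rows = (np.arange(Ht) + 0.5) * H / Ht - 0.5
    cols = (np.arange(Wt) + 0.5) * W / Wt - 0.5
    rr, cc = np.meshgrid(np.clip(rows, 0, H - 1), np.clip(cols, 0, W - 1),
                         indexing="ij")
    return ndimage.map_coordinates(arr.astype(np.float64), [rr, cc], order=1,
                                   mode="nearest").astype(np.float32)


def upsample_align(smap: SaliencyMap, image_shape: tuple[int, int],
                   orientation: str = STANDARD) -> SaliencyMap:
    """Upsample the rectified map to the image frame and standardize its
    orientation.  Values stay >= 0."""
    if smap.rect is None:
        raise ValueError("feature-resolution map missing")
    up = bilinear_upsample(smap.rect, image_shape)
    up = align_orientation(up, orientation)
    return replace(smap, image_rect=np.ascontiguousarray(up))


def group_average(maps: list[SaliencyMap], group_key: tuple,
                  use_image_frame: bool = True) -> AverageSaliencyMap:
    """Pixelwise arithmetic mean of aligned member maps."""
    if not maps:
        raise ValueError("cannot average an empty list of maps")
    arrays = [(m.image_rect if use_image_frame else m.rect) for m in maps]
    shapes = {a.shape for a in arrays}
    if len(shapes) != 1:
        raise ValueError(f"maps have mismatched dims: {shapes}")
    acc = np.zeros(arrays[0].shape, dtype=np.float64)
    for a in arrays:
        acc += a
    return AverageSaliencyMap(group_key=group_key,
                              mean=(acc / len(arrays)).astype(np.float32),
                              n_members=len(arrays))


def colorize_overlay(saliency: np.ndarray, image: np.ndarray,
                     alpha: float = 0.45) -> np.ndarray:
    """Render a saliency map as a blue-to-red overlay on a grayscale image.

    The map is min-max normalized for display only; a constant map renders
    all-blue by convention.  Returns an (H, W, 3) uint8 RGB image.
    """
    from matplotlib import cm

    saliency = np.asarray(saliency, dtype=np.float64)
    image = np.asarray(image, dtype=np.float64)
    if saliency.shape != image.shape:
        raise ValueError("saliency and image dims differ")
    lo, hi = saliency.min(), saliency.max()
    norm = np.zeros_like(saliency) if hi == lo else (saliency - lo) / (hi - lo)
    heat = cm.jet(norm)[..., :3]
    g = image - image.min()
    if g.max() > 0:
        g = g / g.max()
    rgb = (1 - alpha) * g[..., None] + alpha * heat
    return (np.clip(rgb, 0, 1) * 255).astype(np.uint8)
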