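"""Consensus ROI masks, percentile thresholds and the regional saliency
indices ASI and SSI.

For a region mask M_C and a subject saliency map S (image frame), the
regional index is the mean of the supra-threshold saliency values inside
the region,

    index(C) = (1/N_s) * sum_{(i,j) in M_C, S_ij >= t}  S_ij ,

where t is the 75th percentile (by default) of the group's pooled saliency
distribution and N_s is the count of supra-threshold pixels; when N_s = 0
the index is 0 by convention.  The Age-related Saliency Index (ASI) uses
maps from the age-regression model, the Sex-related Saliency Index (SSI)
uses maps from the sex-classification model; the formula is identical and
so is the code path.  Per subject the index is an ensemble: the mean over
the k (default 20) annotator masks of its group, and the group-level table
entry is the unweighted mean over the group's subjects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phantom import RegionMaskSet
from .saliency import SaliencyMap

REGION_ORDER = ("orbit", "zygoma", "maxilla", "sphenoid", "temporal", "mandible")


def consensus_mask(masks: np.ndarray, rule: float = 0.5) -> np.ndarray:
    """Pixelwise majority vote over k binary masks (ties included)."""
    masks = np.asarray(masks)
    if masks.ndim != 3:
        raise ValueError("masks must be (k, H, W)")
    return masks.mean(axis=0) >= rule


@dataclass(frozen=True)
class SaliencyThreshold:
    """A pooled-percentile saliency threshold for one group."""

    t: float
    quantile: float
    scope: tuple

    def __post_init__(self):
        if not (0.0 < self.quantile < 100.0):
            raise ValueError("quantile must be in (0, 100)")


def group_threshold(maps: list[np.ndarray] | list[SaliencyMap],
                    q: float = 75.0, scope: tuple = ()) -> SaliencyThreshold:
    """q-th percentile of all pixel values pooled over the group's maps.

    Percentiles use linear interpolation between closest ranks.
    """
    arrays = [m.image_rect if isinstance(m, SaliencyMap) else np.asarray(m)
              for m in maps]
    if not arrays:
        raise ValueError("empty group")
    pooled = np.concatenate([a.ravel() for a in arrays])
    if pooled.size == 0:
        raise ValueError("empty pixel pool")
    return SaliencyThreshold(t=float(np.percentile(pooled, q)), quantile=q,
                             scope=tuple(scope))


def region_mean_index(smap: np.ndarray, mask: np.ndarray, t: float
                      ) -> tuple[float, int]:
    """Mean supra-threshold saliency inside one mask; (value, N_s).

    Pixels with S >= t count as supra-threshold (boundary included); if no
    mask pixel reaches t the index is 0 with N_s = 0.
    """
    smap = np.asarray(smap)
    mask = np.asarray(mask, dtype=bool)
    if smap.shape != mask.shape:
        raise ValueError("map and mask dims differ")
    if not mask.any():
        raise ValueError("empty region mask")
    if not np.isfinite(t):
        raise ValueError("threshold must be finite")
    vals = smap[mask]
    supra = vals >= t
    n_s = int(supra.sum())
    value = float(vals[supra].mean()) if n_s else 0.0
    return value, n_s


def ensemble_index(smap: np.ndarray, annotator_masks: np.ndarray, t: float
                   ) -> tuple[float, float]:
    """Mean of region_mean_index over k annotator masks.

    Returns (value, mean N_s over the ensemble).
    """
    annotator_masks = np.asarray(annotator_masks)
    if annotator_masks.ndim != 3 or annotator_masks.shape[0] < 1:
        raise ValueError("annotator_masks must be (k>=1, H, W)")
    vals, counts = zip(*(region_mean_index(smap, m, t)
                         for m in annotator_masks))
    return float(np.mean(vals)), float(np.mean(counts))


def index_table(subject_maps: dict[tuple, list[SaliencyMap]],
                masksets: dict[tuple, RegionMaskSet],
                q: float = 75.0, kind: str = "ASI") -> pd.DataFrame:
    """Full regional index table over groups of subject maps.

    ``subject_maps`` maps a group key — ``(age_bin,)`` or
    ``(age_bin, sex)`` — to the aligned image-frame maps of that group's
    test subjects; ``masksets`` supplies the annotator masks per group.
    Per group the threshold is pooled over all member maps; each subject
    contributes an ensemble index per region and the table entry is their
    unweighted mean.  Groups with no subjects are omitted.

    Columns: kind, sex, age, region, value, N_s, n_subjects, t.
    """
    if kind not in ("ASI", "SSI"):
        raise ValueError("kind must be 'ASI' or 'SSI'")
    rows = []
    for key in sorted(subject_maps.keys()):
        maps = subject_maps[key]
        if not maps:
            continue
        maskset = masksets[key]
        thr = group_threshold(maps, q=q, scope=key)
        age = key[0]
        sex = key[1] if len(key) > 1 else "all"
        for region in REGION_ORDER:
            if region not in maskset.annotators:
                continue
            amasks = maskset.annotators[region]
            per_subject = [ensemble_index(m.image_rect, amasks, thr.t)
                           for m in maps]
            values = [v for v, _ in per_subject]
            counts = [c for _, c in per_subject]
            rows.append({"kind": kind, "sex": sex, "age": age,
                         "region": region,
                         "value": float(np.mean(values)),
                         "N_s": float(np.mean(counts)),
                         "n_subjects": len(maps), "t": thr.t})
    return pd.DataFrame(rows)
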