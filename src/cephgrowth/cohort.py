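"""Cohort bookkeeping: one-year age bins, stratified splits, age subsets.

The age task uses sex x age-bin stratified 7:1.5:1.5 train/val/test splits
with one-year age bins 4-5 ... 18-19; the sex task uses age-specific
subsets (default ages 6, 9, 12, 15 and 18), each split with the same
ratios.  Splits are deterministic given a seed, use largest-remainder
rounding within each stratum, and never place a subject in two sets.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .phantom import AGE_MIN, AGE_MAX

SPLIT_NAMES = ("train", "val", "test")
DEFAULT_RATIOS = (0.70, 0.15, 0.15)
DEFAULT_SUBSET_AGES = (6, 9, 12, 15, 18)


def age_bin(age) -> np.ndarray | int:
    """One-year bin label: floor(age), valid for ages in [4, 19)."""
    a = np.asarray(age, dtype=float)
    if np.any(a < AGE_MIN) or np.any(a >= AGE_MAX):
        raise ValueError(f"age outside [{AGE_MIN}, {AGE_MAX})")
    bins = np.floor(a).astype(int)
    return int(bins) if np.isscalar(age) else bins


def _largest_remainder_counts(n: int, ratios: np.ndarray) -> np.ndarray:
    exact = n * ratios
    base = np.floor(exact).astype(int)
    rem = exact - base
    short = n - base.sum()
    order = np.argsort(-rem, kind="stable")
    base[order[:short]] += 1
    return base


def stratified_split(metadata: pd.DataFrame,
                     ratios: tuple[float, float, float] = DEFAULT_RATIOS,
                     strata: tuple[str, ...] = ("sex", "age_bin"),
                     seed: int = 0) -> pd.DataFrame:
    """Assign subjects to train/val/test within each stratum.

    Within every stratum the subjects are shuffled (seeded) and cut at the
    cumulative ratios using largest-remainder rounding, so per-stratum
    fractions are within one subject of the requested ratios.  Returns a
    DataFrame with columns ``subject_id`` and ``split``.
    """
    ratios = np.asarray(ratios, dtype=float)
    if abs(ratios.sum() - 1.0) > 1e-9:
        raise ValueError("ratios must sum to 1")
    meta = metadata.copy()
    if "age_bin" in strata and "age_bin" not in meta.columns:
        meta["age_bin"] = age_bin(meta["age"].to_numpy())
    for col in strata:
        if col not in meta.columns:
            raise ValueError(f"stratum column {col!r} missing from metadata")

    rng = np.random.default_rng(seed)
    parts = []
    # sort group keys for a deterministic stratum order
    grouped = meta.groupby(list(strata), sort=True, observed=True)
    for _, grp in grouped:
        ids = grp["subject_id"].to_numpy()
        ids = ids[np.argsort(ids, kind="stable")]
        rng.shuffle(ids)
        counts = _largest_remainder_counts(len(ids), ratios)
        edges = np.cumsum(counts)
        assign = np.empty(len(ids), dtype=object)
        assign[:edges[0]] = SPLIT_NAMES[0]
        assign[edges[0]:edges[1]] = SPLIT_NAMES[1]
        assign[edges[1]:] = SPLIT_NAMES[2]
        parts.append(pd.DataFrame({"subject_id": ids, "split": assign}))
    out = pd.concat(parts, ignore_index=True)
    return out.sort_values("subject_id", kind="stable").reset_index(drop=True)


def attach_split(metadata: pd.DataFrame, assignment: pd.DataFrame) -> pd.DataFrame:
    """Join the split assignment back onto the metadata table."""
    return metadata.merge(assignment, on="subject_id", validate="one_to_one")


def select_age_subsets(metadata: pd.DataFrame,
                       ages: tuple[int, ...] = DEFAULT_SUBSET_AGES
                       ) -> dict[int, pd.DataFrame]:
    """Age-specific subsets for the sex task: subjects with floor(age) == a."""
    bins = age_bin(metadata["age"].to_numpy())
    return {a: metadata.loc[bins == a].reset_index(drop=True) for a in ages}
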