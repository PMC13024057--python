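"""Synthetic lateral-cephalogram phantom cohorts with planted growth structure.

A phantom is a grayscale image containing six parametric "skeletal" regions
laid out in a fixed lateral-skull arrangement (orbit, zygoma, maxilla,
sphenoid, temporal, mandible).  Each region carries two planted signals:

* an *age* signal — the region's linear size scales as
  ``s(age) = s0 * (1 + beta * g(age))`` where ``g`` is a logistic growth
  schedule with region-specific midpoint and rate, while the region's
  *remodeling appearance* (fill density boost, trabecular texture contrast
  and a bright growth-front rim along the boundary) is proportional to the
  current remodeling activity ``beta * g'(age)`` — the radiographic
  analogue of active ossification, fading once the region matures;
* a *sex* signal — male subjects receive an additional multiplicative size
  offset ``delta * d(age)`` where ``d`` is a monotone dimorphism schedule
  rising from 0 at age 4 toward 1 at age 19.

Because the generating schedules are known, the "ground-truth importance"
of each region for age prediction at a given age is computable
(:func:`planted_importance`), which is what makes the phantom usable as a
recovery benchmark for saliency-based regional indices.

All geometry is specified in fractions of the canvas side so cohorts can be
rendered at any resolution (desk-scale 128 px up to full-scale 1000 px).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import draw as skdraw
from skimage import morphology as skmorph

AGE_MIN = 4.0
AGE_MAX = 19.0  # exclusive upper bound; ages up to and including 18.99

REGION_NAMES = ("orbit", "zygoma", "maxilla", "sphenoid", "temporal", "mandible")

MALE = "male"
FEMALE = "female"
STANDARD = "standard"
MIRRORED = "mirrored"


def _check_age(age: float) -> None:
    if not (AGE_MIN <= age < AGE_MAX):
        raise ValueError(f"age {age!r} outside the modeled range [{AGE_MIN}, {AGE_MAX})")


@dataclass(frozen=True)
class RegionTemplate:
    """One parametric skeletal region and its planted growth/dimorphism law.

    Parameters
    ----------
    name:
        One of the six canonical region names.
    shape:
        ``"disk"``, ``"ellipse"`` or ``"polygon"``.
    params:
        Geometry in canvas fractions.  disk: ``(row, col, radius)``;
        ellipse: ``(row, col, r_radius, c_radius)``; polygon: ``(N, 2)``
        array-like of (row, col) vertices.
    growth_coeff:
        beta >= 0; fractional linear-size increase at full schedule.
    growth_midpoint, growth_rate:
        Logistic schedule ``g(age) = 1 / (1 + exp(-rate*(age - midpoint)))``.
    dimorphism_coeff:
        delta >= 0; extra male size offset at full dimorphism schedule.
    dimorphism_intensity:
        extra male fill brightness at full dimorphism schedule (denser,
        more robust male cortical bone).
    dimorphism_power:
        ``d(age) = ((age - 4) / 15) ** power`` — monotone on [4, 19) into [0, 1].
    base_intensity:
        Fill gray level in [0, 1].
    """

    name: str
    shape: str
    params: tuple
    growth_coeff: float
    growth_midpoint: float
    growth_rate: float
    dimorphism_coeff: float = 0.0
    dimorphism_intensity: float = 0.0
    dimorphism_power: float = 2.0
    base_intensity: float = 0.6

    def __post_init__(self):
        if self.name not in REGION_NAMES:
            raise ValueError(f"unknown region name {self.name!r}")
        if self.shape not in ("disk", "ellipse", "polygon"):
            raise ValueError(f"unknown shape {self.shape!r}")
        if self.growth_coeff < 0:
            raise ValueError("growth_coeff must be >= 0")
        if self.dimorphism_coeff < 0:
            raise ValueError("dimorphism_coeff must be >= 0")
        for v in (self.growth_coeff, self.growth_midpoint, self.growth_rate,
                  self.dimorphism_coeff, self.dimorphism_power):
            if not math.isfinite(v):
                raise ValueError("schedule parameters must be finite")

    def growth_schedule(self, age) -> np.ndarray:
        """Logistic growth fraction g(age) in (0, 1)."""
        age = np.asarray(age, dtype=float)
        return 1.0 / (1.0 + np.exp(-self.growth_rate * (age - self.growth_midpoint)))

    def growth_rate_of_change(self, age) -> np.ndarray:
        """d g / d age — peaks at the schedule midpoint."""
        g = self.growth_schedule(age)
        return self.growth_rate * g * (1.0 - g)

    def dimorphism_schedule(self, age) -> np.ndarray:
        age = np.asarray(age, dtype=float)
        x = np.clip((age - AGE_MIN) / (AGE_MAX - AGE_MIN), 0.0, 1.0)
        return x ** self.dimorphism_power

    def size_scale(self, age: float, sex: str) -> float:
        """Linear size multiplier at (age, sex) relative to the base shape."""
        s = 1.0 + self.growth_coeff * float(self.growth_schedule(age))
        if sex == MALE:
            s += self.dimorphism_coeff * float(self.dimorphism_schedule(age))
        return s

    def max_size_scale(self) -> float:
        """Upper bound of the size multiplier over ages and sexes."""
        return 1.0 + self.growth_coeff + self.dimorphism_coeff


def default_regions() -> tuple[RegionTemplate, ...]:
    """The canonical six-region layout.

    Temporal and sphenoid carry early growth schedules (midpoints ~5–5.5 y),
    maxilla and zygoma late ones (~10.5–11 y), so regional age-importance
    crosses over around age 8.  The sex signal sits in the mandible with a
    dimorphism schedule accelerating toward age 18.
    """
    return (
        RegionTemplate("orbit", "disk", (0.30, 0.30, 0.070),
                       growth_coeff=0.03, growth_midpoint=8.0, growth_rate=0.8,
                       base_intensity=0.50),
        RegionTemplate("zygoma", "ellipse", (0.46, 0.33, 0.045, 0.065),
                       growth_coeff=0.32, growth_midpoint=11.0, growth_rate=0.9,
                       base_intensity=0.70),
        RegionTemplate("maxilla", "polygon",
                       ((0.56, 0.20), (0.57, 0.40), (0.68, 0.38), (0.67, 0.18)),
                       growth_coeff=0.32, growth_midpoint=10.5, growth_rate=0.9,
                       base_intensity=0.65),
        RegionTemplate("sphenoid", "ellipse", (0.36, 0.55, 0.060, 0.090),
                       growth_coeff=0.30, growth_midpoint=5.5, growth_rate=0.9,
                       base_intensity=0.60),
        RegionTemplate("temporal", "ellipse", (0.28, 0.78, 0.110, 0.055),
                       growth_coeff=0.32, growth_midpoint=5.0, growth_rate=0.9,
                       base_intensity=0.60),
        RegionTemplate("mandible", "polygon",
                       ((0.80, 0.18), (0.90, 0.32), (0.91, 0.52), (0.86, 0.62),
                        (0.64, 0.66), (0.64, 0.59), (0.82, 0.55), (0.80, 0.40),
                        (0.77, 0.28), (0.74, 0.21)),
                       growth_coeff=0.08, growth_midpoint=8.0, growth_rate=0.9,
                       dimorphism_coeff=0.16, dimorphism_intensity=0.10,
                       base_intensity=0.68),
    )


@dataclass(frozen=True)
class PhantomSpec:
    """Acquisition regime of a phantom cohort.

    ``noise_sd`` (intensity units on a [0, 1] scale), ``jitter_sd`` (pixels
    at 128 px canvas; scaled proportionally for other canvas sizes),
    ``size_jitter_sd`` (fractional per-region size deviation from the age
    norm — biological variation) and ``flip_prob`` control per-subject
    nuisance variation.  ``texture_amp`` is the contrast of the
    band-limited trabecular texture at peak remodeling activity;
    ``activity_boost`` and ``growth_front_amp`` likewise scale with the
    normalized remodeling activity of each region.  Setting any amplitude
    to 0 disables that cue.
    """

    canvas_side: int = 128
    regions: tuple[RegionTemplate, ...] = field(default_factory=default_regions)
    noise_sd: float = 0.03
    jitter_sd: float = 1.5
    size_jitter_sd: float = 0.03
    flip_prob: float = 0.5
    texture_amp: float = 0.06       # trabecular texture contrast
    texture_baseline: float = 1.0   # contrast fraction retained at maturity
    texture_sigma_hi: float = 2.5   # texture correlation length (px @128), young
    texture_sigma_lo: float = 1.0   # correlation length at full maturity
    growth_front_amp: float = 0.0   # peak brightness of the remodeling rim
    growth_front_width: float = 0.016  # rim width as a fraction of canvas side
    activity_boost: float = 0.0     # region brightness gain at peak remodeling
    intensity_gain_range: tuple[float, float] = (0.9, 1.1)
    background: float = 0.08

    def __post_init__(self):
        if self.canvas_side < 32:
            raise ValueError("canvas_side must be >= 32")
        if not (0.0 <= self.flip_prob <= 1.0):
            raise ValueError("flip_prob must be in [0, 1]")
        if (self.noise_sd < 0 or self.jitter_sd < 0 or self.texture_amp < 0
                or self.size_jitter_sd < 0):
            raise ValueError(
                "noise_sd, jitter_sd, size_jitter_sd and texture_amp must be >= 0")
        names = [r.name for r in self.regions]
        if len(set(names)) != len(names):
            raise ValueError("duplicate region names in spec")

    def region(self, name: str) -> RegionTemplate:
        for r in self.regions:
            if r.name == name:
                return r
        raise KeyError(name)

    def peak_growth_activity(self) -> float:
        """Largest value of beta * g'(age) over all regions and ages.

        The logistic derivative peaks at rate/4, so the peak activity of
        region r is beta_r * rate_r / 4.  Used to normalize the
        growth-front rim contrast to [0, 1].
        """
        return max((r.growth_coeff * r.growth_rate / 4.0 for r in self.regions),
                   default=1.0) or 1.0

    def growth_activity(self, name: str, age: float) -> float:
        """Normalized remodeling activity of a region at an age, in [0, 1]."""
        reg = self.region(name)
        raw = reg.growth_coeff * float(reg.growth_rate_of_change(age))
        return raw / self.peak_growth_activity()

    def validate_layout(self) -> None:
        """Raise if canonical footprints can overlap at zero jitter.

        Checks pairwise disjointness of the rasterized regions at both the
        base size and the maximal size each region can reach over ages and
        sexes plus a 4-sigma size-jitter allowance (size scaling is
        monotone, so the maximal footprint contains all intermediate ones
        for shapes scaled about their centroid).
        """
        margin = 1.0 + 4.0 * self.size_jitter_sd
        for scale_kind in ("base", "max"):
            stack = []
            for reg in self.regions:
                s = 1.0 if scale_kind == "base" else reg.max_size_scale() * margin
                stack.append(_rasterize(reg, s, self.canvas_side, (0.0, 0.0)))
            stack = np.array(stack)
            overlap = stack.sum(axis=0) > 1
            if overlap.any():
                pairs = [
                    (a.name, b.name)
                    for i, a in enumerate(self.regions)
                    for j, b in enumerate(self.regions)
                    if i < j and (stack[i] & stack[j]).any()
                ]
                raise ValueError(f"overlapping canonical footprints: {pairs}")


@dataclass(frozen=True)
class Subject:
    """One phantom subject: id, age in years, sex, acquisition orientation."""

    id: str
    age: float
    sex: str
    orientation: str = STANDARD

    def __post_init__(self):
        _check_age(self.age)
        if self.sex not in (MALE, FEMALE):
            raise ValueError(f"sex must be {MALE!r} or {FEMALE!r}")
        if self.orientation not in (STANDARD, MIRRORED):
            raise ValueError("orientation must be 'standard' or 'mirrored'")


def _rasterize(reg: RegionTemplate, scale: float, side: int,
               jitter_px: tuple[float, float]) -> np.ndarray:
    """Boolean footprint of a region scaled about its centroid, shifted by jitter."""
    dj = np.asarray(jitter_px, dtype=float)
    mask = np.zeros((side, side), dtype=bool)
    if reg.shape == "disk":
        r0, c0, rad = reg.params
        rr, cc = skdraw.disk((r0 * side + dj[0], c0 * side + dj[1]),
                             rad * side * scale, shape=(side, side))
    elif reg.shape == "ellipse":
        r0, c0, rr_rad, cc_rad = reg.params
        rr, cc = skdraw.ellipse(r0 * side + dj[0], c0 * side + dj[1],
                                rr_rad * side * scale, cc_rad * side * scale,
                                shape=(side, side))
    else:
        pts = np.asarray(reg.params, dtype=float) * side
        cen = pts.mean(axis=0)
        pts = cen + scale * (pts - cen) + dj
        rr, cc = skdraw.polygon(pts[:, 0], pts[:, 1], shape=(side, side))
    mask[rr, cc] = True
    return mask


def region_masks(spec: PhantomSpec, age: float, sex: str,
                 jitter_px: tuple[float, float] = (0.0, 0.0),
                 orientation: str = STANDARD) -> dict[str, np.ndarray]:
    """Ground-truth footprints of all six regions at (age, sex)."""
    _check_age(age)
    masks = {}
    for reg in spec.regions:
        m = _rasterize(reg, reg.size_scale(age, sex), spec.canvas_side, jitter_px)
        if orientation == MIRRORED:
            m = m[:, ::-1]
        masks[reg.name] = m
    return masks


def render_phantom(spec: PhantomSpec, subject: Subject, seed: int
                   ) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Render one phantom image plus its post-transform truth masks.

    Deterministic given ``(spec, subject, seed)``.  Returns a float32 image in
    [0, 1] of shape ``(canvas_side, canvas_side)`` and a dict mapping region
    name to its boolean footprint in the same (possibly mirrored) frame.
    """
    _check_age(subject.age)
    rng = np.random.default_rng(seed)
    side = spec.canvas_side
    px_scale = side / 128.0

    jitter = rng.normal(0.0, spec.jitter_sd * px_scale, size=2) if spec.jitter_sd > 0 \
        else np.zeros(2)
    gain = rng.uniform(*spec.intensity_gain_range)
    # subject-level biological variation: each region's size deviates
    # fractionally from its age norm, so a region whose growth schedule has
    # saturated carries almost no age information relative to this noise
    size_eps = (rng.normal(0.0, spec.size_jitter_sd, size=len(spec.regions))
                if spec.size_jitter_sd > 0 else np.zeros(len(spec.regions)))

    img = np.full((side, side), spec.background, dtype=np.float64)
    masks: dict[str, np.ndarray] = {}
    for reg, eps in zip(spec.regions, size_eps):
        m = _rasterize(reg,
                       reg.size_scale(subject.age, subject.sex) * (1.0 + eps),
                       side, (jitter[0], jitter[1]))
        # actively remodeling bone is denser: the fill brightness carries a
        # hump proportional to the normalized growth activity beta * g'(age);
        # male bone additionally densifies along the dimorphism schedule
        fill = (reg.base_intensity
                + spec.activity_boost * spec.growth_activity(reg.name,
                                                             subject.age))
        if subject.sex == MALE and reg.dimorphism_intensity > 0:
            fill += reg.dimorphism_intensity * float(
                reg.dimorphism_schedule(subject.age))
        img[m] = fill
        if spec.texture_amp > 0:
            # trabecular texture: band-limited noise whose correlation
            # length shrinks (spatial frequency rises) as the region
            # matures; optionally its contrast tracks the remodeling
            # activity when texture_baseline < 1
            g = float(reg.growth_schedule(subject.age))
            sigma = (spec.texture_sigma_hi
                     + (spec.texture_sigma_lo - spec.texture_sigma_hi) * g
                     ) * px_scale
            activity = spec.growth_activity(reg.name, subject.age)
            amp = spec.texture_amp * (spec.texture_baseline
                                      + (1.0 - spec.texture_baseline) * activity)
            white = rng.standard_normal((side, side))
            tex = ndimage.gaussian_filter(white, sigma)
            sd = tex.std()
            if sd > 0:
                img[m] += amp * tex[m] / sd
        if spec.growth_front_amp > 0:
            # remodeling rim: a bright band along the region boundary whose
            # contrast tracks the current growth activity beta * g'(age),
            # fading as the region matures (ossification-front analogue)
            width = max(1, round(spec.growth_front_width * side))
            rim = m & ~ndimage.binary_erosion(m, iterations=width)
            img[rim] += spec.growth_front_amp * spec.growth_activity(
                reg.name, subject.age)
        masks[reg.name] = m

    img *= gain
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=(side, side))
    img = np.clip(img, 0.0, 1.0).astype(np.float32)

    if subject.orientation == MIRRORED:
        img = img[:, ::-1].copy()
        masks = {k: v[:, ::-1].copy() for k, v in masks.items()}
    return img, masks


@dataclass
class Cohort:
    """An in-memory phantom cohort: metadata table plus rendered images.

    ``metadata`` columns: subject_id, age, sex, orientation, render_seed.
    ``images`` is float32 of shape (n, side, side), row-aligned with metadata.
    """

    spec: PhantomSpec
    metadata: pd.DataFrame
    images: np.ndarray

    def subject(self, idx: int) -> Subject:
        row = self.metadata.iloc[idx]
        return Subject(row.subject_id, float(row.age), row.sex, row.orientation)

    def truth_masks(self, idx: int) -> dict[str, np.ndarray]:
        row = self.metadata.iloc[idx]
        _, masks = render_phantom(self.spec, self.subject(idx), int(row.render_seed))
        return masks


def sample_cohort(spec: PhantomSpec, n: int, age_law="uniform",
                  sex_ratio: float = 0.5, seed: int = 0,
                  render_images: bool = True) -> Cohort:
    """Draw a cohort of ``n`` subjects and render their phantoms.

    ``age_law`` is ``"uniform"`` (uniform over [4, 19)) or a callable
    ``f(rng, n) -> ages``.  ``sex_ratio`` is the probability of *male* (the
    convention is recorded in the metadata column semantics: sex is the
    string label).  Ages are recorded to two decimals.  Orientation is
    mirrored with probability ``spec.flip_prob``.  Deterministic given seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if age_law == "uniform":
        ages = rng.uniform(AGE_MIN, AGE_MAX, size=n)
    elif callable(age_law):
        ages = np.asarray(age_law(rng, n), dtype=float)
    else:
        raise ValueError(f"unknown age_law {age_law!r}")
    ages = np.minimum(np.round(ages, 2), AGE_MAX - 0.01)
    sexes = np.where(rng.random(n) < sex_ratio, MALE, FEMALE)
    orients = np.where(rng.random(n) < spec.flip_prob, MIRRORED, STANDARD)
    render_seeds = rng.integers(0, 2**31 - 1, size=n)

    meta = pd.DataFrame({
        "subject_id": [f"S{seed:04d}_{i:05d}" for i in range(n)],
        "age": ages,
        "sex": sexes,
        "orientation": orients,
        "render_seed": render_seeds,
    })
    if render_images:
        side = spec.canvas_side
        images = np.empty((n, side, side), dtype=np.float32)
        for i in range(n):
            subj = Subject(meta.subject_id[i], float(ages[i]), sexes[i], orients[i])
            images[i], _ = render_phantom(spec, subj, int(render_seeds[i]))
    else:
        images = np.empty((0, spec.canvas_side, spec.canvas_side), dtype=np.float32)
    return Cohort(spec=spec, metadata=meta, images=images)


def planted_importance(spec: PhantomSpec, age: float) -> dict[str, float]:
    """Ground-truth regional importance for age prediction at ``age``.

    The score of region r is ``|beta_r * g_r'(age)|`` — the magnitude of the
    age-derivative of the planted size signal — normalized to sum to 1 when
    any score is positive.  Regions with beta = 0 score 0 at every age.
    """
    _check_age(age)
    scores = {r.name: abs(r.growth_coeff * float(r.growth_rate_of_change(age)))
              for r in spec.regions}
    total = sum(scores.values())
    if total > 0:
        scores = {k: v / total for k, v in scores.items()}
    return scores


@dataclass(frozen=True)
class AnnotatorJitter:
    """Perturbation law for simulated manual segmentations.

    Small random affine (translation in px at 128-px canvas, rotation in
    degrees, log-uniform-ish scale factor) plus morphological dilation or
    erosion of random integer radius up to ``morph_max``.
    """

    translate_sd: float = 1.5
    rotate_sd: float = 2.0
    scale_sd: float = 0.02
    morph_max: int = 1

    @property
    def is_zero(self) -> bool:
        return (self.translate_sd == 0 and self.rotate_sd == 0
                and self.scale_sd == 0 and self.morph_max == 0)


def _affine_mask(mask: np.ndarray, angle_deg: float, scale: float,
                 shift: np.ndarray) -> np.ndarray:
    """Rotate/scale a mask about its centroid, then translate. Nearest-neighbor."""
    if not mask.any():
        return mask.copy()
    cen = np.array(ndimage.center_of_mass(mask))
    th = math.radians(angle_deg)
    rot = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
    fwd = rot * scale
    inv = np.linalg.inv(fwd)
    # output coords y -> input coords: inv @ (y - cen - shift) + cen
    offset = cen - inv @ (cen + shift)
    out = ndimage.affine_transform(mask.astype(np.float32), inv, offset=offset,
                                   order=0, mode="constant", cval=0.0)
    return out > 0.5


def simulate_annotations(truth_masks: dict[str, np.ndarray], k: int = 20,
                         jitter: AnnotatorJitter = AnnotatorJitter(),
                         seed: int = 0, max_retries: int = 5
                         ) -> dict[str, np.ndarray]:
    """Simulate ``k`` annotator replicas of each truth mask.

    Returns a dict mapping region name to a boolean array of shape
    ``(k, H, W)``.  With zero jitter the replicas are exact copies.  A
    perturbation that empties a mask is redrawn up to ``max_retries`` times,
    then raises.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    out: dict[str, np.ndarray] = {}
    for name, truth in truth_masks.items():
        replicas = np.empty((k,) + truth.shape, dtype=bool)
        for i in range(k):
            if jitter.is_zero:
                replicas[i] = truth
                continue
            for attempt in range(max_retries + 1):
                angle = rng.normal(0.0, jitter.rotate_sd)
                scale = 1.0 + rng.normal(0.0, jitter.scale_sd)
                shift = rng.normal(0.0, jitter.translate_sd, size=2)
                rep = _affine_mask(truth, angle, max(scale, 0.1), shift)
                if jitter.morph_max > 0:
                    radius = int(rng.integers(-jitter.morph_max, jitter.morph_max + 1))
                    if radius > 0:
                        rep = skmorph.dilation(rep, skmorph.disk(radius))
                    elif radius < 0:
                        rep = skmorph.erosion(rep, skmorph.disk(-radius))
                if rep.any():
                    replicas[i] = rep
                    break
            else:
                raise RuntimeError(
                    f"annotator jitter emptied mask {name!r} after "
                    f"{max_retries} retries")
        out[name] = replicas
    return out


@dataclass
class RegionMaskSet:
    """ROI templates for one (age_bin, sex) group.

    ``truth`` holds the jitter-free canonical footprints rendered at the bin
    midpoint age; ``annotators`` holds k simulated manual replicas per
    region; ``consensus`` (filled by the regional module) the majority-vote
    masks.
    """

    group_key: tuple
    truth: dict[str, np.ndarray]
    annotators: dict[str, np.ndarray]
    consensus: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def k(self) -> int:
        first = next(iter(self.annotators.values()))
        return first.shape[0]


def build_maskset(spec: PhantomSpec, age_bin: int, sex: str, k: int = 20,
                  jitter: AnnotatorJitter = AnnotatorJitter(), seed: int = 0
                  ) -> RegionMaskSet:
    """Truth + simulated annotator masks for an (age_bin, sex) group.

    Templates are rendered at the bin midpoint (age_bin + 0.5), standard
    orientation, zero jitter — the phantom analogue of the per-group
    consensus templates segmented on representative radiographs.
    """
    truth = region_masks(spec, age_bin + 0.5, sex)
    annot = simulate_annotations(truth, k=k, jitter=jitter, seed=seed)
    return RegionMaskSet(group_key=(age_bin, sex), truth=truth, annotators=annot)
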