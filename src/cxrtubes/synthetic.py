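"""Synthetic radiograph-shaped fixtures with known ground truth.

Nothing here attempts photorealism: the generator emulates exactly the
inputs the assessment pipeline consumes — anatomical landmark coordinates,
rasterized per-class tube masks, multilabel classifier scores and noisy
"reader" annotations — on a cohort whose tube presence and category mixture
mirror an ICU case series (about 6 in 10 films intubated, half with a
central line, category frequencies dominated by Normal positions).

Geometry is drawn *inversely* from the rule table: a requested category
fixes the admissible band of tip-to-landmark distances and the tip is
sampled inside it with a safety margin of a few mm, so that rasterization
and skeletonization noise (sub-millimetre for tips, a few percent for arc
lengths) cannot flip the category.  The full loop
generate -> rasterize -> extract -> classify therefore recovers the
requested category, which is what the round-trip tests check.

Scores follow a binormal model: the true label's latent score is
Normal(mu, 1) with mu = sqrt(2) * Phi^-1(target_auc), competitors are
Normal(0, 1), and both are squashed to [0, 1] by a logistic; the squash is
monotone so the one-vs-rest AUC equals the target by construction.

Randomness: one global seed; each image uses an independent substream keyed
by (seed, image index), so changing the cohort size does not perturb the
images already generated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import binary_dilation
from scipy.stats import norm

from .geometry import ImageMeta, LandmarkSet, Point
from .masks import MaskChannelSet
from .rules import LABELS, ClassScores

# category vocabularies per tube; "SwanGanz" marks a Swan-Ganz catheter,
# whose position grade is Normal by convention
ETT_CATEGORIES = ("Normal", "Borderline", "Abnormal")
CVC_CATEGORIES = ("Normal", "Borderline", "Abnormal", "SwanGanz")
NGT_CATEGORIES = ("Normal", "Borderline", "Abnormal", "IncompletelyImaged")


@dataclass(frozen=True)
class SimConfig:
    """Cohort-level knobs of the generator.

    Defaults mirror a 303-film ICU series: ETT present on 178 films with
    category counts 140/33/5, CVC on 148 with 98/27/12 plus 11 Swan-Ganz,
    NGT on 39 with 20/4/2/13, and ECG leads on 151.  Images are 640x640 at
    0.6 mm/pixel (38 cm field of view, a plausible portable chest film).
    """

    n_images: int = 303
    image_size: Tuple[int, int] = (640, 640)  # (width, height)
    spacing_mm: float = 0.6
    ett_presence: float = 178 / 303
    cvc_presence: float = 148 / 303
    ngt_presence: float = 39 / 303
    ett_mixture: Tuple[float, ...] = (140 / 178, 33 / 178, 5 / 178)
    cvc_mixture: Tuple[float, ...] = (98 / 148, 27 / 148, 12 / 148, 11 / 148)
    ngt_mixture: Tuple[float, ...] = (20 / 39, 4 / 39, 2 / 39, 13 / 39)
    ecg_fraction: float = 151 / 303
    target_auc: float = 0.7
    landmark_noise_sd_mm: float = 3.0
    line_thickness_px: int = 3
    tip_radius_px: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        for name, mix in (
            ("ett_mixture", self.ett_mixture),
            ("cvc_mixture", self.cvc_mixture),
            ("ngt_mixture", self.ngt_mixture),
        ):
            if abs(sum(mix) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
        if not (0.5 < self.target_auc < 1.0):
            raise ValueError("target_auc must lie in (0.5, 1)")
        if self.landmark_noise_sd_mm < 0:
            raise ValueError("landmark_noise_sd_mm must be >= 0")
        w, h = self.image_size
        if w < 256 or h < 256:
            raise ValueError(
                "image too small to honor anatomical placement bands"
            )

    def meta(self, image_id: str = "") -> ImageMeta:
        w, h = self.image_size
        return ImageMeta(width=w, height=h, spacing_row=self.spacing_mm,
                         spacing_col=self.spacing_mm, image_id=image_id)


@dataclass
class SyntheticImage:
    """One generated case: channels, landmarks, scores and its ground truth."""

    image_id: str
    meta: ImageMeta
    landmarks: LandmarkSet
    masks: MaskChannelSet
    scores: ClassScores
    truth: Dict[str, Optional[str]]  # tube kind -> category, None if absent
    ecg: bool


def image_rng(seed: int, index: int) -> np.random.Generator:
    """Counter-based per-image substream."""
    return np.random.default_rng([seed, index])


# ---------------------------------------------------------------------------
# anatomy


def sample_anatomy(cfg: SimConfig, rng: np.random.Generator) -> LandmarkSet:
    """Plausible landmark geometry.

    The carina sits in a central band of the upper chest; the cavoatrial
    junction lies below and to the (image-) right of it by a jittered
    offset; the gastro-esophageal junction sits in the lower third, left of
    midline.  All points are strictly in-bounds.
    """
    w, h = cfg.image_size
    sp = cfg.spacing_mm
    carina = Point(
        x=float(rng.uniform(0.45 * w, 0.55 * w)),
        y=float(rng.uniform(0.30 * h, 0.38 * h)),
    )
    caj = Point(
        x=carina.x + rng.uniform(15.0, 30.0) / sp,
        y=carina.y + rng.uniform(25.0, 45.0) / sp,
    )
    gej = Point(
        x=float(rng.uniform(0.40 * w, 0.50 * w)),
        y=float(rng.uniform(0.58 * h, 0.62 * h)),
    )
    lm = LandmarkSet(carina=carina, cavoatrial_junction=caj, ge_junction=gej)
    for p in (carina, caj, gej):
        if not (0 <= p.x < w and 0 <= p.y < h):
            raise ValueError("image too small: landmark fell out of bounds")
    return lm


# ---------------------------------------------------------------------------
# tube geometry


def _bezier(p0, p1, p2, n: int = 200) -> np.ndarray:
    """Quadratic Bezier sampled densely, as an (n, 2) array of (x, y)."""
    t = np.linspace(0.0, 1.0, n)[:, None]
    p0, p1, p2 = (np.asarray(p, dtype=float) for p in (p0, p1, p2))
    return (1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t**2 * p2


def _curved_walk(
    start: Tuple[float, float],
    arc_mm: float,
    spacing: float,
    heading_deg: float,
    curvature_deg_per_cm: float,
    bounds: Tuple[int, int],
) -> np.ndarray:
    """Constant-curvature walk of a given arc length (used for the
    intragastric part of an NGT).  Heading 0 points straight down."""
    w, h = bounds
    step_px = 1.0
    n = max(2, int(math.ceil(arc_mm / (step_px * spacing))))
    pts = [np.asarray(start, dtype=float)]
    phi = math.radians(heading_deg)
    dphi = math.radians(curvature_deg_per_cm) * step_px * spacing / 10.0
    for _ in range(n):
        d = np.array([math.sin(phi), math.cos(phi)])  # (dx, dy), down = +y
        nxt = pts[-1] + step_px * d
        nxt[0] = min(max(nxt[0], 2.0), w - 3.0)
        nxt[1] = min(max(nxt[1], 2.0), h - 3.0)
        pts.append(nxt)
        phi += dphi
    return np.asarray(pts)


def sample_tube(
    tube_kind: str,
    category: str,
    landmarks: LandmarkSet,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> Tuple[np.ndarray, Optional[Point]]:
    """Draw a tube polyline and tip realizing the requested category.

    Distances are sampled inside the category's admissible band with margins
    of a few mm so the rasterize/extract round trip is category-stable.
    Returns ``(polyline (n, 2) of (x, y), tip)``; the tip is ``None`` for an
    incompletely imaged NGT (it lies off the film).
    """
    w, h = cfg.image_size
    sp = cfg.spacing_mm

    if tube_kind == "ETT":
        carina = landmarks.carina
        if carina is None:
            raise ValueError("ETT generation requires a carina landmark")
        if category == "Normal":
            d = rng.uniform(37.0, 68.0)
        elif category == "Borderline":
            d = (rng.uniform(5.0, 33.0) if rng.random() < 0.5
                 else rng.uniform(72.0, 105.0))
        elif category == "Abnormal":
            d = rng.uniform(-30.0, -2.0)
        else:
            raise ValueError(f"impossible ETT category {category!r}")
        tip = Point(x=carina.x + rng.uniform(-3, 3), y=carina.y - d / sp)
        entry = (tip.x + rng.uniform(-10, 10), 0.0)
        mid = (tip.x + rng.uniform(-8, 8), tip.y * 0.5)
        poly = _bezier(entry, mid, (tip.x, tip.y))
        return poly, tip

    if tube_kind == "CVC":
        caj = landmarks.cavoatrial_junction
        if caj is None:
            raise ValueError("CVC generation requires a cavoatrial junction")
        if category == "Normal":
            d = rng.uniform(5.0, 40.0)
        elif category == "Borderline":
            d = rng.uniform(-23.0, -3.0)
        elif category == "Abnormal":
            d = rng.uniform(-60.0, -28.0)
        elif category == "SwanGanz":
            d = rng.uniform(-20.0, 30.0)
        else:
            raise ValueError(f"impossible CVC category {category!r}")
        tip = Point(x=caj.x + rng.uniform(-5, 5), y=caj.y - d / sp)
        side = 0.0 if rng.random() < 0.5 else float(w - 1)
        entry = (side, rng.uniform(0.08 * h, 0.18 * h))
        mid = ((entry[0] + tip.x) / 2.0, entry[1])
        poly = _bezier(entry, mid, (tip.x, tip.y))
        return poly, tip

    if tube_kind == "NGT":
        gej = landmarks.ge_junction
        if category == "IncompletelyImaged":
            # only a short distal-less stub is on the film, exiting below
            length = rng.uniform(40.0, 80.0)
            x0 = rng.uniform(0.35 * w, 0.55 * w)
            poly = _curved_walk(
                (x0, float(h - 1)), length, sp, heading_deg=180.0 +
                rng.uniform(-15, 15), curvature_deg_per_cm=rng.uniform(-3, 3),
                bounds=(w, h),
            )
            return poly, None
        if gej is None:
            raise ValueError(f"NGT {category} requires a GE junction")
        entry = (gej.x + rng.uniform(-10, 10), 0.0)
        if category == "Abnormal":
            # tip above the GE junction (esophageal placement)
            carina_y = landmarks.carina.y if landmarks.carina else 0.35 * h
            d_above = rng.uniform(15.0, 80.0)
            tip_y = max(gej.y - d_above / sp, carina_y + 15.0)
            tip = Point(x=gej.x + rng.uniform(-4, 4), y=tip_y)
            mid = (entry[0] + rng.uniform(-8, 8), tip.y * 0.5)
            poly = _bezier(entry, mid, (tip.x, tip.y))
            return poly, tip
        if category == "Normal":
            d_beyond = rng.uniform(115.0, 135.0)
        elif category == "Borderline":
            d_beyond = rng.uniform(10.0, 85.0)
        else:
            raise ValueError(f"impossible NGT category {category!r}")
        near_gej = (gej.x + rng.uniform(-2, 2), gej.y + rng.uniform(-2, 2))
        mid = (entry[0] + rng.uniform(-8, 8), gej.y * 0.5)
        upper = _bezier(entry, mid, near_gej)
        lower = _curved_walk(
            near_gej, d_beyond, sp,
            heading_deg=rng.uniform(-10, 10),
            curvature_deg_per_cm=rng.uniform(1.0, 3.0),
            bounds=(w, h),
        )
        poly = np.vstack([upper, lower[1:]])
        tip = Point(x=float(lower[-1, 0]), y=float(lower[-1, 1]))
        return poly, tip

    raise ValueError(f"unknown tube kind {tube_kind!r}")


# ---------------------------------------------------------------------------
# rasterization


def _draw_polyline(canvas: np.ndarray, poly: np.ndarray) -> None:
    """Set every pixel along a densely sampled polyline."""
    h, w = canvas.shape
    # densify so consecutive points are <= 1 px apart
    segs = np.diff(poly, axis=0)
    steps = np.maximum(np.abs(segs).max(axis=1), 1.0)
    pts = [poly[:1]]
    for i, n in enumerate(np.ceil(steps).astype(int)):
        t = np.linspace(0, 1, n + 1)[1:, None]
        pts.append(poly[i] + t * segs[i])
    dense = np.vstack(pts)
    xs = np.clip(np.round(dense[:, 0]).astype(int), 0, w - 1)
    ys = np.clip(np.round(dense[:, 1]).astype(int), 0, h - 1)
    canvas[ys, xs] = True


def _disk(radius: int) -> np.ndarray:
    r = int(radius)
    yy, xx = np.mgrid[-r: r + 1, -r: r + 1]
    return (xx * xx + yy * yy) <= r * r


def rasterize_line(
    poly: np.ndarray, image_size: Tuple[int, int], thickness_px: int = 3
) -> np.ndarray:
    """Binary line channel: the polyline dilated to the given thickness."""
    w, h = image_size
    canvas = np.zeros((h, w), dtype=bool)
    _draw_polyline(canvas, np.asarray(poly, dtype=float))
    if thickness_px > 1:
        canvas = binary_dilation(canvas, structure=_disk(thickness_px // 2))
    return canvas


def rasterize_tip(
    tip: Point, image_size: Tuple[int, int], radius_px: int = 4
) -> np.ndarray:
    """Binary tip channel: a disc centred on the tip."""
    w, h = image_size
    canvas = np.zeros((h, w), dtype=bool)
    cx, cy = int(round(tip.x)), int(round(tip.y))
    r = int(radius_px)
    yy, xx = np.mgrid[-r: r + 1, -r: r + 1]
    sel = yy * yy + xx * xx <= r * r
    ys, xs = yy[sel] + cy, xx[sel] + cx
    ok = (ys >= 0) & (ys < h) & (xs >= 0) & (xs < w)
    canvas[ys[ok], xs[ok]] = True
    return canvas


# ---------------------------------------------------------------------------
# scores and reader noise


def binormal_mu(target_auc: float) -> float:
    """Latent-mean separation giving the requested binormal AUC."""
    return math.sqrt(2.0) * float(norm.ppf(target_auc))


def sample_scores(
    positive_labels: Sequence[str],
    target_auc: float,
    rng: np.random.Generator,
) -> ClassScores:
    """Binormal multilabel scores: positives Normal(mu, 1), the rest
    Normal(0, 1), logistic-squashed into [0, 1]."""
    mu = binormal_mu(target_auc)
    pos = set(positive_labels)
    unknown = pos - set(LABELS)
    if unknown:
        raise ValueError(f"unknown labels: {sorted(unknown)}")
    z = rng.normal(0.0, 1.0, size=len(LABELS))
    scores = {}
    for i, lb in enumerate(LABELS):
        latent = z[i] + (mu if lb in pos else 0.0)
        scores[lb] = 1.0 / (1.0 + math.exp(-latent))
    return ClassScores(scores)


def positive_labels_for(truth: Mapping[str, Optional[str]]) -> List[str]:
    """Ground-truth binary labels implied by per-tube categories."""
    pos: List[str] = []
    for tube, cat in truth.items():
        if cat is None:
            continue
        if tube == "CVC" and cat == "SwanGanz":
            pos += ["SwanGanzPresent", "CVC_Normal"]
        else:
            pos.append(f"{tube}_{cat}")
    return pos


def corrupt_landmarks(
    landmarks: LandmarkSet,
    sd_mm: float,
    rng: np.random.Generator,
    meta: ImageMeta,
) -> LandmarkSet:
    """Simulated reader: isotropic Gaussian displacement of each landmark,
    sd_mm per axis, clipped in-bounds."""
    def jitter(p: Optional[Point]) -> Optional[Point]:
        if p is None:
            return None
        nx = p.x + rng.normal(0.0, sd_mm) / meta.spacing_col
        ny = p.y + rng.normal(0.0, sd_mm) / meta.spacing_row
        return Point(
            x=float(min(max(nx, 0.0), meta.width - 1)),
            y=float(min(max(ny, 0.0), meta.height - 1)),
        )

    return LandmarkSet(
        carina=jitter(landmarks.carina),
        cavoatrial_junction=jitter(landmarks.cavoatrial_junction),
        ge_junction=jitter(landmarks.ge_junction),
        t1_level_y=landmarks.t1_level_y,
        aortic_arch_upper_y=landmarks.aortic_arch_upper_y,
    )


# ---------------------------------------------------------------------------
# cohort generation


def _sample_category(
    rng: np.random.Generator, categories: Sequence[str], mixture: Sequence[float]
) -> str:
    return categories[int(rng.choice(len(categories), p=mixture))]


def generate_image(cfg: SimConfig, index: int) -> SyntheticImage:
    """Generate one case from its (seed, index) substream."""
    rng = image_rng(cfg.seed, index)
    image_id = f"synth-{index:04d}"
    meta = cfg.meta(image_id)
    landmarks = sample_anatomy(cfg, rng)
    w, h = cfg.image_size

    truth: Dict[str, Optional[str]] = {"ETT": None, "CVC": None, "NGT": None}
    ngt_line = np.zeros((h, w), dtype=bool)
    cvc_line = np.zeros((h, w), dtype=bool)
    cvc_tip = np.zeros((h, w), dtype=bool)
    ett_tip = np.zeros((h, w), dtype=bool)

    if rng.random() < cfg.ett_presence:
        cat = _sample_category(rng, ETT_CATEGORIES, cfg.ett_mixture)
        truth["ETT"] = cat
        _, tip = sample_tube("ETT", cat, landmarks, cfg, rng)
        ett_tip = rasterize_tip(tip, cfg.image_size, cfg.tip_radius_px)
    if rng.random() < cfg.cvc_presence:
        cat = _sample_category(rng, CVC_CATEGORIES, cfg.cvc_mixture)
        truth["CVC"] = cat
        poly, tip = sample_tube("CVC", cat, landmarks, cfg, rng)
        cvc_line = rasterize_line(poly, cfg.image_size, cfg.line_thickness_px)
        cvc_tip = rasterize_tip(tip, cfg.image_size, cfg.tip_radius_px)
    if rng.random() < cfg.ngt_presence:
        cat = _sample_category(rng, NGT_CATEGORIES, cfg.ngt_mixture)
        truth["NGT"] = cat
        poly, _ = sample_tube("NGT", cat, landmarks, cfg, rng)
        ngt_line = rasterize_line(poly, cfg.image_size, cfg.line_thickness_px)

    scores = sample_scores(positive_labels_for(truth), cfg.target_auc, rng)
    ecg = bool(rng.random() < cfg.ecg_fraction)
    masks = MaskChannelSet(
        ngt_line=ngt_line, cvc_line=cvc_line, cvc_tip=cvc_tip,
        ett_tip=ett_tip, meta=meta,
    )
    return SyntheticImage(
        image_id=image_id, meta=meta, landmarks=landmarks, masks=masks,
        scores=scores, truth=truth, ecg=ecg,
    )


def generate_dataset(cfg: SimConfig) -> List[SyntheticImage]:
    return [generate_image(cfg, i) for i in range(cfg.n_images)]
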