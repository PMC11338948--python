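"""Distance-based position rules for tubes and lines, and score correction.

The RANZCR-CLiP scheme grades each tube on a chest radiograph as Normal,
Borderline or Abnormal (plus Incompletely-Imaged for nasogastric tubes) from
the position of its tip relative to reference anatomy:

* **ETT** — tip 3.5–7 cm above the carina is Normal; closer or farther is
  Borderline; at/below the carina (or at T1 level or above) is Abnormal.
  The radiograph-reading surrogate "two posterior ribs" is taken at its
  stated 3.5 cm value.
* **NGT** — tip at least 10 cm beyond the gastro-esophageal junction is
  Normal; beyond but closer is Borderline; above the junction is Abnormal;
  tip off-film with under 10 cm of visible tube is Incompletely Imaged.
* **CVC** — tip above the cavoatrial junction is Normal; below it but within
  the upper third of the right atrium is Borderline; lower is Abnormal.
  Swan-Ganz catheters are Normal by convention.

These geometric categories are then used to *upgrade* the scores of an
upstream multilabel classifier: when geometry says the position is worse
than the classifier's top pick, the two implicated label scores are swapped.
Swapping preserves ranking semantics, keeps scores a permutation of the
input within the tube group, and is idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Set, Tuple

# ---------------------------------------------------------------------------
# labels and categories

LABELS: Tuple[str, ...] = (
    "ETT_Normal",
    "ETT_Borderline",
    "ETT_Abnormal",
    "NGT_Normal",
    "NGT_Borderline",
    "NGT_Abnormal",
    "NGT_IncompletelyImaged",
    "CVC_Normal",
    "CVC_Borderline",
    "CVC_Abnormal",
    "SwanGanzPresent",
)

TUBE_GROUPS: Dict[str, Tuple[str, ...]] = {
    "ETT": ("ETT_Normal", "ETT_Borderline", "ETT_Abnormal"),
    "NGT": (
        "NGT_Normal",
        "NGT_Borderline",
        "NGT_Abnormal",
        "NGT_IncompletelyImaged",
    ),
    "CVC": ("CVC_Normal", "CVC_Borderline", "CVC_Abnormal"),
}

CATEGORIES = ("Normal", "Borderline", "Abnormal", "IncompletelyImaged",
              "Indeterminate")

# severity ordering used by the upgrade rule; categories outside this map
# (Indeterminate, IncompletelyImaged) never participate in upgrades
_RANK = {"Normal": 0, "Borderline": 1, "Abnormal": 2}

ALL_RULES: frozenset = frozenset(
    {
        "ETT_BELOW_CARINA",
        "ETT_T1_HIGH",
        "ETT_LOW",
        "ETT_HIGH",
        "NGT_INCOMPLETE",
        "NGT_ABOVE_GEJ",
        "NGT_SHORT",
        "CVC_ABOVE_ARCH",
        "CVC_BELOW_CAJ",
        "CVC_BELOW_RA_THIRD",
        "SWAN_GANZ_NORMAL",
    }
)


@dataclass(frozen=True)
class RuleConfig:
    """Thresholds and switches of the rule table.

    Distances are millimetres.  ``ett_min_mm``/``ett_max_mm`` bound the
    Normal ETT band above the carina (3.5 cm = "two posterior ribs", 7 cm =
    twice that).  ``ngt_min_mm`` is the 10 cm ("four posterior ribs")
    beyond-junction requirement.  ``ra_upper_third_mm`` approximates the
    height of the upper third of the right atrium below the cavoatrial
    junction; no landmark for it exists in the data model, so this is an
    engineering stand-in, configurable and defaulting to 25 mm.
    """

    ett_min_mm: float = 35.0
    ett_max_mm: float = 70.0
    ngt_min_mm: float = 100.0
    ra_upper_third_mm: float = 25.0
    distance_mode: str = "vertical"  # "vertical" | "euclidean"
    boundary_inclusive_normal: bool = True
    swan_ganz_score_threshold: float = 0.9
    enabled_rules: frozenset = ALL_RULES

    def __post_init__(self) -> None:
        if not (0 < self.ett_min_mm < self.ett_max_mm):
            raise ValueError("require 0 < ett_min_mm < ett_max_mm")
        if self.ngt_min_mm <= 0 or self.ra_upper_third_mm <= 0:
            raise ValueError("ngt_min_mm and ra_upper_third_mm must be > 0")
        if self.distance_mode not in ("vertical", "euclidean"):
            raise ValueError(f"unknown distance_mode {self.distance_mode!r}")
        unknown = set(self.enabled_rules) - ALL_RULES
        if unknown:
            raise ValueError(f"unknown rule identifiers: {sorted(unknown)}")
        object.__setattr__(self, "enabled_rules",
                           frozenset(self.enabled_rules))


@dataclass
class ClassScores:
    """The 11 per-label classifier scores of one radiograph.

    Multilabel: each score lies in [0, 1] independently; there is no
    sum-to-one constraint.
    """

    scores: Dict[str, float]

    def __post_init__(self) -> None:
        missing = set(LABELS) - set(self.scores)
        extra = set(self.scores) - set(LABELS)
        if missing or extra:
            raise ValueError(
                f"scores must cover exactly the 11 labels; "
                f"missing={sorted(missing)} extra={sorted(extra)}"
            )
        for k, v in self.scores.items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"score {k}={v} outside [0, 1]")

    def __getitem__(self, label: str) -> float:
        return self.scores[label]

    def copy(self) -> "ClassScores":
        return ClassScores(dict(self.scores))

    def as_dict(self) -> Dict[str, float]:
        return dict(self.scores)

    def group_argmax(self, tube_kind: str) -> str:
        labels = TUBE_GROUPS[tube_kind]
        return max(labels, key=lambda lb: (self.scores[lb], -labels.index(lb)))


@dataclass
class GeometricAssessment:
    """Outcome of the rule table for one tube: category plus matched rules."""

    category: str
    matched_rules: Tuple[str, ...] = ()


@dataclass
class RuleDecision:
    """Final record for one tube on one radiograph."""

    tube_kind: str
    geometric_category: str
    fired_rules: List[str]
    d_vertical_mm: Optional[float]
    d_euclidean_mm: Optional[float]
    adjusted_scores: Optional[ClassScores]
    final_label: Optional[str]
    d_beyond_mm: Optional[float] = None


# ---------------------------------------------------------------------------
# the rule table


def assess_ett(
    d_mm: Optional[float],
    t1_above: Optional[bool],
    cfg: RuleConfig,
) -> GeometricAssessment:
    """Grade an endotracheal tube from its signed height above the carina.

    ``d_mm`` is positive when the tip is above (cranial to) the carina;
    ``None`` means the carina landmark is absent, which yields Indeterminate
    rather than a guess.  ``t1_above`` is only evaluated when supplied.
    """
    if d_mm is None:
        return GeometricAssessment("Indeterminate")
    if t1_above:
        return GeometricAssessment("Abnormal", ("ETT_T1_HIGH",))
    if d_mm <= 0:
        return GeometricAssessment("Abnormal", ("ETT_BELOW_CARINA",))
    lo, hi = cfg.ett_min_mm, cfg.ett_max_mm
    if cfg.boundary_inclusive_normal:
        if d_mm < lo:
            return GeometricAssessment("Borderline", ("ETT_LOW",))
        if d_mm > hi:
            return GeometricAssessment("Borderline", ("ETT_HIGH",))
    else:
        if d_mm <= lo:
            return GeometricAssessment("Borderline", ("ETT_LOW",))
        if d_mm >= hi:
            return GeometricAssessment("Borderline", ("ETT_HIGH",))
    return GeometricAssessment("Normal")


def assess_ngt(
    d_beyond_mm: Optional[float],
    above_gej: Optional[bool],
    incomplete: bool,
    visible_len_mm: float,
    cfg: RuleConfig,
) -> GeometricAssessment:
    """Grade a nasogastric tube.

    ``d_beyond_mm`` is the arc length of tube past the gastro-esophageal
    junction.  The incompletely-imaged clause fires first: a tube running
    off the film with under ``ngt_min_mm`` of visible length cannot be
    graded.  Absent junction landmark yields Indeterminate.
    """
    if incomplete and visible_len_mm < cfg.ngt_min_mm:
        return GeometricAssessment("IncompletelyImaged", ("NGT_INCOMPLETE",))
    if above_gej is None or d_beyond_mm is None:
        return GeometricAssessment("Indeterminate")
    if above_gej:
        return GeometricAssessment("Abnormal", ("NGT_ABOVE_GEJ",))
    if d_beyond_mm >= cfg.ngt_min_mm:
        return GeometricAssessment("Normal")
    return GeometricAssessment("Borderline", ("NGT_SHORT",))


def assess_cvc(
    d_mm: Optional[float],
    below_arch: Optional[bool],
    swan_ganz: bool,
    cfg: RuleConfig,
) -> GeometricAssessment:
    """Grade a central venous catheter from its signed height above the
    cavoatrial junction.

    Swan-Ganz catheters are Normal by convention.  Only the tip-position
    component is evaluated: the 45-degree vessel-wall-angle, coil/kink and
    aberrant-vessel clauses need vessel anatomy beyond this data model.
    ``below_arch`` is evaluated only when the aortic-arch landmark was
    supplied; a tip above the arch is proximal to the SVC, hence Borderline.
    """
    if swan_ganz:
        return GeometricAssessment("Normal", ("SWAN_GANZ_NORMAL",))
    if d_mm is None:
        return GeometricAssessment("Indeterminate")
    if d_mm >= 0:
        if below_arch is False:
            return GeometricAssessment("Borderline", ("CVC_ABOVE_ARCH",))
        return GeometricAssessment("Normal")
    if d_mm >= -cfg.ra_upper_third_mm:
        return GeometricAssessment("Borderline", ("CVC_BELOW_CAJ",))
    return GeometricAssessment("Abnormal", ("CVC_BELOW_RA_THIRD",))


def classify_ett(d_mm, t1_above, cfg: RuleConfig) -> str:
    return assess_ett(d_mm, t1_above, cfg).category


def classify_ngt(d_beyond_mm, above_gej, incomplete, visible_len_mm,
                 cfg: RuleConfig) -> str:
    return assess_ngt(d_beyond_mm, above_gej, incomplete, visible_len_mm,
                      cfg).category


def classify_cvc(d_mm, below_arch, swan_ganz, cfg: RuleConfig) -> str:
    return assess_cvc(d_mm, below_arch, swan_ganz, cfg).category


# ---------------------------------------------------------------------------
# score correction


def _upgrade_group(
    scores: Dict[str, float],
    tube_kind: str,
    assessment: GeometricAssessment,
    cfg: RuleConfig,
) -> Tuple[Dict[str, float], List[str]]:
    """Swap the argmax label's score with the geometric category's label
    score when geometry is strictly worse.  Returns (scores, fired rules)."""
    enabled = [r for r in assessment.matched_rules if r in cfg.enabled_rules]
    cat = assessment.category
    if cat not in _RANK:
        # Indeterminate / IncompletelyImaged: never adjust
        return scores, enabled
    if assessment.matched_rules and not enabled:
        # the clause that produced this category is switched off
        return scores, []
    labels = TUBE_GROUPS[tube_kind]
    argmax = max(labels, key=lambda lb: (scores[lb], -labels.index(lb)))
    argmax_cat = argmax.split("_", 1)[1]
    if argmax_cat not in _RANK:
        return scores, enabled
    if _RANK[cat] <= _RANK[argmax_cat]:
        # geometry no worse than the classifier: never downgrade
        return scores, enabled
    target = f"{tube_kind}_{cat}"
    out = dict(scores)
    out[argmax], out[target] = out[target], out[argmax]
    return out, enabled


def apply_rules(
    scores: ClassScores,
    assessments: Mapping[str, GeometricAssessment],
    cfg: RuleConfig,
    distances: Optional[Mapping[str, Mapping[str, Optional[float]]]] = None,
) -> Tuple[ClassScores, Dict[str, RuleDecision]]:
    """Rule-based correction of classifier scores.

    For each tube whose geometric category is strictly worse than the
    classifier's current top label (Normal < Borderline < Abnormal) the two
    implicated scores are swapped — an upgrade, never a downgrade.
    Indeterminate and IncompletelyImaged assessments leave scores untouched.
    ``distances`` optionally carries per-tube ``d_vertical_mm`` /
    ``d_euclidean_mm`` / ``d_beyond_mm`` for the decision records.
    """
    adjusted = scores.as_dict()
    decisions: Dict[str, RuleDecision] = {}
    for tube_kind, assessment in assessments.items():
        if tube_kind not in TUBE_GROUPS:
            raise ValueError(f"unknown tube kind {tube_kind!r}")
        adjusted, fired = _upgrade_group(adjusted, tube_kind, assessment, cfg)
        d = (distances or {}).get(tube_kind, {})
        decisions[tube_kind] = RuleDecision(
            tube_kind=tube_kind,
            geometric_category=assessment.category,
            fired_rules=fired,
            d_vertical_mm=d.get("d_vertical_mm"),
            d_euclidean_mm=d.get("d_euclidean_mm"),
            d_beyond_mm=d.get("d_beyond_mm"),
            adjusted_scores=None,  # filled below, shared object
            final_label=None,
        )
    final_scores = ClassScores(adjusted)
    for tube_kind, dec in decisions.items():
        dec.adjusted_scores = final_scores
        dec.final_label = final_scores.group_argmax(tube_kind)
    return final_scores, decisions
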