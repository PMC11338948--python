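"""End-to-end assessment of one radiograph: masks + landmarks + scores
-> geometric categories, distances and rule-corrected scores.

This is the deterministic post-processing stage that sits after the
segmentation and classification networks: tips are extracted from the
per-class mask channels by connected-component analysis, metric distances to
the reference anatomy are computed from the pixel spacing, the rule table
grades each tube, and classifier scores are upgraded accordingly.
"""

from __future__ import annotations

import logging
import math
from typing import Dict, Optional, Tuple

from .geometry import LandmarkSet, Point, euclidean_distance_mm, vertical_separation_mm
from .masks import (
    MaskChannelSet,
    arc_length_beyond_mm,
    find_components,
    is_incompletely_imaged,
    ngt_tip_from_line,
    select_tip,
    visible_line_length_mm,
)
from .rules import (
    ClassScores,
    GeometricAssessment,
    RuleConfig,
    RuleDecision,
    apply_rules,
    assess_cvc,
    assess_ett,
    assess_ngt,
)

logger = logging.getLogger(__name__)


def _signed_rule_distance(
    tip: Point, landmark: Point, meta, cfg: RuleConfig
) -> Tuple[float, float, float]:
    """(d_vertical, d_euclidean, d_for_rules) in mm.

    Rules default to the cranio-caudal (vertical) separation because the
    criteria are phrased as above/below; in euclidean mode the straight-line
    distance is used with the sign carried over from the vertical component.
    """
    d_vert = vertical_separation_mm(tip, landmark, meta)
    d_euc = euclidean_distance_mm(tip, landmark, meta)
    if cfg.distance_mode == "euclidean":
        d_rule = math.copysign(d_euc, d_vert) if d_vert != 0 else 0.0
    else:
        d_rule = d_vert
    return d_vert, d_euc, d_rule


def assess_radiograph(
    masks: MaskChannelSet,
    landmarks: LandmarkSet,
    scores: ClassScores,
    cfg: Optional[RuleConfig] = None,
    swan_ganz: Optional[bool] = None,
) -> Tuple[ClassScores, Dict[str, RuleDecision]]:
    """Run the full post-network pipeline on one radiograph.

    Tubes whose channels are empty are treated as not present and get no
    decision.  Tubes whose reference landmark is missing are graded
    Indeterminate and their scores are left unchanged.  ``swan_ganz``
    overrides the Swan-Ganz presence flag; by default it is derived from
    the ``SwanGanzPresent`` score, firing only above a confident threshold
    (``cfg.swan_ganz_score_threshold``) because the override suppresses the
    position rules entirely.
    """
    cfg = cfg or RuleConfig()
    meta = masks.meta
    assessments: Dict[str, GeometricAssessment] = {}
    distances: Dict[str, Dict[str, Optional[float]]] = {}

    # --- ETT: tip channel vs carina -------------------------------------
    ett_tip = select_tip(find_components(masks.ett_tip), "ETT", meta,
                         reference=landmarks.carina)
    if ett_tip is not None:
        if landmarks.carina is None:
            assessments["ETT"] = assess_ett(None, None, cfg)
            distances["ETT"] = {}
        else:
            d_vert, d_euc, d_rule = _signed_rule_distance(
                ett_tip.tip, landmarks.carina, meta, cfg)
            t1_above = (
                ett_tip.tip.y <= landmarks.t1_level_y
                if landmarks.t1_level_y is not None else None
            )
            assessments["ETT"] = assess_ett(d_rule, t1_above, cfg)
            distances["ETT"] = {"d_vertical_mm": d_vert,
                                "d_euclidean_mm": d_euc}

    # --- CVC: tip channel vs cavoatrial junction ------------------------
    cvc_tip = select_tip(find_components(masks.cvc_tip), "CVC", meta,
                         reference=landmarks.cavoatrial_junction)
    has_cvc_line = bool(masks.cvc_line.any())
    if swan_ganz is None:
        swan_ganz = scores["SwanGanzPresent"] >= cfg.swan_ganz_score_threshold
    swan = bool(swan_ganz)
    if cvc_tip is not None or (has_cvc_line and swan):
        if cvc_tip is None or landmarks.cavoatrial_junction is None:
            assessments["CVC"] = assess_cvc(None, None, swan, cfg)
            distances["CVC"] = {}
        else:
            d_vert, d_euc, d_rule = _signed_rule_distance(
                cvc_tip.tip, landmarks.cavoatrial_junction, meta, cfg)
            below_arch = (
                cvc_tip.tip.y >= landmarks.aortic_arch_upper_y
                if landmarks.aortic_arch_upper_y is not None else None
            )
            assessments["CVC"] = assess_cvc(d_rule, below_arch, swan, cfg)
            distances["CVC"] = {"d_vertical_mm": d_vert,
                                "d_euclidean_mm": d_euc}

    # --- NGT: line channel only (no tip channel in the modified model) --
    if masks.ngt_line.any():
        incomplete = is_incompletely_imaged(masks.ngt_line, [])
        visible = visible_line_length_mm(masks.ngt_line, meta)
        tip = ngt_tip_from_line(masks.ngt_line, meta, landmarks.carina)
        gej = landmarks.ge_junction
        if gej is None or tip is None:
            assessments["NGT"] = assess_ngt(None, None, incomplete, visible,
                                            cfg)
            distances["NGT"] = {}
        else:
            above_gej = tip.y < gej.y
            d_beyond = (
                0.0 if above_gej
                else arc_length_beyond_mm(masks.ngt_line, meta, gej, tip)
            )
            d_vert = vertical_separation_mm(tip, gej, meta)
            d_euc = euclidean_distance_mm(tip, gej, meta)
            assessments["NGT"] = assess_ngt(d_beyond, above_gej, incomplete,
                                            visible, cfg)
            distances["NGT"] = {
                "d_vertical_mm": d_vert,
                "d_euclidean_mm": d_euc,
                "d_beyond_mm": d_beyond,
            }

    adjusted, decisions = apply_rules(scores, assessments, cfg, distances)
    for tube, dec in decisions.items():
        logger.debug(
            "%s %s: %s fired=%s final=%s",
            meta.image_id, tube, dec.geometric_category, dec.fired_rules,
            dec.final_label,
        )
    return adjusted, decisions
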