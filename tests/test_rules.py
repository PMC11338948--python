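import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cxrtubes.rules import (
    ALL_RULES,
    LABELS,
    TUBE_GROUPS,
    ClassScores,
    GeometricAssessment,
    RuleConfig,
    apply_rules,
    assess_cvc,
    assess_ett,
    assess_ngt,
    classify_cvc,
    classify_ett,
    classify_ngt,
)

CFG = RuleConfig()


def make_scores(**overrides):
    base = {lb: 0.1 for lb in LABELS}
    base.update(overrides)
    return ClassScores(base)


# ---------------------------------------------------------------------------
# independent truth-table oracle, coded directly from the criteria wording


def oracle_ett(d, t1_above, cfg):
    if d is None:
        return "Indeterminate"
    if t1_above is True:
        return "Abnormal"
    if d <= 0:
        return "Abnormal"
    inside = (
        cfg.ett_min_mm <= d <= cfg.ett_max_mm
        if cfg.boundary_inclusive_normal
        else cfg.ett_min_mm < d < cfg.ett_max_mm
    )
    return "Normal" if inside else "Borderline"


def oracle_ngt(d_beyond, above, incomplete, visible, cfg):
    if incomplete and visible < cfg.ngt_min_mm:
        return "IncompletelyImaged"
    if above is None or d_beyond is None:
        return "Indeterminate"
    if above:
        return "Abnormal"
    return "Normal" if d_beyond >= cfg.ngt_min_mm else "Borderline"


def oracle_cvc(d, below_arch, swan, cfg):
    if swan:
        return "Normal"
    if d is None:
        return "Indeterminate"
    if d >= 0:
        return "Borderline" if below_arch is False else "Normal"
    return "Borderline" if d >= -cfg.ra_upper_third_mm else "Abnormal"


def dense_grid(cfg):
    grid = list(np.linspace(-200.0, 200.0, 1601))
    for b in (0.0, cfg.ett_min_mm, cfg.ett_max_mm, cfg.ngt_min_mm,
              -cfg.ra_upper_third_mm):
        grid += [b - 1e-9, b, b + 1e-9]
    return grid


class TestEttRule:
    @pytest.mark.parametrize(
        "d, expected",
        [
            (20.0, "Borderline"),   # under 3.5 cm above the carina
            (80.0, "Borderline"),   # over 7 cm above the carina
            (0.0, "Abnormal"),      # at the carina
            (-12.0, "Abnormal"),    # below the carina
            (35.0, "Normal"),       # inclusive lower boundary
            (70.0, "Normal"),       # inclusive upper boundary
            (50.0, "Normal"),
            (None, "Indeterminate"),
        ],
    )
    def test_categories(self, d, expected):
        assert classify_ett(d, None, CFG) == expected

    def test_t1_clause_only_when_supplied(self):
        assert classify_ett(50.0, True, CFG) == "Abnormal"
        assert classify_ett(50.0, False, CFG) == "Normal"
        assert classify_ett(50.0, None, CFG) == "Normal"

    def test_exclusive_boundaries(self):
        cfg = RuleConfig(boundary_inclusive_normal=False)
        assert classify_ett(35.0, None, cfg) == "Borderline"
        assert classify_ett(70.0, None, cfg) == "Borderline"

    def test_truth_table_equivalence(self):
        for cfg in (CFG, RuleConfig(boundary_inclusive_normal=False)):
            for d in dense_grid(cfg) + [None]:
                for t1 in (None, True, False):
                    assert classify_ett(d, t1, cfg) == oracle_ett(d, t1, cfg)


class TestNgtRule:
    @pytest.mark.parametrize(
        "d, above, incomplete, visible, expected",
        [
            (120.0, False, False, 400.0, "Normal"),
            (50.0, False, False, 400.0, "Borderline"),
            (0.0, True, False, 300.0, "Abnormal"),
            (None, None, True, 80.0, "IncompletelyImaged"),
            (50.0, False, True, 80.0, "IncompletelyImaged"),
            # off-film but plenty of visible tube: graded normally
            (120.0, False, True, 350.0, "Normal"),
            (None, None, False, 0.0, "Indeterminate"),
        ],
    )
    def test_categories(self, d, above, incomplete, visible, expected):
        assert classify_ngt(d, above, incomplete, visible, CFG) == expected

    def test_truth_table_equivalence(self):
        for d in dense_grid(CFG) + [None]:
            for above in (None, True, False):
                for inc in (True, False):
                    for vis in (0.0, 80.0, 100.0, 350.0):
                        got = classify_ngt(d, above, inc, vis, CFG)
                        assert got == oracle_ngt(d, above, inc, vis, CFG)


class TestCvcRule:
    @pytest.mark.parametrize(
        "d, swan, expected",
        [
            (15.0, False, "Normal"),        # above the cavoatrial junction
            (-10.0, False, "Borderline"),   # within the upper-RA band
            (-25.0, False, "Borderline"),   # band boundary
            (-40.0, False, "Abnormal"),     # below the upper third of the RA
            (-40.0, True, "Normal"),        # Swan-Ganz overrides position
            (None, True, "Normal"),
            (None, False, "Indeterminate"),
        ],
    )
    def test_categories(self, d, swan, expected):
        assert classify_cvc(d, None, swan, CFG) == expected

    def test_arch_clause_only_when_supplied(self):
        assert classify_cvc(60.0, False, False, CFG) == "Borderline"
        assert classify_cvc(60.0, True, False, CFG) == "Normal"
        assert classify_cvc(60.0, None, False, CFG) == "Normal"

    def test_truth_table_equivalence(self):
        for d in dense_grid(CFG) + [None]:
            for arch in (None, True, False):
                for swan in (True, False):
                    got = classify_cvc(d, arch, swan, CFG)
                    assert got == oracle_cvc(d, arch, swan, CFG)


def test_exactly_one_category_everywhere():
    """Exhaustiveness/exclusivity: a single category for every input."""
    for d in dense_grid(CFG):
        assert classify_ett(d, None, CFG) in (
            "Normal", "Borderline", "Abnormal")
        assert classify_cvc(d, None, False, CFG) in (
            "Normal", "Borderline", "Abnormal")
        if d >= 0:
            assert classify_ngt(d, False, False, 300.0, CFG) in (
                "Normal", "Borderline")


# ---------------------------------------------------------------------------
# score correction


class TestApplyRules:
    def test_upgrade_normal_to_borderline(self):
        scores = make_scores(ETT_Normal=0.8, ETT_Borderline=0.15,
                             ETT_Abnormal=0.05)
        adjusted, decisions = apply_rules(
            scores, {"ETT": assess_ett(20.0, None, CFG)}, CFG
        )
        assert adjusted["ETT_Normal"] == 0.15
        assert adjusted["ETT_Borderline"] == 0.8
        assert adjusted["ETT_Abnormal"] == 0.05
        assert decisions["ETT"].final_label == "ETT_Borderline"
        assert decisions["ETT"].fired_rules == ["ETT_LOW"]

    def test_upgrade_to_abnormal(self):
        scores = make_scores(ETT_Normal=0.5, ETT_Borderline=0.3,
                             ETT_Abnormal=0.2)
        adjusted, decisions = apply_rules(
            scores, {"ETT": assess_ett(-5.0, None, CFG)}, CFG
        )
        assert adjusted["ETT_Normal"] == 0.2
        assert adjusted["ETT_Abnormal"] == 0.5
        assert decisions["ETT"].final_label == "ETT_Abnormal"

    def test_no_op_when_argmax_matches_geometry(self):
        scores = make_scores(ETT_Normal=0.9)
        adjusted, _ = apply_rules(
            scores, {"ETT": assess_ett(50.0, None, CFG)}, CFG
        )
        assert adjusted.as_dict() == scores.as_dict()

    def test_indeterminate_and_incomplete_leave_scores(self):
        scores = make_scores(NGT_Normal=0.9, ETT_Normal=0.9)
        for assessment in (
            GeometricAssessment("Indeterminate"),
            GeometricAssessment("IncompletelyImaged", ("NGT_INCOMPLETE",)),
        ):
            adjusted, _ = apply_rules(scores, {"NGT": assessment}, CFG)
            assert adjusted.as_dict() == scores.as_dict()

    def test_never_downgrades(self):
        scores = make_scores(CVC_Abnormal=0.9, CVC_Normal=0.05)
        adjusted, _ = apply_rules(
            scores, {"CVC": assess_cvc(15.0, None, False, CFG)}, CFG
        )
        assert adjusted.as_dict() == scores.as_dict()

    def test_disabled_rule_never_fires(self):
        cfg = RuleConfig(enabled_rules=frozenset(ALL_RULES - {"ETT_LOW"}))
        scores = make_scores(ETT_Normal=0.8, ETT_Borderline=0.1)
        adjusted, decisions = apply_rules(
            scores, {"ETT": assess_ett(20.0, None, cfg)}, cfg
        )
        assert adjusted.as_dict() == scores.as_dict()
        assert decisions["ETT"].fired_rules == []

    def test_fired_rules_subset_of_enabled(self):
        cfg = RuleConfig(enabled_rules=frozenset({"ETT_LOW", "ETT_HIGH"}))
        scores = make_scores(ETT_Normal=0.8, ETT_Borderline=0.1)
        _, decisions = apply_rules(
            scores, {"ETT": assess_ett(20.0, None, cfg)}, cfg
        )
        assert set(decisions["ETT"].fired_rules) <= set(cfg.enabled_rules)


score_vectors = st.lists(
    st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
    min_size=len(LABELS), max_size=len(LABELS),
)
distances = st.one_of(
    st.none(), st.floats(min_value=-150, max_value=150, allow_nan=False)
)


@given(vals=score_vectors, d_ett=distances, d_cvc=distances,
       d_ngt=distances, swan=st.booleans())
def test_apply_rules_properties(vals, d_ett, d_cvc, d_ngt, swan):
    """Idempotence, per-group score permutation, upgrade monotonicity."""
    scores = ClassScores(dict(zip(LABELS, vals)))
    assessments = {
        "ETT": assess_ett(d_ett, None, CFG),
        "CVC": assess_cvc(d_cvc, None, swan, CFG),
        "NGT": assess_ngt(d_ngt, False if d_ngt is not None else None,
                          False, 300.0, CFG),
    }
    adjusted, decisions = apply_rules(scores, assessments, CFG)
    rank = {"Normal": 0, "Borderline": 1, "Abnormal": 2}
    for tube, labels in TUBE_GROUPS.items():
        before = sorted(scores[lb] for lb in labels)
        after = sorted(adjusted[lb] for lb in labels)
        assert before == after  # permutation within the group
        geom = decisions[tube].geometric_category
        final_cat = decisions[tube].final_label.split("_", 1)[1]
        if geom in rank and final_cat in rank:
            argmax_before = scores.group_argmax(tube).split("_", 1)[1]
            if argmax_before in rank:
                assert rank[final_cat] >= min(
                    rank[argmax_before], rank[geom]
                )
    twice, _ = apply_rules(adjusted, assessments, CFG)
    assert twice.as_dict() == adjusted.as_dict()  # idempotent


def test_scores_validation():
    with pytest.raises(ValueError):
        ClassScores({lb: 0.5 for lb in LABELS[:-1]})
    with pytest.raises(ValueError):
        make_scores(ETT_Normal=1.5)


def test_config_validation():
    with pytest.raises(ValueError):
        RuleConfig(ett_min_mm=80.0, ett_max_mm=70.0)
    with pytest.raises(ValueError):
        RuleConfig(enabled_rules=frozenset({"NOT_A_RULE"}))
    with pytest.raises(ValueError):
        RuleConfig(distance_mode="manhattan")
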