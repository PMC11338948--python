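"""scikit-learn-style wrappers around the rule table and score correction.

:class:`TubeRuleClassifier` is a deterministic classifier: its "features"
are the metric tip-to-landmark measurements and flags for one tube kind and
its predictions are the geometric position categories.  There is nothing to
estimate, so ``fit`` only validates parameters, but exposing the
fit/predict/get_params surface lets the rule table drop into sklearn
pipelines, cross-validation and comparison harnesses unchanged.

:class:`RuleScoreCorrector` is the matching transformer: given the 11
classifier score columns plus per-tube geometric categories it returns the
rule-corrected (upgraded) scores.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .rules import (
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
)

#: feature columns expected per tube kind (order used for plain arrays)
FEATURE_COLUMNS = {
    "ETT": ("d_mm", "t1_above"),
    "NGT": ("d_beyond_mm", "above_gej", "incomplete", "visible_len_mm"),
    "CVC": ("d_mm", "swan_ganz", "below_arch"),
}


def _as_frame(X, columns) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        missing = [c for c in columns if c not in X.columns]
        # optional trailing columns may be absent entirely
        required = columns[:1]
        if any(c in missing for c in required):
            raise ValueError(f"X lacks required columns {missing}")
        df = X.copy()
        for c in missing:
            df[c] = np.nan
        return df
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[1] > len(columns):
        raise ValueError(
            f"X has {X.shape[1]} columns, expected at most {len(columns)}"
        )
    df = pd.DataFrame(X, columns=columns[: X.shape[1]])
    for c in columns[X.shape[1]:]:
        df[c] = np.nan
    return df


def _opt_bool(v) -> Optional[bool]:
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return None
    return bool(v)


def _opt_float(v) -> Optional[float]:
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return None
    return float(v)


class TubeRuleClassifier(BaseEstimator, ClassifierMixin):
    """Deterministic position classifier for one tube kind.

    Parameters mirror :class:`~cxrtubes.rules.RuleConfig`.  ``X`` is a
    DataFrame (or array in the documented column order) of per-image
    measurements:

    * ETT — ``d_mm`` (signed mm above the carina), optional ``t1_above``;
    * NGT — ``d_beyond_mm``, ``above_gej``, ``incomplete``,
      ``visible_len_mm``;
    * CVC — ``d_mm`` (signed mm above the cavoatrial junction),
      ``swan_ganz``, optional ``below_arch``.

    NaN measurements mean "landmark absent" and predict Indeterminate.
    """

    def __init__(
        self,
        tube_kind: str = "ETT",
        ett_min_mm: float = 35.0,
        ett_max_mm: float = 70.0,
        ngt_min_mm: float = 100.0,
        ra_upper_third_mm: float = 25.0,
        boundary_inclusive_normal: bool = True,
    ):
        self.tube_kind = tube_kind
        self.ett_min_mm = ett_min_mm
        self.ett_max_mm = ett_max_mm
        self.ngt_min_mm = ngt_min_mm
        self.ra_upper_third_mm = ra_upper_third_mm
        self.boundary_inclusive_normal = boundary_inclusive_normal

    def _config(self) -> RuleConfig:
        return RuleConfig(
            ett_min_mm=self.ett_min_mm,
            ett_max_mm=self.ett_max_mm,
            ngt_min_mm=self.ngt_min_mm,
            ra_upper_third_mm=self.ra_upper_third_mm,
            boundary_inclusive_normal=self.boundary_inclusive_normal,
        )

    def fit(self, X=None, y=None):
        if self.tube_kind not in FEATURE_COLUMNS:
            raise ValueError(f"unknown tube_kind {self.tube_kind!r}")
        self._config()  # validates thresholds
        self.classes_ = np.array(
            ["Abnormal", "Borderline", "IncompletelyImaged", "Indeterminate",
             "Normal"]
        )
        self.n_features_in_ = len(FEATURE_COLUMNS[self.tube_kind])
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "classes_")
        cols = FEATURE_COLUMNS[self.tube_kind]
        df = _as_frame(X, cols)
        cfg = self._config()
        out = []
        for _, row in df.iterrows():
            if self.tube_kind == "ETT":
                a = assess_ett(_opt_float(row["d_mm"]),
                               _opt_bool(row["t1_above"]), cfg)
            elif self.tube_kind == "NGT":
                a = assess_ngt(
                    _opt_float(row["d_beyond_mm"]),
                    _opt_bool(row["above_gej"]),
                    bool(row["incomplete"]),
                    float(row["visible_len_mm"]),
                    cfg,
                )
            else:
                a = assess_cvc(
                    _opt_float(row["d_mm"]),
                    _opt_bool(row["below_arch"]),
                    bool(row["swan_ganz"]),
                    cfg,
                )
            out.append(a.category)
        return np.asarray(out, dtype=object)


class RuleScoreCorrector(BaseEstimator, TransformerMixin):
    """Transformer applying the rule-based score upgrade.

    ``X`` is a DataFrame with the 11 label score columns plus, per tube,
    an optional ``<TUBE>_category`` column holding the geometric category
    (missing or NaN categories leave that tube's scores untouched).
    Output keeps the same shape with the score columns adjusted.
    """

    def __init__(self, enabled_rules=None):
        self.enabled_rules = enabled_rules

    def _config(self) -> RuleConfig:
        rules = (
            ALL_RULES if self.enabled_rules is None
            else frozenset(self.enabled_rules)
        )
        return RuleConfig(enabled_rules=rules)

    def fit(self, X=None, y=None):
        self._config()
        self.n_features_in_ = (
            X.shape[1] if hasattr(X, "shape") and X is not None else None
        )
        self._fitted = True
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "_fitted")
        if not isinstance(X, pd.DataFrame):
            raise ValueError("RuleScoreCorrector expects a DataFrame")
        missing = [lb for lb in LABELS if lb not in X.columns]
        if missing:
            raise ValueError(f"missing score columns: {missing}")
        cfg = self._config()
        out = X.copy()
        if not cfg.enabled_rules:
            return out  # correction switched off entirely
        for i, row in X.iterrows():
            assessments = {}
            for tube in TUBE_GROUPS:
                col = f"{tube}_category"
                if col in X.columns and isinstance(row[col], str):
                    assessments[tube] = GeometricAssessment(row[col])
            if not assessments:
                continue
            scores = ClassScores({lb: float(row[lb]) for lb in LABELS})
            adjusted, _ = apply_rules(scores, assessments, cfg)
            for lb in LABELS:
                out.at[i, lb] = adjusted[lb]
        return out
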