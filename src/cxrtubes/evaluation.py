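"""Study-style evaluation: bootstrap AUCs, landmark error, paired tests.

Each classification label is scored one-vs-rest with the Mann-Whitney form
of the AUC (ties count one half); 95 % confidence intervals come from
resampling radiographs with replacement (percentile method, 1000 draws by
default).  Labels within a tube group are additionally averaged, and the
confidence interval of that average is obtained by bootstrapping the
averaged statistic itself, not by averaging per-label intervals.

Landmark accuracy is the mean absolute error: the per-image Euclidean
distance in mm between predicted and reference coordinates, summarised as
mean and SD and compared between conditions with a paired t-test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import ImageMeta, Point, euclidean_distance_mm
from .rules import LABELS, TUBE_GROUPS

logger = logging.getLogger(__name__)


class UndefinedAUCError(ValueError):
    """AUC cannot be computed (only one class present)."""


def auc_one_vs_rest(labels: Sequence, scores: Sequence) -> float:
    """Mann-Whitney AUC: probability a random positive outscores a random
    negative, with ties counted one half.

    Raises :class:`UndefinedAUCError` when only one class is present, the
    situation the evaluation reports as an explicit "undefined" cell.
    """
    y = np.asarray(labels).astype(bool)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape or y.ndim != 1:
        raise ValueError("labels and scores must be 1-D and equally long")
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise UndefinedAUCError(
            f"AUC undefined: {n_pos} positives, {n_neg} negatives"
        )
    ranks = stats.rankdata(s)  # midranks handle ties
    r_pos = ranks[y].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def bootstrap_ci(
    metric: Callable[[np.ndarray], float],
    n: int,
    n_boot: int = 1000,
    seed: int = 0,
    strata: Optional[np.ndarray] = None,
) -> Tuple[float, float, float]:
    """Percentile bootstrap of ``metric`` over images.

    ``metric`` receives an index array into the dataset and returns a float
    (raising :class:`UndefinedAUCError` when the resample is degenerate, in
    which case the draw is repeated, up to ``10 * n_boot`` attempts).  When
    ``strata`` is given, resampling is stratified within each stratum so
    rare classes cannot vanish from a resample.

    Returns ``(point, lo, hi)`` with the 2.5/97.5 percentile bounds.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    idx_full = np.arange(n)
    point = metric(idx_full)  # propagate undefined on the full data
    rng = np.random.default_rng(seed)
    if strata is not None:
        strata = np.asarray(strata)
        groups = [np.flatnonzero(strata == g) for g in np.unique(strata)]
    vals = np.empty(n_boot)
    attempts = 0
    i = 0
    while i < n_boot:
        if attempts >= 10 * n_boot:
            raise UndefinedAUCError(
                "bootstrap exhausted: metric undefined on too many resamples"
            )
        attempts += 1
        if strata is None:
            idx = rng.integers(0, n, size=n)
        else:
            idx = np.concatenate(
                [g[rng.integers(0, g.size, size=g.size)] for g in groups]
            )
        try:
            vals[i] = metric(idx)
        except UndefinedAUCError:
            continue
        i += 1
    lo, hi = np.percentile(vals, [2.5, 97.5])
    return point, float(lo), float(hi)


def group_average_auc(per_label_aucs: Mapping[str, Optional[float]]) -> float:
    """Unweighted mean of the defined per-label AUCs within a tube group."""
    defined = [v for v in per_label_aucs.values() if v is not None]
    if not defined:
        raise UndefinedAUCError("no defined per-label AUC in group")
    return float(np.mean(defined))


# ---------------------------------------------------------------------------
# dataset-level AUC tables


def _label_metric(y: np.ndarray, s: np.ndarray) -> Callable[[np.ndarray], float]:
    def metric(idx: np.ndarray) -> float:
        return auc_one_vs_rest(y[idx], s[idx])

    return metric


def _group_metric(
    ys: Sequence[np.ndarray], ss: Sequence[np.ndarray]
) -> Callable[[np.ndarray], float]:
    """Average AUC over the group's labels, skipping labels undefined on the
    resample; undefined only if every label is."""

    def metric(idx: np.ndarray) -> float:
        vals = []
        for y, s in zip(ys, ss):
            try:
                vals.append(auc_one_vs_rest(y[idx], s[idx]))
            except UndefinedAUCError:
                continue
        if not vals:
            raise UndefinedAUCError("all group labels undefined on resample")
        return float(np.mean(vals))

    return metric


def evaluate_scores(
    y_true: pd.DataFrame,
    y_score: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
) -> Dict:
    """Per-label and group-averaged AUC table with bootstrap CIs.

    ``y_true`` holds one binary column per label, ``y_score`` the matching
    score columns; rows are radiographs.  Undefined AUCs (single-class
    labels) appear as the explicit string ``"undefined"``, never silently
    dropped.
    """
    labels = [lb for lb in LABELS if lb in y_true.columns]
    if not labels:
        raise ValueError("y_true contains no known label columns")
    report: Dict = {"per_label": {}, "groups": {}}
    for k, lb in enumerate(labels):
        y = y_true[lb].to_numpy().astype(bool)
        s = y_score[lb].to_numpy(dtype=float)
        try:
            point, lo, hi = bootstrap_ci(
                _label_metric(y, s), len(y), n_boot=n_boot, seed=seed + k
            )
            report["per_label"][lb] = {"auc": point, "lo": lo, "hi": hi}
        except UndefinedAUCError:
            report["per_label"][lb] = "undefined"
    for g, (tube, group_labels) in enumerate(TUBE_GROUPS.items()):
        present = [lb for lb in group_labels if lb in labels]
        defined = [
            lb for lb in present if report["per_label"].get(lb) != "undefined"
        ]
        if not defined:
            report["groups"][tube] = "undefined"
            continue
        ys = [y_true[lb].to_numpy().astype(bool) for lb in defined]
        ss = [y_score[lb].to_numpy(dtype=float) for lb in defined]
        try:
            point, lo, hi = bootstrap_ci(
                _group_metric(ys, ss), len(ys[0]), n_boot=n_boot,
                seed=seed + 1000 + g,
            )
            report["groups"][tube] = {"auc": point, "lo": lo, "hi": hi}
        except UndefinedAUCError:
            report["groups"][tube] = "undefined"
    return report


def stratified_report(
    y_true: pd.DataFrame,
    y_score: pd.DataFrame,
    flag: Sequence[bool],
    n_boot: int = 1000,
    seed: int = 0,
) -> Dict[str, Dict]:
    """Independent AUC tables for the flag's two strata (e.g. radiographs
    with vs without ECG leads).  Empty or degenerate strata report
    "undefined" cells rather than disappearing."""
    flag = np.asarray(flag, dtype=bool)
    if flag.size != len(y_true):
        raise ValueError("flag must cover every image")
    out: Dict[str, Dict] = {}
    for name, sel in (("with", flag), ("without", ~flag)):
        if not sel.any():
            out[name] = {"per_label": {}, "groups": {}, "n": 0}
            continue
        rep = evaluate_scores(
            y_true.loc[sel].reset_index(drop=True),
            y_score.loc[sel].reset_index(drop=True),
            n_boot=n_boot,
            seed=seed,
        )
        rep["n"] = int(sel.sum())
        out[name] = rep
    return out


# ---------------------------------------------------------------------------
# landmark error


def landmark_distances_mm(
    predicted: Mapping[str, Point],
    truth: Mapping[str, Point],
    metas: Mapping[str, ImageMeta],
) -> np.ndarray:
    """Per-image Euclidean distance (mm) between prediction and reference.

    Images missing either annotation are excluded (and counted in the log),
    matching how unlabeled films are handled in practice.
    """
    common = sorted(set(predicted) & set(truth))
    skipped = (set(predicted) | set(truth)) - set(common)
    if skipped:
        logger.info("landmark MAE: %d images lack a pairing", len(skipped))
    if not common:
        raise ValueError("no image has both predicted and truth annotations")
    return np.array(
        [
            euclidean_distance_mm(predicted[i], truth[i], metas[i])
            for i in common
        ]
    )


def landmark_mae_mm(
    predicted: Mapping[str, Point],
    truth: Mapping[str, Point],
    metas: Mapping[str, ImageMeta],
    ddof: int = 0,
) -> Tuple[float, float]:
    """Mean and SD (population by default, ``ddof=1`` for sample) of the
    per-image landmark distance in mm."""
    d = landmark_distances_mm(predicted, truth, metas)
    return float(d.mean()), float(d.std(ddof=ddof))


def paired_difference_test(
    distances_a: Sequence[float], distances_b: Sequence[float]
) -> Tuple[float, Tuple[float, float], float]:
    """Two-sided paired t-test on per-image distance differences (B - A).

    Returns ``(mean difference, (ci_lo, ci_hi), p)``.  Identical inputs give
    a zero difference with p guarded to 1.
    """
    a = np.asarray(distances_a, dtype=float)
    b = np.asarray(distances_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired conditions must be equally long 1-D vectors")
    n = a.size
    if n < 2:
        raise ValueError("paired test needs at least 2 images")
    d = b - a
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        return mean, (mean, mean), 1.0
    se = sd / math.sqrt(n)
    tcrit = stats.t.ppf(0.975, n - 1)
    res = stats.ttest_rel(b, a)
    return mean, (mean - tcrit * se, mean + tcrit * se), float(res.pvalue)


def is_significant(
    p: float, ci_a: Tuple[float, float], ci_b: Tuple[float, float]
) -> bool:
    """Study significance convention: p < 0.05 AND non-overlapping 95 % CIs."""
    lo_a, hi_a = ci_a
    lo_b, hi_b = ci_b
    non_overlap = hi_a < lo_b or hi_b < lo_a
    return bool(p < 0.05 and non_overlap)


# ---------------------------------------------------------------------------
# small report arithmetic (timing and cohort tables)


def parse_duration_s(text: str) -> int:
    """Parse ``H:MM:SS`` (or ``HH:MM:SS``) into seconds."""
    parts = text.strip().split(":")
    if len(parts) != 3:
        raise ValueError(f"expected H:MM:SS, got {text!r}")
    h, m, s = (int(p) for p in parts)
    if not (0 <= m < 60 and 0 <= s < 60) or h < 0:
        raise ValueError(f"invalid duration {text!r}")
    return h * 3600 + m * 60 + s


def percent_reduction(before: str, after: str) -> float:
    """Percentage reduction between two H:MM:SS durations (e.g. reading
    times with and without assistance)."""
    t0 = parse_duration_s(before)
    t1 = parse_duration_s(after)
    if t0 <= 0:
        raise ValueError("baseline duration must be positive")
    return 100.0 * (t0 - t1) / t0


def percent(part: int, total: int, ndigits: int = 1) -> float:
    """Cohort-table percentage, rounded as printed, e.g. 140 of 178 -> 78.7."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * part / total, ndigits)


def format_count_percent(part: int, total: int, ndigits: int = 1) -> str:
    return f"{part} ({percent(part, total, ndigits)})"
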