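"""Diagnostic-performance machinery: ROC / AUC, Youden-optimal thresholds,
confusion statistics, chi-squared association and paired AUC comparison.

Conventions: a case's score is the *decrease* ``-change`` (percent), the
positive class is the gold-standard responder, and a candidate cut ``c``
calls responder iff ``change < -c``.  AUC is computed with the rank
(Mann-Whitney) formulation, which equals trapezoidal integration of the
empirical curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "RocResult",
    "ConfusionStats",
    "roc",
    "youden_optimal",
    "confusion_stats",
    "chi_squared",
    "compare_auc",
    "auc_groups",
]


@dataclass
class RocResult:
    thresholds: np.ndarray     # candidate cuts c (percent decrease required)
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    optimal_threshold: float
    youden_j: float
    scores: np.ndarray         # -change, kept for paired AUC comparison
    labels: np.ndarray         # boolean, True = gold responder

    @property
    def n_pos(self) -> int:
        return int(self.labels.sum())

    @property
    def n_neg(self) -> int:
        return int((~self.labels).sum())


def _as_bool_labels(gold) -> np.ndarray:
    arr = np.asarray(gold)
    if arr.dtype == bool:
        return arr
    return np.asarray([str(g) == "responder" for g in gold])


def roc(changes, gold) -> RocResult:
    """ROC analysis of percent changes against binary gold labels."""
    changes = np.asarray(changes, dtype=float)
    labels = _as_bool_labels(gold)
    if changes.shape != labels.shape:
        raise ValueError("changes and labels must have equal length")
    n_pos, n_neg = int(labels.sum()), int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    scores = -changes
    # Mann-Whitney AUC with tie correction via midranks
    ranks = stats.rankdata(scores)
    auc = (ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    uniq = np.unique(scores)
    cuts = np.concatenate(
        [[-np.inf], (uniq[:-1] + uniq[1:]) / 2.0 if len(uniq) > 1 else [], [np.inf]]
    )
    sens = np.array([(scores[labels] > c).mean() for c in cuts])
    spec = np.array([(scores[~labels] <= c).mean() for c in cuts])
    j = sens + spec - 1.0
    best = _argmax_smallest_magnitude(j, cuts)
    return RocResult(
        thresholds=cuts,
        sensitivity=sens,
        specificity=spec,
        auc=float(auc),
        optimal_threshold=float(cuts[best]),
        youden_j=float(j[best]),
        scores=scores,
        labels=labels,
    )


def _argmax_smallest_magnitude(j, cuts):
    jmax = j.max()
    tied = np.flatnonzero(j >= jmax - 1e-12)
    return tied[np.argmin(np.abs(cuts[tied]))]


def youden_optimal(result: RocResult):
    """(optimal threshold, max J); ties broken toward the smaller magnitude."""
    j = result.sensitivity + result.specificity - 1.0
    best = _argmax_smallest_magnitude(j, result.thresholds)
    return float(result.thresholds[best]), float(j[best])


def _ratio(num, den):
    return num / den if den > 0 else None


@dataclass
class ConfusionStats:
    tp: int
    tn: int
    fp: int
    fn: int
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    accuracy: float | None
    youden_j: float | None
    chi2_stat: float | None
    chi2_p: float | None

    @property
    def significant(self) -> bool | None:
        return None if self.chi2_p is None else bool(self.chi2_p < 0.05)

    def as_percent_row(self) -> dict:
        """Table row with ratios as integer percentages (half-up, matching
        how clinical tables print) and J at two decimals."""

        def pct(x):
            return None if x is None else int(np.floor(100.0 * x + 0.5))

        return {
            "sensitivity_pct": pct(self.sensitivity),
            "specificity_pct": pct(self.specificity),
            "ppv_pct": pct(self.ppv),
            "npv_pct": pct(self.npv),
            "accuracy_pct": pct(self.accuracy),
            "youden_j": None if self.youden_j is None else round(self.youden_j, 2),
            "chi2_p": self.chi2_p,
            "significant": self.significant,
        }


def confusion_stats(tp: int, tn: int, fp: int, fn: int) -> ConfusionStats:
    """Sensitivity, specificity, PPV, NPV, accuracy, J and chi-squared from a
    2x2 confusion table.  Undefined ratios (zero denominator) are ``None``."""
    if min(tp, tn, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    total = tp + tn + fp + fn
    sens = _ratio(tp, tp + fn)
    spec = _ratio(tn, tn + fp)
    youden = sens + spec - 1.0 if sens is not None and spec is not None else None
    chi2_stat, chi2_p, _ = chi_squared(tp, tn, fp, fn)
    return ConfusionStats(
        tp=tp,
        tn=tn,
        fp=fp,
        fn=fn,
        sensitivity=sens,
        specificity=spec,
        ppv=_ratio(tp, tp + fp),
        npv=_ratio(tn, tn + fn),
        accuracy=_ratio(tp + tn, total),
        youden_j=youden,
        chi2_stat=chi2_stat,
        chi2_p=chi2_p,
    )


def chi_squared(tp: int, tn: int, fp: int, fn: int, correction: bool = False):
    """Pearson chi-squared on the 2x2 table, 1 df, no continuity correction by
    default.  Returns (statistic, p, significant) with ``None`` entries when a
    zero marginal makes the statistic undefined."""
    table = np.array([[tp, fn], [fp, tn]], dtype=float)
    if table.sum() <= 0:
        raise ValueError("empty table")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        return None, None, None
    stat, p, _, _ = stats.chi2_contingency(table, correction=correction)
    return float(stat), float(p), bool(p < 0.05)


# ---------------------------------------------------------------------------
# paired AUC comparison (DeLong)


def _midrank(x):
    """Midranks as used by the DeLong placement values."""
    return stats.rankdata(x, method="average")


def _delong_placements(scores, labels):
    pos, neg = scores[labels], scores[~labels]
    m, n = len(pos), len(neg)
    all_ranks = _midrank(np.concatenate([pos, neg]))
    v10 = (all_ranks[:m] - _midrank(pos)) / n          # per-positive placements
    v01 = 1.0 - (all_ranks[m:] - _midrank(neg)) / m    # per-negative placements
    return v10, v01


def compare_auc(roc_a: RocResult, roc_b: RocResult):
    """DeLong paired test for two correlated ROC curves on the same cases.

    Returns (z, p) for the two-sided comparison of the AUCs.
    """
    if not np.array_equal(roc_a.labels, roc_b.labels):
        raise ValueError("ROC results are not paired on the same cases")
    labels = roc_a.labels
    v10 = np.column_stack(
        [
            _delong_placements(roc_a.scores, labels)[0],
            _delong_placements(roc_b.scores, labels)[0],
        ]
    )
    v01 = np.column_stack(
        [
            _delong_placements(roc_a.scores, labels)[1],
            _delong_placements(roc_b.scores, labels)[1],
        ]
    )
    m, n = v10.shape[0], v01.shape[0]
    s10 = np.cov(v10, rowvar=False)
    s01 = np.cov(v01, rowvar=False)
    s = s10 / m + s01 / n
    contrast = np.array([1.0, -1.0])
    var = float(contrast @ s @ contrast)
    diff = roc_a.auc - roc_b.auc
    if var <= 0:
        return 0.0, 1.0
    z = diff / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def auc_groups(rocs: dict, alpha: float = 0.05):
    """Partition named ROC results into groups by the transitive closure of
    pairwise non-significant DeLong comparisons (the 'same circle' reading of
    an AUC intercomparison diagram)."""
    names = list(rocs)
    parent = {n: n for n in names}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            _, p = compare_auc(rocs[a], rocs[b])
            if p >= alpha:
                parent[find(a)] = find(b)
    groups = {}
    for n in names:
        groups.setdefault(find(n), []).append(n)
    return sorted(groups.values(), key=lambda g: -max(rocs[n].auc for n in g))
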