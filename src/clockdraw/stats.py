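"""Statistical validation toolkit.

ROC/AUC with the DeLong paired comparison of correlated AUCs, Wilcoxon
rank-sum contrasts with Bonferroni-Holm adjustment, Kruskal-Wallis with
post-hoc pairwise tests, and Pearson correlations with Fisher-z intervals.

AUC follows the Mann-Whitney convention throughout — the probability that a
randomly chosen positive (unimpaired, by default orientation) outscores a
randomly chosen negative, with ties counted half — and the DeLong
variance/covariance uses midrank structural components, so AUC and U remain
mutually consistent under ties.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "RocResult",
    "PairedAucTest",
    "roc_curve",
    "delong_test",
    "auc_variance",
    "rank_sum_test",
    "holm_adjust",
    "kruskal_wallis",
    "pearson_ci",
]


@dataclass
class RocResult:
    """A ROC curve: (FPR, TPR) pairs at each cutoff, plus the AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    cutoffs: np.ndarray
    auc: float
    n_positive: int
    n_negative: int


def _check_labels(labels) -> np.ndarray:
    y = np.asarray(labels).astype(bool)
    if y.all() or (~y).all():
        raise ValueError("both classes must be present")
    return y


def roc_curve(scores, labels, *, positive_high: bool = True) -> RocResult:
    """ROC curve and AUC (Mann-Whitney pair statistic).

    ``labels`` are truthy for the positive (higher-scoring, by convention
    unimpaired) class; set ``positive_high=False`` for reverse-coded scores.
    """
    y = _check_labels(labels)
    s = np.asarray(scores, dtype=float)
    if not positive_high:
        s = -s
    order = np.argsort(-s, kind="mergesort")
    s_sorted, y_sorted = s[order], y[order]
    npos, nneg = int(y.sum()), int((~y).sum())
    # step through distinct cutoffs
    distinct = np.r_[np.flatnonzero(np.diff(s_sorted)), len(s_sorted) - 1]
    tps = np.cumsum(y_sorted)[distinct]
    fps = np.cumsum(~y_sorted)[distinct]
    tpr = np.r_[0.0, tps / npos]
    fpr = np.r_[0.0, fps / nneg]
    cutoffs = np.r_[np.inf, s_sorted[distinct]]
    # AUC via midranks (ties counted half)
    ranks = sps.rankdata(s)
    auc = (ranks[y].sum() - npos * (npos + 1) / 2.0) / (npos * nneg)
    return RocResult(fpr, tpr, cutoffs, float(auc), npos, nneg)


def _structural_components(s: np.ndarray, y: np.ndarray):
    """DeLong midrank structural components V10 (per positive) and V01
    (per negative)."""
    pos, neg = s[y], s[~y]
    m, n = len(pos), len(neg)
    allr = sps.rankdata(np.concatenate([pos, neg]))
    rp = sps.rankdata(pos)
    rn = sps.rankdata(neg)
    v10 = (allr[:m] - rp) / n
    v01 = 1.0 - (allr[m:] - rn) / m
    return v10, v01


def auc_variance(scores, labels) -> float:
    """DeLong variance estimate of a single AUC."""
    y = _check_labels(labels)
    s = np.asarray(scores, dtype=float)
    v10, v01 = _structural_components(s, y)
    return float(np.var(v10, ddof=1) / len(v10) + np.var(v01, ddof=1) / len(v01))


@dataclass
class PairedAucTest:
    """DeLong paired comparison of two AUCs measured on the same subjects."""

    auc_a: float
    auc_b: float
    var_a: float
    var_b: float
    covariance: float
    z: float
    p: float


def delong_test(scores_a, scores_b, labels) -> PairedAucTest:
    """Nonparametric paired test of AUC_a vs AUC_b (DeLong structural
    components with midranks); two-sided p."""
    y = _check_labels(labels)
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    if sa.shape != sb.shape or sa.shape[0] != y.shape[0]:
        raise ValueError("scores_a, scores_b and labels must be equal length")
    va10, va01 = _structural_components(sa, y)
    vb10, vb01 = _structural_components(sb, y)
    auc_a, auc_b = float(va10.mean()), float(vb10.mean())
    m, n = len(va10), len(va01)
    s10 = np.cov(np.vstack([va10, vb10]), ddof=1)
    s01 = np.cov(np.vstack([va01, vb01]), ddof=1)
    S = s10 / m + s01 / n
    var_diff = S[0, 0] + S[1, 1] - 2 * S[0, 1]
    if var_diff <= 1e-16:
        z = 0.0
        p = 1.0
    else:
        z = (auc_a - auc_b) / math.sqrt(var_diff)
        p = 2.0 * sps.norm.sf(abs(z))
    return PairedAucTest(auc_a, auc_b, float(S[0, 0]), float(S[1, 1]),
                         float(S[0, 1]), float(z), float(min(p, 1.0)))


def rank_sum_test(x, y) -> tuple[float, float]:
    """Wilcoxon rank-sum (Mann-Whitney U) two-sided test.

    Exact enumeration for small samples (n_x + n_y <= 12, no ties),
    otherwise the tie-corrected normal approximation with continuity
    correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sample")
    ties = len(np.unique(np.concatenate([x, y]))) < x.size + y.size
    method = "exact" if (x.size + y.size <= 12 and not ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def holm_adjust(pvalues) -> np.ndarray:
    """Bonferroni-Holm step-down adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def kruskal_wallis(*groups) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H with chi-square reference (k-1 df)."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty group")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if all(np.array_equal(a, arrays[0]) for a in arrays[1:]) and all(
        np.ptp(a) == 0 for a in arrays
    ):
        return 0.0, 1.0  # all observations identical: H = 0 by convention
    res = sps.kruskal(*arrays)
    return float(res.statistic), float(res.pvalue)


def pearson_ci(x, y, level: float = 0.95) -> tuple[float, float, float]:
    """Pearson r with a Fisher-z confidence interval."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 4:
        raise ValueError("need n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance input")
    res = sps.pearsonr(x, y)
    ci = res.confidence_interval(confidence_level=level)
    return float(res.statistic), float(ci.low), float(ci.high)
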