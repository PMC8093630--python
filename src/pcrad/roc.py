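"""ROC/AUC estimation and inference.

The AUC is the Mann-Whitney estimator (ties count 1/2).  Confidence intervals
use the DeLong structural-component variance with a normal quantile.
Significance against the chance value AUC = 0.5 uses the identity between the
AUC and the Mann-Whitney U statistic: an exact rank-sum p-value when the
product of class sizes is small and the scores are tie-free, a tie-corrected
normal approximation otherwise.  Multiplicity over many candidate models is
controlled with the Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats as sps

__all__ = ["auc", "auc_ci", "delong_variance", "mason_graham_p", "benjamini_hochberg"]

EXACT_PAIR_LIMIT = 10_000  # exact rank-sum null up to this many (pos, neg) pairs


def _split(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both outcome classes must be present")
    return pos, neg


def auc(scores, labels) -> float:
    """Mann-Whitney AUC: P(score_pos > score_neg) + 0.5 P(tie)."""
    pos, neg = _split(scores, labels)
    ranks = sps.rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def delong_variance(scores, labels) -> float:
    """DeLong variance of the AUC estimator from structural components."""
    pos, neg = _split(scores, labels)
    m, n = pos.size, neg.size
    if m < 2 or n < 2:
        raise ValueError("DeLong variance needs >= 2 members per class")

    def midrank(x):
        return sps.rankdata(x, method="average")

    allr = midrank(np.concatenate([pos, neg]))
    v10 = (allr[:m] - midrank(pos)) / n  # per-positive placement values
    v01 = 1.0 - (allr[m:] - midrank(neg)) / m  # per-negative
    return float(np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n)


def auc_ci(scores, labels, level: float = 0.95) -> tuple[float, float]:
    """DeLong normal-quantile confidence interval, truncated to [0, 1]."""
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    a = auc(scores, labels)
    var = delong_variance(scores, labels)
    if var <= 0:
        warnings.warn("degenerate DeLong variance: interval collapses to the estimate", stacklevel=2)
        return (a, a)
    z = sps.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(var)
    return (float(max(0.0, a - half)), float(min(1.0, a + half)))


def mason_graham_p(scores, labels) -> float:
    """Two-sided p-value for H0: AUC = 0.5 via the Mann-Whitney U identity.

    Exact rank-sum null distribution when n_pos * n_neg <= 10^4 and the scores
    are tie-free; tie-corrected normal approximation otherwise.
    """
    pos, neg = _split(scores, labels)
    scores = np.concatenate([pos, neg])
    exact = pos.size * neg.size <= EXACT_PAIR_LIMIT and np.unique(scores).size == scores.size
    res = sps.mannwhitneyu(
        pos, neg, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return float(res.pvalue)


def benjamini_hochberg(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (original order preserved)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvals must be a non-empty 1D sequence")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
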