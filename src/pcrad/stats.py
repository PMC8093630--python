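"""Univariate group-comparison statistics for cohort characteristics tables.

Continuous covariates are compared between responders and non-responders with
the Welch two-sample t-test (unequal variances, Welch-Satterthwaite degrees of
freedom, available both from raw samples and from printed n/mean/sd
summaries).  Categorical covariates use the exact Fisher test, extended to
r x c tables by full Freeman-Halton enumeration of all tables with the
observed margins.  Correlation screening between continuous covariates uses
Spearman rank correlation.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import gammaln

__all__ = [
    "GroupSummary",
    "WelchResult",
    "welch_t_from_summaries",
    "welch_t",
    "fisher_exact",
    "spearman_matrix",
]


@dataclass(frozen=True)
class GroupSummary:
    """Sample size, mean and standard deviation of one group."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group size must be >= 2")
        if self.sd <= 0:
            raise ValueError("sd must be positive")


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float


def welch_t_from_summaries(g1: GroupSummary, g2: GroupSummary) -> WelchResult:
    """Welch two-sample t-test from per-group (n, mean, sd) summaries.

    t = (m1 - m2) / sqrt(s1^2/n1 + s2^2/n2) with Welch-Satterthwaite degrees
    of freedom (left non-integer) and a two-sided p from the t distribution.
    """
    v1 = g1.sd**2 / g1.n
    v2 = g2.sd**2 / g2.n
    t = (g1.mean - g2.mean) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (g1.n - 1) + v2**2 / (g2.n - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return WelchResult(float(t), float(df), float(p))


def welch_t(raw1, raw2) -> WelchResult:
    """Welch two-sample t-test from raw per-group samples."""
    x1 = np.asarray(raw1, dtype=float)
    x2 = np.asarray(raw2, dtype=float)
    if x1.size < 2 or x2.size < 2:
        raise ValueError("each group needs at least 2 observations")
    s1 = x1.std(ddof=1)
    s2 = x2.std(ddof=1)
    if s1 == 0 or s2 == 0:
        raise ValueError("zero variance group")
    return welch_t_from_summaries(
        GroupSummary(x1.size, float(x1.mean()), float(s1)),
        GroupSummary(x2.size, float(x2.mean()), float(s2)),
    )


def _drop_zero_margins(table: np.ndarray) -> np.ndarray:
    rows = table.sum(axis=1) > 0
    cols = table.sum(axis=0) > 0
    if not rows.all() or not cols.all():
        warnings.warn("dropping zero-margin rows/columns from contingency table", stacklevel=3)
    return table[np.ix_(rows, cols)]


def fisher_exact(table) -> float:
    """Exact two-sided Fisher test for an r x c contingency table.

    The p-value is the total multivariate hypergeometric probability, with the
    observed margins fixed, of every table whose probability does not exceed
    that of the observed table (Freeman-Halton extension; a relative slack of
    1e-7 on the observed probability absorbs floating-point ties, matching the
    convention of common statistical software).  Tables in scope are small
    (here at most 3 x 2 with N = 60), so full enumeration is used.
    """
    table = np.asarray(table, dtype=np.int64)
    if table.ndim != 2 or np.any(table < 0) or table.sum() == 0:
        raise ValueError("table must be a non-negative 2D array with positive total")
    table = _drop_zero_margins(table)
    r, c = table.shape
    if r < 2 or c < 2:
        raise ValueError("table must be at least 2x2 after dropping zero margins")

    row = table.sum(axis=1)
    col = table.sum(axis=0)
    n = int(table.sum())
    lf = gammaln(np.arange(n + 1) + 1.0)
    log_const = lf[row].sum() + lf[col].sum() - lf[n]

    def log_prob(cells: np.ndarray) -> float:
        return float(log_const - lf[cells].sum())

    log_obs = log_prob(table.ravel())
    total = 0.0

    def recurse(i: int, col_rem: np.ndarray, acc: list[int]) -> None:
        nonlocal total
        if i == r - 1:
            lp = log_prob(np.array(acc + list(col_rem)))
            if lp <= log_obs + 1e-7:
                total += np.exp(lp)
            return
        # enumerate all compositions of row[i] over c cells bounded by col_rem
        for cells in itertools.product(*(range(min(int(row[i]), int(m)) + 1) for m in col_rem[:-1])):
            last = int(row[i]) - sum(cells)
            if 0 <= last <= col_rem[-1]:
                recurse(i + 1, col_rem - np.array(cells + (last,)), acc + list(cells) + [last])

    recurse(0, col.copy(), [])
    return float(min(total, 1.0))


def spearman_matrix(columns: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman rank correlation (average ranks for ties).

    Constant columns yield NaN entries and a warning.
    """
    df = pd.DataFrame(columns)
    if len(df) < 3:
        raise ValueError("need at least 3 subjects")
    constant = [c for c in df.columns if df[c].nunique() <= 1]
    if constant:
        warnings.warn(f"constant columns give undefined correlations: {constant}", stacklevel=2)
    ranks = np.column_stack([sps.rankdata(df[c].to_numpy()) for c in df.columns])
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.atleast_2d(np.corrcoef(ranks, rowvar=False))
    out = pd.DataFrame(rho, index=df.columns, columns=df.columns)
    np.fill_diagonal(out.values, 1.0)
    for c in constant:
        out.loc[c, :] = np.nan
        out.loc[:, c] = np.nan
    return out
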