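"""Independent reference implementations used to cross-check the package.

These deliberately re-derive results from first principles (full DP
matrices, row-by-row rule application, textbook closed forms) and share no
code with the implementation under test.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import betainc


def gotoh_local_score(
    a: str,
    b: str,
    score_fn,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> float:
    """Optimal local alignment score by the full affine-gap DP recurrence.

    A gap of length L costs ``gap_open + L * gap_extend``.  ``score_fn``
    maps a residue pair to its substitution score.
    """
    n, m = len(a), len(b)
    neg = -math.inf
    h = [[0.0] * (m + 1) for _ in range(n + 1)]
    e = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in a (along b)
    f = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in b (along a)
    best = 0.0
    first = gap_open + gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e[i][j] = max(h[i][j - 1] - first, e[i][j - 1] - gap_extend)
            f[i][j] = max(h[i - 1][j] - first, f[i - 1][j] - gap_extend)
            diag = h[i - 1][j - 1] + score_fn(a[i - 1], b[j - 1])
            h[i][j] = max(0.0, diag, e[i][j], f[i][j])
            best = max(best, h[i][j])
    return best


def de_status_by_rule(replicate_means, threshold: float = 1.0) -> str:
    """Literal application of the replicate-consistent threshold rule."""
    means = list(replicate_means)
    if any(m != m for m in means):
        return "not_evaluated"
    if all(m > threshold for m in means):
        return "up"
    if all(m < -threshold for m in means):
        return "down"
    return "unchanged"


def pooled_ttest_pvalue(x, y) -> float:
    """Two-sided pooled-variance Student's t-test from the textbook formula.

    t = (mean_x - mean_y) / (s_p * sqrt(1/n1 + 1/n2)) with the pooled SD
    s_p, and p = I_{df/(df+t^2)}(df/2, 1/2) via the regularized incomplete
    beta function.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    df = n1 + n2 - 2
    sp2 = (
        (n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)
    ) / df
    t = (x.mean() - y.mean()) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
    return float(betainc(df / 2.0, 0.5, df / (df + t * t)))


def fisher_oneway_f(groups) -> float:
    """One-way ANOVA F statistic from the sum-of-squares decomposition."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    k = len(groups)
    n_total = len(all_vals)
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    return (ss_between / (k - 1)) / (ss_within / (n_total - k))
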