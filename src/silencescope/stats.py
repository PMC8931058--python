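"""Rank-based statistical battery, implemented from first principles.

The per-cell metrics are compared exactly the way single-cell imaging studies
report them: one-tailed Mann–Whitney U for two-condition panels, Dunn's
multiple-comparison z tests (the Kruskal–Wallis post hoc) for time courses,
and Pearson correlation with a simple linear-regression line for single-cell
scatter plots.  Significance bands follow the ***/*/n.s. convention at
p < 0.001 / p < 0.05 / otherwise.

The Mann–Whitney p-value is exact — by enumeration of the rank-sum
distribution — for small tie-free samples (n_a + n_b ≤ 20), and otherwise
uses the normal approximation with tie and continuity corrections.  Dunn's z
for groups i, j over pooled ranks is::

    z_ij = (meanrank_i − meanrank_j) / sqrt((N(N+1)/12 − T) (1/n_i + 1/n_j))

with tie term ``T = Σ(t³ − t) / (12(N − 1))``, two-sided normal p, and
Bonferroni adjustment over the comparisons actually performed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata, norm


@dataclass
class TestResult:
    """One comparison's outcome; ``p_adjusted`` is set by multi-comparison
    procedures and is never smaller than ``p_value``."""

    __test__ = False  # not a pytest class despite the name

    method_name: str
    statistic: float
    p_value: float
    n_per_group: tuple[int, ...]
    alternative: str = "two_sided"
    p_adjusted: float | None = None
    comparison: tuple = ()

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")
        if self.p_adjusted is not None and self.p_adjusted < self.p_value - 1e-12:
            raise ValueError("adjusted p cannot be below the raw p")

    @property
    def band(self) -> str:
        return significance_band(self.p_adjusted if self.p_adjusted is not None
                                 else self.p_value)


def significance_band(p: float) -> str:
    """***, * or n.s. at the 0.001 / 0.05 thresholds."""
    if p < 0.001:
        return "***"
    if p < 0.05:
        return "*"
    return "n.s."


# ---------------------------------------------------------------------------
# Mann–Whitney U
# ---------------------------------------------------------------------------

def _exact_u_sf(n1: int, n2: int) -> np.ndarray:
    """Null distribution of U for sample sizes (n1, n2) without ties.

    Returns the array of counts c[u] = number of arrangements with U = u,
    computed by the classical recurrence over ranks (equivalently, the
    number of ways to place n1 items among n1 + n2 with u inversions against
    the other sample).
    """
    # c[k][u]: ways to choose k ranks from the first m with U-contribution u
    max_u = n1 * n2
    c = np.zeros((n1 + 1, max_u + 1), dtype=float)
    c[0, 0] = 1.0
    for m in range(1, n1 + n2 + 1):
        # adding rank m: if taken as sample-1, it beats (m - 1 - k_prev) sample-2 ranks
        new = c.copy()
        for k in range(min(m, n1), 0, -1):
            shift = m - k  # number of sample-2 ranks below this one
            if shift > max_u:
                continue
            new[k, shift:] = c[k, shift:] + c[k - 1, : max_u + 1 - shift]
            new[k, :shift] = c[k, :shift]
        c = new
    return c[n1]


def mann_whitney_one_tailed(a, b, alternative: str = "greater") -> TestResult:
    """Mann–Whitney U test of sample ``a`` against sample ``b``.

    ``alternative='greater'`` tests whether values in ``a`` tend to exceed
    those in ``b`` (and symmetrically for ``'less'``); ``'two_sided'`` doubles
    the smaller tail.  Exact enumeration is used when n_a + n_b ≤ 20 and the
    pooled data are tie-free; otherwise the normal approximation with tie and
    continuity corrections.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if alternative not in ("greater", "less", "two_sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0  # number of (a, b) pairs with a > b (+ ties/2)
    u2 = n1 * n2 - u1

    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = np.any(tie_counts > 1)

    if n1 + n2 <= 20 and not has_ties:
        counts = _exact_u_sf(n1, n2)
        total = counts.sum()
        sf = np.cumsum(counts[::-1])[::-1] / total  # P(U >= u)
        p_greater = float(sf[int(round(u1))])
        p_less = float(sf[int(round(u2))])
        method = "mann-whitney-exact"
    else:
        mu = n1 * n2 / 2.0
        n = n1 + n2
        tie_term = (tie_counts ** 3 - tie_counts).sum() / (n * (n - 1))
        sigma = np.sqrt(n1 * n2 / 12.0 * ((n + 1) - tie_term))
        if sigma == 0:
            p_greater = p_less = 0.5
        else:
            p_greater = float(norm.sf((u1 - mu - 0.5) / sigma))
            p_less = float(norm.sf((u2 - mu - 0.5) / sigma))
        method = "mann-whitney-normal"

    if alternative == "greater":
        p = p_greater
    elif alternative == "less":
        p = p_less
    else:
        p = min(1.0, 2.0 * min(p_greater, p_less))
    return TestResult(method_name=method, statistic=float(u1),
                      p_value=min(max(p, 0.0), 1.0), n_per_group=(n1, n2),
                      alternative=alternative)


# ---------------------------------------------------------------------------
# Dunn's multiple comparisons
# ---------------------------------------------------------------------------

def dunn_test(groups: list, adjust: str = "bonferroni",
              pairs: list[tuple[int, int]] | None = None) -> list[TestResult]:
    """Dunn's post hoc z tests on pooled ranks.

    ``groups`` is a list of samples; ``pairs`` restricts the comparisons
    performed (0-based group indices; default all pairs), and the Bonferroni
    factor counts only the comparisons performed.  Two-sided p-values.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size == 0 for g in groups):
        raise ValueError("every group must be non-empty")
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    import warnings as _warnings
    if len(groups) == 2:
        _warnings.warn("Dunn's test with only two groups; consider Mann-Whitney",
                       stacklevel=2)
    pooled = np.concatenate(groups)
    n_tot = pooled.size
    ranks = rankdata(pooled)
    sizes = [g.size for g in groups]
    mean_ranks = []
    start = 0
    for s in sizes:
        mean_ranks.append(ranks[start:start + s].mean())
        start += s
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts ** 3 - tie_counts).sum() / (12.0 * (n_tot - 1))
    base_var = n_tot * (n_tot + 1) / 12.0 - tie_term

    if pairs is None:
        pairs = [(i, j) for i in range(len(groups)) for j in range(i + 1, len(groups))]
    m = len(pairs)
    if adjust not in ("bonferroni", "none"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    results = []
    for i, j in pairs:
        se = np.sqrt(base_var * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p = float(2.0 * norm.sf(abs(z)))
        p_adj = min(1.0, m * p) if adjust == "bonferroni" else p
        results.append(TestResult(
            method_name="dunn", statistic=float(z), p_value=min(p, 1.0),
            n_per_group=(sizes[i], sizes[j]), alternative="two_sided",
            p_adjusted=p_adj, comparison=(i, j)))
    return results


# ---------------------------------------------------------------------------
# correlation / regression / paired t
# ---------------------------------------------------------------------------

def pearson_with_fit(x, y) -> tuple[float, float, float]:
    """Product-moment correlation r plus the least-squares line (slope,
    intercept).  Raises on fewer than 3 points, non-finite values, or zero
    variance in x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need matched samples with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("values must be finite")
    dx = x - x.mean()
    dy = y - y.mean()
    sxx = float((dx * dx).sum())
    syy = float((dy * dy).sum())
    sxy = float((dx * dy).sum())
    if sxx == 0:
        raise ValueError("zero variance in x")
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    r = sxy / np.sqrt(sxx * syy) if syy > 0 else 0.0
    return float(r), float(slope), intercept


def paired_t_one_tailed(a, b, alternative: str = "greater") -> TestResult:
    """Thin utility: one-tailed paired t-test on matched samples."""
    from scipy.stats import ttest_rel
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    res = ttest_rel(a, b, alternative={"two_sided": "two-sided"}.get(alternative, alternative))
    return TestResult(method_name="paired-t", statistic=float(res.statistic),
                      p_value=float(res.pvalue), n_per_group=(a.size, b.size),
                      alternative=alternative)
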