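"""Shared nonparametric statistical machinery.

All group comparisons in this package are rank-based: Kruskal-Wallis for
k-group firing-rate comparisons, two-sample Kolmogorov-Smirnov for
distribution shapes, Spearman rank correlation for monotone association.
Multiple comparisons across units are corrected with the Holm step-down
procedure at alpha = 0.001, the convention adopted throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

#: Default family-wise significance level for per-unit tests.
DEFAULT_ALPHA = 0.001

#: Sentinel for statistics that are undefined on the given input
#: (too few samples, constant data, empty class).
UNDEFINED = float("nan")


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    n: tuple[int, ...]
    method: str


def kruskal_wallis(*groups, permutation: int | None = None, seed: int | None = None) -> TestResult:
    """Kruskal-Wallis H test on two or more value sequences.

    The H statistic uses average ranks with tie correction; the p-value comes
    from the chi-square approximation (df = k - 1). ``permutation`` switches to
    a seeded label-permutation p-value (for very small groups where the
    chi-square approximation is poor).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("empty group")
    h, p = sps.kruskal(*groups)
    if permutation is not None:
        if seed is None:
            raise ValueError("permutation p-value requires an explicit seed")
        rng = np.random.default_rng(seed)
        pooled = np.concatenate(groups)
        sizes = [g.size for g in groups]
        edges = np.cumsum(sizes)[:-1]
        count = 0
        for _ in range(permutation):
            perm = rng.permutation(pooled)
            h_perm, _ = sps.kruskal(*np.split(perm, edges))
            if h_perm >= h:
                count += 1
        p = (count + 1) / (permutation + 1)
        method = "kruskal-wallis (permutation)"
    else:
        method = "kruskal-wallis (chi2)"
    return TestResult(float(h), float(p), tuple(g.size for g in groups), method)


def ks_two_sample(x, y) -> TestResult:
    """Two-sample Kolmogorov-Smirnov test, D = sup |ECDF_x - ECDF_y|."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty input")
    res = sps.ks_2samp(x, y, method="asymp")
    return TestResult(float(res.statistic), float(res.pvalue), (x.size, y.size), "ks-2samp")


def spearman(
    x, y, *, n_permutations: int = 10_000, seed: int | None = None, small_n: int = 20
) -> TestResult:
    """Spearman rank correlation with average ranks for ties.

    For n > ``small_n`` the two-sided p-value uses the large-sample t
    approximation; for smaller n it is estimated by seeded permutation of one
    variable (``n_permutations`` draws), since the t approximation is
    unreliable there. Constant input yields an undefined (NaN) statistic.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must be paired")
    n = x.size
    if n < 3 or np.all(x == x[0]) or np.all(y == y[0]):
        return TestResult(UNDEFINED, UNDEFINED, (n,), "spearman (undefined)")
    rho, p = sps.spearmanr(x, y)
    if n <= small_n:
        if seed is None:
            raise ValueError("permutation p-value requires an explicit seed")
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_permutations):
            r_perm, _ = sps.spearmanr(x, rng.permutation(y))
            if abs(r_perm) >= abs(rho) - 1e-12:
                count += 1
        p = (count + 1) / (n_permutations + 1)
        method = "spearman (permutation)"
    else:
        method = "spearman (t-approx)"
    return TestResult(float(rho), float(p), (n,), method)


def holm_bonferroni(p_values, alpha: float = DEFAULT_ALPHA):
    """Holm step-down correction.

    Sort p-values ascending and reject p_(i) while
    p_(i) <= alpha / (m - i + 1); adjusted p-values are the running maximum of
    (m - i + 1) * p_(i), capped at 1. Returns ``(flags, adjusted)`` in the
    input order. NaN entries are never rejected and do not count toward m.
    """
    p = np.asarray(p_values, dtype=float)
    valid = ~np.isnan(p)
    if np.any((p[valid] < 0) | (p[valid] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    flags = np.zeros(p.shape, dtype=bool)
    adjusted = np.full(p.shape, np.nan)
    m = int(valid.sum())
    if m == 0:
        return flags, adjusted
    idx = np.flatnonzero(valid)[np.argsort(p[valid], kind="stable")]
    running = 0.0
    still_rejecting = True
    for i, j in enumerate(idx):
        factor = m - i
        adj = min(1.0, factor * p[j])
        running = max(running, adj)
        adjusted[j] = running
        if still_rejecting and p[j] <= alpha / factor:
            flags[j] = True
        else:
            still_rejecting = False
    return flags, adjusted
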