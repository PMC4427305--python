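"""Univariate statistics, correlations and the undetected-diversity estimate.

Environmental variables come as per-group summaries (mean, SD, n), so the
t-test supports both raw-value and summary entry. Variance homogeneity is
checked with the Brown-Forsythe variant of Levene's test (deviations from
group medians); when it rejects, Welch's t is the fallback. For variables
violating normality the Mann-Whitney U test is used, with an exact
enumeration p-value for small samples (midranks for ties) and a
tie-corrected normal approximation otherwise.

The undetected-diversity estimate extrapolates how many functional-gene
OTUs a primer set missed: if the detected OTUs all fall in lineages making
up a fraction ``f_det`` of total community diversity, and other lineages
known to harbour the gene make up ``f_other``, then under a stable
denitrifier/non-denitrifier ratio across lineages the undetected count is
``U = D * f_other / f_det``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass
class GroupSummary:
    """Mean/SD/n of one variable in one group (as printed in survey tables)."""

    group: str
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group summaries need n >= 2")
        if self.sd < 0:
            raise ValueError("SD must be non-negative")

    @classmethod
    def from_values(cls, group: str, values) -> "GroupSummary":
        v = np.asarray(values, dtype=float)
        return cls(group, len(v), float(v.mean()), float(v.std(ddof=1)))


@dataclass
class TestResult:
    statistic: float
    p_value: float
    df: float | None = None
    method: str = ""


def _as_summary(x, name: str) -> GroupSummary:
    if isinstance(x, GroupSummary):
        return x
    return GroupSummary.from_values(name, x)


def t_test(a, b, mode: str = "pooled") -> TestResult:
    """Two-sided two-sample t-test from raw values or GroupSummary objects.

    ``pooled`` is the classic equal-variance Student's t; ``welch`` drops
    that assumption. Zero variance in both groups with equal means returns
    t = 0, p = 1.
    """
    sa, sb = _as_summary(a, "A"), _as_summary(b, "B")
    if sa.sd == 0 and sb.sd == 0:
        if sa.mean == sb.mean:
            return TestResult(0.0, 1.0, sa.n + sb.n - 2, mode)
        return TestResult(np.inf if sa.mean > sb.mean else -np.inf, 0.0, None, mode)
    res = sps.ttest_ind_from_stats(
        sa.mean, sa.sd, sa.n, sb.mean, sb.sd, sb.n, equal_var=(mode == "pooled")
    )
    if mode == "pooled":
        df = sa.n + sb.n - 2
    else:
        va, vb = sa.sd**2 / sa.n, sb.sd**2 / sb.n
        df = (va + vb) ** 2 / (va**2 / (sa.n - 1) + vb**2 / (sb.n - 1))
    return TestResult(float(res.statistic), float(res.pvalue), float(df), mode)


def t_test_gated(a_values, b_values, alpha: float = 0.05) -> TestResult:
    """Pooled t by default; Welch when a Levene pre-test rejects at alpha."""
    lev = levene(a_values, b_values)
    mode = "welch" if lev.p_value < alpha else "pooled"
    return t_test(a_values, b_values, mode=mode)


def levene(*groups) -> TestResult:
    """Brown-Forsythe test (Levene with deviations from group medians)."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    for g in arrays:
        if len(g) < 2:
            raise ValueError("each group needs at least 2 observations")
    if np.ptp(np.concatenate(arrays)) == 0:
        return TestResult(0.0, 1.0, None, "brown-forsythe")
    w, p = sps.levene(*arrays, center="median")
    return TestResult(float(w), float(p), None, "brown-forsythe")


# ---------------------------------------------------------------------------
# Mann-Whitney U

EXACT_LIMIT = 16  # exact enumeration up to this combined sample size


def _u_from_ranks(rank_sum_a: float, n_a: int) -> float:
    return rank_sum_a - n_a * (n_a + 1) / 2.0


def mann_whitney_u(a, b) -> TestResult:
    """Two-sided Mann-Whitney U with midrank ties.

    Exact p by complete enumeration of rank assignments when
    n_a + n_b <= 16, otherwise the tie-corrected normal approximation
    (with continuity correction).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty group")
    na, nb = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    u_a = _u_from_ranks(ranks[:na].sum(), na)
    mu = na * nb / 2.0

    if na + nb <= EXACT_LIMIT:
        # enumerate every way the pooled midranks split between the groups
        obs_dev = abs(u_a - mu)
        total = hits = 0
        idx = range(na + nb)
        for comb in itertools.combinations(idx, na):
            rs = ranks[list(comb)].sum()
            u = _u_from_ranks(rs, na)
            total += 1
            if abs(u - mu) >= obs_dev - 1e-12:
                hits += 1
        return TestResult(float(u_a), hits / total, None, "exact-enumeration")

    # normal approximation with tie correction
    n = na + nb
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (n * (n - 1))
    var = na * nb / 12.0 * (n + 1 - tie_term)
    if var == 0:
        return TestResult(float(u_a), 1.0, None, "normal-approx")
    z = (abs(u_a - mu) - 0.5) / np.sqrt(var)
    p = min(1.0, 2.0 * sps.norm.sf(max(z, 0.0)))
    return TestResult(float(u_a), float(p), None, "normal-approx")


def correlation(x, y, method: str = "pearson") -> TestResult:
    """Pearson product-moment or Spearman rank correlation with its p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need matched vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a zero-variance vector")
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    elif method == "spearman":
        r, p = sps.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return TestResult(float(r), float(p), float(len(x) - 2), method)


# ---------------------------------------------------------------------------
# undetected functional diversity

@dataclass
class UndetectedEstimate:
    detected: int
    f_detected: float
    f_other: float
    undetected: float
    detected_share: float


def undetected_diversity(detected: int, f_detected: float, f_other: float) -> UndetectedEstimate:
    """Stable-ratio extrapolation of primer-missed functional OTUs.

    U = D * f_other / f_detected; the detected share of the guild is then
    D / (D + U). Example: 60 detected nirK OTUs confined to lineages
    holding 6% of community diversity, with other nirK-bearing lineages at
    12%, imply 120 undetected OTUs — only a third of the guild was seen.
    """
    if detected < 0:
        raise ValueError("detected OTU count must be >= 0")
    for name, f in (("f_detected", f_detected), ("f_other", f_other)):
        if not 0 < f <= 1:
            raise ValueError(f"{name} must lie in (0, 1]")
    u = detected * f_other / f_detected
    share = detected / (detected + u) if detected + u > 0 else 1.0
    return UndetectedEstimate(detected, f_detected, f_other, u, share)
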