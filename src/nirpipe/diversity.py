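"""Alpha diversity, rarefaction and sample summaries.

Estimators follow the mothur conventions used in amplicon surveys:

* Good's coverage: ``100 * (1 - singletons/N)``;
* Chao1 richness in the bias-corrected form
  ``S_obs + n1*(n1-1) / (2*(n2+1))`` (defined even when doubletons are
  absent), with a log-normal 95% CI on the estimated excess;
* inverse Simpson ``1/D`` with ``D = sum n_i*(n_i-1) / (N*(N-1))`` and a
  delta-method CI;
* analytical (hypergeometric) rarefaction, no resampling.

Also here: the abundant (>1% relative abundance, strict) vs non-abundant
OTU partition, Venn region counts for 2-3 units, and the per-sample
summary rows / phylum percentage tables used in reporting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.special import gammaln

from .io import CountTable

Z95 = 1.959963984540054


def _counts_array(counts: Sequence[int]) -> np.ndarray:
    c = np.asarray(counts, dtype=float)
    if np.any(c < 0):
        raise ValueError("negative counts")
    return c[c > 0]


def goods_coverage(counts: Sequence[int]) -> float:
    """Percent probability that the next read belongs to an already-seen OTU."""
    c = _counts_array(counts)
    n = c.sum()
    if n < 1:
        raise ValueError("coverage undefined for an empty sample")
    singletons = int((c == 1).sum())
    return 100.0 * (1.0 - singletons / n)


def chao1(counts: Sequence[int]) -> tuple[float, tuple[float, float]]:
    """Bias-corrected Chao1 estimate with a log-normal 95% CI.

    With no singletons the estimate equals the observed richness and the
    CI degenerates to [S_obs, S_obs].
    """
    c = _counts_array(counts)
    if c.sum() < 1:
        raise ValueError("chao1 undefined for an empty sample")
    s_obs = len(c)
    n1 = int((c == 1).sum())
    n2 = int((c == 2).sum())
    est = s_obs + n1 * (n1 - 1) / (2.0 * (n2 + 1))
    t = est - s_obs
    if t <= 0:
        return float(est), (float(s_obs), float(s_obs))
    # variance of the bias-corrected estimator (Chao 1987 / mothur)
    var = (
        n1 * (n1 - 1) / (2.0 * (n2 + 1))
        + n1 * (2 * n1 - 1) ** 2 / (4.0 * (n2 + 1) ** 2)
        + n1 ** 2 * n2 * (n1 - 1) ** 2 / (4.0 * (n2 + 1) ** 4)
    )
    k = np.exp(Z95 * np.sqrt(np.log(1.0 + var / t ** 2)))
    return float(est), (float(s_obs + t / k), float(s_obs + t * k))


def inverse_simpson(counts: Sequence[int]) -> tuple[float, tuple[float, float]]:
    """1/D with D the unbiased Simpson concentration; delta-method 95% CI."""
    c = _counts_array(counts)
    n = c.sum()
    if n < 2:
        raise ValueError("inverse Simpson needs at least 2 reads")
    d = float((c * (c - 1)).sum() / (n * (n - 1)))
    if d == 0:
        raise ValueError("inverse Simpson undefined: every read is a singleton")
    inv = 1.0 / d
    p = c / n
    var_d = 4.0 / n * float((p ** 3).sum() - (p ** 2).sum() ** 2)
    half = Z95 * np.sqrt(max(var_d, 0.0)) / d ** 2
    return inv, (inv - half, inv + half)


def rarefaction_point(counts: Sequence[int], n: int) -> float:
    """Expected number of OTUs in a random subsample of n reads.

    E[S_n] = sum_i [1 - C(N - n_i, n) / C(N, n)], the exact hypergeometric
    expectation (computed with log-gammas for numerical range).
    """
    c = _counts_array(counts)
    total = int(c.sum())
    if not 1 <= n <= total:
        raise ValueError(f"subsample size {n} outside [1, {total}]")

    def logcomb(a: float, b: float) -> float:
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    denom = logcomb(total, n)
    s = 0.0
    for ni in c:
        if total - ni < n:
            s += 1.0
        else:
            s += 1.0 - np.exp(logcomb(total - ni, n) - denom)
    return float(s)


def rarefaction_curve(counts: Sequence[int], points: Sequence[int]) -> list[tuple[int, float]]:
    return [(n, rarefaction_point(counts, n)) for n in points]


# ---------------------------------------------------------------------------
# abundance partition and Venn regions

def partition_abundance(
    table: CountTable, threshold: float = 0.01
) -> dict[str, tuple[set[str], set[str]]]:
    """Per-sample split into abundant (> threshold, strict) and non-abundant OTUs.

    Only OTUs present in a sample are partitioned; an OTU at exactly the
    threshold is non-abundant.
    """
    out: dict[str, tuple[set[str], set[str]]] = {}
    for sample in table.sample_ids:
        col = table.data[sample]
        total = int(col.sum())
        if total <= 0:
            raise ValueError(f"sample {sample!r} has zero total count")
        present = col[col > 0]
        abundant = set(present[present / total > threshold].index)
        out[sample] = (abundant, set(present.index) - abundant)
    return out


def venn_counts(sets: Mapping[str, set]) -> dict:
    """Inclusion-exclusion region counts for 2 or 3 labelled units.

    Returns region counts keyed by sorted '&'-joined unit names, plus per-
    unit unique/shared percentages (relative to each unit's own total).
    """
    names = list(sets)
    if len(names) not in (2, 3):
        raise ValueError("venn_counts supports 2 or 3 units")
    regions: dict[str, int] = {}
    universe = set().union(*sets.values())
    for x in universe:
        member = frozenset(n for n in names if x in sets[n])
        key = "&".join(sorted(member))
        regions[key] = regions.get(key, 0) + 1
    summary = {}
    for n in names:
        total = len(sets[n])
        unique = regions.get(n, 0)
        shared = total - unique
        summary[n] = {
            "total": total,
            "unique": unique,
            "shared": shared,
            "unique_pct": round(100.0 * unique / total, 2) if total else 0.0,
            "shared_pct": round(100.0 * shared / total, 2) if total else 0.0,
        }
    return {"regions": regions, "units": summary}


# ---------------------------------------------------------------------------
# summaries

def observed_estimated_ratio(observed: int, estimated: float) -> float:
    """Observed/estimated richness ratio, reported to 2 decimals."""
    if estimated <= 0:
        raise ValueError("estimated richness must be positive")
    return round(observed / estimated, 2)


@dataclass
class AlphaSummary:
    sample: str
    n_sequences: int
    coverage: float
    observed: int
    abundant: int
    non_abundant: int
    chao1: float
    chao1_ci: tuple[float, float]
    ratio: float
    inverse_simpson: float
    inverse_simpson_ci: tuple[float, float]

    def row(self) -> dict:
        return {
            "sample": self.sample,
            "n_sequences": self.n_sequences,
            "coverage_pct": round(self.coverage, 2),
            "observed_otus": self.observed,
            "abundant": self.abundant,
            "non_abundant": self.non_abundant,
            "chao1": round(self.chao1, 1),
            "chao1_lci": round(self.chao1_ci[0], 1),
            "chao1_uci": round(self.chao1_ci[1], 1),
            "obs_est_ratio": self.ratio,
            "inv_simpson": round(self.inverse_simpson, 2),
            "inv_simpson_lci": round(self.inverse_simpson_ci[0], 2),
            "inv_simpson_uci": round(self.inverse_simpson_ci[1], 2),
        }


def summarize_sample(
    table: CountTable, sample: str, abundance_threshold: float = 0.01
) -> AlphaSummary:
    col = table.data[sample]
    counts = [int(x) for x in col[col > 0]]
    est, ci = chao1(counts)
    inv, inv_ci = inverse_simpson(counts)
    ab, nab = partition_abundance(table, abundance_threshold)[sample]
    return AlphaSummary(
        sample=sample,
        n_sequences=int(sum(counts)),
        coverage=goods_coverage(counts),
        observed=len(counts),
        abundant=len(ab),
        non_abundant=len(nab),
        chao1=est,
        chao1_ci=ci,
        ratio=observed_estimated_ratio(len(counts), est),
        inverse_simpson=inv,
        inverse_simpson_ci=inv_ci,
    )


def phylum_distribution(
    taxonomy: Mapping[str, str], otu_sets: Mapping[str, set]
) -> dict[str, dict[str, tuple[float, int]]]:
    """Percent (and count) of OTUs per phylum within each unit.

    ``taxonomy`` maps OTU id -> phylum label ('Unclassified' allowed);
    percentages are rounded to 2 decimals and computed against the unit's
    total OTU count.
    """
    out: dict[str, dict[str, tuple[float, int]]] = {}
    for unit, otus in otu_sets.items():
        missing = [o for o in otus if o not in taxonomy]
        if missing:
            raise ValueError(f"OTUs without a taxon label: {missing[:5]}")
        total = len(otus)
        counts: dict[str, int] = {}
        for o in otus:
            counts[taxonomy[o]] = counts.get(taxonomy[o], 0) + 1
        out[unit] = {
            ph: (round(100.0 * k / total, 2), k) for ph, k in sorted(counts.items())
        }
    return out
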