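"""Beta diversity between sediment types and the permutation test.

Community membership is compared with the Jaccard dissimilarity on OTU
presence sets, community structure with Bray-Curtis on relative
abundances. Group-level values are computed on replicate-pooled counts
(one value per pair of groups); per-replicate distance matrices feed a
one-way PERMANOVA whose pseudo-F follows Anderson's partitioning of
squared distances and whose p-value comes from unrestricted label
permutations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import CountTable, DistanceMatrix
from .diversity import partition_abundance


def jaccard_dissimilarity(a: set, b: set) -> float:
    """1 - |A n B| / |A u B| on OTU id sets."""
    union = a | b
    if not union:
        raise ValueError("Jaccard undefined for two empty sets")
    return 1.0 - len(a & b) / len(union)


def bray_curtis(x: Sequence[float], y: Sequence[float]) -> float:
    """Bray-Curtis dissimilarity on relative abundances over a shared universe."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("count vectors must align on the same OTU universe")
    if x.sum() <= 0 or y.sum() <= 0:
        raise ValueError("zero total count in a sample")
    px, py = x / x.sum(), y / y.sum()
    return float(np.abs(px - py).sum() / (px + py).sum())


def pool_groups(table: CountTable, groups: Mapping[str, str]) -> CountTable:
    """Sum replicate columns into one column per group label."""
    unknown = [s for s in table.sample_ids if s not in groups]
    if unknown:
        raise ValueError(f"samples without a group label: {unknown}")
    df = table.data.T.groupby([groups[s] for s in table.sample_ids]).sum().T
    return CountTable(df)


def sample_distance_matrix(table: CountTable, metric: str = "braycurtis") -> DistanceMatrix:
    """Pairwise Bray-Curtis (or Jaccard) distances between sample columns."""
    samples = table.sample_ids
    n = len(samples)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if metric == "braycurtis":
                d = bray_curtis(table.data[samples[i]], table.data[samples[j]])
            elif metric == "jaccard":
                ci = table.data[samples[i]]
                cj = table.data[samples[j]]
                d = jaccard_dissimilarity(
                    set(ci[ci > 0].index), set(cj[cj > 0].index)
                )
            else:
                raise ValueError(f"unknown metric {metric!r}")
            values[i, j] = values[j, i] = d
    return DistanceMatrix(samples, values)


# ---------------------------------------------------------------------------
# PERMANOVA

@dataclass
class PermanovaResult:
    pseudo_f: float
    p_value: float
    n_permutations: int
    ss_total: float
    ss_within: float
    warning: str | None = None


def _pseudo_f(d2: np.ndarray, labels: np.ndarray) -> float:
    """Anderson's pseudo-F from squared distances and a label vector."""
    n = len(labels)
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    groups = np.unique(labels)
    for g in groups:
        idx = np.flatnonzero(labels == g)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    a = len(groups)
    ss_between = ss_total - ss_within
    if ss_within <= 0:
        return 0.0 if ss_between <= 0 else np.inf
    return (ss_between / (a - 1)) / (ss_within / (n - a))


def permanova(
    dm: DistanceMatrix,
    labels: Mapping[str, str] | Sequence[str],
    n_permutations: int = 9999,
    seed: int | np.random.Generator = 0,
) -> PermanovaResult:
    """One-way PERMANOVA on a sample distance matrix.

    p = (1 + #{permuted F >= observed F}) / (1 + n_permutations), with
    unrestricted permutations of the raw labels. A group of size 1 is
    allowed but flagged as low-power.
    """
    if isinstance(labels, Mapping):
        lab = np.array([labels[s] for s in dm.ids])
    else:
        lab = np.asarray(list(labels))
    if len(lab) != len(dm):
        raise ValueError("label count does not match distance matrix")
    groups, counts = np.unique(lab, return_counts=True)
    if len(groups) < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    warning = None
    if counts.min() < 2:
        warning = "a group has fewer than 2 samples; test has low power"

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    d2 = dm.values ** 2
    n = len(lab)
    ss_total = float(d2[np.triu_indices(n, k=1)].sum() / n)
    f_obs = _pseudo_f(d2, lab)
    if ss_total == 0:
        return PermanovaResult(0.0, 1.0, n_permutations, 0.0, 0.0, warning)

    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(lab)
        if _pseudo_f(d2, perm) >= f_obs:
            hits += 1
    p = (1 + hits) / (1 + n_permutations)
    ssw = 0.0
    for g in groups:
        idx = np.flatnonzero(lab == g)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ssw += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    return PermanovaResult(float(f_obs), float(p), n_permutations, ss_total, float(ssw), warning)


# ---------------------------------------------------------------------------
# the three-level beta table (all / abundant / non-abundant)

def beta_table(
    table: CountTable,
    groups: Mapping[str, str],
    abundance_threshold: float = 0.01,
    n_permutations: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Jaccard/Bray-Curtis between pooled groups at three abundance levels.

    Levels: all OTUs, abundant (> threshold in a pooled group, union over
    groups) and non-abundant (the complement within the observed universe).
    PERMANOVA runs on per-replicate Bray-Curtis matrices at each level.
    """
    pooled = pool_groups(table, groups)
    if len(pooled.sample_ids) != 2:
        raise ValueError("beta_table compares exactly two groups")
    g1, g2 = pooled.sample_ids
    parts = partition_abundance(pooled, abundance_threshold)
    abundant_union = parts[g1][0] | parts[g2][0]
    universe = set(pooled.data.index[pooled.totals() > 0])
    levels = {
        "all": universe,
        "abundant": abundant_union,
        "non_abundant": universe - abundant_union,
    }

    rows = []
    for level, otus in levels.items():
        sel = [o for o in pooled.data.index if o in otus]
        if not sel:
            rows.append({"level": level, "jaccard": np.nan, "bray_curtis": np.nan,
                         "pseudo_F": np.nan, "p_value": np.nan,
                         "n_permutations": 0})
            continue
        sub = pooled.data.loc[sel]
        c1, c2 = sub[g1], sub[g2]
        jac = jaccard_dissimilarity(set(c1[c1 > 0].index), set(c2[c2 > 0].index))
        bc = bray_curtis(c1.to_numpy(), c2.to_numpy())
        rep = CountTable(table.data.loc[sel])
        dm = sample_distance_matrix(rep, "braycurtis")
        res = permanova(dm, groups, n_permutations, seed)
        rows.append(
            {
                "level": level,
                "jaccard": round(jac, 6),
                "bray_curtis": round(bc, 6),
                "pseudo_F": round(res.pseudo_f, 4),
                "p_value": res.p_value,
                "n_permutations": res.n_permutations,
            }
        )
    return pd.DataFrame(rows).set_index("level")
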