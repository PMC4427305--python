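"""Pairwise distances, OTU clustering and functional cutoff calibration.

Distances follow the mothur convention: pairwise global alignment, then
distance = (mismatches + internal gap events) / (columns where both
sequences have a base), with terminal gaps ignored and a contiguous gap
run counting as a single event. Clustering is agglomerative with
average linkage (mothur's historical "average neighbor") by default.

For the coding nir genes the OTU cutoff is not fixed a priori: a grid of
nucleotide distances (5-20%) is scanned and the chosen cutoff is the
smallest at which every OTU representative translates to a unique protein,
so that OTUs track functional (protein-level) diversity rather than
synonymous variation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import edlib
import numpy as np
import pandas as pd
from Bio import Align
from scipy.cluster.hierarchy import linkage, fcluster

from .io import CountTable, DistanceMatrix, Read
from .frameshift import translate
from .preprocess import IUPAC, _iter_cigar

_NT_VALID = set(IUPAC) | {"-", "."}


def _check_alphabet(seq: str, sid: str) -> None:
    bad = set(seq.upper()) - _NT_VALID
    if bad:
        raise ValueError(f"sequence {sid!r} contains non-IUPAC characters {sorted(bad)}")


def _nt_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1
    a.mismatch_score = -1
    a.open_gap_score = -2
    a.extend_gap_score = -1
    return a


_ALIGNER = _nt_aligner()


def align_pair(a: str, b: str, engine: str = "needleman") -> tuple[str, str]:
    """Globally align two sequences; returns the two gapped strings.

    ``needleman`` uses the match 1 / mismatch -1 / gap open -2 / extend -1
    scoring; ``edlib`` uses unit-cost edit distance (much faster, near
    identical alignments for closely related amplicons).
    """
    if engine == "needleman":
        aln = _ALIGNER.align(a, b)[0]
        return str(aln[0]), str(aln[1])
    if engine == "edlib":
        res = edlib.align(a, b, task="path", mode="NW")
        ga, gb = [], []
        pa = pb = 0
        for length, op in _iter_cigar(res["cigar"]):
            if op in ("=", "X"):
                ga.append(a[pa:pa + length]); gb.append(b[pb:pb + length])
                pa += length; pb += length
            elif op == "I":  # present in a only
                ga.append(a[pa:pa + length]); gb.append("-" * length)
                pa += length
            elif op == "D":  # present in b only
                ga.append("-" * length); gb.append(b[pb:pb + length])
                pb += length
        return "".join(ga), "".join(gb)
    raise ValueError(f"unknown alignment engine {engine!r}")


def distance_from_alignment(ga: str, gb: str) -> float:
    """Distance from a gapped pair: (mismatches + gap events) / compared columns.

    Terminal gap columns are excluded; a contiguous internal gap run counts
    once; the denominator counts columns where both sequences have a base.
    """
    start = max(len(ga) - len(ga.lstrip("-")), len(gb) - len(gb.lstrip("-")))
    end = min(len(ga.rstrip("-")), len(gb.rstrip("-")))
    mism = compared = 0
    gap_events = 0
    in_gap_a = in_gap_b = False
    for k in range(start, end):
        x, y = ga[k], gb[k]
        if x == "-":
            if not in_gap_a:
                gap_events += 1
            in_gap_a = True
        else:
            in_gap_a = False
        if y == "-":
            if not in_gap_b:
                gap_events += 1
            in_gap_b = True
        else:
            in_gap_b = False
        if x != "-" and y != "-":
            compared += 1
            if x != y:
                mism += 1
    if compared == 0:
        return 1.0
    return min(1.0, (mism + gap_events) / compared)


#: pairs whose coarse edit-distance ratio exceeds this are reported as that
#: ratio without an exact alignment; they sit far above any clustering
#: cutoff (grid maximum 0.20), where only their magnitude matters
EXACT_DISTANCE_CEILING = 0.35


def _edlib_distance(a: str, b: str) -> float:
    """Distance under the same convention, read directly off the edlib CIGAR.

    A cheap edit-distance pass screens each pair first; only pairs that
    could matter for clustering (coarse ratio <= EXACT_DISTANCE_CEILING)
    get the exact CIGAR treatment. Each CIGAR run maps to: '='/'X' ->
    compared columns (X are mismatches); 'I'/'D' -> one gap event per run,
    terminal runs ignored.
    """
    ed = edlib.align(a, b, mode="NW")["editDistance"]
    coarse = ed / min(len(a), len(b))
    if coarse > EXACT_DISTANCE_CEILING:
        return min(1.0, coarse)
    ops = list(_iter_cigar(edlib.align(a, b, task="path", mode="NW")["cigar"]))
    if ops and ops[0][1] in "ID":
        ops = ops[1:]
    if ops and ops[-1][1] in "ID":
        ops = ops[:-1]
    mism = compared = gap_events = 0
    for length, op in ops:
        if op == "=":
            compared += length
        elif op == "X":
            compared += length
            mism += length
        else:
            gap_events += 1
    if compared == 0:
        return 1.0
    return min(1.0, (mism + gap_events) / compared)


def pairwise_distance(
    ids: Sequence[str], seqs: Sequence[str], engine: str = "needleman"
) -> DistanceMatrix:
    """All-pairs distances over sequences (see module docstring for the convention)."""
    if len(ids) < 2:
        raise ValueError("need at least 2 sequences")
    for sid, s in zip(ids, seqs):
        _check_alphabet(s, sid)
    n = len(ids)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if seqs[i] == seqs[j]:
                continue
            if engine == "edlib":
                d = _edlib_distance(seqs[i], seqs[j])
            else:
                d = distance_from_alignment(*align_pair(seqs[i], seqs[j], engine))
            values[i, j] = values[j, i] = d
    return DistanceMatrix(ids, values)


# ---------------------------------------------------------------------------
# dereplication and abundance-greedy preclustering

def dereplicate(reads: Sequence[Read]) -> tuple[list[tuple[str, str, int]], dict[str, dict[str, int]]]:
    """Collapse identical sequences.

    Returns uniques as (id, sequence, total abundance) sorted by decreasing
    abundance (ties: first seen), and per-unique per-sample counts. The
    unique id is the id of the first read carrying that sequence.
    """
    by_seq: dict[str, str] = {}
    counts: dict[str, dict[str, int]] = {}
    order: dict[str, int] = {}
    for k, read in enumerate(reads):
        uid = by_seq.get(read.seq)
        if uid is None:
            uid = read.id
            by_seq[read.seq] = uid
            counts[uid] = {}
            order[uid] = k
        sample = read.sample or "all"
        counts[uid][sample] = counts[uid].get(sample, 0) + 1
    seq_of = {uid: s for s, uid in by_seq.items()}
    totals = {uid: sum(c.values()) for uid, c in counts.items()}
    uniques = sorted(
        ((uid, seq_of[uid], totals[uid]) for uid in counts),
        key=lambda u: (-u[2], order[u[0]]),
    )
    return uniques, counts


def precluster(
    uniques: Sequence[tuple[str, str, int]],
    counts: dict[str, dict[str, int]],
    diffs: int = 2,
    min_fold: float = 2.0,
    max_candidates: int = 500,
) -> tuple[list[tuple[str, str, int]], dict[str, dict[str, int]], dict[str, str]]:
    """Merge rare uniques into abundant near-identical ones (denoising).

    A unique joins the most abundant seed within ``diffs`` edit operations
    whose abundance is at least ``min_fold`` times its own — the standard
    abundance-greedy treatment of residual pyrosequencing noise after
    dereplication. Returns merged uniques, merged per-sample counts and the
    unique-to-seed mapping.
    """
    seed_ids: list[str] = []
    strong_ids: list[str] = []  # seeds that can absorb a singleton (ab >= min_fold)
    seed_seq: dict[str, str] = {}
    seed_ab: dict[str, int] = {}
    mapping: dict[str, str] = {}
    merged: dict[str, dict[str, int]] = {}
    for uid, seq, ab in sorted(uniques, key=lambda u: -u[2]):
        target = None
        # singletons (the vast majority) only need the strong-seed list
        pool = strong_ids if ab <= 1 else seed_ids
        for sid in pool[:max_candidates]:
            if seed_ab[sid] < min_fold * ab:
                continue
            sseq = seed_seq[sid]
            if abs(len(sseq) - len(seq)) > diffs:
                continue
            if edlib.align(seq, sseq, mode="NW", k=diffs)["editDistance"] != -1:
                target = sid
                break
        if target is None:
            seed_ids.append(uid)
            seed_seq[uid] = seq
            seed_ab[uid] = ab
            if ab >= min_fold:
                strong_ids.append(uid)
            mapping[uid] = uid
            merged[uid] = dict(counts[uid])
        else:
            mapping[uid] = target
            if seed_ab[target] < min_fold <= seed_ab[target] + ab:
                strong_ids.append(target)
            seed_ab[target] += ab
            for sample, c in counts[uid].items():
                merged[target][sample] = merged[target].get(sample, 0) + c
    out = sorted(
        ((sid, seed_seq[sid], seed_ab[sid]) for sid in seed_ids),
        key=lambda u: -u[2],
    )
    return out, merged, mapping


# ---------------------------------------------------------------------------
# clustering

@dataclass
class OtuAssignment:
    cutoff: float
    assignment: dict[str, str]          # sequence id -> OTU id
    representatives: dict[str, str]     # OTU id -> representative sequence id
    table: CountTable

    @property
    def n_otus(self) -> int:
        return len(self.representatives)


def cluster_average_neighbor(
    dm: DistanceMatrix,
    cutoff: float,
    counts: dict[str, dict[str, int]],
    method: str = "average",
) -> OtuAssignment:
    """Agglomerative clustering of sequences into OTUs at a distance cutoff.

    Merging continues while the inter-cluster linkage distance (average by
    default; ``single``/``complete`` also accepted) is at most ``cutoff``.
    The representative of an OTU is its most abundant member (ties broken
    by lexicographically smallest id); OTUs are labelled Otu0001... by
    decreasing total abundance.
    """
    ids = dm.ids
    totals = {sid: sum(counts[sid].values()) for sid in ids}
    if len(ids) == 1:
        labels = np.array([1])
    else:
        Z = linkage(dm.condensed(), method=method)
        labels = fcluster(Z, t=cutoff, criterion="distance")

    clusters: dict[int, list[str]] = {}
    for sid, lab in zip(ids, labels):
        clusters.setdefault(int(lab), []).append(sid)

    groups = []
    for members in clusters.values():
        rep = min(members, key=lambda m: (-totals[m], m))
        total = sum(totals[m] for m in members)
        groups.append((total, rep, members))
    groups.sort(key=lambda g: (-g[0], g[1]))

    assignment: dict[str, str] = {}
    representatives: dict[str, str] = {}
    samples = sorted({s for sid in ids for s in counts[sid]})
    rows = {}
    for k, (_, rep, members) in enumerate(groups, start=1):
        otu = f"Otu{k:04d}"
        representatives[otu] = rep
        row = dict.fromkeys(samples, 0)
        for m in members:
            assignment[m] = otu
            for sample, c in counts[m].items():
                row[sample] += c
        rows[otu] = row
    df = pd.DataFrame.from_dict(rows, orient="index", columns=samples).fillna(0)
    table = CountTable(df)
    return OtuAssignment(cutoff, assignment, representatives, table)


# ---------------------------------------------------------------------------
# functional cutoff calibration

def _aa_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1
    a.mismatch_score = -1
    a.open_gap_score = -2
    a.extend_gap_score = -1
    return a


_AA_ALIGNER = _aa_aligner()


def aa_p_distance(p1: str, p2: str) -> float:
    """Proportion of differing residues over pairwise-aligned positions
    (gap columns excluded, as in standard p-distance with pairwise deletion)."""
    if p1 == p2:
        return 0.0
    if len(p1) == len(p2):
        diffs = sum(a != b for a, b in zip(p1, p2))
        return diffs / len(p1)
    aln = _AA_ALIGNER.align(p1, p2)[0]
    ga, gb = str(aln[0]), str(aln[1])
    comp = diffs = 0
    for x, y in zip(ga, gb):
        if x != "-" and y != "-":
            comp += 1
            if x != y:
                diffs += 1
    return diffs / comp if comp else 1.0


@dataclass
class CalibrationResult:
    grid: list[float]
    otu_counts: list[int]
    min_aa_distances: list[float]
    chosen: float | None
    assignments: dict[float, OtuAssignment] = field(default_factory=dict)

    @property
    def succeeded(self) -> bool:
        return self.chosen is not None


def calibrate_functional_cutoff(
    ids: Sequence[str],
    seqs: Sequence[str],
    counts: dict[str, dict[str, int]],
    grid: Sequence[float] | None = None,
    dm: DistanceMatrix | None = None,
    engine: str = "needleman",
    method: str = "average",
) -> CalibrationResult:
    """Scan distance cutoffs; choose the smallest preserving unique proteins.

    For each cutoff the frameshift-corrected coding sequences are clustered,
    representatives translated in silico, and all pairwise amino-acid
    p-distances computed. The chosen cutoff is the smallest grid value at
    which every representative pair has AA distance > 0 (all representatives
    encode distinct proteins); if none qualifies the result reports failure
    with the per-cutoff minima.
    """
    if grid is None:
        grid = [round(0.05 + 0.01 * i, 2) for i in range(16)]
    grid = sorted(grid)
    if dm is None:
        dm = pairwise_distance(ids, seqs, engine=engine)
    seq_of = dict(zip(ids, seqs))

    proteins: dict[str, str] = {}

    def protein(sid: str) -> str:
        if sid not in proteins:
            s = seq_of[sid]
            p = translate(s[: len(s) - len(s) % 3])
            if "*" in p[:-1]:
                raise ValueError(f"representative {sid!r} has an internal stop codon")
            proteins[sid] = p
        return proteins[sid]

    otu_counts: list[int] = []
    minima: list[float] = []
    chosen: float | None = None
    assignments: dict[float, OtuAssignment] = {}
    for cutoff in grid:
        asg = cluster_average_neighbor(dm, cutoff, counts, method=method)
        assignments[cutoff] = asg
        reps = list(asg.representatives.values())
        if len(reps) < 2:
            min_d = np.inf
        else:
            min_d = min(
                aa_p_distance(protein(a), protein(b))
                for i, a in enumerate(reps)
                for b in reps[i + 1:]
            )
        otu_counts.append(asg.n_otus)
        minima.append(float(min_d))
        if chosen is None and min_d > 0:
            chosen = cutoff
    return CalibrationResult(list(grid), otu_counts, minima, chosen, assignments)
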