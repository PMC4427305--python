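"""Frameshift detection and correction for protein-coding amplicons.

Pyrosequencing homopolymer errors insert or delete single bases in nirK and
nirS reads, knocking the rest of the read out of frame and wrecking any
protein-level analysis downstream. This module aligns each read against a
position-specific amino-acid profile built from a reference protein
alignment, using a dynamic program whose moves consume 3 nt (codon match),
2 or 4 nt (frameshift: a base lost or gained, penalized), or whole codons
inserted in/deleted from the read relative to the profile. The optimal
path yields a corrected sequence — a lost base is restored as N, a gained
base is removed — and a log-odds score in bits used for quality filtering.

The profile is an explicit position frequency matrix with log-odds scores,
not a full profile HMM: at amplicon scale the two make the same corrections
and the matrix form is directly verifiable against brute-force path
enumeration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AA_ALPHABET)}
X_INDEX = len(AA_ALPHABET)  # unknown residue: neutral score 0

_CODON_TO_AA: dict[str, str] = {}
for codon, aa in standard_dna_table.forward_table.items():
    _CODON_TO_AA[codon] = aa
for codon in standard_dna_table.stop_codons:
    _CODON_TO_AA[codon] = "*"


def codon_aa(codon: str) -> str:
    """Translate one codon; anything ambiguous (N etc.) becomes X."""
    return _CODON_TO_AA.get(codon, "X")


def translate(seq: str) -> str:
    """Codon-wise translation; ambiguous codons become X, stops '*'."""
    return "".join(codon_aa(seq[i:i + 3]) for i in range(0, len(seq) - len(seq) % 3, 3))


class ProfileError(ValueError):
    pass


@dataclass
class CodonProfile:
    """Position-specific amino-acid log-odds profile (bits).

    ``matrix`` has one row per retained alignment column and 21 columns:
    the 20 amino acids plus a neutral X column fixed at 0 bits.
    """

    matrix: np.ndarray
    background: np.ndarray
    gap_penalty: float = 8.0         # bits, per whole-codon indel vs profile
    frameshift_penalty: float = 12.0  # bits, per single-base indel

    def __len__(self) -> int:
        return self.matrix.shape[0]

    def score(self, column: int, aa: str) -> float:
        return float(self.matrix[column, AA_INDEX.get(aa, X_INDEX)])


def build_codon_profile(
    reference_alignment: Sequence[str],
    pseudocount: float = 0.5,
    background: np.ndarray | None = None,
    gap_penalty: float = 8.0,
    frameshift_penalty: float = 12.0,
    max_gap_fraction: float = 0.5,
) -> CodonProfile:
    """Build the profile from >= 5 aligned reference protein sequences.

    Columns with more than ``max_gap_fraction`` gaps are dropped; remaining
    frequencies are smoothed with ``pseudocount`` and converted to log2
    odds against ``background`` (uniform 1/20 by default).
    """
    seqs = [s.upper() for s in reference_alignment]
    if len(seqs) < 5:
        raise ProfileError(f"need >= 5 reference proteins, got {len(seqs)}")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ProfileError("reference alignment rows have unequal lengths")
    ncol = lengths.pop()
    if background is None:
        background = np.full(len(AA_ALPHABET), 1.0 / len(AA_ALPHABET))

    rows = []
    for c in range(ncol):
        column = [s[c] for s in seqs]
        gaps = sum(ch in "-." for ch in column)
        if gaps / len(column) > max_gap_fraction:
            continue
        counts = np.full(len(AA_ALPHABET), pseudocount, dtype=float)
        for ch in column:
            if ch in AA_INDEX:
                counts[AA_INDEX[ch]] += 1.0
        freqs = counts / counts.sum()
        rows.append(np.log2(freqs / background))
    if len(rows) < 20:
        raise ProfileError(f"profile has only {len(rows)} usable columns (< 20)")
    matrix = np.column_stack([np.array(rows), np.zeros(len(rows))])
    return CodonProfile(matrix, background, gap_penalty, frameshift_penalty)


@dataclass
class FrameshiftResult:
    read_id: str
    corrected: str
    score: float
    frameshifts: int
    positions: list[int] = field(default_factory=list)
    passed: bool = True

    @property
    def protein(self) -> str:
        return translate(self.corrected)


# DP move codes
_M3, _FS2, _FS4, _INS, _DEL = 0, 1, 2, 3, 4
_NEG = -1e30


def _codon_scores(read: str, profile: CodonProfile):
    """Per-read-position score lookups for codon and frameshift moves."""
    L = len(read)
    M = profile.matrix
    aa3 = np.full(L, X_INDEX, dtype=int)
    for p in range(L - 2):
        aa3[p] = AA_INDEX.get(codon_aa(read[p:p + 3]), X_INDEX)
    # 4-nt move: best single-base removal out of read[p:p+4]
    aa4 = np.full((L, 4), X_INDEX, dtype=int)
    for p in range(L - 3):
        quad = read[p:p + 4]
        for d in range(4):
            aa4[p, d] = AA_INDEX.get(codon_aa(quad[:d] + quad[d + 1:]), X_INDEX)
    S3 = M[:, aa3]              # column x read-pos
    S4 = M[:, aa4].max(axis=2)  # column x read-pos (best removal)
    return S3, S4, aa4


def correct_frameshifts(
    read_id: str,
    read: str,
    profile: CodonProfile,
    floor_score: float = -1e9,
    min_length: int = 60,
) -> FrameshiftResult:
    """Align a read to the profile and repair single-base indels.

    Semi-global: leading/trailing profile columns are free, the read must
    be consumed except for at most 2 trailing bases (kept verbatim).
    Equal-score paths prefer fewer frameshifts, then the leftmost move.
    """
    read = read.upper()
    L = len(read)
    if L < min_length:
        raise ValueError(f"read {read_id!r} shorter than {min_length} nt")
    Mcols = len(profile)
    g = profile.gap_penalty
    f = profile.frameshift_penalty
    S3, S4, aa4 = _codon_scores(read, profile)
    xfs = -f  # frameshift codon scored as neutral X minus the penalty

    dp = np.full((L + 1, Mcols + 1), _NEG)
    dp[0, :] = 0.0  # free leading profile columns
    ks = np.arange(Mcols + 1)
    for i in range(1, L + 1):
        cand = np.full(Mcols + 1, _NEG)
        prev = dp[i - 3] if i >= 3 else None
        if i >= 3:
            cand[1:] = prev[:-1] + S3[:, i - 3]               # codon match
            cand = np.maximum(cand, prev - g)                 # codon insert in read
        if i >= 2:
            cand[1:] = np.maximum(cand[1:], dp[i - 2, :-1] + xfs)     # 2-nt move
        if i >= 4:
            cand[1:] = np.maximum(cand[1:], dp[i - 4, :-1] + S4[:, i - 4] - f)
        # whole-codon deletion from the read (skip profile columns), a
        # running max over k < j of cand[k] - g*(j-k)
        run = np.maximum.accumulate(cand + g * ks)
        cand[1:] = np.maximum(cand[1:], run[:-1] - g * ks[1:])
        dp[i] = cand

    # free trailing profile columns; allow <=2 unaligned read tail bases
    ends = [(i, j) for i in range(max(0, L - 2), L + 1) for j in range(Mcols + 1)]
    best_i, best_j = max(ends, key=lambda ij: dp[ij])
    score = float(dp[best_i, best_j])
    if score <= _NEG / 2 or score < floor_score:
        return FrameshiftResult(read_id, read, score, 0, [], passed=False)

    pieces: list[str] = [read[best_i:]]
    positions: list[int] = []
    nfs = 0
    i, j = best_i, best_j
    tol = 1e-6

    def close(a: float, b: float) -> bool:
        return abs(a - b) <= tol

    while i > 0:
        v = dp[i, j]
        moved = False
        # preference: fewer frameshifts first, then leftmost-style order
        if i >= 3 and j >= 1 and close(dp[i - 3, j - 1] + S3[j - 1, i - 3], v):
            pieces.append(read[i - 3:i]); i -= 3; j -= 1; moved = True
        elif i >= 3 and close(dp[i - 3, j] - g, v):
            pieces.append(read[i - 3:i]); i -= 3; moved = True
        elif j >= 1 and close(dp[i, j - 1] - g, v):
            j -= 1; moved = True
        elif i >= 2 and j >= 1 and close(dp[i - 2, j - 1] + xfs, v):
            pieces.append(read[i - 2:i] + "N")
            positions.append(i - 2); nfs += 1; i -= 2; j -= 1; moved = True
        elif i >= 4 and j >= 1 and close(dp[i - 4, j - 1] + S4[j - 1, i - 4] - f, v):
            quad = read[i - 4:i]
            col = profile.matrix[j - 1]
            drop = int(np.argmax([col[aa4[i - 4, d]] for d in range(4)]))
            pieces.append(quad[:drop] + quad[drop + 1:])
            positions.append(i - 4); nfs += 1; i -= 4; j -= 1; moved = True
        if not moved:
            raise AssertionError("traceback failed to reproduce DP score")
    pieces.append(read[:i])
    corrected = "".join(reversed(pieces))
    positions.reverse()
    return FrameshiftResult(read_id, corrected, score, nfs, positions, passed=True)


def score_filter(
    results: Sequence[FrameshiftResult], threshold_bits: float
) -> tuple[list[FrameshiftResult], float]:
    """Keep results scoring at least ``threshold_bits``; also return kept fraction."""
    kept = [r for r in results if r.passed and r.score >= threshold_bits]
    frac = len(kept) / len(results) if results else 0.0
    return kept, frac
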