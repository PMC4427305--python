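"""Demultiplexing, read filtering and chimera flagging.

The filter cascade follows standard 454 amplicon QC: match the MID barcode
on the 5' prefix (Hamming distance, tolerance 1), match the forward primer
next (IUPAC-aware, tolerance 2), trim both, then discard trimmed reads
shorter than 200 bp or containing a homopolymer longer than 8 nt.
Chimeras are flagged by a simplified two-parent (bimera) scorer over
abundance-ranked candidate parents, and known contaminant reads
(chloroplast/mitochondrial annotations supplied as a list) are removed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

import edlib
import numpy as np

from .config import RunConfig
from .io import Read

IUPAC = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"}, "U": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"G", "C"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"},
    "H": {"A", "C", "T"}, "V": {"A", "C", "G"},
    "N": {"A", "C", "G", "T"},
}

#: fixed order in which filters are applied and reported
FILTER_ORDER = ("barcode", "primer", "short", "homopolymer", "chimera", "contaminant")


@dataclass
class FilterReport:
    """Per-reason rejection counts; kept + sum(rejected) == input."""

    input: int = 0
    kept: int = 0
    rejected: dict[str, int] = field(default_factory=dict)

    def record(self, fate: str) -> None:
        self.input += 1
        if fate == "kept":
            self.kept += 1
        else:
            reason = fate.split(":", 1)[1]
            self.rejected[reason] = self.rejected.get(reason, 0) + 1

    @property
    def conserved(self) -> bool:
        return self.kept + sum(self.rejected.values()) == self.input

    def removed_fraction(self, reasons: Sequence[str]) -> float:
        """Combined fraction of input removed for the given reasons."""
        if self.input == 0:
            return 0.0
        return sum(self.rejected.get(r, 0) for r in reasons) / self.input

    def to_dict(self) -> dict:
        return {"input": self.input, "kept": self.kept, "rejected": dict(self.rejected)}


def hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def iupac_mismatches(seq: str, pattern: str) -> int:
    """Mismatches of seq against an IUPAC-degenerate pattern (equal length)."""
    n = 0
    for base, pat in zip(seq, pattern):
        if base not in IUPAC.get(pat, set()):
            n += 1
    return n


@lru_cache(maxsize=32)
def _homopolymer_re(limit: int) -> re.Pattern:
    return re.compile(r"(.)\1{%d,}" % limit)


def has_long_homopolymer(seq: str, max_run: int) -> bool:
    """True when any single-base run exceeds ``max_run``."""
    return _homopolymer_re(max_run).search(seq) is not None


def max_homopolymer_run(seq: str) -> int:
    best = run = 1
    for i in range(1, len(seq)):
        run = run + 1 if seq[i] == seq[i - 1] else 1
        if run > best:
            best = run
    return best if seq else 0


def demultiplex_filter(read: Read, config: RunConfig) -> Read:
    """Assign a sample by MID and apply the QC cascade; sets fate in place.

    Filter order: barcode -> primer -> length -> homopolymer. The length
    and homopolymer tests apply to the trimmed read (barcode and primer are
    synthetic constructs and carry no sequencing noise of interest).
    """
    barcodes = list(config.barcode_map)
    if not barcodes:
        raise ValueError("config has no barcodes")
    blen = len(barcodes[0])
    prefix = read.seq[:blen]
    hits = [b for b in barcodes if hamming(prefix, b) <= config.max_barcode_mismatch]
    if len(hits) == 0:
        read.fate = "rejected:barcode"
        return read
    if len(hits) > 1:
        # distinct MIDs both within tolerance: cannot demultiplex safely
        read.fate = "rejected:barcode_ambiguous"
        return read
    sample = config.barcode_map[hits[0]]

    primer = config.primer_forward.upper()
    segment = read.seq[blen:blen + len(primer)]
    if len(segment) < len(primer) or iupac_mismatches(segment, primer) > config.max_primer_mismatch:
        read.fate = "rejected:primer"
        return read

    trimmed = read.seq[blen + len(primer):]
    if len(trimmed) < config.min_length:
        read.fate = "rejected:short"
        return read
    if has_long_homopolymer(trimmed, config.max_homopolymer):
        read.fate = "rejected:homopolymer"
        return read

    read.sample = sample
    read.seq = trimmed
    read.fate = "kept"
    return read


def demultiplex_all(reads: Iterable[Read], config: RunConfig) -> tuple[list[Read], FilterReport]:
    """Run the cascade over all reads; returns kept reads and the report."""
    report = FilterReport()
    kept: list[Read] = []
    for read in reads:
        demultiplex_filter(read, config)
        report.record(read.fate)
        if read.fate == "kept":
            kept.append(read)
    return kept, report


# ---------------------------------------------------------------------------
# chimera (bimera) detection

def _match_profile(query: str, parent: str) -> np.ndarray:
    """Boolean per-query-position identity profile from a global alignment."""
    res = edlib.align(query, parent, task="path", mode="NW")
    profile = np.zeros(len(query), dtype=bool)
    qpos = 0
    for length, op in _iter_cigar(res["cigar"]):
        if op == "=":
            profile[qpos:qpos + length] = True
            qpos += length
        elif op in ("X", "I"):  # mismatch / base absent from parent
            qpos += length
        # 'D': parent-only bases, no query positions consumed
    return profile


def _iter_cigar(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""


@dataclass
class BimeraCall:
    score: float
    flagged: bool
    best_parents: tuple[str, str] | None = None
    breakpoint: int | None = None


def detect_bimera(
    query: str,
    candidates: Sequence[tuple[str, str, int]],
    query_abundance: int = 1,
    min_parent_fold: float = 2.0,
    divergence_threshold: float = 0.02,
    min_segment: int = 30,
    min_model_identity: float = 0.98,
) -> BimeraCall:
    """Score a query as a two-parent chimera against abundant candidates.

    ``candidates`` are (id, sequence, abundance) tuples. Only candidates at
    least ``min_parent_fold`` times the query's abundance may act as parents
    (a chimera cannot outnumber the templates it arose from). The score is
    the identity gain of the best single-breakpoint two-parent model over
    the best single parent, maximised by exhaustive breakpoint search; a
    query is flagged when the gain exceeds ``divergence_threshold``, both
    parent segments span at least ``min_segment`` query bases, and the
    two-parent model explains the query almost perfectly
    (``min_model_identity``) — a genuine bimera is a mosaic of its parents
    up to sequencing error, whereas a real divergent sequence is not.
    """
    L = len(query)
    parents = [
        (pid, seq) for pid, seq, ab in candidates
        if ab >= min_parent_fold * query_abundance
    ]
    if len(parents) < 2 or L < 2 * min_segment:
        return BimeraCall(0.0, False)

    ids = [pid for pid, _ in parents]
    profiles = np.array([_match_profile(query, seq) for _, seq in parents])
    totals = profiles.sum(axis=1)
    best_single = totals.max() / L

    # cumulative matches: pref[p, b] = matches of parent p on query[:b]
    pref = np.concatenate(
        [np.zeros((len(parents), 1), dtype=int), np.cumsum(profiles, axis=1)], axis=1
    )
    bps = np.arange(min_segment, L - min_segment + 1)
    left = pref[:, bps]                       # parent x breakpoint
    right = totals[:, None] - pref[:, bps]
    combo = left.max(axis=0) + right.max(axis=0)
    k = int(np.argmax(combo))
    best_two = combo[k] / L
    score = float(best_two - best_single)
    flagged = score > divergence_threshold and best_two >= min_model_identity
    bp = int(bps[k])
    lp = ids[int(left[:, k].argmax())]
    rp = ids[int(right[:, k].argmax())]
    return BimeraCall(score, flagged, (lp, rp), bp)


def flag_bimeras(
    uniques: Sequence[tuple[str, str, int]],
    min_parent_fold: float = 2.0,
    divergence_threshold: float = 0.02,
    min_segment: int = 30,
    min_model_identity: float = 0.98,
    max_parents: int = 50,
) -> dict[str, BimeraCall]:
    """Run bimera detection over dereplicated (id, seq, abundance) records.

    Candidates for each query are the ``max_parents`` most abundant other
    sequences; queries are processed from rare to abundant.
    """
    ranked = sorted(uniques, key=lambda u: -u[2])
    calls: dict[str, BimeraCall] = {}
    for uid, seq, ab in sorted(uniques, key=lambda u: u[2]):
        cands = [c for c in ranked[:max_parents + 1] if c[0] != uid]
        calls[uid] = detect_bimera(
            seq, cands, ab, min_parent_fold, divergence_threshold,
            min_segment, min_model_identity,
        )
    return calls


def remove_contaminants(
    reads: Sequence[Read],
    contaminant_ids: Iterable[str],
    annotations: dict[str, str] | None = None,
) -> tuple[list[Read], FilterReport]:
    """Remove reads whose annotation id is on the contaminant list.

    ``annotations`` maps read id -> annotation id (e.g. source organelle
    label from the truth table); without it, read ids are matched directly.
    """
    listed = set(contaminant_ids)
    report = FilterReport()
    kept = []
    for read in reads:
        key = annotations.get(read.id, read.id) if annotations else read.id
        if key in listed:
            read.fate = "rejected:contaminant"
        else:
            read.fate = "kept"
            kept.append(read)
        report.record(read.fate)
    return kept, report
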