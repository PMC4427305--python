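"""Synthetic marker-gene pools, communities, reads and qPCR plates.

Everything downstream of sequencing is testable without real data: this
module generates (a) pools of 16S-like or codon-structured nir-like genes
with controlled divergence, (b) log-series/lognormal community abundances
with few abundant and many rare taxa, (c) barcoded, primer-decorated reads
carrying 454-style errors — uniform substitutions plus homopolymer indels
that cause frameshifts — and two-parent chimeras, with a complete truth
record per read, and (d) qPCR plates with set curve parameters, Cq noise
and per-sample inhibition.

Every generator is a pure function of its seed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .frameshift import _CODON_TO_AA, translate
from .io import CountTable, Read

BASES = "ACGT"

_RUN3_RE = re.compile(r"(.)\1{2,}")

#: fictional phylum labels so taxonomy-resolved reporting is testable
#: without a classifier
PHYLA = (
    "Limobacterota", "Vasacota", "Pelitrophica", "Arenimonadota",
    "Aestuariota", "Fluctibacterota", "Salinivirgota", "Crenarchia",
    "Nitrosophaerota", "Unclassified",
)

# codon machinery: for each codon, single-nt neighbours that change the
# protein, and synonymous alternatives
_CODONS = [c for c in _CODON_TO_AA if _CODON_TO_AA[c] != "*"]
_SYNONYMS = {
    c: [d for d in _CODONS if d != c and _CODON_TO_AA[d] == _CODON_TO_AA[c]]
    for c in _CODONS
}


def _nonsyn_neighbours(codon: str, hamming: int) -> list[str]:
    out = []
    for d in _CODONS:
        if _CODON_TO_AA[d] != _CODON_TO_AA[codon]:
            h = sum(x != y for x, y in zip(codon, d))
            if h == hamming:
                out.append(d)
    return out


_NONSYN = {
    c: {h: _nonsyn_neighbours(c, h) for h in (1, 2, 3)} for c in _CODONS
}


@dataclass
class MarkerPool:
    marker: str                      # "16S" or "coding"
    sequences: dict[str, str]
    taxon_of: dict[str, str]         # sequence id -> taxon id
    phylum_of: dict[str, str]        # taxon id -> phylum label
    proteins: dict[str, str] = field(default_factory=dict)
    identity_range: tuple[float, float] = (0.0, 1.0)

    @property
    def ids(self) -> list[str]:
        return list(self.sequences)

    @property
    def taxa(self) -> list[str]:
        return sorted(set(self.taxon_of.values()))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(BASES), size=length))


def _mutate_positions(
    rng: np.random.Generator, seq: str, positions: np.ndarray
) -> str:
    s = list(seq)
    for p in positions:
        s[p] = rng.choice([b for b in BASES if b != s[p]])
    return "".join(s)


def generate_marker_pool(
    n_taxa: int,
    marker: str = "16S",
    identity_range: tuple[float, float] = (0.80, 0.95),
    synonymous_variants: int = 0,
    seed: int = 0,
    length: int | None = None,
    synonymous_radius: int = 9,
) -> MarkerPool:
    """Generate a reference pool of marker genes with controlled divergence.

    Default amplicon lengths are 450 bp (16S-like) and 474 bp (nir-like,
    divisible by 3), matching 454 Titanium read lengths. Taxa radiate from
    a random ancestor; when the divergence budget allows, each taxon
    mutates a disjoint set of positions so pairwise distances are exact,
    otherwise positions are drawn at random and distances concentrate
    around the midpoint of the requested range. Coding taxa differ at the
    protein level and carry ``synonymous_variants`` extra nucleotide
    variants each (identical protein, within ``synonymous_radius`` nt).
    """
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    lo, hi = identity_range
    if not (0.5 < lo <= hi < 1.0):
        raise ValueError("identity_range must lie within (0.5, 1.0)")
    rng = np.random.default_rng(seed)
    coding = marker != "16S"
    if length is None:
        length = 474 if coding else 450
    if coding and length % 3:
        raise ValueError("coding pool length must be divisible by 3")
    d_lo, d_hi = 1.0 - hi, 1.0 - lo

    # per-taxon divergence from the ancestor (half the pairwise target)
    halves = rng.uniform(d_lo / 2, d_hi / 2, size=n_taxa)
    budgets = np.round(halves * length).astype(int)
    budgets = np.maximum(budgets, 1)
    disjoint = budgets.sum() <= length * (0.9 if not coding else 0.8)
    if not disjoint:
        # overlapping random positions: solve 2q(1-q) + (2/3)q^2 = d_mid
        d_mid = (d_lo + d_hi) / 2
        disc = 4.0 - 4.0 * (4.0 / 3.0) * d_mid
        q = (2.0 - np.sqrt(disc)) / (2.0 * 4.0 / 3.0)
        budgets = np.full(n_taxa, max(1, round(q * length)))

    sequences: dict[str, str] = {}
    proteins: dict[str, str] = {}
    taxon_of: dict[str, str] = {}
    phylum_of: dict[str, str] = {}

    if not coding:
        if d_hi * length / 2 < 1 and n_taxa > 2:
            raise ValueError("identity_range too narrow for this length")
        ancestor = _random_seq(rng, length)
        if disjoint:
            order = rng.permutation(length)
            cuts = np.concatenate([[0], np.cumsum(budgets)])
            pos_sets = [order[cuts[i]:cuts[i + 1]] for i in range(n_taxa)]
        else:
            pos_sets = [
                rng.choice(length, size=budgets[i], replace=False)
                for i in range(n_taxa)
            ]
        for t in range(n_taxa):
            tid = f"T{t + 1:03d}"
            sequences[tid] = _mutate_positions(rng, ancestor, pos_sets[t])
            taxon_of[tid] = tid
            phylum_of[tid] = PHYLA[t % len(PHYLA)]
    else:
        n_codons = length // 3
        anc_codons = [rng.choice(_CODONS) for _ in range(n_codons)]
        for t in range(n_taxa):
            tid = f"T{t + 1:03d}"
            for _ in range(20):  # redraw on a (rare) protein collision
                codons = _diverge_codons(rng, anc_codons, int(budgets[t]))
                prot = translate("".join(codons))
                if prot not in proteins.values():
                    break
            seq = "".join(codons)
            sequences[tid] = seq
            proteins[tid] = prot
            taxon_of[tid] = tid
            phylum_of[tid] = PHYLA[t % len(PHYLA)]
            for v in range(synonymous_variants):
                vid = f"{tid}v{v + 1}"
                var = _synonymous_variant(rng, codons, synonymous_radius)
                sequences[vid] = var
                proteins[vid] = prot
                taxon_of[vid] = tid
    return MarkerPool(
        marker="coding" if coding else "16S",
        sequences=sequences,
        taxon_of=taxon_of,
        phylum_of=phylum_of,
        proteins=proteins,
        identity_range=identity_range,
    )


def _diverge_codons(
    rng: np.random.Generator, ancestor: list[str], nt_budget: int
) -> list[str]:
    """Spend exactly ~nt_budget nucleotide changes on nonsynonymous codon swaps."""
    codons = list(ancestor)
    order = rng.permutation(len(codons))
    spent = 0
    for idx in order:
        if spent >= nt_budget:
            break
        want = min(3, nt_budget - spent)
        choice = None
        for h in range(want, 0, -1):
            options = _NONSYN[codons[idx]][h]
            if options:
                choice = options[rng.integers(len(options))]
                spent += h
                break
        if choice is not None:
            codons[idx] = choice
    return codons


def _synonymous_variant(
    rng: np.random.Generator, codons: list[str], radius: int
) -> str:
    out = list(codons)
    candidates = [i for i, c in enumerate(out) if _SYNONYMS[c]]
    rng.shuffle(candidates)
    spent = 0
    for i in candidates:
        if spent >= radius:
            break
        syn = _SYNONYMS[out[i]]
        pick = syn[rng.integers(len(syn))]
        spent += sum(x != y for x, y in zip(out[i], pick))
        out[i] = pick
    return "".join(out)


# ---------------------------------------------------------------------------
# community abundances

def simulate_community(
    pool: MarkerPool,
    n_samples: int,
    depth: int,
    model: str = "lognormal",
    sigma: float = 2.0,
    logseries_p: float = 0.995,
    sample_sigma: float = 0.0,
    samples: Sequence[str] | None = None,
    seed: int = 0,
) -> CountTable:
    """True per-template counts: columns sum to ``depth`` exactly.

    ``lognormal`` draws taxon weights exp(sigma*Z) (sigma=0 -> uniform);
    ``logseries`` draws integer weights from a Fisher log-series with
    parameter ``logseries_p``. Both give a small abundant (>1%) fraction
    and a long rare tail at survey-like settings. Within a taxon, reads
    split uniformly across its synonymous variants. ``sample_sigma`` adds
    per-sample lognormal wobble to the weights.
    """
    rng = np.random.default_rng(seed)
    ids = pool.ids
    taxa = pool.taxa
    if depth < len(taxa):
        raise ValueError("depth too small for the number of taxa")
    if model == "lognormal":
        w = np.exp(sigma * rng.standard_normal(len(taxa)))
    elif model == "logseries":
        from scipy.stats import logser

        w = logser.rvs(logseries_p, size=len(taxa), random_state=rng).astype(float)
    else:
        raise ValueError(f"unknown abundance model {model!r}")
    # spread taxon weight uniformly over its variants
    members = {t: [i for i in ids if pool.taxon_of[i] == t] for t in taxa}
    weights = np.array(
        [w[taxa.index(pool.taxon_of[i])] / len(members[pool.taxon_of[i]]) for i in ids]
    )
    if samples is None:
        samples = [f"S{k + 1}" for k in range(n_samples)]
    cols = {}
    for s in samples:
        ws = weights
        if sample_sigma > 0:
            ws = weights * np.exp(sample_sigma * rng.standard_normal(len(ids)))
        cols[s] = rng.multinomial(depth, ws / ws.sum())
    df = pd.DataFrame(cols, index=ids)
    return CountTable(df)


def aggregate_by_taxon(table: CountTable, pool: MarkerPool) -> CountTable:
    """Collapse template-level counts to taxon level (merges synonyms)."""
    df = table.data.groupby([pool.taxon_of[i] for i in table.data.index]).sum()
    return CountTable(df)


# ---------------------------------------------------------------------------
# reads

@dataclass
class ReadTruthRecord:
    source: str                       # template id (first parent for chimeras)
    sample: str
    is_chimera: bool = False
    parents: tuple[str, str] | None = None
    indel_positions: tuple[int, ...] = ()
    n_substitutions: int = 0


def _inject_errors(
    rng: np.random.Generator, seq: str, sub_rate: float, hp_indel_rate: float
) -> tuple[str, int, tuple[int, ...]]:
    s = list(seq)
    nsub = 0
    if sub_rate > 0:
        hits = np.flatnonzero(rng.random(len(s)) < sub_rate)
        for p in hits:
            s[p] = rng.choice([b for b in BASES if b != s[p]])
        nsub = len(hits)
    indels: list[int] = []
    if hp_indel_rate > 0:
        # homopolymer runs of >= 3 in the (possibly substituted) sequence
        runs = [
            (m.start(), m.end() - m.start())
            for m in _RUN3_RE.finditer("".join(s))
        ]
        offset = 0
        for rstart, rlen in runs:
            # indel probability grows with run length
            if rng.random() < hp_indel_rate * (rlen - 2):
                pos = rstart + offset + int(rng.integers(rlen))
                if rng.random() < 0.5:
                    s.insert(pos, s[pos])
                    offset += 1
                else:
                    del s[pos]
                    offset -= 1
                indels.append(pos)
    return "".join(s), nsub, tuple(indels)


def simulate_reads(
    pool: MarkerPool,
    true_table: CountTable,
    barcode_of_sample: Mapping[str, str],
    primer: str,
    sub_rate: float = 0.001,
    hp_indel_rate: float = 0.005,
    chimera_rate: float = 0.02,
    length_jitter: int = 0,
    seed: int = 0,
) -> tuple[list[Read], dict[str, ReadTruthRecord]]:
    """Emit barcode+primer+template reads with injected errors and truth.

    Chimeras are two-parent single-breakpoint joins between templates of
    the same sample (breakpoint uniform in the middle 60%), drawn with
    probability ``chimera_rate`` per read; parents are sampled by
    abundance. ``length_jitter`` truncates up to that many 3' bases.
    """
    for rate in (sub_rate, hp_indel_rate, chimera_rate):
        if not 0 <= rate < 1:
            raise ValueError("rates must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    reads: list[Read] = []
    truth: dict[str, ReadTruthRecord] = {}
    ids = list(true_table.data.index)
    for sample in true_table.sample_ids:
        barcode = barcode_of_sample[sample]
        col = true_table.data[sample].to_numpy()
        templates = np.repeat(np.arange(len(ids)), col)
        probs = col / col.sum() if col.sum() else None
        k = 0
        for tidx in templates:
            rid = f"{sample}_r{k:06d}"
            k += 1
            src = ids[tidx]
            tpl = pool.sequences[src]
            rec = ReadTruthRecord(source=src, sample=sample)
            if chimera_rate > 0 and rng.random() < chimera_rate and len(ids) > 1:
                other = src
                for _ in range(20):  # retry so a dominant taxon can't suppress the rate
                    other = ids[rng.choice(len(ids), p=probs)]
                    if other != src:
                        break
                if other != src:
                    tpl2 = pool.sequences[other]
                    bp = int(rng.integers(int(0.2 * len(tpl)), int(0.8 * len(tpl))))
                    tpl = tpl[:bp] + tpl2[bp:]
                    rec.is_chimera = True
                    rec.parents = (src, other)
            seq, nsub, indels = _inject_errors(rng, tpl, sub_rate, hp_indel_rate)
            rec.n_substitutions = nsub
            rec.indel_positions = indels
            if length_jitter > 0:
                cut = int(rng.integers(0, length_jitter + 1))
                if cut:
                    seq = seq[:-cut]
            reads.append(Read(id=rid, seq=barcode + primer.upper() + seq))
            truth[rid] = rec
    return reads, truth


# ---------------------------------------------------------------------------
# qPCR plates

def simulate_qpcr_plate(
    true_copies_per_g: Mapping[str, Mapping[str, float]],
    curves: Mapping[str, tuple[float, float]],
    inhibition: Mapping[str, Mapping[str, float]],
    cq_noise_sd: float = 0.15,
    replicates: int = 3,
    dilution_levels: Sequence[float] = tuple(10.0 ** np.arange(1, 10)),
    spike_copies: float = 1e6,
    dilution_factor: float = 1.0,
    extract_volume_ul: float = 50.0,
    template_volume_ul: float = 2.5,
    sediment_mass_g: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate one plate: standards, unknowns and spike wells per target.

    ``true_copies_per_g[target][sample]`` and ``inhibition[target][sample]``
    define the truth; standards follow Cq = slope*log10(copies) + intercept
    + noise and inhibited unknowns are shifted by slope*log10(factor),
    i.e. the instrument sees factor x the true template.
    """
    rng = np.random.default_rng(seed)
    rows = []
    well = 0
    for target, samples in true_copies_per_g.items():
        slope, intercept = curves[target]
        if slope >= 0:
            raise ValueError("standard-curve slope must be negative")
        for level in dilution_levels:
            for _ in range(replicates):
                cq = slope * np.log10(level) + intercept + rng.normal(0, cq_noise_sd)
                rows.append((f"W{well:04d}", target, "standard", "", level, cq))
                well += 1
        for sample, cpg in samples.items():
            factor = inhibition[target][sample]
            if not 0 < factor <= 1:
                raise ValueError("inhibition factors must lie in (0, 1]")
            true_rxn = (
                cpg * sediment_mass_g * template_volume_ul
                / extract_volume_ul / dilution_factor
            )
            for _ in range(replicates):
                cq = (
                    slope * np.log10(factor * true_rxn) + intercept
                    + rng.normal(0, cq_noise_sd)
                )
                rows.append((f"W{well:04d}", target, "unknown", sample, np.nan, cq))
                well += 1
            for _ in range(replicates):
                cq = (
                    slope * np.log10(factor * (true_rxn + spike_copies)) + intercept
                    + rng.normal(0, cq_noise_sd)
                )
                rows.append(
                    (f"W{well:04d}", target, "spike", sample, spike_copies, cq)
                )
                well += 1
    return pd.DataFrame(
        rows, columns=["well", "target", "role", "sample", "copies", "cq"]
    )
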