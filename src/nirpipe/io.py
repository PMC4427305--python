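"""Readers and writers for the pipeline's on-disk formats.

Formats handled here so every other module stays format-agnostic:

* FASTA (+ optional 454-style QUAL) in and out, via Biopython;
* OTU count tables as TSV (``otu_id``, ``total``, one column per sample),
  with an exporter to mothur's transposed "shared" dialect;
* square phylip distance matrices;
* qPCR plate tables as CSV (well, target, role, sample, copies, Cq);
* JSON run summaries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord
from Bio.Seq import Seq


class FormatError(ValueError):
    """Raised on malformed input files."""


# ---------------------------------------------------------------------------
# reads

@dataclass
class Read:
    """One amplicon read and its processing fate."""

    id: str
    seq: str
    qual: list[int] | None = None
    sample: str | None = None
    fate: str | None = None  # "kept" or "rejected:<reason>"

    def __len__(self) -> int:
        return len(self.seq)


def read_fasta(path: str | Path, qual_path: str | Path | None = None) -> list[Read]:
    """Read a FASTA file (optionally with a matching QUAL file) into Reads.

    Sequences are upper-cased and U is mapped to T; record order is
    preserved. With a QUAL file, ids must match one-to-one in order.
    """
    path = Path(path)
    reads: list[Read] = []
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        seq = str(rec.seq).upper().replace("U", "T")
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} (#{i + 1}) has an empty sequence")
        reads.append(Read(id=rec.id, seq=seq))
    if qual_path is not None:
        quals = list(SeqIO.parse(str(qual_path), "qual"))
        if len(quals) != len(reads):
            raise FormatError(
                f"{qual_path}: {len(quals)} qual records vs {len(reads)} fasta records"
            )
        for read, q in zip(reads, quals):
            if read.id != q.id:
                raise FormatError(
                    f"qual id {q.id!r} does not match fasta id {read.id!r}"
                )
            read.qual = list(q.letter_annotations["phred_quality"])
    return reads


def write_fasta(reads: Iterable[Read], path: str | Path) -> None:
    records = [SeqRecord(Seq(r.seq), id=r.id, description="") for r in reads]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# count tables

@dataclass
class CountTable:
    """OTU x sample matrix of integer counts.

    ``data`` is a pandas DataFrame indexed by OTU id with one integer column
    per sample. Optional per-OTU taxon labels and representative sequences
    ride along.
    """

    data: pd.DataFrame
    taxonomy: dict[str, str] = field(default_factory=dict)
    representatives: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise FormatError("duplicate OTU ids in count table")
        self.data = self.data.astype(int)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def totals(self) -> pd.Series:
        return self.data.sum(axis=1)

    def sample_counts(self, sample: str) -> pd.Series:
        return self.data[sample]

    def sorted(self) -> "CountTable":
        """Rows by decreasing total abundance then OTU id; columns by sample id."""
        df = self.data[sorted(self.data.columns)]
        order = sorted(df.index, key=lambda o: (-int(df.loc[o].sum()), o))
        return CountTable(df.loc[order], dict(self.taxonomy), dict(self.representatives))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountTable):
            return NotImplemented
        return self.sorted().data.equals(other.sorted().data)


def write_count_table(table: CountTable, path: str | Path) -> None:
    """Write TSV: ``otu_id  total  <sample...>``, rows by decreasing total."""
    t = table.sorted()
    df = t.data.copy()
    df.insert(0, "total", df.sum(axis=1))
    df.index.name = "otu_id"
    df.to_csv(path, sep="\t")


def read_count_table(path: str | Path) -> CountTable:
    df = pd.read_csv(path, sep="\t", index_col="otu_id")
    if df.index.has_duplicates:
        raise FormatError(f"{path}: duplicate OTU ids")
    df = df.drop(columns=["total"])
    return CountTable(df.astype(int))


def write_mothur_shared(table: CountTable, label: str, path: str | Path) -> None:
    """Export to mothur's transposed 'shared' dialect (one row per sample)."""
    t = table.sorted()
    otus = t.otu_ids
    with open(path, "w") as fh:
        fh.write("label\tGroup\tnumOtus\t" + "\t".join(otus) + "\n")
        for sample in t.sample_ids:
            counts = "\t".join(str(int(c)) for c in t.data[sample])
            fh.write(f"{label}\t{sample}\t{len(otus)}\t{counts}\n")


# ---------------------------------------------------------------------------
# distance matrices

class DistanceMatrix:
    """Symmetric pairwise distances over sequence or sample ids, in [0,1]."""

    def __init__(self, ids: Sequence[str], values: np.ndarray):
        values = np.asarray(values, dtype=float)
        n = len(ids)
        if values.shape != (n, n):
            raise FormatError(f"distance matrix shape {values.shape} vs {n} ids")
        if not np.allclose(values, values.T, atol=1e-9):
            raise FormatError("distance matrix not symmetric")
        if np.any(np.diag(values) != 0):
            raise FormatError("distance matrix diagonal must be zero")
        self.ids = list(ids)
        self.values = values
        self._index = {x: i for i, x in enumerate(self.ids)}

    def __len__(self) -> int:
        return len(self.ids)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        a, b = pair
        return float(self.values[self._index[a], self._index[b]])

    def condensed(self) -> np.ndarray:
        """Upper-triangle values in scipy condensed order."""
        iu = np.triu_indices(len(self.ids), k=1)
        return self.values[iu]

    def filter(self, keep: Sequence[str]) -> "DistanceMatrix":
        idx = [self._index[x] for x in keep]
        return DistanceMatrix(list(keep), self.values[np.ix_(idx, idx)])


def write_phylip_distances(dm: DistanceMatrix, path: str | Path) -> None:
    """Square phylip format; ids are limited to 64 characters."""
    with open(path, "w") as fh:
        fh.write(f"{len(dm)}\n")
        for name, row in zip(dm.ids, dm.values):
            if len(name) > 64:
                raise FormatError(f"id {name!r} longer than 64 characters")
            fh.write(name + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")


def read_phylip_distances(path: str | Path) -> DistanceMatrix:
    with open(path) as fh:
        header = fh.readline()
        try:
            n = int(header.strip())
        except ValueError as exc:
            raise FormatError(f"{path}: bad phylip header {header!r}") from exc
        ids, rows = [], []
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            ids.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
    if len(ids) != n:
        raise FormatError(f"{path}: header says {n} taxa, found {len(ids)}")
    return DistanceMatrix(ids, np.array(rows))


# ---------------------------------------------------------------------------
# qPCR plates

PLATE_COLUMNS = ["well", "target", "role", "sample", "copies", "cq"]


def read_qpcr_plate(path: str | Path) -> pd.DataFrame:
    """Read a plate CSV with columns well, target, role, sample, copies, cq.

    ``role`` is one of standard/unknown/spike; ``copies`` is the known input
    for standards and the spike amount for spike wells (NaN for unknowns).
    """
    df = pd.read_csv(path)
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing plate columns {missing}")
    bad = set(df["role"]) - {"standard", "unknown", "spike"}
    if bad:
        raise FormatError(f"{path}: unknown well roles {sorted(bad)}")
    return df


def write_qpcr_plate(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, columns=PLATE_COLUMNS)


# ---------------------------------------------------------------------------
# JSON summaries

def write_json(obj: dict, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=_default) + "\n")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
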