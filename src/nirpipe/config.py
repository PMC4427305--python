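"""Run configuration for the amplicon + qPCR pipeline.

A :class:`RunConfig` gathers everything a single marker-gene run needs:
the sample sheet (sample -> group/replicate), the MID barcode map, the
primer pair, read-filter parameters, the OTU cutoff (fixed for 16S,
calibrated over a grid for the coding nir genes) and the master seed.
All randomness in the pipeline flows from this one seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

VALID_MARKERS = ("16S", "nirK", "nirS")

#: default grid of nucleotide distance cutoffs tested when calibrating a
#: functional (protein-diversity-preserving) OTU threshold: 5%..20% in 1% steps
DEFAULT_CUTOFF_GRID = tuple(round(0.05 + 0.01 * i, 2) for i in range(16))


class ConfigError(ValueError):
    """Raised when a RunConfig violates one of its invariants."""


@dataclass
class RunConfig:
    """Parameters of one pipeline run.

    Defaults mirror the conventions of 454 amplicon surveys of sediment
    communities: barcode mismatch tolerance 1, primer mismatch tolerance 2,
    minimum trimmed length 200 bp, maximum homopolymer 8 nt, abundant-OTU
    threshold 1% relative abundance.
    """

    sample_map: dict[str, tuple[str, int]] = field(default_factory=dict)
    barcode_map: dict[str, str] = field(default_factory=dict)
    primer_forward: str = ""
    primer_reverse: str = ""
    marker: str = "16S"
    min_length: int = 200
    max_homopolymer: int = 8
    max_barcode_mismatch: int = 1
    max_primer_mismatch: int = 2
    cutoff: float = 0.03
    cutoff_grid: tuple[float, ...] = DEFAULT_CUTOFF_GRID
    abundance_threshold: float = 0.01
    permutations: int = 9999
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.marker not in VALID_MARKERS:
            raise ConfigError(
                f"unknown marker {self.marker!r}; expected one of {VALID_MARKERS}"
            )
        if self.min_length <= 0:
            raise ConfigError("min_length must be positive")
        if self.max_homopolymer < 1:
            raise ConfigError("max_homopolymer must be >= 1")
        barcodes = list(self.barcode_map)
        if len(set(barcodes)) != len(barcodes):
            raise ConfigError("barcode sequences must be unique")
        if barcodes:
            lengths = {len(b) for b in barcodes}
            if len(lengths) != 1:
                raise ConfigError("all MID barcodes must have equal length")
        for c in self.cutoff_grid:
            if not 0.0 < c < 1.0:
                raise ConfigError(f"cutoff {c} outside (0,1)")
        if not 0.0 < self.cutoff < 1.0:
            raise ConfigError(f"cutoff {self.cutoff} outside (0,1)")
        if not 0.0 < self.abundance_threshold < 1.0:
            raise ConfigError("abundance_threshold must lie in (0,1)")
        if self.permutations < 1:
            raise ConfigError("permutations must be >= 1")

    @property
    def is_coding(self) -> bool:
        """True for the protein-coding nitrite-reductase markers."""
        return self.marker in ("nirK", "nirS")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cutoff_grid"] = list(self.cutoff_grid)
        d["sample_map"] = {s: list(v) for s, v in self.sample_map.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "sample_map" in d:
            d["sample_map"] = {s: tuple(v) for s, v in d["sample_map"].items()}
        if "cutoff_grid" in d:
            d["cutoff_grid"] = tuple(d["cutoff_grid"])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load a config from YAML or JSON (decided by extension)."""
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls.from_dict(data)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(self.to_dict()))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=2))
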