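"""End-to-end orchestration: reads in, tables and summaries out.

Stage order mirrors the wet-lab analysis: demultiplex and QC-filter,
frameshift-correct and score-filter coding reads, remove listed
contaminants, dereplicate and precluster, flag and drop bimeras, compute
pairwise distances, cluster into OTUs (fixed 3% for 16S, calibrated
functional cutoff for nirK/nirS), then alpha/beta summaries and optional
qPCR quantification. Every stage appends its read-accounting to a log
whose totals always conserve the input count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import community, diversity, io, otu, preprocess, qpcr
from .config import RunConfig
from .frameshift import CodonProfile, correct_frameshifts, score_filter


@dataclass
class PipelineResult:
    config: RunConfig
    table: io.CountTable | None
    assignment: otu.OtuAssignment | None
    calibration: otu.CalibrationResult | None
    reports: dict[str, preprocess.FilterReport]
    alpha: pd.DataFrame | None = None
    beta: pd.DataFrame | None = None
    qpcr_curves: dict | None = None
    qpcr_table: pd.DataFrame | None = None
    stage_log: list[dict] = field(default_factory=list)

    @property
    def empty(self) -> bool:
        return self.table is None or self.table.data.empty


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(
    config: RunConfig,
    reads: Sequence[io.Read],
    profile: CodonProfile | None = None,
    score_threshold: float = 0.0,
    contaminant_ids: Sequence[str] = (),
    read_annotations: dict[str, str] | None = None,
    qpcr_plate: pd.DataFrame | None = None,
    outdir: str | Path | None = None,
    engine: str | None = None,
    precluster_diffs: int | None = None,
) -> PipelineResult:
    """Run the full analysis on a set of raw reads.

    Deterministic given ``config.seed``. For coding markers a
    :class:`CodonProfile` is required; ``score_threshold`` is the bit-score
    retention cutoff. ``engine`` picks the pairwise aligner (default:
    exact Needleman scoring up to 80 unique sequences, edlib beyond).
    """
    reports: dict[str, preprocess.FilterReport] = {}
    log: list[dict] = []
    n_input = len(reads)

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - reported with stage name
            raise StageError(name, exc) from exc

    kept, rep = stage("demultiplex", preprocess.demultiplex_all, reads, config)
    reports["demultiplex"] = rep
    log.append({"stage": "demultiplex", "in": n_input, "kept": rep.kept, **rep.rejected})

    if config.is_coding and kept:
        if profile is None:
            raise StageError("frameshift", ValueError("coding marker needs a CodonProfile"))
        results = [
            stage("frameshift", correct_frameshifts, r.id, r.seq, profile)
            for r in kept
        ]
        passed, frac = score_filter(results, score_threshold)
        ok_ids = {r.read_id for r in passed}
        corrected = {r.read_id: r.corrected for r in passed}
        survivors = []
        fs_report = preprocess.FilterReport()
        for r in kept:
            if r.id in ok_ids:
                r.seq = corrected[r.id]
                r.fate = "kept"
                survivors.append(r)
            else:
                r.fate = "rejected:low_score"
            fs_report.record(r.fate)
        reports["frameshift"] = fs_report
        log.append({"stage": "frameshift", "in": len(kept), "kept": len(survivors),
                    "kept_fraction": round(frac, 4)})
        kept = survivors

    if contaminant_ids:
        kept, rep = stage(
            "contaminants", preprocess.remove_contaminants,
            kept, contaminant_ids, read_annotations,
        )
        reports["contaminants"] = rep
        log.append({"stage": "contaminants", "in": rep.input, "kept": rep.kept,
                    **rep.rejected})

    if not kept:
        warnings.warn("no reads survived quality control; emitting empty result")
        result = PipelineResult(config, None, None, None, reports, stage_log=log)
        if outdir is not None:
            _write_artifacts(result, Path(outdir))
        return result

    uniques, counts = stage("dereplicate", otu.dereplicate, kept)
    log.append({"stage": "dereplicate", "in": len(kept), "uniques": len(uniques)})

    if precluster_diffs is None:
        # mothur pre.cluster convention: ~1 difference per 100 bp of read
        median_len = int(np.median([len(u[1]) for u in uniques])) if uniques else 0
        precluster_diffs = max(1, round(median_len / 100))
    if precluster_diffs > 0 and len(uniques) > 1:
        uniques, counts, _ = stage(
            "precluster", otu.precluster, uniques, counts, precluster_diffs
        )
        log.append({"stage": "precluster", "uniques": len(uniques)})

    chimera_report = preprocess.FilterReport()
    if len(uniques) > 2:
        calls = stage("chimera", preprocess.flag_bimeras, uniques)
        flagged = {uid for uid, call in calls.items() if call.flagged}
        n_reads_before = sum(u[2] for u in uniques)
        removed_reads = sum(u[2] for u in uniques if u[0] in flagged)
        uniques = [u for u in uniques if u[0] not in flagged]
        counts = {uid: c for uid, c in counts.items() if uid not in flagged}
        chimera_report.input = n_reads_before
        chimera_report.kept = n_reads_before - removed_reads
        if removed_reads:
            chimera_report.rejected["chimera"] = removed_reads
        log.append({"stage": "chimera", "flagged_uniques": len(flagged),
                    "removed_reads": removed_reads})
    reports["chimera"] = chimera_report

    ids = [u[0] for u in uniques]
    seqs = [u[1] for u in uniques]
    if engine is None:
        engine = "needleman" if len(ids) <= 80 else "edlib"

    calibration = None
    if len(ids) == 1:
        # degenerate: one unique sequence -> one OTU
        table = io.CountTable(pd.DataFrame(counts[ids[0]], index=["Otu0001"]))
        assignment = otu.OtuAssignment(
            config.cutoff, {ids[0]: "Otu0001"}, {"Otu0001": ids[0]}, table
        )
    else:
        dm = stage("distances", otu.pairwise_distance, ids, seqs, engine)
        if config.is_coding:
            calibration = stage(
                "calibrate", otu.calibrate_functional_cutoff,
                ids, seqs, counts, config.cutoff_grid, dm,
            )
            cutoff = calibration.chosen if calibration.succeeded else max(config.cutoff_grid)
            assignment = calibration.assignments[cutoff]
        else:
            assignment = stage(
                "cluster", otu.cluster_average_neighbor, dm, config.cutoff, counts
            )
        table = assignment.table
    log.append({"stage": "cluster", "cutoff": assignment.cutoff, "otus": assignment.n_otus})

    alpha = pd.DataFrame(
        [
            diversity.summarize_sample(table, s, config.abundance_threshold).row()
            for s in table.sample_ids
            if table.data[s].sum() > 0
        ]
    )

    beta = None
    groups = {s: g for s, (g, _) in config.sample_map.items() if s in table.sample_ids}
    if len(set(groups.values())) == 2 and len(groups) == len(table.sample_ids):
        beta = stage(
            "compare", community.beta_table, table, groups,
            config.abundance_threshold, config.permutations, config.seed,
        )

    curves = qtable = None
    if qpcr_plate is not None:
        curves, qtable = stage("qpcr", qpcr.process_plate, qpcr_plate)

    result = PipelineResult(
        config, table, assignment, calibration, reports,
        alpha, beta, curves, qtable, log,
    )
    if outdir is not None:
        _write_artifacts(result, Path(outdir))
    return result


def _write_artifacts(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    summary = {
        "marker": result.config.marker,
        "seed": result.config.seed,
        "stages": result.stage_log,
        "reports": {k: v.to_dict() for k, v in result.reports.items()},
    }
    if result.table is not None:
        io.write_count_table(result.table, outdir / "counts.tsv")
        summary["n_otus"] = len(result.table.otu_ids)
    if result.calibration is not None:
        pd.DataFrame(
            {
                "cutoff": result.calibration.grid,
                "otus": result.calibration.otu_counts,
                "min_aa_distance": result.calibration.min_aa_distances,
            }
        ).to_csv(outdir / "calibration.tsv", sep="\t", index=False)
        summary["chosen_cutoff"] = result.calibration.chosen
    if result.alpha is not None and not result.alpha.empty:
        result.alpha.to_csv(outdir / "alpha.tsv", sep="\t", index=False)
    if result.beta is not None:
        result.beta.to_csv(outdir / "beta.tsv", sep="\t")
    if result.qpcr_table is not None:
        result.qpcr_table.to_csv(outdir / "qpcr.tsv", sep="\t", index=False)
    io.write_json(summary, outdir / "run_summary.json")
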