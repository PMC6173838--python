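"""End-to-end orchestration: simulate -> orthologs -> anchor -> build -> losses.

``run_demo`` exercises every stage of the pipeline on one simulated dataset
and scores the results against the simulator's ground truth, writing all
intermediate files plus a JSON report.  The report contains no timestamps
or machine state, so identical configs produce byte-identical reports —
reproducibility is checked by diffing, not trusted.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .anchoring import AnchorCall, AnchorSummary, anchor_scaffolds, summarize
from .chromosomes import emit_agp, place_scaffolds
from .io_formats import group_by_seq, write_agp
from .loss import SYNTENIC_LOSS, LossCall, detect_losses
from .orthologs import best_hits, map_to_ref_genes
from .simulate import SimConfig, SimulatedDataset, plant_syntenic_loss, simulate

__all__ = ["RunConfig", "PipelineError", "run_demo", "pick_plantable_genes",
           "write_assignments_tsv", "write_calls_tsv", "write_losses_tsv",
           "summary_to_dict"]

log = logging.getLogger("syntenic")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class RunConfig:
    """One document configuring every stage of a demo run."""

    sim: SimConfig = field(default_factory=SimConfig)
    out_dir: str = "runs/demo"
    n_planted_losses: int = 5  # interior genes deleted to exercise loss detection
    min_len_bp: int = 0  # anchor every scaffold in the demo (simulated scaffolds are small)
    denominator: str = "hit_genes"
    gap_len: int = 100
    max_flank_scan: int = 3
    max_intervening: int = 0
    log_level: str = "INFO"


def pick_plantable_genes(dataset: SimulatedDataset, n: int, seed: int,
                         spacing: int = 3) -> list[str]:
    """Choose ``n`` reference genes safe to delete for loss-detection tests.

    Safe means: interior on their scaffold (both flanks exist) and at least
    ``spacing`` gene positions away from any other pick and from scaffold
    edges, so the flanking context of each planted loss stays intact.
    """
    rng = np.random.default_rng(seed)
    by_scaffold = group_by_seq(dataset.derived_annotation)
    candidates: list[str] = []
    for scaffold in sorted(by_scaffold):
        genes = by_scaffold[scaffold]
        for i in range(spacing, len(genes) - spacing):
            candidates.append(genes[i].gene_id)
    if len(candidates) < n:
        raise ValueError(f"only {len(candidates)} plantable genes, need {n}")
    picked: list[str] = []
    taken: set[str] = set()
    order = rng.permutation(len(candidates))
    by_id = {g.gene_id: g for g in dataset.derived_annotation}
    starts = {s: [g.gene_id for g in gs] for s, gs in by_scaffold.items()}
    index_of = {gid: (s, i) for s, gids in starts.items() for i, gid in enumerate(gids)}
    for k in order:
        gid = candidates[int(k)]
        s, i = index_of[gid]
        if any((s, j) in taken for j in range(i - spacing, i + spacing + 1)):
            continue
        picked.append(gid)
        taken.add((s, i))
        for j in range(i - spacing, i + spacing + 1):
            taken.add((s, j))
        if len(picked) == n:
            break
    if len(picked) < n:
        raise ValueError("could not place all planted losses with the required spacing")
    # plant_syntenic_loss expects reference gene ids.
    return sorted("rg" + by_id[g].gene_id[2:] for g in picked)


def run_demo(config: RunConfig) -> dict:
    """Run the whole pipeline on simulated data and score it against truth."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": _config_dict(config), "stages": {}}
    stage = "simulate"
    try:
        dataset = simulate(config.sim)
        if config.n_planted_losses:
            targets = pick_plantable_genes(
                dataset, config.n_planted_losses, seed=config.sim.seed + 1,
                spacing=config.max_flank_scan,
            )
            dataset = plant_syntenic_loss(dataset, targets)
        dataset.write(out)
        report["stages"]["simulate"] = {
            "ref_genes": len(dataset.ref_annotation),
            "derived_genes": len(dataset.derived_annotation),
            "scaffolds": len(dataset.derived_lengths),
            "hits": len(dataset.hit_table),
            "planted_losses": config.n_planted_losses,
        }
        log.info("simulate: %d ref genes, %d scaffolds", len(dataset.ref_annotation),
                 len(dataset.derived_lengths))

        stage = "best_hits"
        assignments = best_hits(dataset.hit_table)
        write_assignments_tsv(assignments, out / "orthologs.tsv")
        report["stages"]["best_hits"] = {"assigned": len(assignments)}

        stage = "anchor"
        result = anchor_scaffolds(
            assignments, dataset.derived_annotation, dataset.derived_lengths,
            min_len_bp=config.min_len_bp, denominator=config.denominator,
        )
        write_calls_tsv(result.calls, out / "calls.tsv")
        summary = summarize(result.calls)
        (out / "summary.json").write_text(
            json.dumps(summary_to_dict(summary), indent=1, sort_keys=True) + "\n"
        )
        truth_map = dataset.truth.scaffold_to_chrom
        called = [c for c in result.calls if c.assigned_chrom is not None]
        correct = sum(1 for c in called if truth_map.get(c.scaffold_id) == c.assigned_chrom)
        report["stages"]["anchor"] = {
            "calls": len(result.calls),
            "skipped_short": len(result.skipped),
            "summary": summary_to_dict(summary),
            "accuracy_vs_truth": round(correct / len(called), 6) if called else None,
        }

        stage = "build"
        placements = place_scaffolds(result.calls, assignments, dataset.derived_annotation)
        agp_rows = emit_agp(placements, dataset.derived_lengths, gap_len=config.gap_len)
        write_agp(agp_rows, out / "hypothetical.agp")
        report["stages"]["build"] = {
            "placements": len(placements),
            "hypothetical_chromosomes": len({p.target_chrom for p in placements}),
        }

        stage = "detect_losses"
        q2r = map_to_ref_genes(assignments, dataset.ref_annotation)
        calls = detect_losses(
            dataset.ref_annotation, dataset.derived_annotation, q2r,
            max_flank_scan=config.max_flank_scan, max_intervening=config.max_intervening,
        )
        write_losses_tsv(calls, out / "losses.tsv")
        called_ids = {c.ref_gene_id for c in calls if c.status == SYNTENIC_LOSS}
        true_ids = set(dataset.truth.lost_gene_ids)
        recall = len(called_ids & true_ids) / len(true_ids) if true_ids else None
        precision = len(called_ids & true_ids) / len(called_ids) if called_ids else None
        report["stages"]["detect_losses"] = {
            "loss_calls": len(calls),
            "syntenic_loss_calls": len(called_ids),
            "recall_vs_truth": None if recall is None else round(recall, 6),
            "precision_vs_truth": None if precision is None else round(precision, 6),
        }
    except Exception as exc:  # partial outputs stay, marked
        (out / "report.json.partial").write_text(
            json.dumps({"failed_stage": stage, "error": str(exc)}, indent=1) + "\n"
        )
        raise PipelineError(stage, exc) from exc

    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True) + "\n")
    return report


def _config_dict(config: RunConfig) -> dict:
    # The report captures the scientific configuration only; filesystem and
    # logging details would break byte-identity between equivalent runs.
    d = dataclasses.asdict(config)
    d.pop("out_dir")
    d.pop("log_level")
    return d


# ---------------------------------------------------------------------------
# Tabular writers shared by the pipeline and the CLI.

def write_assignments_tsv(assignments: Mapping, path) -> None:
    rows = [
        {
            "query_gene_id": a.query_gene_id,
            "subject_seq_id": a.subject_seq_id,
            "subject_midpoint": a.subject_midpoint,
            "bitscore": a.bitscore,
            "ambiguous": a.ambiguous,
            "reciprocal": a.reciprocal,
        }
        for a in (assignments[k] for k in sorted(assignments))
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_calls_tsv(calls: Sequence[AnchorCall], path) -> None:
    rows = [
        {
            "scaffold_id": c.scaffold_id,
            "scaffold_len": c.scaffold_len,
            "n_genes": c.n_genes,
            "n_hit_genes": c.n_hit_genes,
            "assigned_chrom": c.assigned_chrom or "",
            "top_fraction": round(c.top_fraction, 6),
            "class": c.klass,
            "ambiguous": c.ambiguous,
            "votes": ";".join(f"{k}:{v}" for k, v in sorted(c.votes.items())),
        }
        for c in calls
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_losses_tsv(calls: Sequence[LossCall], path) -> None:
    rows = [
        {
            "ref_gene_id": c.ref_gene_id,
            "ref_chrom": c.ref_chrom,
            "status": c.status,
            "left_flank_id": c.left_flank_id or "",
            "right_flank_id": c.right_flank_id or "",
            "query_scaffold": c.query_scaffold or "",
            "interval_start": "" if c.interval_start is None else c.interval_start,
            "interval_end": "" if c.interval_end is None else c.interval_end,
            "interval_len": "" if c.interval_len is None else c.interval_len,
            "n_intervening_query_genes": c.n_intervening_query_genes,
        }
        for c in calls
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def summary_to_dict(summary: AnchorSummary) -> dict:
    return {
        "schema_version": 1,
        "counts": dict(summary.counts),
        "bp": dict(summary.bp),
        "shares_pct": dict(summary.shares_pct),
        "total_bp": summary.total_bp,
    }
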