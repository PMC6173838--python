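"""Genome-evolution simulator producing fully ground-truthed test data.

The generator emulates the comparison underlying the pipeline: a reference
genome organised into chromosomes (29 by default, the channel catfish
karyotype, n = 29) and a derived genome descended from it through
inter-chromosomal translocations, chromosome fission (modelling the n = 29
vs n = 30 karyotype difference between channel and striped catfish), gene
losses and pseudogenizations, finally shattered into scaffolds the way a
draft short-read assembly is.  Alongside the two annotations it emits a
noisy BLAST-style hit table (missing, spurious and tied hits at configurable
rates) and the complete ground truth, so every downstream stage can be
scored for parameter recovery without any real sequencing data.

Geometry is deliberately simple: genes of a fixed length separated by fixed
intergenic spacers.  Scaffold and chromosome lengths are therefore exact
functions of their gene counts, which keeps bp bookkeeping testable.  The
simulator works at gene-model granularity; it does not mutate nucleotides,
simulate reads, or model repeats.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .io_formats import (
    GeneRecord,
    HitRecord,
    ValidationError,
    write_blast_tab,
    write_gff3,
    write_lengths,
)

__all__ = ["SimConfig", "GroundTruth", "SimulatedDataset", "simulate", "plant_syntenic_loss"]


@dataclass(frozen=True)
class SimConfig:
    """Study-design knobs for one simulated genome pair.

    Defaults model a 29-chromosome reference of 200 evenly spaced gene models
    per chromosome (2 kb genes, 8 kb spacers), a single fission taking the
    derived karyotype from n=29 to n=30, and noise-free hits.
    """

    seed: int = 0
    n_chrom_ref: int = 29
    genes_per_chrom: int = 200
    gene_len_bp: int = 2000
    intergenic_bp: int = 8000
    n_translocations: int = 0
    translocation_block_genes: int = 10
    n_fissions: int = 1
    n_losses: int = 0
    n_pseudogenes: int = 0
    scaffold_mean_genes: int = 25
    hit_miss_rate: float = 0.0
    spurious_hit_rate: float = 0.0
    paralog_tie_rate: float = 0.0

    def validate(self) -> None:
        rates = {
            "hit_miss_rate": self.hit_miss_rate,
            "spurious_hit_rate": self.spurious_hit_rate,
            "paralog_tie_rate": self.paralog_tie_rate,
        }
        for name, r in rates.items():
            if not (0.0 <= r <= 1.0):
                raise ValidationError(f"{name} must be in [0, 1], got {r}")
        counts = {
            "n_chrom_ref": self.n_chrom_ref,
            "genes_per_chrom": self.genes_per_chrom,
            "gene_len_bp": self.gene_len_bp,
            "intergenic_bp": self.intergenic_bp,
            "n_translocations": self.n_translocations,
            "translocation_block_genes": self.translocation_block_genes,
            "n_fissions": self.n_fissions,
            "n_losses": self.n_losses,
            "n_pseudogenes": self.n_pseudogenes,
            "scaffold_mean_genes": self.scaffold_mean_genes,
        }
        for name, c in counts.items():
            if c < 0:
                raise ValidationError(f"{name} must be non-negative, got {c}")
        if self.n_chrom_ref < 1 or self.genes_per_chrom < 1:
            raise ValidationError("need at least one chromosome and one gene per chromosome")
        if self.scaffold_mean_genes < 1:
            raise ValidationError("scaffold_mean_genes must be >= 1")
        total = self.n_chrom_ref * self.genes_per_chrom
        if self.n_translocations * self.translocation_block_genes > total:
            raise ValidationError(
                "n_translocations * translocation_block_genes exceeds the gene total"
            )
        if self.n_losses + self.n_pseudogenes > total:
            raise ValidationError("more losses+pseudogenizations than genes")


@dataclass
class GroundTruth:
    """Everything the simulator knows that the pipeline must rediscover."""

    gene_origin: dict[str, str]  # derived gene id -> ancestral (reference) chromosome
    scaffold_to_chrom: dict[str, str]  # scaffold id -> majority origin chromosome
    lost_gene_ids: set[str]  # reference gene ids with no derived descendant
    pseudogene_ids: set[str]  # derived gene ids flipped to pseudogene
    event_log: list[dict]  # ordered record of applied events

    def to_json(self) -> str:
        payload = {
            "gene_origin": dict(sorted(self.gene_origin.items())),
            "scaffold_to_chrom": dict(sorted(self.scaffold_to_chrom.items())),
            "lost_gene_ids": sorted(self.lost_gene_ids),
            "pseudogene_ids": sorted(self.pseudogene_ids),
            "event_log": self.event_log,
        }
        return json.dumps(payload, indent=1, sort_keys=False)


@dataclass
class SimulatedDataset:
    config: SimConfig
    ref_annotation: list[GeneRecord]
    derived_annotation: list[GeneRecord]
    hit_table: list[HitRecord]
    ref_lengths: dict[str, int]
    derived_lengths: dict[str, int]
    truth: GroundTruth

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Emit the dataset as plain-text files; deterministic for a fixed config."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "ref_gff3": outdir / "ref.gff3",
            "derived_gff3": outdir / "derived.gff3",
            "hits": outdir / "hits.tsv",
            "ref_lengths": outdir / "ref.lengths.tsv",
            "derived_lengths": outdir / "derived.lengths.tsv",
            "truth": outdir / "truth.json",
        }
        write_gff3(self.ref_annotation, paths["ref_gff3"])
        write_gff3(self.derived_annotation, paths["derived_gff3"])
        write_blast_tab(self.hit_table, paths["hits"])
        write_lengths(self.ref_lengths, paths["ref_lengths"])
        write_lengths(self.derived_lengths, paths["derived_lengths"])
        paths["truth"].write_text(self.truth.to_json() + "\n")
        return paths


# One simulated gene travelling through the event pipeline.
@dataclass
class _Gene:
    idx: int  # 1-based global index; names both the ref and derived gene
    origin_chrom: str
    biotype: str = "protein_coding"

    @property
    def ref_id(self) -> str:
        return f"rg{self.idx:05d}"

    @property
    def derived_id(self) -> str:
        return f"qg{self.idx:05d}"


def _layout(genes: Sequence[_Gene], seq_id: str, gene_len: int, spacer: int, derived: bool
            ) -> tuple[list[GeneRecord], int]:
    """Place genes evenly along a sequence: spacer, gene, spacer, gene, ..., spacer."""
    records = []
    pos = spacer
    for g in genes:
        records.append(
            GeneRecord(
                gene_id=g.derived_id if derived else g.ref_id,
                seq_id=seq_id,
                start=pos,
                end=pos + gene_len,
                strand="+",
                biotype=g.biotype if derived else "protein_coding",
            )
        )
        pos += gene_len + spacer
    return records, pos  # pos == total length including trailing spacer


def simulate(config: SimConfig) -> SimulatedDataset:
    """Generate a reference/derived genome pair, hit table and ground truth.

    Events apply in a fixed order: reciprocal block translocations, then
    fissions (split at an intergenic point), then gene losses, then
    pseudogenizations, then fragmentation into scaffolds whose gene counts
    are geometric with the configured mean.  Fragmentation breakpoints fall
    only in intergenic space, so gene models are never truncated.  The same
    config (seed included) always yields byte-identical outputs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    event_log: list[dict] = []

    # Reference: chr1..chrN, genes numbered sequentially along chromosomes.
    ref_chroms = [f"chr{i + 1}" for i in range(config.n_chrom_ref)]
    chrom_genes: dict[str, list[_Gene]] = {}
    idx = 1
    for chrom in ref_chroms:
        chrom_genes[chrom] = [
            _Gene(idx=idx + j, origin_chrom=chrom) for j in range(config.genes_per_chrom)
        ]
        idx += config.genes_per_chrom

    ref_annotation: list[GeneRecord] = []
    ref_lengths: dict[str, int] = {}
    for chrom in ref_chroms:
        recs, length = _layout(
            chrom_genes[chrom], chrom, config.gene_len_bp, config.intergenic_bp, derived=False
        )
        ref_annotation.extend(recs)
        ref_lengths[chrom] = length
    ref_by_id = {g.gene_id: g for g in ref_annotation}

    # The derived genome starts as a gene-order copy and accumulates events.
    derived: dict[str, list[_Gene]] = {c: list(chrom_genes[c]) for c in ref_chroms}
    derived_names = list(ref_chroms)

    # 1. Reciprocal block translocations.
    block = config.translocation_block_genes
    for _ in range(config.n_translocations):
        candidates = [c for c in derived_names if len(derived[c]) >= block]
        if len(candidates) < 2:
            break
        ca, cb = (candidates[i] for i in rng.choice(len(candidates), size=2, replace=False))
        ia = int(rng.integers(0, len(derived[ca]) - block + 1))
        ib = int(rng.integers(0, len(derived[cb]) - block + 1))
        blk_a = derived[ca][ia : ia + block]
        blk_b = derived[cb][ib : ib + block]
        derived[ca][ia : ia + block] = blk_b
        derived[cb][ib : ib + block] = blk_a
        event_log.append(
            {
                "event": "translocation",
                "chrom_a": ca,
                "chrom_b": cb,
                "index_a": ia,
                "index_b": ib,
                "block_genes": block,
                "genes_a": [g.ref_id for g in blk_a],
                "genes_b": [g.ref_id for g in blk_b],
            }
        )

    # 2. Fissions: split one chromosome at an intergenic point (n=29 -> n=30).
    n_new = 0
    for _ in range(config.n_fissions):
        splittable = [c for c in derived_names if len(derived[c]) >= 2]
        if not splittable:
            break
        chrom = splittable[int(rng.integers(0, len(splittable)))]
        cut = int(rng.integers(1, len(derived[chrom])))
        n_new += 1
        new_name = f"{chrom}_fis{n_new}"
        derived[new_name] = derived[chrom][cut:]
        derived[chrom] = derived[chrom][:cut]
        derived_names.append(new_name)
        event_log.append(
            {"event": "fission", "chrom": chrom, "new_chrom": new_name, "cut_index": cut}
        )

    # 3. Losses: delete genes outright.
    all_positions = [(c, i) for c in derived_names for i in range(len(derived[c]))]
    lost_ref_ids: set[str] = set()
    if config.n_losses:
        picks = rng.choice(len(all_positions), size=config.n_losses, replace=False)
        doomed = sorted(
            (all_positions[int(p)] for p in picks), key=lambda ci: (ci[0], -ci[1])
        )
        for chrom, i in doomed:  # delete right-to-left so indices stay valid
            gene = derived[chrom].pop(i)
            lost_ref_ids.add(gene.ref_id)
            event_log.append({"event": "loss", "gene": gene.ref_id, "chrom": chrom})

    # 4. Pseudogenizations: biotype flip, gene retained.
    pseudo_ids: set[str] = set()
    if config.n_pseudogenes:
        survivors = [(c, i) for c in derived_names for i in range(len(derived[c]))]
        picks = rng.choice(len(survivors), size=config.n_pseudogenes, replace=False)
        for p in sorted(int(x) for x in picks):
            chrom, i = survivors[p]
            g = derived[chrom][i]
            derived[chrom][i] = dataclasses.replace(g, biotype="pseudogene")
            pseudo_ids.add(g.derived_id)
            event_log.append({"event": "pseudogenization", "gene": g.ref_id, "chrom": chrom})

    # 5. Fragmentation into scaffolds; geometric gene counts, intergenic cuts.
    p_break = 1.0 / config.scaffold_mean_genes
    scaffolds: list[tuple[str, list[_Gene]]] = []
    n_sc = 0
    for chrom in derived_names:
        genes = derived[chrom]
        if not genes:
            continue
        start = 0
        while start < len(genes):
            size = int(rng.geometric(p_break))
            size = min(size, len(genes) - start)
            n_sc += 1
            name = f"sc{n_sc:07d}"
            scaffolds.append((name, genes[start : start + size]))
            event_log.append(
                {
                    "event": "fragmentation",
                    "scaffold": name,
                    "source_chrom": chrom,
                    "first_gene": genes[start].ref_id,
                    "n_genes": size,
                }
            )
            start += size

    derived_annotation: list[GeneRecord] = []
    derived_lengths: dict[str, int] = {}
    gene_origin: dict[str, str] = {}
    for name, genes in scaffolds:
        recs, length = _layout(
            genes, name, config.gene_len_bp, config.intergenic_bp, derived=True
        )
        derived_annotation.extend(recs)
        derived_lengths[name] = length
        for g in genes:
            gene_origin[g.derived_id] = g.origin_chrom

    scaffold_to_chrom = {
        name: _majority_origin(genes) for name, genes in scaffolds
    }

    # 6. Hit table: one true hit per surviving derived gene (unless missed),
    #    plus spurious and tied hits at the configured rates.
    hit_table: list[HitRecord] = []
    for name, genes in scaffolds:
        for g in genes:
            ref_rec = ref_by_id[g.ref_id]
            if rng.random() >= config.hit_miss_rate:
                score = 500.0 + float(rng.uniform(-5.0, 5.0))
                hit_table.append(_make_hit(g, ref_rec, config, round(score, 1)))
                if rng.random() < config.paralog_tie_rate and config.n_chrom_ref > 1:
                    other = _random_other_chrom(rng, ref_chroms, g.origin_chrom)
                    hit_table.append(
                        _random_hit(rng, g, other, ref_lengths[other], config,
                                    bitscore=round(score, 1))
                    )
            if rng.random() < config.spurious_hit_rate:
                other = ref_chroms[int(rng.integers(0, len(ref_chroms)))]
                hit_table.append(
                    _random_hit(rng, g, other, ref_lengths[other], config,
                                bitscore=round(float(rng.uniform(50.0, 300.0)), 1))
                )

    truth = GroundTruth(
        gene_origin=gene_origin,
        scaffold_to_chrom=scaffold_to_chrom,
        lost_gene_ids=lost_ref_ids,
        pseudogene_ids=pseudo_ids,
        event_log=event_log,
    )
    return SimulatedDataset(
        config=config,
        ref_annotation=ref_annotation,
        derived_annotation=derived_annotation,
        hit_table=hit_table,
        ref_lengths=ref_lengths,
        derived_lengths=derived_lengths,
        truth=truth,
    )


def _majority_origin(genes: Sequence[_Gene]) -> str:
    votes: dict[str, int] = {}
    for g in genes:
        votes[g.origin_chrom] = votes.get(g.origin_chrom, 0) + 1
    best = max(votes.values())
    return min(c for c, v in votes.items() if v == best)


def _make_hit(g: _Gene, ref_rec: GeneRecord, config: SimConfig, bitscore: float) -> HitRecord:
    return HitRecord(
        query_id=g.derived_id,
        subject_id=ref_rec.seq_id,
        pct_identity=98.0,
        aln_len=config.gene_len_bp,
        mismatches=int(config.gene_len_bp * 0.02),
        gap_opens=0,
        q_start=1,
        q_end=config.gene_len_bp,
        s_start=ref_rec.start + 1,
        s_end=ref_rec.end,
        evalue=0.0,
        bitscore=bitscore,
    )


def _random_other_chrom(rng: np.random.Generator, chroms: Sequence[str], avoid: str) -> str:
    others = [c for c in chroms if c != avoid]
    return others[int(rng.integers(0, len(others)))]


def _random_hit(rng: np.random.Generator, g: _Gene, chrom: str, chrom_len: int,
                config: SimConfig, bitscore: float) -> HitRecord:
    span = min(config.gene_len_bp, chrom_len - 1)
    start = int(rng.integers(1, max(2, chrom_len - span)))
    return HitRecord(
        query_id=g.derived_id,
        subject_id=chrom,
        pct_identity=80.0,
        aln_len=span,
        mismatches=int(span * 0.2),
        gap_opens=1,
        q_start=1,
        q_end=span,
        s_start=start,
        s_end=start + span - 1,
        evalue=1e-20,
        bitscore=bitscore,
    )


def plant_syntenic_loss(dataset: SimulatedDataset, target_gene_ids: Iterable[str]
                        ) -> SimulatedDataset:
    """Delete specific reference genes from the derived genome, flanks intact.

    ``target_gene_ids`` name reference genes (``rg...``).  Each target must be
    an interior gene: its derived descendant must have at least one gene on
    each side on its scaffold, otherwise there is no flanking context for
    loss detection and the call is rejected.  Returns a new dataset with the
    targets removed from the derived annotation and hit table, scaffold
    coordinates re-laid-out, and ground truth updated.
    """
    targets = set(target_gene_ids)
    ref_ids = {g.gene_id for g in dataset.ref_annotation}
    missing = targets - ref_ids
    if missing:
        raise ValidationError(f"targets not in reference annotation: {sorted(missing)}")

    derived_ids = {"qg" + t[2:] for t in targets}
    by_scaffold: dict[str, list[GeneRecord]] = {}
    for g in dataset.derived_annotation:
        by_scaffold.setdefault(g.seq_id, []).append(g)

    config = dataset.config
    new_annotation: list[GeneRecord] = []
    new_lengths: dict[str, int] = {}
    removed: set[str] = set()
    for scaffold in sorted(by_scaffold):
        genes = sorted(by_scaffold[scaffold], key=lambda g: g.start)
        keep: list[GeneRecord] = []
        for i, g in enumerate(genes):
            if g.gene_id in derived_ids:
                if i == 0 or i == len(genes) - 1:
                    raise ValidationError(
                        f"no flank: gene {g.gene_id} sits at the edge of {scaffold}"
                    )
                removed.add(g.gene_id)
            else:
                keep.append(g)
        pos = config.intergenic_bp
        for g in keep:
            new_annotation.append(dataclasses.replace(g, start=pos, end=pos + g.length))
            pos += g.length + config.intergenic_bp
        new_lengths[scaffold] = pos

    not_present = derived_ids - removed
    if not_present:
        raise ValidationError(
            f"targets already absent from the derived genome: {sorted(not_present)}"
        )

    new_hits = [h for h in dataset.hit_table if h.query_id not in derived_ids]
    truth = dataset.truth
    new_truth = GroundTruth(
        gene_origin={k: v for k, v in truth.gene_origin.items() if k not in derived_ids},
        scaffold_to_chrom=dict(truth.scaffold_to_chrom),
        lost_gene_ids=truth.lost_gene_ids | targets,
        pseudogene_ids=set(truth.pseudogene_ids),
        event_log=truth.event_log
        + [{"event": "planted_loss", "gene": t} for t in sorted(targets)],
    )
    return SimulatedDataset(
        config=config,
        ref_annotation=list(dataset.ref_annotation),
        derived_annotation=new_annotation,
        hit_table=new_hits,
        ref_lengths=dict(dataset.ref_lengths),
        derived_lengths=new_lengths,
        truth=new_truth,
    )
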