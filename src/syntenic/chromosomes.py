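"""Order and orient anchored scaffolds into hypothetical chromosomes.

Anchoring says which chromosome a scaffold belongs to; this module decides
where on it.  Each placed scaffold is positioned by the median subject
coordinate of the genes that voted for its chromosome (median, not mean,
so a minority of translocated genes cannot drag a scaffold around), and
oriented by the sign of the rank correlation between gene order along the
scaffold and subject position: genes running with the chromosome give "+",
against it "-".  Scaffolds with fewer than two informative genes cannot be
oriented and default to "+" with ``low_confidence`` set.

The result is emitted as AGP 2.1, the standard format for describing how
components tile a larger object, with fixed-length placeholder gaps between
consecutive scaffolds.  These objects are *hypothetical* chromosomes — an
inference from a relative's karyotype, not physical mapping — and the gap
lengths carry no biological meaning.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import median
from typing import Iterable, Mapping, Sequence

from scipy.stats import kendalltau

from .anchoring import AnchorCall, CONSERVED, REARRANGED
from .io_formats import AgpRow, GeneRecord, ValidationError, group_by_seq
from .orthologs import OrthologAssignment

__all__ = ["ScaffoldPlacement", "place_scaffolds", "emit_agp", "placements_from_agp"]


@dataclass(frozen=True)
class ScaffoldPlacement:
    scaffold_id: str
    target_chrom: str
    order_index: int
    orientation: str  # "+" or "-"
    median_subject_pos: int
    orientation_support: int  # informative (untied) gene pairs
    low_confidence: bool


def place_scaffolds(calls: Iterable[AnchorCall],
                    assignments: Mapping[str, OrthologAssignment],
                    derived_annotation: Iterable[GeneRecord]
                    ) -> list[ScaffoldPlacement]:
    """Assign an order index and orientation to every anchored scaffold.

    Only conserved and rearranged calls are placed (unplaced scaffolds have
    no vote to position them by).  Within a chromosome, scaffolds sort by
    median subject position, ties broken by longer scaffold then name.
    """
    by_scaffold = group_by_seq(derived_annotation)
    per_chrom: dict[str, list[tuple]] = {}
    for call in calls:
        if call.klass not in (CONSERVED, REARRANGED):
            continue
        if call.scaffold_id not in by_scaffold:
            raise ValidationError(
                f"call references scaffold {call.scaffold_id!r} absent from the annotation"
            )
        chrom = call.assigned_chrom
        # Genes voting for the assigned chromosome, in scaffold order.
        voters = [
            (g.start, assignments[g.gene_id].subject_midpoint)
            for g in by_scaffold[call.scaffold_id]
            if g.gene_id in assignments
            and assignments[g.gene_id].subject_seq_id == chrom
        ]
        positions = [p for _, p in voters]
        med = int(median(positions))
        orientation, support = _orient(voters)
        per_chrom.setdefault(chrom, []).append(
            (med, -call.scaffold_len, call.scaffold_id, orientation, support)
        )

    placements: list[ScaffoldPlacement] = []
    for chrom in sorted(per_chrom):
        entries = sorted(per_chrom[chrom])
        for idx, (med, _neglen, scaffold, orientation, support) in enumerate(entries):
            placements.append(
                ScaffoldPlacement(
                    scaffold_id=scaffold,
                    target_chrom=chrom,
                    order_index=idx,
                    orientation=orientation,
                    median_subject_pos=med,
                    orientation_support=support,
                    low_confidence=support < 1,
                )
            )
    return placements


def _orient(voters: Sequence[tuple[int, int]]) -> tuple[str, int]:
    """Orientation from the rank correlation of scaffold order vs subject position.

    Returns ("+" or "-", number of informative pairs).  Informative pairs are
    those untied in both coordinates; with fewer than two genes or a zero
    correlation the orientation defaults to "+".
    """
    if len(voters) < 2:
        return "+", 0
    xs = [s for s, _ in voters]
    ys = [p for _, p in voters]
    support = sum(
        1
        for i in range(len(voters))
        for j in range(i + 1, len(voters))
        if xs[i] != xs[j] and ys[i] != ys[j]
    )
    if support == 0:
        return "+", 0
    tau = kendalltau(xs, ys).statistic
    return ("-" if tau < 0 else "+"), support


def emit_agp(placements: Iterable[ScaffoldPlacement],
             lengths: Mapping[str, int],
             gap_len: int = 100) -> list[AgpRow]:
    """Serialize placements as AGP rows, one object per hypothetical chromosome.

    Object IDs are ``hypChr<N>`` (a leading ``chr`` on the source chromosome
    name is folded in rather than repeated).  Consecutive scaffolds are
    separated by a fixed ``gap_len`` gap of type "scaffold" — a placeholder,
    not an estimate.
    """
    per_chrom: dict[str, list[ScaffoldPlacement]] = {}
    for p in placements:
        per_chrom.setdefault(p.target_chrom, []).append(p)

    rows: list[AgpRow] = []
    for chrom in sorted(per_chrom):
        entries = sorted(per_chrom[chrom], key=lambda p: p.order_index)
        seen = {p.order_index for p in entries}
        if len(seen) != len(entries):
            raise ValidationError(f"duplicate order_index on chromosome {chrom}")
        obj = "hypChr" + (chrom[3:] if chrom.lower().startswith("chr") else chrom)
        pos, part = 1, 1
        for i, p in enumerate(entries):
            if i > 0:
                rows.append(
                    AgpRow(
                        object_id=obj,
                        object_start=pos,
                        object_end=pos + gap_len - 1,
                        part_number=part,
                        component_type="U",
                        gap_length=gap_len,
                        gap_type="scaffold",
                        linkage="no",
                        evidence="align_genus",
                    )
                )
                pos += gap_len
                part += 1
            if p.scaffold_id not in lengths:
                raise ValidationError(f"scaffold {p.scaffold_id!r} missing from lengths")
            slen = lengths[p.scaffold_id]
            rows.append(
                AgpRow(
                    object_id=obj,
                    object_start=pos,
                    object_end=pos + slen - 1,
                    part_number=part,
                    component_type="W",
                    component_id=p.scaffold_id,
                    component_start=1,
                    component_end=slen,
                    orientation=p.orientation,
                )
            )
            pos += slen
            part += 1
    return rows


def placements_from_agp(rows: Iterable[AgpRow]) -> list[ScaffoldPlacement]:
    """Reconstruct scaffold order and orientation from AGP rows (round-trip aid).

    Positional metadata that AGP does not carry (median subject position,
    support) comes back zeroed.
    """
    placements: list[ScaffoldPlacement] = []
    counters: dict[str, int] = {}
    for r in rows:
        if r.component_type != "W":
            continue
        chrom = r.object_id
        if chrom.startswith("hypChr"):
            chrom = "chr" + chrom[len("hypChr"):]
        idx = counters.get(chrom, 0)
        counters[chrom] = idx + 1
        placements.append(
            ScaffoldPlacement(
                scaffold_id=r.component_id,
                target_chrom=chrom,
                order_index=idx,
                orientation=r.orientation,
                median_subject_pos=0,
                orientation_support=0,
                low_confidence=False,
            )
        )
    return placements
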