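"""Majority-vote anchoring of draft scaffolds onto reference chromosomes.

Each scaffold's gene models vote with the chromosome their best hit lands
on.  A scaffold whose top chromosome collects strictly more than half of
the votes is classified *conserved* — hypothesized to descend from a common
ancestral chromosome shared with the reference species.  A scaffold whose
top chromosome gets 50% or less is *rearranged*: its gene content is split
across chromosomes, the signature of inter-chromosomal rearrangement since
the species split.  Scaffolds with no voting genes at all are *unplaced*.

The 50% threshold is strict (a 5-vs-5 split is rearranged, not conserved),
and by default the denominator is the genes that actually have hits; the
``all_genes`` denominator, which punishes scaffolds for unhittable genes,
is available as an option.  Scaffolds below a length cutoff (1 Mb by
default, matching the usual "anchor only the big scaffolds" practice) are
excluded from calls and reported separately.

``summarize`` turns the calls into genome-wide bookkeeping: bp per class
and the percent share of conserved vs rearranged sequence, rounded with
largest-remainder repair so the two shares always print as a sum of 100.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io_formats import GeneRecord, ValidationError, group_by_seq
from .orthologs import OrthologAssignment

__all__ = ["AnchorCall", "AnchorResult", "AnchorSummary", "anchor_scaffolds", "summarize"]

CONSERVED = "conserved"
REARRANGED = "rearranged"
UNPLACED = "unplaced"


@dataclass(frozen=True)
class AnchorCall:
    scaffold_id: str
    scaffold_len: int
    n_genes: int
    n_hit_genes: int
    votes: Mapping[str, int]
    assigned_chrom: str | None
    top_fraction: float
    klass: str
    ambiguous: bool  # top vote tied across chromosomes


@dataclass(frozen=True)
class AnchorResult:
    calls: tuple[AnchorCall, ...]
    skipped: tuple[str, ...]  # scaffolds below the length cutoff, not called


@dataclass(frozen=True)
class AnchorSummary:
    """Per-class scaffold counts, bp totals and percent shares of classified bp."""

    counts: Mapping[str, int]
    bp: Mapping[str, int]
    shares_pct: Mapping[str, int]  # over conserved+rearranged bp; sums to 100
    total_bp: int


def anchor_scaffolds(assignments: Mapping[str, OrthologAssignment],
                     derived_annotation: Iterable[GeneRecord],
                     lengths: Mapping[str, int],
                     min_len_bp: int = 1_000_000,
                     denominator: str = "hit_genes") -> AnchorResult:
    """Vote every scaffold onto a chromosome and classify it.

    ``denominator`` selects what the winning fraction is measured against:
    ``"hit_genes"`` (default) divides by genes with an assignment,
    ``"all_genes"`` by all genes annotated on the scaffold.
    """
    if denominator not in ("hit_genes", "all_genes"):
        raise ValidationError(f"unknown denominator {denominator!r}")
    by_scaffold = group_by_seq(derived_annotation)
    for scaffold in by_scaffold:
        if scaffold not in lengths:
            raise ValidationError(f"scaffold {scaffold!r} missing from the length table")

    calls: list[AnchorCall] = []
    skipped: list[str] = []
    for scaffold in sorted(by_scaffold):
        scaffold_len = lengths[scaffold]
        if scaffold_len < min_len_bp:
            skipped.append(scaffold)
            continue
        genes = by_scaffold[scaffold]
        votes: dict[str, int] = {}
        for g in genes:
            a = assignments.get(g.gene_id)
            if a is not None:
                votes[a.subject_seq_id] = votes.get(a.subject_seq_id, 0) + 1
        n_hit = sum(votes.values())
        if n_hit == 0:
            calls.append(
                AnchorCall(scaffold, scaffold_len, len(genes), 0, {}, None, 0.0,
                           UNPLACED, ambiguous=False)
            )
            continue
        top = max(votes.values())
        winners = sorted(c for c, v in votes.items() if v == top)
        assigned = winners[0]
        denom = n_hit if denominator == "hit_genes" else len(genes)
        frac = top / denom
        klass = CONSERVED if frac > 0.5 else REARRANGED
        calls.append(
            AnchorCall(
                scaffold_id=scaffold,
                scaffold_len=scaffold_len,
                n_genes=len(genes),
                n_hit_genes=n_hit,
                votes=dict(sorted(votes.items())),
                assigned_chrom=assigned,
                top_fraction=frac,
                klass=klass,
                ambiguous=len(winners) > 1,
            )
        )
    return AnchorResult(calls=tuple(calls), skipped=tuple(skipped))


def _largest_remainder(values: Sequence[float], total: int = 100) -> list[int]:
    """Round percentages to integers that sum exactly to ``total``."""
    floors = [int(v) for v in values]
    shortfall = total - sum(floors)
    order = sorted(range(len(values)), key=lambda i: (-(values[i] - floors[i]), i))
    out = list(floors)
    for i in order[:shortfall]:
        out[i] += 1
    return out


def summarize(calls: Iterable[AnchorCall]) -> AnchorSummary:
    """Aggregate calls into per-class bp totals and percent shares.

    Shares are computed over the classified (conserved + rearranged) bp only,
    so unplaced sequence never dilutes the two-way split, and rounded by the
    largest-remainder method so the printed shares sum to exactly 100.
    """
    calls = list(calls)
    if not calls:
        raise ValidationError("nothing to summarize: empty call set")
    counts = {CONSERVED: 0, REARRANGED: 0, UNPLACED: 0}
    bp = {CONSERVED: 0, REARRANGED: 0, UNPLACED: 0}
    for c in calls:
        counts[c.klass] += 1
        bp[c.klass] += c.scaffold_len
    total_bp = sum(bp.values())
    classified = bp[CONSERVED] + bp[REARRANGED]
    if classified > 0:
        raw = [100.0 * bp[CONSERVED] / classified, 100.0 * bp[REARRANGED] / classified]
        conserved_pct, rearranged_pct = _largest_remainder(raw)
        shares = {CONSERVED: conserved_pct, REARRANGED: rearranged_pct}
    else:
        shares = {}
    return AnchorSummary(counts=counts, bp=bp, shares_pct=shares, total_bp=total_bp)
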