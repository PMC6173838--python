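"""Reduce a BLAST-style hit table to one assignment per query gene.

The anchoring vote needs a single "gene match" per gene model: the subject
sequence (chromosome) its best hit lands on.  ``best_hits`` performs that
reduction with a total deterministic order — bitscore, then alignment
length, then lexicographically smallest subject, then subject start — so
the output never depends on input row order.  A tie in top bitscore across
distinct subjects is flagged ``ambiguous`` rather than hidden.

``reciprocal_filter`` adds the classic reciprocal-best-hit (RBH) orthology
check on top: a pair is reciprocal when each partner is the other's best
hit.  Non-reciprocal assignments are retained but flagged, so callers can
choose the stricter mode without losing coverage.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, replace
from typing import Iterable, Mapping

from .io_formats import GeneRecord, HitRecord, group_by_seq

__all__ = ["OrthologAssignment", "best_hits", "reciprocal_filter", "map_to_ref_genes"]


@dataclass(frozen=True)
class OrthologAssignment:
    query_gene_id: str
    subject_seq_id: str
    subject_midpoint: int  # 0-based midpoint of the subject span
    bitscore: float
    ambiguous: bool = False  # top bitscore tied across distinct subjects
    reciprocal: bool = False


def _rank_key(h: HitRecord) -> tuple:
    # Higher bitscore, then longer alignment, then lexicographically smallest
    # subject, then smallest subject start: a total order for determinism.
    lo, _ = h.subject_interval
    return (-h.bitscore, -h.aln_len, h.subject_id, lo, h.q_start)


def best_hits(hits: Iterable[HitRecord], sum_hsps: bool = False
              ) -> dict[str, OrthologAssignment]:
    """Pick each query's best hit; queries without hits are simply absent.

    With ``sum_hsps=True``, bitscores of multiple HSPs between one query and
    one subject are summed before ranking subjects (the best single HSP of
    the winning subject still supplies the reported coordinates).  Default is
    the single best HSP, the simplest reading of a per-gene best hit.
    """
    per_query: dict[str, list[HitRecord]] = {}
    for h in hits:
        per_query.setdefault(h.query_id, []).append(h)

    out: dict[str, OrthologAssignment] = {}
    for query, qhits in per_query.items():
        qhits = sorted(qhits, key=_rank_key)
        if sum_hsps:
            totals: dict[str, float] = {}
            for h in qhits:
                totals[h.subject_id] = totals.get(h.subject_id, 0.0) + h.bitscore
            top = max(totals.values())
            winners = sorted(s for s, t in totals.items() if t == top)
            subject = winners[0]
            rep = next(h for h in qhits if h.subject_id == subject)
            ambiguous = len(winners) > 1
            score = top
        else:
            rep = qhits[0]
            subject = rep.subject_id
            top = rep.bitscore
            ambiguous = len({h.subject_id for h in qhits if h.bitscore == top}) > 1
            score = top
        out[query] = OrthologAssignment(
            query_gene_id=query,
            subject_seq_id=subject,
            subject_midpoint=rep.subject_midpoint,
            bitscore=score,
            ambiguous=ambiguous,
        )
    return out


def reciprocal_filter(forward: Mapping[str, OrthologAssignment],
                      reverse: Mapping[str, OrthologAssignment]
                      ) -> dict[str, OrthologAssignment]:
    """Flag forward assignments that are mutual best hits.

    ``reverse`` must map subject-side identifiers back into query-side
    identifiers with the same best-hit semantics.  An assignment g -> s is
    reciprocal iff reverse(s) -> g.  Everything is retained; only the flag
    changes.
    """
    out: dict[str, OrthologAssignment] = {}
    for query, a in forward.items():
        back = reverse.get(a.subject_seq_id)
        out[query] = replace(a, reciprocal=back is not None and back.subject_seq_id == query)
    return out


def map_to_ref_genes(assignments: Mapping[str, OrthologAssignment],
                     ref_annotation: Iterable[GeneRecord]
                     ) -> dict[str, str]:
    """Resolve chromosome-level assignments to the reference gene they land in.

    BLAST hits against whole chromosomes carry coordinates, not gene
    identities; this locates each assignment's subject midpoint inside the
    reference gene models.  Assignments whose midpoint falls in intergenic
    space are dropped.  Returns query gene id -> reference gene id.
    """
    by_chrom = group_by_seq(ref_annotation)
    starts = {c: [g.start for g in genes] for c, genes in by_chrom.items()}
    out: dict[str, str] = {}
    for query, a in assignments.items():
        genes = by_chrom.get(a.subject_seq_id)
        if not genes:
            continue
        i = bisect_right(starts[a.subject_seq_id], a.subject_midpoint) - 1
        if i >= 0 and genes[i].start <= a.subject_midpoint < genes[i].end:
            out[query] = genes[i].gene_id
    return out
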