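"""Synteny-based detection of lineage-specific gene losses.

A reference gene is a candidate loss when no query gene maps onto it.  The
candidate becomes a *syntenic* loss call when its genomic neighbourhood is
demonstrably conserved in the query: the nearest flanking reference genes
that do have query orthologs lie together on one query scaffold with (by
default) nothing unexplained between them.  That is the classic
conserved-flanks argument — if the neighbours of a missing gene sit side by
side in the query genome, the gene was lost rather than simply left out of
the assembly's gene set.

The module reports, for each syntenic loss, the query intergenic interval
between the inner edges of the two flank orthologs.  It deliberately does
NOT scan that interval for residual sequence similarity; the interval
coordinates are the hand-off point for such an external check (e.g. a
translated BLAST of the interval).  A run of consecutive lost genes shares
one interval — a two-gene cluster loss yields two calls with the same
flanks, matching how tandem losses present in real genomes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .io_formats import GeneRecord, ValidationError, group_by_seq

__all__ = ["LossCall", "detect_losses", "SYNTENIC_LOSS", "UNRESOLVED_SPLIT_FLANKS",
           "UNRESOLVED_FLANK_MISSING", "UNRESOLVED_INTERVENING_GENES"]

SYNTENIC_LOSS = "syntenic_loss"
UNRESOLVED_SPLIT_FLANKS = "unresolved_split_flanks"
UNRESOLVED_FLANK_MISSING = "unresolved_flank_missing"
UNRESOLVED_INTERVENING_GENES = "unresolved_intervening_genes"


@dataclass(frozen=True)
class LossCall:
    ref_gene_id: str
    ref_chrom: str
    status: str
    left_flank_id: str | None = None
    right_flank_id: str | None = None
    query_scaffold: str | None = None
    interval_start: int | None = None  # 0-based half-open, query coordinates
    interval_end: int | None = None
    n_intervening_query_genes: int = 0

    @property
    def interval_len(self) -> int | None:
        if self.interval_start is None or self.interval_end is None:
            return None
        return self.interval_end - self.interval_start


def detect_losses(ref_annotation: Iterable[GeneRecord],
                  query_annotation: Iterable[GeneRecord],
                  query_to_ref: Mapping[str, str],
                  max_flank_scan: int = 3,
                  max_intervening: int = 0) -> list[LossCall]:
    """Call reference genes lost from the query inside conserved flanking context.

    Parameters
    ----------
    query_to_ref
        Orthology map, query gene id -> reference gene id (best-hit or RBH;
        see :func:`syntenic.orthologs.map_to_ref_genes`).  A reference gene
        is "absent" when it is nobody's image under this map.
    max_flank_scan
        How many reference genes to scan on each side for the nearest flank
        with a query ortholog.
    max_intervening
        How many unrelated query genes may sit between the flank orthologs
        before the locus stops counting as a clean syntenic loss.  Unrelated
        means: not an ortholog of any reference gene between the flanks.

    Returns one :class:`LossCall` per ortholog-less reference gene, sorted by
    reference position.  Statuses other than ``syntenic_loss`` mark loci
    where the flanking context could not establish synteny.
    """
    ref_by_chrom = group_by_seq(ref_annotation)
    query_by_scaffold = group_by_seq(query_annotation)
    query_index: dict[str, tuple[str, int, GeneRecord]] = {}
    for scaffold, genes in query_by_scaffold.items():
        for i, g in enumerate(genes):
            query_index[g.gene_id] = (scaffold, i, g)

    # Invert the orthology map: reference gene -> its query genes.
    ref_to_queries: dict[str, list[str]] = {}
    for q, r in query_to_ref.items():
        ref_to_queries.setdefault(r, []).append(q)
    for qs in ref_to_queries.values():
        qs.sort()

    calls: list[LossCall] = []
    for chrom in sorted(ref_by_chrom):
        genes = ref_by_chrom[chrom]
        for i, g in enumerate(genes):
            if g.gene_id in ref_to_queries:
                continue  # has a query ortholog: not lost
            left = _nearest_flank(genes, i, -1, max_flank_scan, ref_to_queries)
            right = _nearest_flank(genes, i, +1, max_flank_scan, ref_to_queries)
            if left is None or right is None:
                calls.append(LossCall(g.gene_id, chrom, UNRESOLVED_FLANK_MISSING))
                continue
            lq = _query_ortholog(left, ref_to_queries, query_index)
            rq = _query_ortholog(right, ref_to_queries, query_index)
            l_scaf, _l_idx, l_gene = query_index[lq]
            r_scaf, _r_idx, r_gene = query_index[rq]
            if l_scaf != r_scaf:
                calls.append(
                    LossCall(g.gene_id, chrom, UNRESOLVED_SPLIT_FLANKS,
                             left_flank_id=left.gene_id, right_flank_id=right.gene_id)
                )
                continue
            intervening = _count_unrelated_between(
                query_by_scaffold[l_scaf], query_index, lq, rq,
                genes, left, right, query_to_ref,
            )
            # Interval between the inner edges of the flank orthologs,
            # symmetric in which flank is "left" on the query scaffold.
            first, second = sorted((l_gene, r_gene), key=lambda x: x.start)
            start, end = first.end, max(first.end, second.start)
            status = SYNTENIC_LOSS if intervening <= max_intervening \
                else UNRESOLVED_INTERVENING_GENES
            calls.append(
                LossCall(
                    ref_gene_id=g.gene_id,
                    ref_chrom=chrom,
                    status=status,
                    left_flank_id=left.gene_id,
                    right_flank_id=right.gene_id,
                    query_scaffold=l_scaf,
                    interval_start=start if status == SYNTENIC_LOSS else None,
                    interval_end=end if status == SYNTENIC_LOSS else None,
                    n_intervening_query_genes=intervening,
                )
            )
    return calls


def _nearest_flank(genes, i, step, max_scan, ref_to_queries):
    for d in range(1, max_scan + 1):
        j = i + step * d
        if j < 0 or j >= len(genes):
            return None
        if genes[j].gene_id in ref_to_queries:
            return genes[j]
    return None


def _query_ortholog(ref_gene, ref_to_queries, query_index):
    # A flank may map to several query genes (e.g. a split model); take the
    # lexicographically first that is present in the query annotation.
    for q in ref_to_queries[ref_gene.gene_id]:
        if q in query_index:
            return q
    raise ValidationError(
        f"flank {ref_gene.gene_id} has orthologs absent from the query annotation"
    )


def _count_unrelated_between(scaffold_genes, query_index, lq, rq,
                             ref_genes, left, right, query_to_ref) -> int:
    """Query genes strictly between the flank orthologs that the reference
    interval does not account for."""
    li = query_index[lq][1]
    ri = query_index[rq][1]
    lo, hi = sorted((li, ri))
    between_ref_ids = {
        g.gene_id
        for g in ref_genes
        if min(left.start, right.start) < g.start < max(left.start, right.start)
    }
    count = 0
    for g in scaffold_genes[lo + 1 : hi]:
        if query_to_ref.get(g.gene_id) not in between_ref_ids:
            count += 1
    return count
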