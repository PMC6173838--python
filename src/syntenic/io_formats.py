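"""Readers and writers for the external formats the pipeline touches.

Coordinate contract
-------------------
Internally every interval is 0-based half-open, so ``length = end - start``
with no off-by-one arithmetic anywhere else in the package.  The external
formats disagree with that convention and with each other:

* GFF3 gene rows are 1-based, inclusive on both ends.
* BLAST tabular (``-outfmt 6``) subject/query coordinates are 1-based
  inclusive and may run high-to-low on the minus strand.
* AGP 2.1 object and component coordinates are 1-based inclusive.

Conversion happens here, at the boundary, and nowhere else.  BLAST rows are
kept verbatim (1-based, orientation preserved) inside :class:`HitRecord`
because downstream code treats them as an opaque alignment dialect and
converts on demand.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "GeneRecord",
    "HitRecord",
    "AgpRow",
    "FormatError",
    "ValidationError",
    "read_gff3",
    "write_gff3",
    "read_blast_tab",
    "write_blast_tab",
    "read_agp",
    "write_agp",
    "read_lengths",
    "write_lengths",
    "group_by_seq",
]


class FormatError(ValueError):
    """A file does not parse as the expected dialect (reported with line number)."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant."""


@dataclass(frozen=True)
class GeneRecord:
    """One gene model on one sequence, in internal 0-based half-open coordinates."""

    gene_id: str
    seq_id: str
    start: int
    end: int
    strand: str = "+"
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"gene {self.gene_id!r}: need 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id!r}: bad strand {self.strand!r}")
        if self.biotype not in ("protein_coding", "pseudogene"):
            raise ValidationError(f"gene {self.gene_id!r}: bad biotype {self.biotype!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class HitRecord:
    """One row of 12-column BLAST tabular output, coordinates kept as in the file."""

    query_id: str
    subject_id: str
    pct_identity: float
    aln_len: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.bitscore < 0:
            raise ValidationError(f"hit {self.query_id}->{self.subject_id}: bitscore < 0")
        if self.aln_len < 1:
            raise ValidationError(f"hit {self.query_id}->{self.subject_id}: aln_len < 1")
        if not (0.0 <= self.pct_identity <= 100.0):
            raise ValidationError(
                f"hit {self.query_id}->{self.subject_id}: pct_identity outside [0, 100]"
            )

    @property
    def subject_interval(self) -> tuple[int, int]:
        """Subject span as internal 0-based half-open, orientation folded away."""
        lo, hi = sorted((self.s_start, self.s_end))
        return lo - 1, hi

    @property
    def subject_midpoint(self) -> int:
        lo, hi = self.subject_interval
        return (lo + hi) // 2


# AGP 2.1: W = scaffold component, U = gap of unknown size.
@dataclass(frozen=True)
class AgpRow:
    object_id: str
    object_start: int  # 1-based inclusive, as in the format
    object_end: int
    part_number: int
    component_type: str  # "W" or "U"
    component_id: str | None = None
    component_start: int | None = None
    component_end: int | None = None
    orientation: str | None = None
    gap_length: int | None = None
    gap_type: str | None = None
    linkage: str | None = None
    evidence: str | None = None

    def __post_init__(self) -> None:
        if self.part_number < 1:
            raise ValidationError(f"AGP {self.object_id}: part_number must be >= 1")
        if not (1 <= self.object_start <= self.object_end):
            raise ValidationError(
                f"AGP {self.object_id} part {self.part_number}: bad object span"
            )
        span = self.object_end - self.object_start + 1
        if self.component_type == "W":
            if None in (self.component_id, self.component_start, self.component_end):
                raise ValidationError(
                    f"AGP {self.object_id} part {self.part_number}: W row missing component fields"
                )
            if self.orientation not in ("+", "-"):
                raise ValidationError(
                    f"AGP {self.object_id} part {self.part_number}: bad orientation"
                )
            if self.component_end - self.component_start + 1 != span:
                raise ValidationError(
                    f"AGP {self.object_id} part {self.part_number}: component span != object span"
                )
        elif self.component_type == "U":
            if self.gap_length != span:
                raise ValidationError(
                    f"AGP {self.object_id} part {self.part_number}: gap_length != object span"
                )
        else:
            raise ValidationError(
                f"AGP {self.object_id} part {self.part_number}: "
                f"unsupported component_type {self.component_type!r}"
            )


# ---------------------------------------------------------------------------
# GFF3 (gene rows only)

_GFF3_TYPES = {"gene": "protein_coding", "pseudogene": "pseudogene"}


def read_gff3(path: str | Path) -> list[GeneRecord]:
    """Read gene and pseudogene rows from a GFF3 file.

    Only ``gene``/``pseudogene`` feature rows are consumed; mRNA, exon and
    other hierarchy rows are ignored.  1-based inclusive GFF3 coordinates are
    converted to internal 0-based half-open.  Records come back sorted by
    ``(seq_id, start, gene_id)``; a duplicated gene ID raises
    :class:`ValidationError`.
    """
    records: list[GeneRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, got {len(fields)}"
                )
            seq_id, _source, ftype, start_s, end_s, _score, strand, _phase, attrs = fields
            if ftype not in _GFF3_TYPES:
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            gene_id = _gff3_attr(attrs, "ID")
            if gene_id is None:
                raise FormatError(f"{path}:{lineno}: gene row lacks an ID attribute")
            if gene_id in seen:
                raise ValidationError(f"duplicate gene ID {gene_id!r} at {path}:{lineno}")
            seen.add(gene_id)
            records.append(
                GeneRecord(
                    gene_id=gene_id,
                    seq_id=seq_id,
                    start=start1 - 1,
                    end=end1,
                    strand=strand if strand in ("+", "-") else "+",
                    biotype=_GFF3_TYPES[ftype],
                )
            )
    records.sort(key=lambda g: (g.seq_id, g.start, g.gene_id))
    return records


def _gff3_attr(attrs: str, key: str) -> str | None:
    for part in attrs.split(";"):
        part = part.strip()
        if part.startswith(key + "="):
            return part[len(key) + 1 :]
    return None


def write_gff3(records: Iterable[GeneRecord], path: str | Path, source: str = "syntenic") -> None:
    """Write gene records as GFF3 gene/pseudogene rows (external 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in records:
            ftype = "pseudogene" if g.biotype == "pseudogene" else "gene"
            fh.write(
                f"{g.seq_id}\t{source}\t{ftype}\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )


def group_by_seq(records: Iterable[GeneRecord]) -> dict[str, list[GeneRecord]]:
    """Group records per sequence, each group sorted by start coordinate."""
    by_seq: dict[str, list[GeneRecord]] = {}
    for g in records:
        by_seq.setdefault(g.seq_id, []).append(g)
    for genes in by_seq.values():
        genes.sort(key=lambda g: (g.start, g.gene_id))
    return by_seq


# ---------------------------------------------------------------------------
# BLAST outfmt-6 tabular

def read_blast_tab(path: str | Path) -> list[HitRecord]:
    """Parse a 12-column BLAST tabular file; row order is preserved."""
    hits: list[HitRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise FormatError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, got {len(fields)}"
                )
            try:
                hits.append(
                    HitRecord(
                        query_id=fields[0],
                        subject_id=fields[1],
                        pct_identity=float(fields[2]),
                        aln_len=int(fields[3]),
                        mismatches=int(fields[4]),
                        gap_opens=int(fields[5]),
                        q_start=int(fields[6]),
                        q_end=int(fields[7]),
                        s_start=int(fields[8]),
                        s_end=int(fields[9]),
                        evalue=float(fields[10]),
                        bitscore=float(fields[11]),
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return hits


def _fmt_float(x: float) -> str:
    # Integral bitscores print without a trailing ".0" so written files look
    # like BLAST's own output and round-trip byte-identically.
    if math.isfinite(x) and x == int(x) and abs(x) < 1e15:
        return str(int(x))
    return repr(x)


def write_blast_tab(hits: Iterable[HitRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    (
                        h.query_id,
                        h.subject_id,
                        f"{h.pct_identity:.3f}",
                        str(h.aln_len),
                        str(h.mismatches),
                        str(h.gap_opens),
                        str(h.q_start),
                        str(h.q_end),
                        str(h.s_start),
                        str(h.s_end),
                        _fmt_float(h.evalue) if h.evalue != 0 else "0.0",
                        _fmt_float(h.bitscore),
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# AGP 2.1

def validate_agp(rows: Sequence[AgpRow]) -> None:
    """Check that parts tile each object contiguously with consecutive part numbers."""
    by_obj: dict[str, list[AgpRow]] = {}
    for r in rows:
        by_obj.setdefault(r.object_id, []).append(r)
    for obj, parts in by_obj.items():
        parts = sorted(parts, key=lambda r: r.part_number)
        expected_start, expected_part = 1, 1
        for r in parts:
            if r.part_number != expected_part:
                raise ValidationError(
                    f"AGP {obj}: part numbers not consecutive at part {r.part_number}"
                )
            if r.object_start != expected_start:
                raise ValidationError(
                    f"AGP {obj} part {r.part_number}: object_start {r.object_start}, "
                    f"expected {expected_start}"
                )
            expected_start = r.object_end + 1
            expected_part += 1


def write_agp(rows: Sequence[AgpRow], path: str | Path) -> None:
    validate_agp(rows)
    with open(path, "w") as fh:
        fh.write("##agp-version 2.1\n")
        for r in rows:
            if r.component_type == "W":
                tail = (
                    r.component_id,
                    str(r.component_start),
                    str(r.component_end),
                    r.orientation,
                )
            else:
                tail = (str(r.gap_length), r.gap_type, r.linkage, r.evidence)
            fh.write(
                "\t".join(
                    (
                        r.object_id,
                        str(r.object_start),
                        str(r.object_end),
                        str(r.part_number),
                        r.component_type,
                        *tail,
                    )
                )
                + "\n"
            )


def read_agp(path: str | Path) -> list[AgpRow]:
    rows: list[AgpRow] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, got {len(fields)}"
                )
            obj, ostart, oend, part, ctype = fields[:5]
            try:
                if ctype == "W":
                    row = AgpRow(
                        object_id=obj,
                        object_start=int(ostart),
                        object_end=int(oend),
                        part_number=int(part),
                        component_type="W",
                        component_id=fields[5],
                        component_start=int(fields[6]),
                        component_end=int(fields[7]),
                        orientation=fields[8],
                    )
                elif ctype == "U":
                    row = AgpRow(
                        object_id=obj,
                        object_start=int(ostart),
                        object_end=int(oend),
                        part_number=int(part),
                        component_type="U",
                        gap_length=int(fields[5]),
                        gap_type=fields[6],
                        linkage=fields[7],
                        evidence=fields[8],
                    )
                else:
                    raise FormatError(
                        f"{path}:{lineno}: unsupported component_type {ctype!r}"
                    )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            rows.append(row)
    validate_agp(rows)
    return rows


# ---------------------------------------------------------------------------
# Sequence length tables (seq_id <TAB> length_bp)

def read_lengths(path: str | Path) -> dict[str, int]:
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns, got {len(fields)}")
            try:
                lengths[fields[0]] = int(fields[1])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer length") from exc
    return lengths


def write_lengths(lengths: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for seq_id in sorted(lengths):
            fh.write(f"{seq_id}\t{lengths[seq_id]}\n")
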