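"""Gene-model annotation I/O and boundary indexing.

Gene models are read from refFlat text (11 tab-separated columns) and held as
:class:`GeneModel` records using 0-based, half-open coordinates throughout —
the convention shared by refFlat and BED, under which a span's length is simply
``end - start``.

A :class:`BoundaryIndex` answers the two queries back-splice calling needs:
which annotated exon boundaries lie within a small tolerance of a junction
coordinate, and which annotated intron contains a coordinate.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal

from intervaltree import IntervalTree

__all__ = [
    "GeneModel",
    "BoundaryHit",
    "IntronHit",
    "BoundaryIndex",
    "read_gene_models",
    "write_gene_models",
    "build_boundary_index",
    "AnnotationParseError",
]

Strand = Literal["+", "-"]


class AnnotationParseError(ValueError):
    """Raised when a refFlat line violates the format contract."""


@dataclass(frozen=True)
class GeneModel:
    """One transcript: ordered, non-overlapping exons on one strand.

    ``exon_starts``/``exon_ends`` are parallel tuples of 0-based half-open
    intervals, strictly increasing and non-overlapping.
    """

    gene_name: str
    transcript_id: str
    chrom: str
    strand: Strand
    exon_starts: tuple[int, ...]
    exon_ends: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationParseError(
                f"unknown strand {self.strand!r} for {self.transcript_id}"
            )
        if len(self.exon_starts) != len(self.exon_ends) or not self.exon_starts:
            raise AnnotationParseError(
                f"exon start/end lists differ in length for {self.transcript_id}"
            )
        prev_end = -1
        for s, e in zip(self.exon_starts, self.exon_ends):
            if not (prev_end <= s < e):
                raise AnnotationParseError(
                    f"exons not strictly ordered/non-overlapping in {self.transcript_id}"
                )
            prev_end = e

    @property
    def exon_count(self) -> int:
        return len(self.exon_starts)

    @property
    def tx_start(self) -> int:
        return self.exon_starts[0]

    @property
    def tx_end(self) -> int:
        return self.exon_ends[-1]

    def exons(self) -> Iterator[tuple[int, int]]:
        return zip(self.exon_starts, self.exon_ends)

    def introns(self) -> Iterator[tuple[int, int]]:
        """Yield the (start, end) of each intron, 0-based half-open."""
        for i in range(self.exon_count - 1):
            yield self.exon_ends[i], self.exon_starts[i + 1]


def _parse_coord_list(text: str, line_no: int) -> tuple[int, ...]:
    try:
        return tuple(int(x) for x in text.strip().rstrip(",").split(",") if x)
    except ValueError as exc:
        raise AnnotationParseError(f"line {line_no}: bad coordinate list {text!r}") from exc


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Parse a refFlat file into a list of :class:`GeneModel`.

    Columns: geneName, name, chrom, strand, txStart, txEnd, cdsStart, cdsEnd,
    exonCount, exonStarts, exonEnds. Trailing commas in the exon lists are
    tolerated. A mismatch between exonCount and the list lengths raises
    :class:`AnnotationParseError` naming the offending line.
    """
    models: list[GeneModel] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 11:
                raise AnnotationParseError(
                    f"line {line_no}: expected 11 tab-separated columns, got {len(fields)}"
                )
            gene_name, name, chrom, strand = fields[0], fields[1], fields[2], fields[3]
            try:
                exon_count = int(fields[8])
            except ValueError as exc:
                raise AnnotationParseError(f"line {line_no}: bad exonCount {fields[8]!r}") from exc
            starts = _parse_coord_list(fields[9], line_no)
            ends = _parse_coord_list(fields[10], line_no)
            if len(starts) != exon_count or len(ends) != exon_count:
                raise AnnotationParseError(
                    f"line {line_no}: exonCount={exon_count} but "
                    f"{len(starts)} starts / {len(ends)} ends"
                )
            if strand not in ("+", "-"):
                raise AnnotationParseError(f"line {line_no}: unknown strand {strand!r}")
            models.append(
                GeneModel(
                    gene_name=gene_name,
                    transcript_id=name,
                    chrom=chrom,
                    strand=strand,  # type: ignore[arg-type]
                    exon_starts=starts,
                    exon_ends=ends,
                )
            )
    return models


def write_gene_models(models: Iterable[GeneModel], path: str | Path) -> None:
    """Write models as refFlat text (CDS columns set to the transcript span)."""
    with open(path, "w") as fh:
        for m in models:
            starts = ",".join(str(s) for s in m.exon_starts) + ","
            ends = ",".join(str(e) for e in m.exon_ends) + ","
            fh.write(
                "\t".join(
                    [
                        m.gene_name,
                        m.transcript_id,
                        m.chrom,
                        m.strand,
                        str(m.tx_start),
                        str(m.tx_end),
                        str(m.tx_start),
                        str(m.tx_end),
                        str(m.exon_count),
                        starts,
                        ends,
                    ]
                )
                + "\n"
            )


@dataclass(frozen=True)
class BoundaryHit:
    """An annotated exon boundary matched by a coordinate query."""

    model: GeneModel
    exon_index: int
    side: Literal["start", "end"]
    coordinate: int  # the annotated boundary coordinate itself


@dataclass(frozen=True)
class IntronHit:
    """An annotated intron containing a queried coordinate."""

    model: GeneModel
    intron_index: int
    start: int
    end: int


@dataclass
class BoundaryIndex:
    """Sorted-coordinate index of exon boundaries plus intron interval trees.

    Boundary queries return every annotated (transcript, exon, side) whose
    coordinate lies within ±tolerance of the query; intron queries return the
    introns whose closed span [start, end] contains the coordinate.  The end
    coordinate is included deliberately: under half-open exons the intron end
    *is* the boundary shared with the downstream exon, which is where a
    minus-strand lariat's 5' end sits.
    """

    _coords: dict[tuple[str, Strand], list[int]] = field(default_factory=dict)
    _hits: dict[tuple[str, Strand], list[list[BoundaryHit]]] = field(default_factory=dict)
    _introns: dict[tuple[str, Strand], IntervalTree] = field(default_factory=dict)

    def query_boundaries(
        self, chrom: str, strand: Strand, coordinate: int, tolerance: int = 0
    ) -> list[BoundaryHit]:
        key = (chrom, strand)
        coords = self._coords.get(key)
        if not coords:
            return []
        lo = bisect.bisect_left(coords, coordinate - tolerance)
        hi = bisect.bisect_right(coords, coordinate + tolerance)
        out: list[BoundaryHit] = []
        for i in range(lo, hi):
            out.extend(self._hits[key][i])
        return out

    def query_introns(self, chrom: str, strand: Strand, coordinate: int) -> list[IntronHit]:
        key = (chrom, strand)
        tree = self._introns.get(key)
        if tree is None:
            return []
        # trees store [start, end+1) so the closed end coordinate matches
        return sorted(
            (iv.data for iv in tree.at(coordinate)),
            key=lambda h: (h.model.transcript_id, h.intron_index),
        )


def build_boundary_index(models: Iterable[GeneModel]) -> BoundaryIndex:
    """Index every exon boundary and intron of the given models."""
    per_key: dict[tuple[str, Strand], dict[int, list[BoundaryHit]]] = {}
    introns: dict[tuple[str, Strand], IntervalTree] = {}
    for m in models:
        key = (m.chrom, m.strand)
        bucket = per_key.setdefault(key, {})
        for i, (s, e) in enumerate(m.exons()):
            bucket.setdefault(s, []).append(BoundaryHit(m, i, "start", s))
            bucket.setdefault(e, []).append(BoundaryHit(m, i, "end", e))
        tree = introns.setdefault(key, IntervalTree())
        for j, (s, e) in enumerate(m.introns()):
            tree.addi(s, e + 1, IntronHit(m, j, s, e))

    index = BoundaryIndex()
    for key, bucket in per_key.items():
        coords = sorted(bucket)
        index._coords[key] = coords
        index._hits[key] = [bucket[c] for c in coords]
    index._introns = introns
    return index
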