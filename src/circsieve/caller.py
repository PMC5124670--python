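"""Back-splice junction calling from chimeric alignment records.

A chimeric record whose acceptor coordinate lies genomically upstream of its
donor on the same chromosome and strand is the signature of circularisation.
Each such record is matched against annotated gene models:

* **exonic circRNA** — the acceptor coincides (within a tolerance) with an
  annotated exon start and the donor with an annotated exon end of the same
  transcript; the candidate spans that run of exons, with its coordinates
  snapped to the annotated boundaries and its exon block structure taken from
  the annotation.
* **ciRNA (circular intronic RNA)** — both coordinates fall inside one
  annotated intron and the junction's 5' end sits at the intron's donor
  boundary (the intron start on '+' transcripts, the intron end on '-'),
  the geometry of a stabilised intron lariat.

Records that fail every criterion are dropped and counted, never called.
Candidates are identified by their :class:`JunctionKey` (chrom, start, end,
strand); read support is the number of *distinct* read identifiers observed
for a key.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

from .annotation import BoundaryIndex, GeneModel, Strand

__all__ = [
    "ChimericJunctionRecord",
    "JunctionKey",
    "CircCandidate",
    "CallReport",
    "ChimericParseError",
    "parse_chimeric_records",
    "write_chimeric_records",
    "call_backsplice",
    "candidate_length",
    "merge_by_key",
    "write_candidates",
    "read_candidates",
]

logger = logging.getLogger(__name__)

CircType = Literal["exonic", "ciRNA"]


class ChimericParseError(ValueError):
    pass


@dataclass(frozen=True)
class ChimericJunctionRecord:
    """One chimeric read alignment (one line of a chimeric junction file)."""

    chrom_donor: str
    pos_donor: int
    strand_donor: str
    chrom_acceptor: str
    pos_acceptor: int
    strand_acceptor: str
    junction_type: int
    read_id: str

    def __post_init__(self) -> None:
        if self.pos_donor < 0 or self.pos_acceptor < 0:
            raise ValueError("positions must be >= 0")
        if self.strand_donor not in "+-" or self.strand_acceptor not in "+-":
            raise ValueError(f"invalid strand in record {self.read_id}")


@dataclass(frozen=True, order=True)
class JunctionKey:
    """Identity under which candidates are counted, filtered and intersected."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"junction key requires start < end, got {self}")

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}:{self.strand}"

    @classmethod
    def parse(cls, text: str) -> "JunctionKey":
        chrom, span, strand = text.rsplit(":", 2)
        start, end = span.split("-")
        return cls(chrom, int(start), int(end), strand)


@dataclass(frozen=True)
class CircCandidate:
    """One predicted circRNA on 0-based half-open genomic coordinates.

    ``exon_sizes``/``exon_offsets`` describe the exon blocks relative to
    ``start`` (BED12 block convention); a ciRNA is a single block covering its
    whole span. ``read_ids`` carries the supporting reads when known (fresh
    calls); candidates re-read from file carry only ``read_count``.
    """

    chrom: str
    start: int
    end: int
    strand: str
    circ_type: CircType
    exon_sizes: tuple[int, ...]
    exon_offsets: tuple[int, ...]
    gene_name: str
    transcript_id: str
    read_count: int
    read_ids: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise ValueError("candidate length must be positive")
        if len(self.exon_sizes) != len(self.exon_offsets) or not self.exon_sizes:
            raise ValueError("exon_sizes and exon_offsets must be parallel, non-empty")
        if self.exon_offsets[0] != 0:
            raise ValueError("first exon offset must be 0")
        for i in range(1, len(self.exon_offsets)):
            if self.exon_offsets[i] <= self.exon_offsets[i - 1]:
                raise ValueError("exon offsets must be strictly increasing")
        if self.exon_offsets[-1] + self.exon_sizes[-1] != self.length:
            raise ValueError("last exon must end at the candidate end")
        if sum(self.exon_sizes) > self.length:
            raise ValueError("exon sizes exceed span")
        if self.circ_type == "ciRNA" and self.exon_count != 1:
            raise ValueError("a ciRNA is a single intronic block")
        if self.read_ids is not None and len(self.read_ids) != self.read_count:
            raise ValueError("read_count must equal the number of distinct read ids")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def exon_count(self) -> int:
        return len(self.exon_sizes)

    @property
    def key(self) -> JunctionKey:
        return JunctionKey(self.chrom, self.start, self.end, self.strand)


def candidate_length(candidate: CircCandidate) -> int:
    """Genomic span of a candidate in nt: ``end - start`` (half-open)."""
    return candidate.end - candidate.start


@dataclass
class CallReport:
    """Bookkeeping of records examined and dropped during calling."""

    n_records: int = 0
    cross_chromosome: int = 0
    strand_mismatch: int = 0
    linear_orientation: int = 0
    unmatched: int = 0

    @property
    def n_called(self) -> int:
        return self.n_records - (
            self.cross_chromosome + self.strand_mismatch + self.linear_orientation + self.unmatched
        )


# ---------------------------------------------------------------------------
# chimeric junction file I/O
#
# Column contract (tab-separated, extra columns ignored):
#   1 chrom_donor  2 pos_donor  3 strand_donor
#   4 chrom_acceptor  5 pos_acceptor  6 strand_acceptor
#   7 junction_type  8 repeat_left  9 repeat_right  10 read_id
# ---------------------------------------------------------------------------

_N_COLUMNS = 10


def parse_chimeric_records(path: str | Path) -> list[ChimericJunctionRecord]:
    """Parse a tab-delimited chimeric junction file (one record per line)."""
    records: list[ChimericJunctionRecord] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < _N_COLUMNS:
                raise ChimericParseError(
                    f"{path}: line {line_no}: expected >= {_N_COLUMNS} columns, "
                    f"got {len(fields)}"
                )
            try:
                records.append(
                    ChimericJunctionRecord(
                        chrom_donor=fields[0],
                        pos_donor=int(fields[1]),
                        strand_donor=fields[2],
                        chrom_acceptor=fields[3],
                        pos_acceptor=int(fields[4]),
                        strand_acceptor=fields[5],
                        junction_type=int(fields[6]),
                        read_id=fields[9],
                    )
                )
            except ValueError as exc:
                raise ChimericParseError(f"{path}: line {line_no}: {exc}") from exc
    return records


def write_chimeric_records(records: Iterable[ChimericJunctionRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                "\t".join(
                    [
                        r.chrom_donor,
                        str(r.pos_donor),
                        r.strand_donor,
                        r.chrom_acceptor,
                        str(r.pos_acceptor),
                        r.strand_acceptor,
                        str(r.junction_type),
                        "0",
                        "0",
                        r.read_id,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# calling
# ---------------------------------------------------------------------------


def _match_exonic(
    index: BoundaryIndex,
    chrom: str,
    strand: Strand,
    acceptor: int,
    donor: int,
    tolerance: int,
) -> tuple[GeneModel, int, int] | None:
    """Find the transcript whose exon run [a..b] the junction spans.

    Acceptor must match an exon start, donor an exon end, of the same
    transcript. When several transcripts match, the one yielding the most
    exons within the span wins; remaining ties break lexicographically by
    transcript id.
    """
    start_hits = [
        h for h in index.query_boundaries(chrom, strand, acceptor, tolerance) if h.side == "start"
    ]
    if not start_hits:
        return None
    end_hits = [
        h for h in index.query_boundaries(chrom, strand, donor, tolerance) if h.side == "end"
    ]
    if not end_hits:
        return None
    ends_by_tx: dict[str, list[int]] = defaultdict(list)
    for h in end_hits:
        ends_by_tx[h.model.transcript_id].append(h.exon_index)

    best: tuple[int, str, GeneModel, int, int] | None = None
    for sh in start_hits:
        for b in ends_by_tx.get(sh.model.transcript_id, ()):
            a = sh.exon_index
            if a > b:
                continue
            n_exons = b - a + 1
            cand = (-n_exons, sh.model.transcript_id, sh.model, a, b)
            if best is None or cand < best:
                best = cand
    if best is None:
        return None
    return best[2], best[3], best[4]


def _match_ciRNA(
    index: BoundaryIndex,
    chrom: str,
    strand: Strand,
    acceptor: int,
    donor: int,
    tolerance: int,
) -> tuple[GeneModel, int, int] | None:
    """Find an intron lariat match: both coordinates in one intron, 5' end at
    the intron's donor boundary (within tolerance).

    Returns (model, snapped_start, snapped_end). The branchpoint side keeps
    its observed coordinate; the donor side snaps to the annotated boundary.
    """
    hits_a = index.query_introns(chrom, strand, acceptor)
    hits_d = index.query_introns(chrom, strand, donor)
    shared = [
        ha
        for ha in hits_a
        if any(
            hd.model.transcript_id == ha.model.transcript_id
            and hd.intron_index == ha.intron_index
            for hd in hits_d
        )
    ]
    best: tuple[str, int, int, GeneModel] | None = None
    for h in shared:
        if strand == "+":
            # lariat 5' end = upstream coordinate = acceptor, at intron start
            if abs(acceptor - h.start) > tolerance:
                continue
            start, end = h.start, donor
        else:
            # lariat 5' end = downstream coordinate = donor, at intron end
            if abs(donor - h.end) > tolerance:
                continue
            start, end = acceptor, h.end
        if not start < end:
            continue
        cand = (h.model.transcript_id, start, end, h.model)
        if best is None or cand < best:
            best = cand
    if best is None:
        return None
    return best[3], best[1], best[2]


def _record_to_candidate(
    record: ChimericJunctionRecord,
    index: BoundaryIndex,
    tolerance: int,
    report: CallReport,
) -> CircCandidate | None:
    if record.chrom_donor != record.chrom_acceptor:
        report.cross_chromosome += 1
        return None
    if record.strand_donor != record.strand_acceptor:
        report.strand_mismatch += 1
        return None
    chrom = record.chrom_donor
    strand: Strand = record.strand_donor  # type: ignore[assignment]
    acceptor, donor = record.pos_acceptor, record.pos_donor
    if not acceptor < donor:
        report.linear_orientation += 1
        return None

    exonic = _match_exonic(index, chrom, strand, acceptor, donor, tolerance)
    if exonic is not None:
        model, a, b = exonic
        start = model.exon_starts[a]
        end = model.exon_ends[b]
        sizes = tuple(model.exon_ends[i] - model.exon_starts[i] for i in range(a, b + 1))
        offsets = tuple(model.exon_starts[i] - start for i in range(a, b + 1))
        return CircCandidate(
            chrom=chrom,
            start=start,
            end=end,
            strand=model.strand,
            circ_type="exonic",
            exon_sizes=sizes,
            exon_offsets=offsets,
            gene_name=model.gene_name,
            transcript_id=model.transcript_id,
            read_count=1,
            read_ids=frozenset({record.read_id}),
        )

    lariat = _match_ciRNA(index, chrom, strand, acceptor, donor, tolerance)
    if lariat is not None:
        model, start, end = lariat
        return CircCandidate(
            chrom=chrom,
            start=start,
            end=end,
            strand=model.strand,
            circ_type="ciRNA",
            exon_sizes=(end - start,),
            exon_offsets=(0,),
            gene_name=model.gene_name,
            transcript_id=model.transcript_id,
            read_count=1,
            read_ids=frozenset({record.read_id}),
        )

    report.unmatched += 1
    return None


def call_backsplice(
    records: Iterable[ChimericJunctionRecord],
    index: BoundaryIndex,
    tolerance: int = 2,
    report: CallReport | None = None,
) -> list[CircCandidate]:
    """Call circRNA candidates from chimeric records.

    Returns one candidate per junction key, with ``read_count`` the number of
    distinct supporting read identifiers. Candidates are sorted by key.
    ``tolerance`` is the boundary-matching slack in nt (coordinates are always
    snapped to the matched annotated boundary, so keys are annotation-stable).
    """
    if report is None:
        report = CallReport()
    per_record: list[CircCandidate] = []
    for record in records:
        report.n_records += 1
        cand = _record_to_candidate(record, index, tolerance, report)
        if cand is not None:
            per_record.append(cand)
    merged = merge_by_key(per_record)
    return [merged[k] for k in sorted(merged)]


def _better_annotation(a: CircCandidate, b: CircCandidate) -> CircCandidate:
    """Pick the representative candidate for a shared key.

    Exonic beats ciRNA (exon-boundary evidence is more specific); then more
    exons; then lexicographically smaller transcript id.
    """
    rank_a = (a.circ_type != "exonic", -a.exon_count, a.transcript_id)
    rank_b = (b.circ_type != "exonic", -b.exon_count, b.transcript_id)
    return a if rank_a <= rank_b else b


def merge_by_key(candidates: Iterable[CircCandidate]) -> dict[JunctionKey, CircCandidate]:
    """Merge per-read candidates of one sample into one entry per key.

    Read support counts *distinct* read identifiers; the annotation fields of
    a key come from the preferred candidate (exonic over ciRNA, then most
    exons, then lexicographic transcript id). Conflicting circ types at one
    key are logged.
    """
    by_key: dict[JunctionKey, CircCandidate] = {}
    reads: dict[JunctionKey, set[str]] = defaultdict(set)
    counts: dict[JunctionKey, int] = defaultdict(int)
    for c in candidates:
        k = c.key
        if c.read_ids is not None:
            reads[k].update(c.read_ids)
        else:
            counts[k] += c.read_count
        if k in by_key:
            prev = by_key[k]
            if prev.circ_type != c.circ_type:
                logger.warning("key %s observed as both exonic and ciRNA; exonic kept", k)
            by_key[k] = _better_annotation(prev, c)
        else:
            by_key[k] = c
    out: dict[JunctionKey, CircCandidate] = {}
    for k, c in by_key.items():
        if reads[k]:
            out[k] = replace(c, read_ids=frozenset(reads[k]), read_count=len(reads[k]))
        else:
            out[k] = replace(c, read_ids=None, read_count=counts[k])
    return out


# ---------------------------------------------------------------------------
# BED12+ candidate file I/O
#
# Standard BED12 columns followed by: read_count, circ_type, gene_name,
# transcript_id. The name column is the junction key.
# ---------------------------------------------------------------------------


def write_candidates(candidates: Iterable[CircCandidate], path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in sorted(candidates, key=lambda c: c.key):
            fh.write(
                "\t".join(
                    [
                        c.chrom,
                        str(c.start),
                        str(c.end),
                        str(c.key),
                        str(c.read_count),
                        c.strand,
                        str(c.start),
                        str(c.end),
                        "0",
                        str(c.exon_count),
                        ",".join(str(s) for s in c.exon_sizes) + ",",
                        ",".join(str(o) for o in c.exon_offsets) + ",",
                        str(c.read_count),
                        c.circ_type,
                        c.gene_name,
                        c.transcript_id,
                    ]
                )
                + "\n"
            )


def read_candidates(path: str | Path) -> list[CircCandidate]:
    out: list[CircCandidate] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 16:
                raise ChimericParseError(
                    f"{path}: line {line_no}: expected 16 columns, got {len(f)}"
                )
            sizes = tuple(int(x) for x in f[10].rstrip(",").split(","))
            offsets = tuple(int(x) for x in f[11].rstrip(",").split(","))
            out.append(
                CircCandidate(
                    chrom=f[0],
                    start=int(f[1]),
                    end=int(f[2]),
                    strand=f[5],
                    circ_type=f[13],  # type: ignore[arg-type]
                    exon_sizes=sizes,
                    exon_offsets=offsets,
                    gene_name=f[14],
                    transcript_id=f[15],
                    read_count=int(f[12]),
                )
            )
    return out
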