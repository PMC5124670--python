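"""Back-splice calling semantics, tested against a brute-force enumerator.

The oracle scans every record against every (exon-start, exon-end) pair and
every intron of every transcript — independent of the indexed implementation.
"""

import numpy as np
import pytest

from circsieve.annotation import GeneModel, build_boundary_index
from circsieve.caller import (
    ChimericJunctionRecord,
    ChimericParseError,
    CircCandidate,
    CallReport,
    JunctionKey,
    call_backsplice,
    candidate_length,
    merge_by_key,
    parse_chimeric_records,
    read_candidates,
    write_candidates,
    write_chimeric_records,
)


def rec(donor, acceptor, read_id="r1", chrom="chr1", strand="+",
        chrom2=None, strand2=None):
    return ChimericJunctionRecord(
        chrom_donor=chrom, pos_donor=donor, strand_donor=strand,
        chrom_acceptor=chrom2 or chrom, pos_acceptor=acceptor,
        strand_acceptor=strand2 or strand, junction_type=1, read_id=read_id,
    )


# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------


def oracle_keys(records, models):
    """Enumerate expected (key -> circ_type, distinct reads) at tolerance 0."""
    out = {}
    for r in records:
        if r.chrom_donor != r.chrom_acceptor or r.strand_donor != r.strand_acceptor:
            continue
        acc, don = r.pos_acceptor, r.pos_donor
        if not acc < don:
            continue
        exonic = None
        for m in models:
            if m.chrom != r.chrom_donor or m.strand != r.strand_donor:
                continue
            for a in range(m.exon_count):
                for b in range(a, m.exon_count):
                    if m.exon_starts[a] == acc and m.exon_ends[b] == don:
                        exonic = JunctionKey(m.chrom, acc, don, m.strand)
        if exonic is not None:
            out.setdefault((exonic, "exonic"), set()).add(r.read_id)
            continue
        for m in models:
            if m.chrom != r.chrom_donor or m.strand != r.strand_donor:
                continue
            for s, e in m.introns():
                if not (s <= acc and don <= e):
                    continue
                if m.strand == "+" and acc == s:
                    key = JunctionKey(m.chrom, s, don, m.strand)
                elif m.strand == "-" and don == e:
                    key = JunctionKey(m.chrom, acc, e, m.strand)
                else:
                    continue
                out.setdefault((key, "ciRNA"), set()).add(r.read_id)
                break
            else:
                continue
            break
    return {k: len(reads) for k, reads in out.items()}


def random_models(rng, n_transcripts):
    models, pos = [], 0
    for i in range(n_transcripts):
        n = int(rng.integers(1, 6))
        starts, ends = [], []
        pos += int(rng.integers(50, 200))
        for _ in range(n):
            starts.append(pos)
            pos += int(rng.integers(20, 120))
            ends.append(pos)
            pos += int(rng.integers(20, 200))
        strand = "+" if rng.random() < 0.5 else "-"
        models.append(GeneModel(f"G{i}", f"T{i:03d}", f"chr{int(rng.integers(1, 3))}",
                                strand, tuple(starts), tuple(ends)))
    return models


def random_records(rng, models, n_records):
    records = []
    for i in range(n_records):
        m = models[int(rng.integers(0, len(models)))]
        kind = rng.random()
        if kind < 0.4 and m.exon_count >= 1:
            # a true back-splice over an exon run
            a = int(rng.integers(0, m.exon_count))
            b = int(rng.integers(a, m.exon_count))
            donor, acceptor = m.exon_ends[b], m.exon_starts[a]
        elif kind < 0.6 and m.exon_count >= 2:
            # lariat inside a random intron, 5' end at the donor boundary
            j = int(rng.integers(0, m.exon_count - 1))
            s, e = m.exon_ends[j], m.exon_starts[j + 1]
            inner = int(rng.integers(s + 1, e))
            if m.strand == "+":
                acceptor, donor = s, inner
            else:
                acceptor, donor = inner, e
        elif kind < 0.8 and m.exon_count >= 2:
            # linear splice junction: donor upstream of acceptor
            j = int(rng.integers(0, m.exon_count - 1))
            donor, acceptor = m.exon_ends[j], m.exon_starts[j + 1]
        else:
            # noise anywhere near the transcript
            lo = max(0, m.tx_start - 50)
            x = int(rng.integers(lo, m.tx_end + 50))
            y = int(rng.integers(lo, m.tx_end + 50))
            donor, acceptor = max(x, y), min(x, y)
            if donor == acceptor:
                donor += 1
        strand = m.strand if rng.random() < 0.9 else ("-" if m.strand == "+" else "+")
        records.append(rec(donor, acceptor, read_id=f"r{i}", chrom=m.chrom,
                           strand=strand))
    return records


# ---------------------------------------------------------------------------
# unit behaviour
# ---------------------------------------------------------------------------


class TestCallBacksplice:
    def test_single_exon_backsplice(self, three_exon_model, index):
        # donor at exon 1's end, acceptor at its start -> one-exon circle
        (c,) = call_backsplice([rec(400, 300)], index, tolerance=0)
        assert (c.start, c.end, c.circ_type) == (300, 400, "exonic")
        assert c.exon_count == 1 and c.exon_sizes == (100,)
        assert c.length == 100

    def test_multi_exon_span_takes_annotation_blocks(self, index):
        (c,) = call_backsplice([rec(600, 100)], index, tolerance=0)
        assert (c.start, c.end) == (100, 600)
        assert c.exon_sizes == (100, 100, 100)
        assert c.exon_offsets == (0, 200, 400)
        assert c.transcript_id == "TX0001"

    def test_lariat_requires_donor_boundary(self, index):
        # intron [200,300): 5' end off the donor site is not a lariat
        assert call_backsplice([rec(250, 220)], index, tolerance=0) == []
        (c,) = call_backsplice([rec(250, 200)], index, tolerance=0)
        assert (c.start, c.end, c.circ_type) == (200, 250, "ciRNA")
        assert c.exon_count == 1

    def test_minus_strand_lariat_uses_intron_end(self, index):
        # minus-strand intron [1100,1300): the donor boundary is its end
        (c,) = call_backsplice([rec(1300, 1150, strand="-")], index, tolerance=0)
        assert (c.start, c.end, c.circ_type) == (1150, 1300, "ciRNA")
        assert call_backsplice([rec(1250, 1150, strand="-")], index, tolerance=0) == []

    def test_linear_orientation_dropped_and_counted(self, index):
        report = CallReport()
        assert call_backsplice([rec(300, 400)], index, tolerance=0,
                               report=report) == []
        assert report.linear_orientation == 1

    def test_cross_chromosome_and_strand_mismatch_dropped(self, index):
        report = CallReport()
        out = call_backsplice(
            [rec(400, 300, chrom2="chr2"), rec(400, 300, strand2="-")],
            index, tolerance=0, report=report)
        assert out == []
        assert report.cross_chromosome == 1 and report.strand_mismatch == 1

    def test_snapping_to_annotated_boundaries(self, index):
        # wobbly endpoints within tolerance snap to the annotation
        (c,) = call_backsplice([rec(399, 302)], index, tolerance=2)
        assert (c.start, c.end) == (300, 400)

    def test_tau_monotonicity(self, index):
        rng = np.random.default_rng(3)
        records = [rec(int(d), int(a), read_id=f"r{i}")
                   for i, (a, d) in enumerate(
                       rng.integers(90, 620, size=(200, 2)))
                   if a < d]
        previous = set()
        for tau in (0, 1, 2, 4):
            keys = {c.key for c in call_backsplice(records, index, tolerance=tau)}
            assert previous <= keys
            previous = keys

    def test_matches_bruteforce_oracle_on_random_instances(self):
        rng = np.random.default_rng(11)
        for trial in range(30):
            models = random_models(rng, int(rng.integers(1, 21)))
            records = random_records(rng, models, 60)
            index = build_boundary_index(models)
            got = {(c.key, c.circ_type): c.read_count
                   for c in call_backsplice(records, index, tolerance=0)}
            assert got == oracle_keys(records, models), f"trial {trial}"


class TestMergeByKey:
    def _cand(self, read_ids, start=300, end=400, circ_type="exonic", tx="TX1"):
        return CircCandidate(
            chrom="chr1", start=start, end=end, strand="+", circ_type=circ_type,
            exon_sizes=(end - start,), exon_offsets=(0,), gene_name="G",
            transcript_id=tx, read_count=len(read_ids),
            read_ids=frozenset(read_ids),
        )

    def test_distinct_reads_sum(self):
        merged = merge_by_key([self._cand({"r1"}), self._cand({"r2"})])
        assert len(merged) == 1
        (c,) = merged.values()
        assert c.read_count == 2

    def test_duplicate_read_id_counted_once(self):
        merged = merge_by_key([self._cand({"r1"}), self._cand({"r1"})])
        (c,) = merged.values()
        assert c.read_count == 1

    def test_disjoint_keys_kept_apart(self):
        merged = merge_by_key([self._cand({"r1"}), self._cand({"r2"}, start=100, end=200)])
        assert len(merged) == 2

    def test_exonic_wins_type_conflict(self):
        merged = merge_by_key([
            self._cand({"r1"}, circ_type="ciRNA", tx="TXa"),
            self._cand({"r2"}, circ_type="exonic", tx="TXb"),
        ])
        (c,) = merged.values()
        assert c.circ_type == "exonic" and c.read_count == 2


class TestCandidateModel:
    def test_length_is_half_open_difference(self):
        c = CircCandidate("chrX", 0, 1, "+", "exonic", (1,), (0,), "G", "T", 1)
        assert candidate_length(c) == 1

    @pytest.mark.parametrize("kwargs", [
        dict(start=100, end=100),                       # empty span
        dict(exon_sizes=(50,), exon_offsets=(10,)),     # first offset not 0
        dict(exon_sizes=(50, 60), exon_offsets=(0, 40)),  # last exon overruns
        dict(circ_type="ciRNA", exon_sizes=(40, 40), exon_offsets=(0, 60)),
    ])
    def test_invalid_candidates_rejected(self, kwargs):
        base = dict(chrom="chr1", start=100, end=200, strand="+",
                    circ_type="exonic", exon_sizes=(100,), exon_offsets=(0,),
                    gene_name="G", transcript_id="T", read_count=1)
        base.update(kwargs)
        with pytest.raises(ValueError):
            CircCandidate(**base)


class TestFileFormats:
    def test_chimeric_round_trip_and_counts(self, tmp_path):
        records = [rec(400, 300, read_id=f"r{i}") for i in range(5)]
        p = tmp_path / "junc.tsv"
        write_chimeric_records(records, p)
        assert parse_chimeric_records(p) == records

    def test_empty_file_empty_list(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("")
        assert parse_chimeric_records(p) == []

    def test_bad_column_count_names_line(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("chr1\t100\t+\n")
        with pytest.raises(ChimericParseError, match="line 1"):
            parse_chimeric_records(p)

    def test_bed_round_trip(self, tmp_path, index):
        cands = call_backsplice(
            [rec(600, 100), rec(250, 200), rec(400, 300, read_id="r2")],
            index, tolerance=0)
        p = tmp_path / "cands.bed"
        write_candidates(cands, p)
        back = read_candidates(p)
        assert [(c.key, c.circ_type, c.exon_sizes, c.exon_offsets, c.read_count,
                 c.gene_name, c.transcript_id) for c in back] == \
               [(c.key, c.circ_type, c.exon_sizes, c.exon_offsets, c.read_count,
                 c.gene_name, c.transcript_id) for c in cands]
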