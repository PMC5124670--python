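"""Coordinate arithmetic on published hg19 circRNA rows.

Under the 0-based half-open convention a circle's length is end - start;
the two SEC62 isoforms (chr3, 3q26.2) and the single-exon NCL circle
reproduce their published lengths from their printed coordinates alone.
"""

from circsieve import CircCandidate, candidate_length

rows = [
    ("SEC62 (5 exons)", "chr3", 169694733, 169706147, "+"),
    ("SEC62 (4 exons)", "chr3", 169694733, 169703653, "+"),
    ("NCL (1 exon)", "chr2", 232325188, 232325275, "-"),
]
for label, chrom, start, end, strand in rows:
    c = CircCandidate(chrom=chrom, start=start, end=end, strand=strand,
                      circ_type="exonic", exon_sizes=(end - start,),
                      exon_offsets=(0,), gene_name="", transcript_id="",
                      read_count=2)
    print(f"{label}: {chrom}:{start}-{end} -> {candidate_length(c)} nt")
# For a single-exon circle the span equals the exon size exactly (NCL: 87).
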