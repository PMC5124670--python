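"""Synthetic genomes, gene models and chimeric junction files with planted truth.

The generator emulates the data layout of a paired-lesion total-RNA circRNA
screen with a poly(A)-selected control library, so the whole pipeline is
testable without any sequencing data:

* toy chromosomes carrying non-overlapping multi-exon gene models;
* planted **exonic circRNAs**: back-splice junctions spanning a run of
  annotated exons of one transcript (1 up to the transcript's exon count);
* planted **intron lariats** (ciRNAs): junctions confined to one intron with
  the 5' end at the intron's donor boundary;
* planted **polyA+ artifact junctions**: back-splice-orientation junctions
  that appear in every library including the poly(A)-selected ones — the
  model of library-prep/misalignment artifacts that survive the caller and
  can only be removed by the polyA+ subtraction filter;
* **linear splice decoys**: ordinary forward splice junctions (donor
  upstream of acceptor) that a back-splice caller must ignore.

Every read is a distinct read identifier ``<sample>:<key>:<i>``;
"independent reads" means distinct identifiers. Output is byte-identical
for a fixed config (ordering is explicit everywhere).

Genome sequence is generated for file completeness only; detection is
junction-coordinate based and never inspects bases.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np

from .annotation import GeneModel, write_gene_models
from .caller import ChimericJunctionRecord, JunctionKey, write_chimeric_records
from .filtering import LibraryType

__all__ = [
    "SampleSpec",
    "SimulationConfig",
    "CircPlant",
    "GroundTruth",
    "generate_annotation",
    "plant_truth",
    "emit_junction_files",
    "simulate",
    "read_truth",
    "write_sample_sheet",
    "read_sample_sheet",
    "SimulationConfigError",
]


class SimulationConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SampleSpec:
    sample_id: str
    library_type: LibraryType
    group: str
    total_mapped_reads: int


def _default_samples() -> tuple[SampleSpec, ...]:
    # five tandem lesion pairs (total RNA) plus one poly(A)+ cell-line library
    out: list[SampleSpec] = []
    depths = [31_000_000, 27_500_000, 35_000_000, 29_000_000, 33_500_000]
    for i, d in enumerate(depths, start=1):
        out.append(SampleSpec(f"DCIS_{i}", "total", "DCIS", d))
        out.append(SampleSpec(f"IDC_{i}", "total", "IDC", d + 1_500_000))
    out.append(SampleSpec("MCF7_polyA", "polyA+", "MCF7", 40_000_000))
    return tuple(out)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters of one synthetic cohort.

    Ranges are inclusive (low, high) pairs. Defaults describe a small
    paired-lesion design: ten total-RNA samples in two groups plus one
    poly(A)+ control, a few dozen planted circles with read support of at
    least two, and enough decoys to exercise every drop path of the caller.
    """

    seed: int = 0
    n_chromosomes: int = 3
    n_genes: int = 30
    exons_per_gene: tuple[int, int] = (2, 8)
    exon_length: tuple[int, int] = (80, 300)
    intron_length: tuple[int, int] = (100, 1000)
    intergenic_gap: tuple[int, int] = (200, 800)
    planted_exonic: int = 40
    planted_lariat: int = 10
    planted_artifacts: int = 8
    support_range: tuple[int, int] = (2, 10)
    linear_decoys: int = 20
    samples: tuple[SampleSpec, ...] = field(default_factory=_default_samples)
    sample_presence_prob: float = 0.7
    allow_artifact_overlap: bool = False

    def __post_init__(self) -> None:
        for name in ("exons_per_gene", "exon_length", "intron_length", "intergenic_gap",
                     "support_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise SimulationConfigError(f"{name}: low {lo} > high {hi}")
            if lo < 1:
                raise SimulationConfigError(f"{name}: low {lo} must be >= 1")
        if self.intron_length[0] < 4:
            raise SimulationConfigError("intron_length low must be >= 4 to fit a lariat")
        for name in ("n_chromosomes", "n_genes"):
            if getattr(self, name) < 1:
                raise SimulationConfigError(f"{name} must be >= 1")
        for name in ("planted_exonic", "planted_lariat", "planted_artifacts",
                     "linear_decoys"):
            if getattr(self, name) < 0:
                raise SimulationConfigError(f"{name} must be >= 0")
        if not 0.0 < self.sample_presence_prob <= 1.0:
            raise SimulationConfigError("sample_presence_prob must be in (0, 1]")

    @property
    def total_samples(self) -> tuple[SampleSpec, ...]:
        return tuple(s for s in self.samples if s.library_type == "total")

    @property
    def polya_samples(self) -> tuple[SampleSpec, ...]:
        return tuple(s for s in self.samples if s.library_type == "polyA+")


@dataclass(frozen=True)
class CircPlant:
    """One planted junction: a true circle or a polyA+ artifact."""

    key: JunctionKey
    circ_type: Literal["exonic", "ciRNA"]
    exon_indices: tuple[int, ...]  # annotated exon indices spanned (exonic only)
    transcript_id: str
    gene_name: str


@dataclass
class GroundTruth:
    circ_records: list[CircPlant]
    artifact_records: list[CircPlant]
    per_sample_support: dict[str, dict[JunctionKey, int]]

    @property
    def circ_keys(self) -> set[JunctionKey]:
        return {p.key for p in self.circ_records}

    @property
    def artifact_keys(self) -> set[JunctionKey]:
        return {p.key for p in self.artifact_records}


# ---------------------------------------------------------------------------
# annotation generation
# ---------------------------------------------------------------------------


def generate_annotation(config: SimulationConfig) -> tuple[dict[str, str], list[GeneModel]]:
    """Lay out ``n_genes`` non-overlapping gene models over toy chromosomes.

    Genes are assigned round-robin to chromosomes and placed left to right
    with random intergenic gaps; strands alternate deterministically with
    the draw. Returns ({chrom: sequence}, models); deterministic per seed.
    """
    rng = np.random.default_rng([config.seed, 101])
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    cursor = {c: 0 for c in chrom_names}
    models: list[GeneModel] = []
    for g in range(config.n_genes):
        chrom = chrom_names[g % config.n_chromosomes]
        gap = int(rng.integers(config.intergenic_gap[0], config.intergenic_gap[1] + 1))
        n_exons = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        pos = cursor[chrom] + gap
        starts: list[int] = []
        ends: list[int] = []
        for e in range(n_exons):
            if e > 0:
                pos += int(rng.integers(config.intron_length[0], config.intron_length[1] + 1))
            exon_len = int(rng.integers(config.exon_length[0], config.exon_length[1] + 1))
            starts.append(pos)
            pos += exon_len
            ends.append(pos)
        cursor[chrom] = pos
        models.append(
            GeneModel(
                gene_name=f"GENE{g + 1}",
                transcript_id=f"TX{g + 1:04d}",
                chrom=chrom,
                strand=strand,  # type: ignore[arg-type]
                exon_starts=tuple(starts),
                exon_ends=tuple(ends),
            )
        )
    genome: dict[str, str] = {}
    for c in chrom_names:
        length = cursor[c] + 500
        bases = rng.integers(0, 4, size=length)
        genome[c] = "".join("ACGT"[b] for b in bases)
    return genome, models


# ---------------------------------------------------------------------------
# truth planting
# ---------------------------------------------------------------------------


def _all_exon_runs(models: Sequence[GeneModel]) -> list[tuple[GeneModel, int, int]]:
    runs = []
    for m in models:
        for a in range(m.exon_count):
            for b in range(a, m.exon_count):
                runs.append((m, a, b))
    return runs


def _run_key(m: GeneModel, a: int, b: int) -> JunctionKey:
    return JunctionKey(m.chrom, m.exon_starts[a], m.exon_ends[b], m.strand)


def plant_truth(models: Sequence[GeneModel], config: SimulationConfig) -> GroundTruth:
    """Choose planted circles, lariats and artifacts on the given models.

    Exonic plants (and artifacts) are whole exon runs of one transcript;
    lariats sit inside one intron with their 5' end at the intron's donor
    boundary (the genomic start of the intron on '+' transcripts, the
    genomic end on '-'). Every planted circle is guaranteed present in at
    least one total-RNA sample; presence in each further total sample is
    Bernoulli(``sample_presence_prob``). Artifacts are present in every
    sample, poly(A)+ included.
    """
    if not models:
        raise SimulationConfigError("no gene models to plant on")
    rng = np.random.default_rng([config.seed, 202])

    runs = _all_exon_runs(models)
    n_runs_needed = config.planted_exonic + (
        0 if config.allow_artifact_overlap else config.planted_artifacts
    )
    if n_runs_needed > len(runs):
        raise SimulationConfigError(
            f"requested {n_runs_needed} exon-run plants but only {len(runs)} runs exist"
        )
    chosen = rng.choice(len(runs), size=n_runs_needed, replace=False)
    exonic_plants = [
        CircPlant(
            key=_run_key(*runs[i]),
            circ_type="exonic",
            exon_indices=tuple(range(runs[i][1], runs[i][2] + 1)),
            transcript_id=runs[i][0].transcript_id,
            gene_name=runs[i][0].gene_name,
        )
        for i in chosen[: config.planted_exonic]
    ]
    if config.allow_artifact_overlap:
        art_idx = rng.choice(len(runs), size=config.planted_artifacts, replace=False)
    else:
        art_idx = chosen[config.planted_exonic:]
    artifact_plants = [
        CircPlant(
            key=_run_key(*runs[i]),
            circ_type="exonic",
            exon_indices=tuple(range(runs[i][1], runs[i][2] + 1)),
            transcript_id=runs[i][0].transcript_id,
            gene_name=runs[i][0].gene_name,
        )
        for i in art_idx
    ]

    introns = [
        (m, j, s, e) for m in models for j, (s, e) in enumerate(m.introns()) if e - s >= 4
    ]
    if config.planted_lariat > len(introns):
        raise SimulationConfigError(
            f"requested {config.planted_lariat} lariats but only {len(introns)} introns exist"
        )
    lariat_plants: list[CircPlant] = []
    for i in rng.choice(len(introns), size=config.planted_lariat, replace=False):
        m, j, s, e = introns[i]
        if m.strand == "+":
            end = int(rng.integers(s + 2, e))  # branchpoint strictly inside
            key = JunctionKey(m.chrom, s, end, m.strand)
        else:
            start = int(rng.integers(s + 1, e - 1))
            key = JunctionKey(m.chrom, start, e, m.strand)
        lariat_plants.append(
            CircPlant(
                key=key,
                circ_type="ciRNA",
                exon_indices=(),
                transcript_id=m.transcript_id,
                gene_name=m.gene_name,
            )
        )

    circ_records = sorted(exonic_plants + lariat_plants, key=lambda p: p.key)
    artifact_records = sorted(artifact_plants, key=lambda p: p.key)

    totals = config.total_samples
    if not totals and circ_records:
        raise SimulationConfigError("no total-RNA samples to carry planted circles")
    support: dict[str, dict[JunctionKey, int]] = {s.sample_id: {} for s in config.samples}
    lo, hi = config.support_range
    for plant in circ_records:
        present = [
            s for s in totals if rng.random() < config.sample_presence_prob
        ]
        if not present:
            present = [totals[int(rng.integers(0, len(totals)))]]
        for s in present:
            support[s.sample_id][plant.key] = int(rng.integers(lo, hi + 1))
    for plant in artifact_records:
        for s in config.samples:
            if s.library_type == "polyA+":
                count = int(rng.integers(1, hi + 1))  # any support convicts
            else:
                a = max(lo, 2)  # must survive the support filter to matter
                count = int(rng.integers(a, max(hi, a) + 1))
            support[s.sample_id][plant.key] = count
    return GroundTruth(
        circ_records=circ_records,
        artifact_records=artifact_records,
        per_sample_support=support,
    )


# ---------------------------------------------------------------------------
# emission
# ---------------------------------------------------------------------------


def _junction_records(
    sample: SampleSpec, keys_counts: Iterable[tuple[JunctionKey, int]]
) -> list[ChimericJunctionRecord]:
    records: list[ChimericJunctionRecord] = []
    for key, count in keys_counts:
        for i in range(count):
            records.append(
                ChimericJunctionRecord(
                    chrom_donor=key.chrom,
                    pos_donor=key.end,
                    strand_donor=key.strand,
                    chrom_acceptor=key.chrom,
                    pos_acceptor=key.start,
                    strand_acceptor=key.strand,
                    junction_type=1,
                    read_id=f"{sample.sample_id}:{key}:{i}",
                )
            )
    return records


def emit_junction_files(
    truth: GroundTruth,
    models: Sequence[GeneModel],
    config: SimulationConfig,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write one chimeric junction file per sample, plus the truth sidecar.

    Planted junctions are emitted in back-splice orientation (acceptor at the
    key start, donor at the key end, read strand = transcript strand), one
    line per distinct read id. Linear decoys are ordinary splice junctions
    (donor genomically upstream of the acceptor) drawn from adjacent exon
    pairs; they appear in every sample. PolyA+ samples carry only artifact
    junctions and decoys.
    """
    if not config.samples:
        raise SimulationConfigError("sample sheet is empty")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng([config.seed, 303])

    adjacent = [
        (m, i) for m in models for i in range(m.exon_count - 1)
    ]
    decoys: list[tuple[GeneModel, int]] = []
    if config.linear_decoys and adjacent:
        idx = rng.choice(len(adjacent), size=min(config.linear_decoys, len(adjacent)),
                         replace=False)
        decoys = [adjacent[i] for i in sorted(idx)]

    paths: dict[str, Path] = {}
    for sample in config.samples:
        counts = truth.per_sample_support.get(sample.sample_id, {})
        records = _junction_records(sample, sorted(counts.items()))
        for d_i, (m, i) in enumerate(decoys):
            n_reads = int(rng.integers(1, 4))
            for r in range(n_reads):
                records.append(
                    ChimericJunctionRecord(
                        chrom_donor=m.chrom,
                        pos_donor=m.exon_ends[i],
                        strand_donor=m.strand,
                        chrom_acceptor=m.chrom,
                        pos_acceptor=m.exon_starts[i + 1],
                        strand_acceptor=m.strand,
                        junction_type=0,
                        read_id=f"{sample.sample_id}:lin{d_i}:{r}",
                    )
                )
        path = outdir / f"{sample.sample_id}.junctions.tsv"
        write_chimeric_records(records, path)
        paths[sample.sample_id] = path

    _write_truth(truth, outdir / "truth.tsv")
    return paths


def _write_truth(truth: GroundTruth, path: Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["key", "kind", "circ_type", "exon_indices", "transcript_id", "gene_name"])
        for p in truth.circ_records:
            w.writerow([str(p.key), "circ", p.circ_type,
                        ",".join(map(str, p.exon_indices)), p.transcript_id, p.gene_name])
        for p in truth.artifact_records:
            w.writerow([str(p.key), "artifact", p.circ_type,
                        ",".join(map(str, p.exon_indices)), p.transcript_id, p.gene_name])
    with open(path.with_name("truth_support.tsv"), "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["sample_id", "key", "read_count"])
        for sample_id in sorted(truth.per_sample_support):
            for key, count in sorted(truth.per_sample_support[sample_id].items()):
                w.writerow([sample_id, str(key), count])


def read_truth(path: str | Path) -> tuple[list[CircPlant], list[CircPlant]]:
    """Read back a truth sidecar: (circ plants, artifact plants)."""
    circ: list[CircPlant] = []
    art: list[CircPlant] = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            plant = CircPlant(
                key=JunctionKey.parse(row["key"]),
                circ_type=row["circ_type"],  # type: ignore[arg-type]
                exon_indices=tuple(
                    int(x) for x in row["exon_indices"].split(",") if x
                ),
                transcript_id=row["transcript_id"],
                gene_name=row["gene_name"],
            )
            (circ if row["kind"] == "circ" else art).append(plant)
    return circ, art


# ---------------------------------------------------------------------------
# sample sheets and the one-call driver
# ---------------------------------------------------------------------------


def write_sample_sheet(
    samples: Sequence[SampleSpec], junction_paths: dict[str, Path], path: str | Path
) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["sample_id", "group", "library_type", "total_mapped_reads",
                    "junction_path"])
        for s in samples:
            w.writerow([s.sample_id, s.group, s.library_type, s.total_mapped_reads,
                        str(junction_paths[s.sample_id])])


def read_sample_sheet(path: str | Path) -> list[tuple[SampleSpec, Path]]:
    out: list[tuple[SampleSpec, Path]] = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            spec = SampleSpec(
                sample_id=row["sample_id"],
                library_type=row["library_type"],  # type: ignore[arg-type]
                group=row["group"],
                total_mapped_reads=int(row["total_mapped_reads"]),
            )
            out.append((spec, Path(row["junction_path"])))
    return out


def _write_fasta(genome: dict[str, str], path: Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in sorted(genome):
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def simulate(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Run the full generator: genome, annotation, truth, junction files.

    Returns the paths of everything written (annotation, genome, sample
    sheet, truth sidecars and one junction file per sample).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, models = generate_annotation(config)
    truth = plant_truth(models, config)
    junction_paths = emit_junction_files(truth, models, config, outdir)

    annotation = outdir / "annotation.refflat.txt"
    write_gene_models(models, annotation)
    fasta = outdir / "genome.fa"
    _write_fasta(genome, fasta)
    sheet = outdir / "samples.tsv"
    write_sample_sheet(config.samples, junction_paths, sheet)

    paths = {"annotation": annotation, "genome": fasta, "sample_sheet": sheet,
             "truth": outdir / "truth.tsv",
             "truth_support": outdir / "truth_support.tsv"}
    paths.update(junction_paths)
    return paths
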