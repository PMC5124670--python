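"""Stage orchestration: detect -> filter -> quantify -> summarize.

Each stage is a plain function over library objects that also writes its
tabular outputs, so the stages compose identically from Python and from the
command line. A JSON manifest records parameters, input checksums and the
stages completed, making a run self-describing and exactly repeatable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from . import __version__
from .annotation import build_boundary_index, read_gene_models
from .caller import (
    CallReport,
    call_backsplice,
    parse_chimeric_records,
    read_candidates,
    write_candidates,
)
from .cohort import group_overlap, summarize_group, write_summary_json
from .filtering import (
    FilterStageReport,
    SampleProfile,
    polya_subtraction,
    support_filter,
    write_filter_report,
)
from .quantify import build_matrix
from .simulate import SampleSpec, read_sample_sheet

__all__ = ["RunConfig", "PipelineError", "detect", "filter_candidates", "quantify",
           "summarize", "run_all", "write_manifest"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    sample_sheet: Path
    annotation: Path
    outdir: Path
    min_support: int = 2
    tolerance: int = 2

    def __post_init__(self) -> None:
        self.sample_sheet = Path(self.sample_sheet)
        self.annotation = Path(self.annotation)
        self.outdir = Path(self.outdir)
        if self.min_support < 1:
            raise PipelineError("min_support must be >= 1")
        if self.tolerance < 0:
            raise PipelineError("tolerance must be >= 0")

    def require_inputs(self) -> None:
        for p in (self.sample_sheet, self.annotation):
            if not p.exists():
                raise PipelineError(f"missing input: {p}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(65536), b""):
            h.update(block)
    return h.hexdigest()


def detect(config: RunConfig) -> list[SampleProfile]:
    """Call back-splice candidates for every sample in the sheet.

    Writes ``<sample>.candidates.bed`` (BED12+) per sample under the output
    directory and returns the raw per-sample profiles.
    """
    config.require_inputs()
    config.outdir.mkdir(parents=True, exist_ok=True)
    models = read_gene_models(config.annotation)
    index = build_boundary_index(models)
    profiles: list[SampleProfile] = []
    for spec, junction_path in read_sample_sheet(config.sample_sheet):
        if not junction_path.exists():
            raise PipelineError(f"missing input: {junction_path}")
        records = parse_chimeric_records(junction_path)
        report = CallReport()
        candidates = call_backsplice(records, index, tolerance=config.tolerance,
                                     report=report)
        logger.info(
            "[detect] %s: %d records, %d called, %d linear, %d unmatched",
            spec.sample_id, report.n_records, report.n_called,
            report.linear_orientation, report.unmatched,
        )
        write_candidates(candidates, config.outdir / f"{spec.sample_id}.candidates.bed")
        profiles.append(
            SampleProfile(
                sample_id=spec.sample_id,
                library_type=spec.library_type,
                group=spec.group,
                total_mapped_reads=spec.total_mapped_reads,
                candidates={c.key: c for c in candidates},
            )
        )
    return profiles


def filter_candidates(
    profiles: Sequence[SampleProfile], config: RunConfig
) -> list[SampleProfile]:
    """Support filter then polyA+ subtraction on every total-RNA profile.

    The two filters commute; the fixed order is for reproducible stage logs.
    Writes ``<sample>.filtered.bed`` per total sample and a per-stage count
    report. PolyA+ profiles pass through untouched (they exist to convict).
    """
    config.outdir.mkdir(parents=True, exist_ok=True)
    polya = [p for p in profiles if p.library_type == "polyA+"]
    out: list[SampleProfile] = []
    reports: list[FilterStageReport] = []
    for p in profiles:
        if p.library_type != "total":
            out.append(p)
            continue
        supported = support_filter(p, k=config.min_support)
        final = polya_subtraction(supported, polya)
        reports.append(
            FilterStageReport(
                sample_id=p.sample_id,
                n_raw=len(p.candidates),
                n_after_support=len(supported.candidates),
                n_after_subtraction=len(final.candidates),
            )
        )
        logger.info("[filter] %s: %d -> %d (support>=%d) -> %d (polyA+ subtraction)",
                    p.sample_id, len(p.candidates), len(supported.candidates),
                    config.min_support, len(final.candidates))
        write_candidates(final.candidates.values(),
                         config.outdir / f"{p.sample_id}.filtered.bed")
        out.append(final)
    write_filter_report(reports, config.outdir / "filter_report.tsv")
    return out


def _load_filtered(config: RunConfig) -> list[SampleProfile]:
    profiles = []
    for spec, _ in read_sample_sheet(config.sample_sheet):
        if spec.library_type != "total":
            continue
        path = config.outdir / f"{spec.sample_id}.filtered.bed"
        if not path.exists():
            raise PipelineError(f"missing input: {path} (run 'filter' first)")
        cands = read_candidates(path)
        profiles.append(
            SampleProfile(
                sample_id=spec.sample_id,
                library_type=spec.library_type,
                group=spec.group,
                total_mapped_reads=spec.total_mapped_reads,
                candidates={c.key: c for c in cands},
            )
        )
    return profiles


def quantify(profiles: Sequence[SampleProfile] | None, config: RunConfig):
    """SRPBM matrix over the filtered total-RNA samples -> ``srpbm.tsv``."""
    if profiles is None:
        profiles = _load_filtered(config)
    totals = [p for p in profiles if p.library_type == "total"]
    matrix = build_matrix(totals, unit="SRPBM")
    matrix.to_tsv(config.outdir / "srpbm.tsv")
    return matrix


def summarize(profiles: Sequence[SampleProfile] | None, config: RunConfig):
    """Group-level genomic-context summaries and the cross-group overlap.

    Group candidate sets are unions of distinct keys over member samples.
    Writes ``summary.json`` and ``overlap.tsv``.
    """
    if profiles is None:
        profiles = _load_filtered(config)
    totals = [p for p in profiles if p.library_type == "total"]
    if not totals:
        raise PipelineError("no total-RNA samples to summarize")
    groups = sorted({p.group for p in totals})
    summaries = []
    for g in groups:
        merged: dict = {}
        for p in totals:
            if p.group == g:
                merged.update(p.candidates)
        summaries.append(summarize_group(merged.values(), group=g))
    write_summary_json(summaries, config.outdir / "summary.json")

    overlap = group_overlap(
        {p.sample_id: p.keys for p in totals},
        {p.sample_id: p.group for p in totals},
    )
    overlap.to_tsv(config.outdir / "overlap.tsv")
    return summaries, overlap


def write_manifest(config: RunConfig, stages: list[str], extra: dict | None = None) -> Path:
    inputs = {}
    for p in (config.sample_sheet, config.annotation):
        if p.exists():
            inputs[str(p)] = _sha256(p)
    manifest = {
        "tool": "circsieve",
        "version": __version__,
        "parameters": {
            "min_support": config.min_support,
            "tolerance": config.tolerance,
            "sample_sheet": str(config.sample_sheet),
            "annotation": str(config.annotation),
            "outdir": str(config.outdir),
        },
        "input_checksums": inputs,
        "stages_completed": stages,
    }
    if extra:
        manifest.update(extra)
    path = config.outdir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def run_all(config: RunConfig) -> Path:
    """Chain detect -> filter -> quantify -> summarize and write the manifest."""
    profiles = detect(config)
    filtered = filter_candidates(profiles, config)
    quantify(filtered, config)
    summarize(filtered, config)
    return write_manifest(config, ["detect", "filter", "quantify", "summarize"])
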