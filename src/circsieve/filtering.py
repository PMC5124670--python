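"""Candidate filtering: minimum junction support and polyA+ subtraction.

Two filters turn raw back-splice calls into high-confidence circRNAs:

* **support filter** — keep only junctions backed by at least ``k``
  independent reads (default ``k = 2``), applied per total-RNA sample;
* **polyA+ subtraction** — a true circRNA is not polyadenylated, so any
  junction key also predicted in a poly(A)-selected library is treated as a
  false positive (mis-amplification, misalignment) and removed from every
  total-RNA sample, regardless of its read count in the polyA+ library.

Both filters are pure set operations on disjoint criteria, hence idempotent
and order-independent; the pipeline applies support first, then subtraction.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal

from .caller import CircCandidate, JunctionKey

__all__ = [
    "SampleProfile",
    "FilterStageReport",
    "support_filter",
    "polya_subtraction",
    "polya_reference_keys",
    "write_filter_report",
]

LibraryType = Literal["total", "polyA+"]


@dataclass
class SampleProfile:
    """One sequencing sample and its candidate circRNA set."""

    sample_id: str
    library_type: LibraryType
    group: str
    total_mapped_reads: int
    candidates: dict[JunctionKey, CircCandidate] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.library_type not in ("total", "polyA+"):
            raise ValueError(f"unknown library type {self.library_type!r}")
        if self.candidates and self.total_mapped_reads <= 0:
            raise ValueError(
                f"sample {self.sample_id}: total_mapped_reads must be > 0 "
                "when candidates are present"
            )

    @property
    def keys(self) -> set[JunctionKey]:
        return set(self.candidates)


def support_filter(profile: SampleProfile, k: int = 2) -> SampleProfile:
    """Retain candidates supported by at least ``k`` independent reads."""
    if k < 1:
        raise ValueError("minimum support k must be >= 1")
    kept = {key: c for key, c in profile.candidates.items() if c.read_count >= k}
    return replace(profile, candidates=kept)


def polya_reference_keys(polya_profiles: Iterable[SampleProfile]) -> set[JunctionKey]:
    """Union of junction keys predicted in any polyA+ sample."""
    keys: set[JunctionKey] = set()
    for p in polya_profiles:
        if p.library_type != "polyA+":
            raise ValueError(f"sample {p.sample_id} is not a polyA+ library")
        keys |= p.keys
    return keys


def polya_subtraction(
    profile: SampleProfile, polya_profiles: Iterable[SampleProfile]
) -> SampleProfile:
    """Remove every candidate whose key appears in any polyA+ profile.

    The polyA+ read count is irrelevant: one polyA+ prediction suffices for
    exclusion.
    """
    if profile.library_type != "total":
        raise ValueError(
            f"polyA+ subtraction applies to total-RNA samples; "
            f"{profile.sample_id} is {profile.library_type}"
        )
    exclude = polya_reference_keys(polya_profiles)
    kept = {key: c for key, c in profile.candidates.items() if key not in exclude}
    return replace(profile, candidates=kept)


@dataclass
class FilterStageReport:
    sample_id: str
    n_raw: int
    n_after_support: int
    n_after_subtraction: int


def write_filter_report(reports: Iterable[FilterStageReport], path: str | Path) -> None:
    """Per-sample candidate counts in/out at each filtering stage, as TSV."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["sample_id", "raw", "after_support", "after_polya_subtraction"])
        for r in reports:
            w.writerow([r.sample_id, r.n_raw, r.n_after_support, r.n_after_subtraction])
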