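"""Sequencing-depth normalisation and expression matrix assembly.

Junction read counts are normalised to SRPBM (spliced reads per billion
mapped reads): raw count divided by the sample's total mapped reads, times
10^9. Gene-level counts use the analogous RPM (reads per million, scale
10^6). Matrices distinguish a missing observation (key never seen in a
sample, encoded NA) from a true zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .filtering import SampleProfile

__all__ = ["ExpressionMatrix", "srpbm", "rpm", "build_matrix", "log_transform"]

Unit = Literal["SRPBM", "RPM"]

_SCALE = {"SRPBM": 1e9, "RPM": 1e6}


def _normalize(raw_count: float, total_mapped: float, scale: float) -> float:
    if total_mapped <= 0:
        raise ZeroDivisionError("total mapped reads must be > 0")
    if raw_count < 0:
        raise ValueError("raw count must be >= 0")
    return raw_count / total_mapped * scale


def srpbm(raw_count: float, total_mapped: float) -> float:
    """Reads per billion mapped reads: ``raw_count / total_mapped * 1e9``."""
    return _normalize(raw_count, total_mapped, 1e9)


def rpm(raw_count: float, total_mapped: float) -> float:
    """Reads per million mapped reads: ``raw_count / total_mapped * 1e6``."""
    return _normalize(raw_count, total_mapped, 1e6)


@dataclass
class ExpressionMatrix:
    """A junction-key (or gene) × sample matrix of normalised values.

    ``values`` is a pandas DataFrame; NaN cells are missing observations
    (key absent from that sample), distinct from an observed zero.
    """

    values: pd.DataFrame
    unit: Unit

    def __post_init__(self) -> None:
        if self.unit not in _SCALE:
            raise ValueError(f"unknown unit {self.unit!r}")
        present = self.values.to_numpy(dtype=float)
        if np.nanmin(present, initial=0.0) < 0:
            raise ValueError("expression values must be non-negative")

    def row(self, key: str) -> pd.Series:
        return self.values.loc[key]

    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", na_rep="NA", index_label="key")

    @classmethod
    def from_tsv(cls, path: str | Path, unit: Unit) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col="key", na_values=["NA"])
        return cls(values=df, unit=unit)


def build_matrix(profiles: Sequence[SampleProfile], unit: Unit = "SRPBM") -> ExpressionMatrix:
    """Assemble the key × sample matrix of normalised junction support.

    Rows are the union of junction keys over all profiles, columns the sample
    ids (input order). A key absent from a sample is NaN; present with raw
    count ``c`` it is ``c / total_mapped * scale``.
    """
    ids = [p.sample_id for p in profiles]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample ids in profiles")
    scale = _SCALE[unit]
    keys = sorted({k for p in profiles for k in p.candidates})
    data = np.full((len(keys), len(ids)), np.nan)
    row_of = {k: i for i, k in enumerate(keys)}
    for j, p in enumerate(profiles):
        for k, c in p.candidates.items():
            data[row_of[k], j] = _normalize(c.read_count, p.total_mapped_reads, scale)
    df = pd.DataFrame(data, index=[str(k) for k in keys], columns=ids)
    return ExpressionMatrix(values=df, unit=unit)


def log_transform(matrix: ExpressionMatrix) -> pd.DataFrame:
    """log10(value + 1), the reporting transform; NaN stays NaN."""
    return np.log10(matrix.values + 1.0)
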