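"""Cohort-level descriptive and inferential statistics for circRNA sets.

Covers the characterisation a circRNA screen reports per group: candidate
counts by class (exonic circRNA vs ciRNA) and chromosome, the length
distribution, the correlation between circle length and the number of
circularised exons, overlap sets between groups, rank-sum comparison of
expression between groups, and circRNA–mRNA expression correlations.

The rank statistics are implemented on mid-ranks with exact small-sample
p-values:

* Spearman's rho — Pearson correlation of mid-ranks; the p-value is an exact
  permutation p for n <= 10 and the usual t-approximation above that. The
  exact branch matters because group sizes in paired tumour designs are
  often 4–6, where the approximation is unreliable.
* Wilcoxon–Mann–Whitney — U on mid-ranks; p exact by enumeration of all
  group assignments when n_a + n_b <= 12, tie-corrected normal approximation
  otherwise.

No multiple-testing correction is applied anywhere.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .caller import CircCandidate, JunctionKey

__all__ = [
    "CohortSummary",
    "OverlapResult",
    "summarize_group",
    "spearman",
    "rank_sum_test",
    "group_overlap",
    "correlate_expression",
]

Alternative = Literal["two-sided", "greater", "less"]

_EXACT_SPEARMAN_MAX_N = 10
_EXACT_RANKSUM_MAX_N = 12
_TIE_EPS = 1e-12

LENGTH_BIN_WIDTH = 2500  # nt; the reporting emphasis threshold is 12500 nt
LENGTH_EMPHASIS_NT = 12500


# ---------------------------------------------------------------------------
# rank statistics
# ---------------------------------------------------------------------------


def _rho_from_ranks(rx: np.ndarray, ry: np.ndarray) -> float:
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = math.sqrt(float(rxc @ rxc) * float(ryc @ ryc))
    if denom == 0.0:
        raise ValueError("Spearman's rho is undefined for a constant input vector")
    return float(rxc @ ryc) / denom


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, rho: float, alternative: Alternative) -> float:
    """Permutation p over all n! pairings of the observed rank vectors."""
    n = len(rx)
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = math.sqrt(float(rxc @ rxc) * float(ryc @ ryc))
    perms = np.array(list(itertools.permutations(ryc)))
    rhos = perms @ rxc / denom
    if alternative == "greater":
        extreme = rhos >= rho - _TIE_EPS
    elif alternative == "less":
        extreme = rhos <= rho + _TIE_EPS
    else:
        extreme = np.abs(rhos) >= abs(rho) - _TIE_EPS
    return float(extreme.mean())


def _t_approx_spearman_p(rho: float, n: int, alternative: Alternative) -> float:
    if abs(rho) >= 1.0:
        p_one = 0.0
    else:
        t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
        p_one = float(sps.t.sf(t, df=n - 2))
    if alternative == "greater":
        return p_one
    if alternative == "less":
        return 1.0 - p_one
    return float(min(1.0, 2.0 * min(p_one, 1.0 - p_one)))


def spearman(
    x: Sequence[float], y: Sequence[float], alternative: Alternative = "two-sided"
) -> tuple[float, float]:
    """Spearman rank correlation on mid-ranks.

    Returns (rho, p). Ties receive average ranks. The p-value is exact (full
    permutation enumeration) for n <= 10, a t-approximation with n - 2
    degrees of freedom otherwise. Raises on constant input (rho undefined)
    or n < 3.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    n = len(xa)
    if n < 3:
        raise ValueError("Spearman correlation requires n >= 3")
    rx = sps.rankdata(xa)
    ry = sps.rankdata(ya)
    rho = _rho_from_ranks(rx, ry)
    if n <= _EXACT_SPEARMAN_MAX_N:
        p = _exact_spearman_p(rx, ry, rho, alternative)
    else:
        p = _t_approx_spearman_p(rho, n, alternative)
    return rho, p


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Mann-Whitney U for sample ``a``, from mid-ranks of the pooled data."""
    n_a = len(a)
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    r_a = float(ranks[:n_a].sum())
    return r_a - n_a * (n_a + 1) / 2.0


def rank_sum_test(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Wilcoxon-Mann-Whitney two-sample rank-sum test.

    Returns (U, two-sided p) where U is the statistic for sample ``a`` on
    mid-ranks. For n_a + n_b <= 12 the p-value is exact, by enumerating all
    C(n, n_a) assignments of the pooled observations to group a (correct
    under ties); larger samples use the tie-corrected normal approximation.
    """
    aa = np.asarray(a, dtype=float)
    ba = np.asarray(b, dtype=float)
    if len(aa) == 0 or len(ba) == 0:
        raise ValueError("both samples must be non-empty")
    n_a, n_b = len(aa), len(ba)
    u_obs = _u_statistic(aa, ba)
    if n_a + n_b <= _EXACT_RANKSUM_MAX_N:
        pooled = np.concatenate([aa, ba])
        ranks = sps.rankdata(pooled)
        offset = n_a * (n_a + 1) / 2.0
        mu = n_a * n_b / 2.0
        n_extreme = 0
        n_total = 0
        for idx in itertools.combinations(range(n_a + n_b), n_a):
            u = float(ranks[list(idx)].sum()) - offset
            n_total += 1
            if abs(u - mu) >= abs(u_obs - mu) - _TIE_EPS:
                n_extreme += 1
        p = n_extreme / n_total
    else:
        _, p = sps.mannwhitneyu(aa, ba, alternative="two-sided", method="asymptotic")
        p = float(p)
    return u_obs, p


# ---------------------------------------------------------------------------
# group characterisation
# ---------------------------------------------------------------------------


@dataclass
class CohortSummary:
    """Descriptive profile of one group's merged candidate set."""

    group: str
    n_candidates: int
    n_exonic: int
    n_ciRNA: int
    exonic_fraction: float | None  # n_exonic / n_candidates; None when empty
    per_chromosome: dict[str, int]
    length_bin_edges: list[int]
    length_hist: list[int]
    exon_count_hist: dict[int, int]
    length_exon_rho: float | None
    length_exon_p: float | None  # one-tailed (greater), exact at small n
    rho_undefined_reason: str | None = None

    def to_dict(self) -> dict:
        return {
            "group": self.group,
            "n_candidates": self.n_candidates,
            "n_exonic": self.n_exonic,
            "n_ciRNA": self.n_ciRNA,
            "exonic_fraction": self.exonic_fraction,
            "exonic_over_total": f"{self.n_exonic}/{self.n_candidates}",
            "per_chromosome": self.per_chromosome,
            "length_bin_edges": self.length_bin_edges,
            "length_hist": self.length_hist,
            "exon_count_hist": {str(k): v for k, v in sorted(self.exon_count_hist.items())},
            "length_exon_rho": self.length_exon_rho,
            "length_exon_p_one_tailed": self.length_exon_p,
            "rho_undefined_reason": self.rho_undefined_reason,
        }


def summarize_group(
    candidates: Iterable[CircCandidate], group: str = ""
) -> CohortSummary:
    """Summarise one group's distinct candidates.

    The length histogram uses fixed 2500-nt bins from zero to cover the
    longest candidate. The length ~ exon-count association is Spearman's rho
    with a one-tailed (positive) p-value, exact at small n; it is left
    undefined (with a stated reason) when there are fewer than three
    candidates or either variable is constant.
    """
    cands = list(candidates)
    n = len(cands)
    n_exonic = sum(1 for c in cands if c.circ_type == "exonic")
    n_ci = n - n_exonic
    per_chrom: dict[str, int] = {}
    for c in cands:
        per_chrom[c.chrom] = per_chrom.get(c.chrom, 0) + 1

    lengths = np.array([c.length for c in cands], dtype=float)
    exon_counts = np.array([c.exon_count for c in cands], dtype=float)

    if n:
        top = int(np.ceil((lengths.max() + 1) / LENGTH_BIN_WIDTH)) * LENGTH_BIN_WIDTH
        edges = np.arange(0, top + LENGTH_BIN_WIDTH, LENGTH_BIN_WIDTH)
        hist, _ = np.histogram(lengths, bins=edges)
    else:
        edges = np.array([0, LENGTH_BIN_WIDTH])
        hist = np.array([0])

    exon_hist: dict[int, int] = {}
    for c in cands:
        exon_hist[c.exon_count] = exon_hist.get(c.exon_count, 0) + 1

    rho: float | None = None
    p: float | None = None
    reason: str | None = None
    if n < 3:
        reason = "fewer than 3 candidates"
    else:
        try:
            rho, p = spearman(lengths, exon_counts, alternative="greater")
        except ValueError as exc:
            reason = str(exc)

    return CohortSummary(
        group=group,
        n_candidates=n,
        n_exonic=n_exonic,
        n_ciRNA=n_ci,
        exonic_fraction=(n_exonic / n) if n else None,
        per_chromosome=dict(sorted(per_chrom.items())),
        length_bin_edges=[int(e) for e in edges],
        length_hist=[int(h) for h in hist],
        exon_count_hist=exon_hist,
        length_exon_rho=rho,
        length_exon_p=p,
        rho_undefined_reason=reason,
    )


# ---------------------------------------------------------------------------
# group overlap
# ---------------------------------------------------------------------------


@dataclass
class OverlapResult:
    """Partition of the cohort's junction keys by group membership.

    ``common`` holds keys present in at least one sample of *every* group;
    ``exclusive[g]`` keys seen only in group ``g``'s samples; ``partial``
    keys seen in more than one but not all groups (empty with two groups).
    ``presence`` is a boolean key × sample table.
    """

    common: set[JunctionKey]
    exclusive: dict[str, set[JunctionKey]]
    partial: set[JunctionKey]
    presence: pd.DataFrame

    def to_tsv(self, path: str | Path) -> None:
        df = self.presence.copy()
        df.insert(0, "membership", [self._membership(JunctionKey.parse(k)) for k in df.index])
        df.to_csv(path, sep="\t", index_label="key")

    def _membership(self, key: JunctionKey) -> str:
        if key in self.common:
            return "common"
        for g, keys in self.exclusive.items():
            if key in keys:
                return f"only:{g}"
        return "partial"


def group_overlap(
    per_sample_keys: Mapping[str, set[JunctionKey]],
    groups: Mapping[str, str],
) -> OverlapResult:
    """Intersect per-sample key sets at the group level.

    A key is *common* when each group has at least one sample containing it,
    *exclusive* to a group when no other group's sample contains it.
    """
    missing = [s for s in per_sample_keys if s not in groups]
    if missing:
        raise ValueError(f"samples without a group label: {missing}")
    labels = sorted(set(groups[s] for s in per_sample_keys))
    keys_by_group: dict[str, set[JunctionKey]] = {g: set() for g in labels}
    for s, keys in per_sample_keys.items():
        keys_by_group[groups[s]] |= keys

    all_keys = set().union(*keys_by_group.values()) if keys_by_group else set()
    common: set[JunctionKey] = set()
    partial: set[JunctionKey] = set()
    exclusive: dict[str, set[JunctionKey]] = {g: set() for g in labels}
    for k in all_keys:
        present_in = [g for g in labels if k in keys_by_group[g]]
        if len(present_in) == len(labels):
            common.add(k)
        elif len(present_in) == 1:
            exclusive[present_in[0]].add(k)
        else:
            partial.add(k)

    samples = sorted(per_sample_keys)
    rows = sorted(all_keys)
    presence = pd.DataFrame(
        [[k in per_sample_keys[s] for s in samples] for k in rows],
        index=[str(k) for k in rows],
        columns=samples,
        dtype=bool,
    )
    return OverlapResult(common=common, exclusive=exclusive, partial=partial, presence=presence)


# ---------------------------------------------------------------------------
# circRNA-mRNA correlation
# ---------------------------------------------------------------------------


def correlate_expression(
    circ_row: Sequence[float],
    gene_row: Sequence[float],
    alternative: Alternative = "two-sided",
) -> tuple[float, float]:
    """Spearman correlation between a circRNA and a gene expression row.

    Computed on pairwise-complete observations (cells missing in either row
    are dropped). Requires at least three complete pairs.
    """
    ca = np.asarray(circ_row, dtype=float)
    ga = np.asarray(gene_row, dtype=float)
    if ca.shape != ga.shape:
        raise ValueError("rows must have equal length")
    mask = ~(np.isnan(ca) | np.isnan(ga))
    if int(mask.sum()) < 3:
        raise ValueError(
            f"insufficient data: {int(mask.sum())} complete pairs, need >= 3"
        )
    return spearman(ca[mask], ga[mask], alternative=alternative)


def write_summary_json(summaries: Iterable[CohortSummary], path: str | Path) -> None:
    payload = {s.group or f"group{i}": s.to_dict() for i, s in enumerate(summaries)}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
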