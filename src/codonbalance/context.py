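"""Colocalization of differentially expressed tRNA genes with
differentially expressed protein-coding neighbors, and chromatin-mark
association tests.

Colocalization: each tRNA gene's interval is expanded symmetrically by a
window; for every up-regulated tRNA gene t the ratio r_t = u_t / a_t of
up-regulated to total protein-coding genes overlapping the window is
computed, and the ratio distributions of up-regulated vs non-differentially
expressed tRNA genes are compared with a two-sample Kolmogorov-Smirnov test
per window size.

Chromatin association: a tRNA gene "has" a mark at distance d when any mark
interval intersects [start - d, end + d]; membership in two disjoint tRNA
sets vs mark presence forms a 2x2 table tested with Fisher's exact test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import TrnaGene

logger = logging.getLogger("codonbalance")


class _IntervalIndex:
    """Per-chromosome sorted starts/ends for O(log n) overlap counting."""

    def __init__(self, intervals: pd.DataFrame):
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, grp in intervals.groupby("chrom"):
            starts = np.sort(grp["start"].to_numpy())
            ends = np.sort(grp["end"].to_numpy())
            self._by_chrom[str(chrom)] = (starts, ends)

    def count_overlaps(self, chrom: str, lo: float, hi: float) -> int:
        """Number of intervals [s, e) with s < hi and e > lo."""
        if chrom not in self._by_chrom:
            return 0
        starts, ends = self._by_chrom[chrom]
        return int(np.searchsorted(starts, hi, side="left")
                   - np.searchsorted(ends, lo, side="right"))

    def any_overlap(self, chrom: str, lo: float, hi: float) -> bool:
        return self.count_overlaps(chrom, lo, hi) > 0


def colocalization_ratios(
    trna_ids: Sequence[str],
    trna_genes: Mapping[str, TrnaGene],
    pc_coords: pd.DataFrame,
    pc_up: set[str],
    window_kb: float,
) -> tuple[pd.Series, int]:
    """r_t = (# up-regulated pc genes) / (# pc genes) within ``window_kb`` of
    each tRNA gene; tRNA genes with no pc neighbor are excluded (count
    returned)."""
    all_idx = _IntervalIndex(pc_coords)
    up_idx = _IntervalIndex(pc_coords[pc_coords["gene_id"].isin(pc_up)])
    w = window_kb * 1000.0
    ratios: dict[str, float] = {}
    n_excluded = 0
    for tid in trna_ids:
        g = trna_genes[tid]
        lo, hi = g.start - w, g.end + w
        a_t = all_idx.count_overlaps(g.chrom, lo, hi)
        if a_t == 0:
            n_excluded += 1
            continue
        u_t = up_idx.count_overlaps(g.chrom, lo, hi)
        ratios[tid] = u_t / a_t
    return pd.Series(ratios, dtype=float), n_excluded


@dataclass
class ColocalizationCell:
    window_kb: float
    ks_statistic: float
    ks_p: float
    n_up: int
    n_nonde: int
    n_excluded: int


def colocalization_test(
    trna_up: set[str] | Sequence[str],
    trna_nonde: set[str] | Sequence[str],
    trna_genes: Sequence[TrnaGene],
    pc_coords: pd.DataFrame,
    pc_up: set[str],
    windows_kb: Sequence[float] = (10.0, 50.0, 100.0),
) -> list[ColocalizationCell]:
    """Two-sample KS test of neighbor ratios, up-regulated vs non-DE tRNA
    genes, per window size. Cells where either group is empty after the
    no-neighbor exclusion are reported with NA statistics."""
    by_id = {g.gene_id: g for g in trna_genes}
    cells: list[ColocalizationCell] = []
    for w in windows_kb:
        r_up, ex_up = colocalization_ratios(sorted(trna_up), by_id, pc_coords,
                                            pc_up, w)
        r_non, ex_non = colocalization_ratios(sorted(trna_nonde), by_id,
                                              pc_coords, pc_up, w)
        n_excluded = ex_up + ex_non
        if n_excluded:
            logger.info("colocalization window %g kb: excluded %d tRNA genes "
                        "with no protein-coding neighbor", w, n_excluded)
        if len(r_up) == 0 or len(r_non) == 0:
            cells.append(ColocalizationCell(w, float("nan"), float("nan"),
                                            len(r_up), len(r_non), n_excluded))
            continue
        d, p = stats.ks_2samp(r_up.to_numpy(), r_non.to_numpy(),
                              method="asymp" if min(len(r_up), len(r_non)) > 25
                              else "auto")
        cells.append(ColocalizationCell(w, float(d), float(p),
                                        len(r_up), len(r_non), n_excluded))
    return cells


@dataclass
class ChromatinCell:
    mark: str
    distance_kb: float
    odds_ratio: float
    p_value: float
    table: tuple[tuple[int, int], tuple[int, int]]  # (set, ~set) x (mark, ~mark)


def chromatin_association(
    marks: Mapping[str, pd.DataFrame],
    trna_set_a: set[str] | Sequence[str],
    trna_set_b: set[str] | Sequence[str],
    trna_genes: Sequence[TrnaGene],
    distances_kb: Sequence[float] = (0.1, 0.5, 1.0),
) -> list[ChromatinCell]:
    """Two-sided Fisher's exact test of mark presence near two disjoint tRNA
    gene sets, per mark and flanking distance."""
    set_a, set_b = set(trna_set_a), set(trna_set_b)
    if not set_a or not set_b:
        raise ValueError("both tRNA gene sets must be non-empty")
    if set_a & set_b:
        raise ValueError("tRNA gene sets must be disjoint")
    by_id = {g.gene_id: g for g in trna_genes}
    cells: list[ChromatinCell] = []
    for mark, intervals in marks.items():
        index = _IntervalIndex(intervals)
        for d_kb in distances_kb:
            d = d_kb * 1000.0
            counts = {}
            for name, ids in (("a", set_a), ("b", set_b)):
                present = sum(
                    index.any_overlap(by_id[t].chrom, by_id[t].start - d,
                                      by_id[t].end + d)
                    for t in sorted(ids))
                counts[name] = (present, len(ids) - present)
            table = np.array([counts["a"], counts["b"]])
            odds, p = stats.fisher_exact(table, alternative="two-sided")
            cells.append(ChromatinCell(mark, d_kb, float(odds), float(p),
                                       ((int(table[0, 0]), int(table[0, 1])),
                                        (int(table[1, 0]), int(table[1, 1])))))
    return cells
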