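"""Sliding-window divergence scan and joint top-5% outlier region calling.

The scan tiles each contig with 40-kb windows advancing in 10-kb steps,
computes window F_ST and the pi ratio (wild over domestic), and calls a
window a joint outlier when it reaches the empirical top 5% of *both*
statistics.  Outlier windows are merged into divergent regions (overlap or
book-ended), genes are assigned by >= 1 bp overlap, and a top-100 gene list
is built by taking the top 50 genes by F_ST and then the top 50 by pi ratio
excluding genes already chosen.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .popgen_stats import (
    WindowStats,
    _window_from_site_arrays,
    group_site_arrays,
    site_fst_wc_arrays,
    site_pi_arrays,
    windows_dataframe,
)
from .vcf_io import ContrastMap, GeneModel, VariantTable

logger = logging.getLogger(__name__)

__all__ = [
    "ScanConfig",
    "DivergentRegion",
    "GeneRankEntry",
    "make_windows",
    "scan_windows",
    "call_outlier_windows",
    "merge_regions",
    "assign_genes",
    "rank_top_genes",
    "evaluate_recovery",
]


@dataclass(frozen=True)
class ScanConfig:
    """Scan parameters; defaults follow the published design (40 kb / 10 kb,
    top 5% of both statistics, >= 10 SNPs per retained window)."""

    window_size_bp: int = 40_000
    step_bp: int = 10_000
    outlier_quantile: float = 0.95
    min_snps: int = 10
    merge_adjacent: bool = True
    weighted_fst: bool = False

    def __post_init__(self) -> None:
        if self.step_bp > self.window_size_bp:
            raise ValueError("step must not exceed window size")
        if not 0 < self.outlier_quantile < 1:
            raise ValueError("outlier quantile must lie in (0, 1)")


@dataclass
class DivergentRegion:
    """A merged run of jointly-selected windows (1-based inclusive)."""

    contig: str
    start: int
    end: int
    n_windows: int
    peak_fst: float
    peak_pi_ratio: float
    genes: list[str] = field(default_factory=list)

    @property
    def span(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class GeneRankEntry:
    gene_name: str
    best_fst: float
    best_pi_ratio: float
    selected_by: str  # "fst" or "pi_ratio"


def make_windows(
    contig_lengths: dict[str, int], config: ScanConfig
) -> list[tuple[str, int, int]]:
    """Build the ordered scan grid of (contig, start, end) windows.

    Windows start at 1, 1+step, ...; the last window is the final
    full-length window fitting in the contig.  Contigs shorter than the
    window size yield one truncated window covering the whole contig.
    """
    windows: list[tuple[str, int, int]] = []
    w, s = config.window_size_bp, config.step_bp
    for contig, length in contig_lengths.items():
        if length <= 0:
            raise ValueError(f"contig {contig} has non-positive length {length}")
        if length < w:
            windows.append((contig, 1, length))
            continue
        n = (length - w) // s + 1
        for i in range(n):
            start = 1 + i * s
            windows.append((contig, start, start + w - 1))
    return windows


def scan_windows(
    table: VariantTable, contrast: ContrastMap, config: ScanConfig
) -> pd.DataFrame:
    """Per-window statistics over the whole scan grid (vectorised).

    Per-site tallies, theta and pi are computed once for the full table;
    each window then aggregates its slice of sites.  Returns the tabulated
    WindowStats (one row per grid window, excluded windows flagged).
    """
    n1, alt1, het1, n2, alt2, het2 = group_site_arrays(table, contrast)
    a, b, c, theta = site_fst_wc_arrays(n1, alt1, het1, n2, alt2, het2)
    pa = site_pi_arrays(n1, alt1)
    pb = site_pi_arrays(n2, alt2)

    contig_arr = table.sites["contig"].to_numpy()
    pos_arr = table.sites["pos"].to_numpy()

    stats: list[WindowStats] = []
    grid = make_windows(table.contig_lengths, config)
    for contig in dict.fromkeys(w[0] for w in grid):
        cmask = contig_arr == contig
        cidx = np.flatnonzero(cmask)
        cpos = pos_arr[cidx]
        for wc, start, end in (w for w in grid if w[0] == contig):
            lo = np.searchsorted(cpos, start, side="left")
            hi = np.searchsorted(cpos, end, side="right")
            sl = cidx[lo:hi]
            stats.append(
                _window_from_site_arrays(
                    contig, start, end,
                    theta[sl], pa[sl], pb[sl],
                    config.min_snps, config.weighted_fst,
                    (a[sl], b[sl], c[sl]),
                )
            )
    return windows_dataframe(stats)


def _top_quantile_threshold(values: np.ndarray, quantile: float) -> float:
    """Smallest value with >= quantile of the sample strictly below it.

    Windows equal to the threshold are selected (inclusive), matching a
    literal "top 5%" on the empirical distribution.  Returns +inf when no
    value qualifies (then nothing is selected).
    """
    v = np.sort(values)
    n = len(v)
    k = math.ceil(quantile * n)
    if k >= n:
        return np.inf
    return float(v[k])


def call_outlier_windows(stats: pd.DataFrame, config: ScanConfig) -> pd.DataFrame:
    """Flag windows in the empirical top 5% of both F_ST and pi ratio.

    Input rows flagged ``excluded`` (too few SNPs) or with undefined F_ST
    or an all-zero-diversity ratio are removed before thresholding.
    Windows whose domestic-side pi is 0 while the wild side is polymorphic
    carry pi_ratio = +inf and rank above every finite ratio.  Returns the
    retained windows with a boolean ``selected`` column.
    """
    retained = stats.loc[
        ~stats["excluded"].astype(bool)
        & ~stats["fst"].isna()
        & (stats["ratio_defined"].astype(bool) | np.isinf(stats["pi_ratio"]))
    ].copy()
    if len(retained) < 20:
        logger.warning(
            "only %d retained windows; top-quantile thresholds unstable", len(retained)
        )
    if retained.empty:
        retained["selected"] = pd.Series(dtype=bool)
        return retained

    fst = retained["fst"].to_numpy(dtype=float)
    ratio = retained["pi_ratio"].to_numpy(dtype=float)
    fst_thr = _top_quantile_threshold(fst, config.outlier_quantile)
    ratio_thr = _top_quantile_threshold(ratio, config.outlier_quantile)
    retained["selected"] = (fst >= fst_thr) & (ratio >= ratio_thr)
    logger.info(
        "retained %d windows; thresholds fst >= %.4g, pi_ratio >= %.4g; selected %d",
        len(retained), fst_thr, ratio_thr, int(retained["selected"].sum()),
    )
    return retained


def merge_regions(selected: pd.DataFrame) -> list[DivergentRegion]:
    """Merge overlapping or book-ended selected windows into regions.

    Peak statistics are the max over member windows; windows on different
    contigs never merge.
    """
    rows = selected.loc[selected["selected"].astype(bool)] if "selected" in selected else selected
    rows = rows.sort_values(["contig", "start", "end"])
    regions: list[DivergentRegion] = []
    cur: DivergentRegion | None = None
    for r in rows.itertuples(index=False):
        if cur is not None and r.contig == cur.contig and r.start <= cur.end + 1:
            cur.end = max(cur.end, r.end)
            cur.n_windows += 1
            cur.peak_fst = max(cur.peak_fst, r.fst)
            cur.peak_pi_ratio = max(cur.peak_pi_ratio, r.pi_ratio)
        else:
            cur = DivergentRegion(
                contig=r.contig, start=int(r.start), end=int(r.end),
                n_windows=1, peak_fst=float(r.fst), peak_pi_ratio=float(r.pi_ratio),
            )
            regions.append(cur)
    return regions


def assign_genes(
    regions: list[DivergentRegion], genes: list[GeneModel]
) -> list[DivergentRegion]:
    """Attach genes overlapping each region by >= 1 bp (in place, returned).

    A gene spanning two regions is listed in both; callers counting the
    gene universe should deduplicate across regions.
    """
    by_contig: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_contig.setdefault(g.contig, []).append(g)
    for region in regions:
        region.genes = [
            g.gene_name
            for g in by_contig.get(region.contig, [])
            if g.start <= region.end and g.end >= region.start
        ]
    return regions


def _gene_best_stats(
    selected: pd.DataFrame, genes: list[GeneModel]
) -> pd.DataFrame:
    """Best (max) window fst and pi_ratio per gene over selected windows."""
    rows = selected.loc[selected["selected"].astype(bool)]
    records = []
    for g in genes:
        sub = rows.loc[
            (rows["contig"] == g.contig)
            & (rows["start"] <= g.end)
            & (rows["end"] >= g.start)
        ]
        if sub.empty:
            continue
        records.append(
            {
                "gene_name": g.gene_name,
                "contig": g.contig,
                "start": g.start,
                "best_fst": float(sub["fst"].max()),
                "best_pi_ratio": float(sub["pi_ratio"].max()),
            }
        )
    return pd.DataFrame(records)


def rank_top_genes(
    selected: pd.DataFrame,
    genes: list[GeneModel],
    n_fst: int = 50,
    n_pi: int = 50,
) -> list[GeneRankEntry]:
    """Top-100 gene rule: top ``n_fst`` genes by best window F_ST, then the
    top ``n_pi`` genes by best pi ratio excluding those already chosen.

    Each gene's "best" statistics are taken over the selected windows that
    overlap it.  Ties break by genomic order (contig, start).  If fewer
    genes exist than requested the shortfall is logged and all are returned.
    """
    best = _gene_best_stats(selected, genes)
    if best.empty:
        return []
    best = best.sort_values(
        ["best_fst", "contig", "start"], ascending=[False, True, True]
    )
    fst_pick = best.head(n_fst)
    entries = [
        GeneRankEntry(r.gene_name, r.best_fst, r.best_pi_ratio, "fst")
        for r in fst_pick.itertuples(index=False)
    ]
    chosen = set(fst_pick["gene_name"])
    rest = best.loc[~best["gene_name"].isin(chosen)].sort_values(
        ["best_pi_ratio", "contig", "start"], ascending=[False, True, True]
    )
    entries.extend(
        GeneRankEntry(r.gene_name, r.best_fst, r.best_pi_ratio, "pi_ratio")
        for r in rest.head(n_pi).itertuples(index=False)
    )
    if len(entries) < n_fst + n_pi:
        logger.info(
            "gene ranking shortfall: %d genes available of %d requested",
            len(entries), n_fst + n_pi,
        )
    return entries


def gene_rank_dataframe(entries: list[GeneRankEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_name": [e.gene_name for e in entries],
            "best_fst": [e.best_fst for e in entries],
            "best_pi_ratio": [e.best_pi_ratio for e in entries],
            "selected_by": [e.selected_by for e in entries],
        }
    )


def _overlap_bp(
    a: tuple[str, int, int], b: tuple[str, int, int]
) -> int:
    if a[0] != b[0]:
        return 0
    return max(0, min(a[2], b[2]) - max(a[1], b[1]) + 1)


def evaluate_recovery(
    regions: list[DivergentRegion],
    truth_intervals: list[tuple[str, int, int]],
) -> tuple[float, float]:
    """Window-level (recall, precision) of called regions against truth.

    A truth sweep counts as recovered when >= 50% of its span lies inside
    called regions; precision is the fraction of called bp overlapping any
    truth interval.  Recall is NaN for empty truth; precision is NaN when
    nothing was called.
    """
    called = [(r.contig, r.start, r.end) for r in regions]
    if truth_intervals:
        recovered = 0
        for t in truth_intervals:
            span = t[2] - t[1] + 1
            cov = sum(_overlap_bp(t, c) for c in called)
            if cov >= 0.5 * span:
                recovered += 1
        recall = recovered / len(truth_intervals)
    else:
        recall = float("nan")
    if called:
        total = sum(c[2] - c[1] + 1 for c in called)
        hit = sum(
            sum(_overlap_bp(t, c) for t in truth_intervals) for c in called
        )
        precision = hit / total
    else:
        precision = float("nan")
    return recall, precision
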