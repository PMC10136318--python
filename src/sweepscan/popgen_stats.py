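"""Per-site and per-window population-genetic statistics.

Implements the two statistics the divergence scan ranks windows by:

* **Weir & Cockerham (1984) F_ST** for two populations, per site, from the
  variance components a (between populations), b (between individuals
  within populations) and c (within individuals):  theta = a/(a+b+c).
  The window value is the arithmetic mean of defined per-site estimates
  ("average F_ST ... for the SNPs in each window"); a ratio-of-sums
  ("weighted") variant is available as a switch.

* **Nucleotide diversity pi** per site, the unbiased expected
  heterozygosity 2p(1-p) * 2n/(2n-1), equal to the mean pairwise allele
  difference at the site; window pi is the sum of per-site pi divided by
  the window span in bp, and the pi ratio is pi_a / pi_b (wild over
  domestic) from window-level values.

All functions take unphased dosages with ``MISSING`` (-1) excluded per
site per group; negative per-site theta values are retained in the window
mean and only the final reported window F_ST is clamped at 0.

A genotype PCA is included purely as a sanity check that simulated
populations separate; it is not part of the scan statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .vcf_io import MISSING, ContrastMap, VariantTable

__all__ = [
    "SiteCounts",
    "WindowStats",
    "site_counts",
    "site_fst_wc",
    "site_pi",
    "window_stats",
    "group_site_arrays",
    "site_fst_wc_arrays",
    "site_pi_arrays",
    "pca_genotypes",
]


@dataclass(frozen=True)
class SiteCounts:
    """Per-group genotype tallies at one site (diploid counts)."""

    n_a: int
    alt_a: int
    het_a: int
    n_b: int
    alt_b: int
    het_b: int

    def __post_init__(self) -> None:
        for n, alt, het in ((self.n_a, self.alt_a, self.het_a),
                            (self.n_b, self.alt_b, self.het_b)):
            if not (0 <= alt <= 2 * n and 0 <= het <= n):
                raise ValueError(f"inconsistent counts: n={n}, alt={alt}, het={het}")


@dataclass
class WindowStats:
    """Statistics for one scan window (coordinates 1-based inclusive)."""

    contig: str
    start: int
    end: int
    n_snps: int
    fst: float          # mean per-site theta, clamped at 0; NaN if undefined
    pi_a: float         # per-bp diversity, group a (wild/broody side)
    pi_b: float         # per-bp diversity, group b (domestic side)
    pi_ratio: float     # pi_a / pi_b; +inf when pi_b == 0 < pi_a
    ratio_defined: bool
    excluded: bool      # True when n_snps < min_snps (window leaves the scan)

    @property
    def span(self) -> int:
        return self.end - self.start + 1


def group_site_arrays(
    table: VariantTable, contrast: ContrastMap
) -> tuple[np.ndarray, ...]:
    """Vectorised per-site tallies (n, alt, het) for each contrast group.

    Returns six arrays of length n_sites: n_a, alt_a, het_a, n_b, alt_b,
    het_b, with MISSING dosages excluded from every tally.
    """
    out = []
    for names in (contrast.samples_a, contrast.samples_b):
        idx = table.sample_index(names)
        d = table.dosage[idx, :]
        called = d != MISSING
        n = called.sum(axis=0)
        alt = np.where(called, d, 0).sum(axis=0)
        het = (d == 1).sum(axis=0)
        out.extend([n.astype(np.int64), alt.astype(np.int64), het.astype(np.int64)])
    return tuple(out)


def site_counts(
    table: VariantTable, contrast: ContrastMap, site_index: int
) -> SiteCounts:
    """Genotype tallies for both contrast groups at one site."""
    arrays = group_site_arrays(table, contrast)
    j = site_index
    return SiteCounts(
        n_a=int(arrays[0][j]), alt_a=int(arrays[1][j]), het_a=int(arrays[2][j]),
        n_b=int(arrays[3][j]), alt_b=int(arrays[4][j]), het_b=int(arrays[5][j]),
    )


def site_fst_wc_arrays(
    n1: np.ndarray, alt1: np.ndarray, het1: np.ndarray,
    n2: np.ndarray, alt2: np.ndarray, het2: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Weir-Cockerham variance components (a, b, c) and theta, vectorised.

    r = 2 populations of n1, n2 called diploids with alt-allele frequencies
    p_i and observed heterozygote frequencies h_i.  theta = a/(a+b+c) is NaN
    where a site is monomorphic overall (a+b+c = 0) or either group has
    fewer than 2 called diploids.
    """
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = np.asarray(alt1, dtype=float) / (2 * n1)
        p2 = np.asarray(alt2, dtype=float) / (2 * n2)
        h1 = np.asarray(het1, dtype=float) / n1
        h2 = np.asarray(het2, dtype=float) / n2

        r = 2.0
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)

        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
        )
        c = hbar / 2
        denom = a + b + c
        theta = np.where(denom != 0, a / denom, np.nan)

    bad = (n1 < 2) | (n2 < 2)
    for arr in (a, b, c, theta):
        arr[bad] = np.nan
    return a, b, c, theta


def site_fst_wc(counts: SiteCounts) -> tuple[float, float, float, float]:
    """Per-site Weir-Cockerham components ``(a, b, c, theta)``.

    Requires >= 2 called diploids in each group; theta is NaN when the site
    is monomorphic overall (zero total variance).
    """
    a, b, c, theta = site_fst_wc_arrays(
        np.array([counts.n_a]), np.array([counts.alt_a]), np.array([counts.het_a]),
        np.array([counts.n_b]), np.array([counts.alt_b]), np.array([counts.het_b]),
    )
    return float(a[0]), float(b[0]), float(c[0]), float(theta[0])


def site_pi_arrays(n: np.ndarray, alt: np.ndarray) -> np.ndarray:
    """Unbiased per-site pi for one group: 2p(1-p) * 2n/(2n-1).

    Equals the mean pairwise difference over all C(2n, 2) pairs of sampled
    alleles.  NaN where fewer than 2 called diploids.
    """
    n = np.asarray(n, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        an = 2 * n
        p = np.asarray(alt, dtype=float) / an
        pi = 2 * p * (1 - p) * an / (an - 1)
    pi = np.where(n >= 2, pi, np.nan)
    return pi


def site_pi(n_called: int, alt_count: int) -> float:
    """Per-site nucleotide diversity for one group (see site_pi_arrays)."""
    return float(site_pi_arrays(np.array([n_called]), np.array([alt_count]))[0])


def _window_from_site_arrays(
    contig: str,
    start: int,
    end: int,
    theta: np.ndarray,
    pi_a: np.ndarray,
    pi_b: np.ndarray,
    min_snps: int,
    weighted: bool = False,
    abc: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
) -> WindowStats:
    span = end - start + 1
    n_snps = len(theta)
    if weighted and abc is not None:
        a, b, c = abc
        ok = ~np.isnan(a)
        denom = np.nansum(a[ok] + b[ok] + c[ok])
        fst_raw = float(np.nansum(a[ok]) / denom) if ok.any() and denom != 0 else np.nan
    else:
        defined = ~np.isnan(theta)
        fst_raw = float(np.mean(theta[defined])) if defined.any() else np.nan
    fst = max(fst_raw, 0.0) if not np.isnan(fst_raw) else np.nan

    wa = float(np.nansum(pi_a)) / span
    wb = float(np.nansum(pi_b)) / span
    if wb > 0:
        ratio, defined_r = wa / wb, True
    elif wa > 0:
        ratio, defined_r = np.inf, False  # maximal evidence: ranked above finites
    else:
        ratio, defined_r = np.nan, False

    return WindowStats(
        contig=contig, start=start, end=end, n_snps=n_snps,
        fst=fst, pi_a=wa, pi_b=wb, pi_ratio=ratio, ratio_defined=defined_r,
        excluded=n_snps < min_snps,
    )


def window_stats(
    table: VariantTable,
    contrast: ContrastMap,
    window: tuple[str, int, int],
    min_snps: int = 10,
    weighted: bool = False,
) -> WindowStats:
    """Compute :class:`WindowStats` for one window of the scan grid."""
    contig, start, end = window
    idx = table.site_slice(contig, start, end)
    n1, alt1, het1, n2, alt2, het2 = (
        arr[idx] for arr in group_site_arrays(table, contrast)
    )
    a, b, c, theta = site_fst_wc_arrays(n1, alt1, het1, n2, alt2, het2)
    pa = site_pi_arrays(n1, alt1)
    pb = site_pi_arrays(n2, alt2)
    return _window_from_site_arrays(
        contig, start, end, theta, pa, pb, min_snps, weighted, (a, b, c)
    )


def windows_dataframe(stats: list[WindowStats]) -> pd.DataFrame:
    """Tabulate a list of WindowStats (one row per window)."""
    return pd.DataFrame(
        {
            "contig": [w.contig for w in stats],
            "start": [w.start for w in stats],
            "end": [w.end for w in stats],
            "n_snps": [w.n_snps for w in stats],
            "fst": [w.fst for w in stats],
            "pi_a": [w.pi_a for w in stats],
            "pi_b": [w.pi_b for w in stats],
            "pi_ratio": [w.pi_ratio for w in stats],
            "ratio_defined": [w.ratio_defined for w in stats],
            "excluded": [w.excluded for w in stats],
        }
    )


def pca_genotypes(table: VariantTable, n_components: int = 2) -> np.ndarray:
    """Sample scores from a PCA of the standardized dosage matrix.

    Monomorphic sites are dropped; missing dosages are imputed with the
    site mean; each site is centred and scaled by sqrt(p(1-p)) before the
    SVD.  Scores are deterministic up to sign.  Intended only as a sanity
    check that simulated populations separate along PC1.
    """
    if table.n_samples < 2 or table.n_sites < 2:
        raise ValueError("PCA needs at least 2 samples and 2 sites")
    d = table.dosage.astype(float)
    d[d == MISSING] = np.nan
    mean = np.nanmean(d, axis=0)
    inds = np.where(np.isnan(d))
    d[inds] = np.take(mean, inds[1])
    p = mean / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("all sites monomorphic; PCA undefined")
    x = (d[:, poly] - mean[poly]) / np.sqrt(p[poly] * (1 - p[poly]))
    x -= x.mean(axis=0)
    if not np.any(x):
        raise ValueError("degenerate (constant) genotype matrix")
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    k = min(n_components, len(s))
    return u[:, :k] * s[:k]
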