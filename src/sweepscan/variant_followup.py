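"""Candidate-variant interrogation inside selected regions.

Four stages, run in the order a validation study would:

1. **Allele-frequency differentiation** — two-sided Fisher exact test on the
   2x2 allele-count table (group x allele) per site, with Benjamini-Hochberg
   adjusted p-values reported alongside the raw ones.
2. **Genotype differentiation** — a site is flagged when each group's modal
   genotype reaches a frequency threshold (default 0.8) and the two modal
   genotypes differ (the fixed-difference pattern).
3. **Phenotype segregation** — individuals are scored yes/no for carrying
   the genotype expected under their phenotype class, tallied per
   population and in total (the validation-cohort table logic).
4. **LD grouping** — composite (genotype-correlation) r-squared between
   dosage vectors over pairwise-complete individuals, with complete-LD
   groups = maximal sets whose pairwise r-squared is 1 within 1e-9.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .vcf_io import MISSING, ContrastMap, VariantTable

logger = logging.getLogger(__name__)

__all__ = [
    "SiteTestResult",
    "SegregationTable",
    "LDResult",
    "allele_freq_test",
    "genotype_differentiation",
    "segregation_score",
    "ld_r2",
]

COMPLETE_LD_TOL = 1e-9


@dataclass(frozen=True)
class SiteTestResult:
    """Fisher exact result for one site's group x allele 2x2 table."""

    contig: str
    pos: int
    ref_a: int
    alt_a: int
    ref_b: int
    alt_b: int
    p_value: float
    bh_adjusted_p: float
    significant: bool


@dataclass
class SegregationTable:
    """Per-population yes/no concordance tallies for one candidate SNP.

    ``populations`` maps population label -> (n, yes, no); totals are the
    column sums.  "Yes" means the individual's genotype lies in the set
    expected for its phenotype class.
    """

    populations: dict[str, tuple[int, int, int]] = field(default_factory=dict)

    @property
    def total(self) -> tuple[int, int, int]:
        n = sum(v[0] for v in self.populations.values())
        yes = sum(v[1] for v in self.populations.values())
        no = sum(v[2] for v in self.populations.values())
        return n, yes, no

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"population": pop, "n": n, "yes": y, "no": no}
            for pop, (n, y, no) in self.populations.items()
        ]
        n, y, no = self.total
        rows.append({"population": "Total", "n": n, "yes": y, "no": no})
        return pd.DataFrame(rows)


@dataclass
class LDResult:
    """Pairwise r-squared matrix over candidate sites plus complete-LD groups."""

    sites: list[tuple[str, int]]
    r2: np.ndarray  # symmetric, diagonal 1, NaN for zero-variance sites
    groups: list[list[int]]  # indices into `sites`, only groups of size >= 2


def allele_freq_test(
    table: VariantTable,
    contrast: ContrastMap,
    site_indices: list[int] | np.ndarray,
    alpha: float = 0.05,
) -> list[SiteTestResult]:
    """Two-sided Fisher exact test of allele counts between contrast groups.

    The 2x2 table is (group a, group b) x (ref alleles, alt alleles) from
    called diploids only.  ``significant`` flags raw p < alpha; the
    BH-adjusted p over the tested sites is reported alongside so users can
    apply a stricter multiple-testing convention.  A site monomorphic for
    the same allele in both groups has p = 1.
    """
    from .popgen_stats import group_site_arrays

    site_indices = np.asarray(site_indices, dtype=np.intp)
    n1, alt1, _, n2, alt2, _ = group_site_arrays(table, contrast)
    results = []
    pvals = []
    for j in site_indices:
        ra = int(2 * n1[j] - alt1[j])
        aa = int(alt1[j])
        rb = int(2 * n2[j] - alt2[j])
        ab = int(alt2[j])
        _, p = fisher_exact([[ra, aa], [rb, ab]], alternative="two-sided")
        pvals.append(float(p))
        results.append((j, ra, aa, rb, ab))
    if not results:
        return []
    bh = multipletests(pvals, method="fdr_bh")[1]
    contig_arr = table.sites["contig"].to_numpy()
    pos_arr = table.sites["pos"].to_numpy()
    return [
        SiteTestResult(
            contig=str(contig_arr[j]), pos=int(pos_arr[j]),
            ref_a=ra, alt_a=aa, ref_b=rb, alt_b=ab,
            p_value=p, bh_adjusted_p=float(q), significant=p < alpha,
        )
        for (j, ra, aa, rb, ab), p, q in zip(results, pvals, bh)
    ]


def genotype_differentiation(
    table: VariantTable,
    contrast: ContrastMap,
    site_indices: list[int] | np.ndarray,
    fix_threshold: float = 0.8,
) -> list[bool]:
    """Flag sites where the groups are (near-)fixed for different genotypes.

    A site is flagged iff in each group the modal genotype (dosage 0/1/2
    over called individuals) has frequency >= ``fix_threshold`` and the two
    modal genotypes differ.
    """
    site_indices = np.asarray(site_indices, dtype=np.intp)
    idx_a = table.sample_index(contrast.samples_a)
    idx_b = table.sample_index(contrast.samples_b)
    flags = []
    for j in site_indices:
        modal = []
        for idx in (idx_a, idx_b):
            d = table.dosage[idx, j]
            d = d[d != MISSING]
            if len(d) == 0:
                modal.append(None)
                break
            counts = np.bincount(d, minlength=3)
            g = int(np.argmax(counts))
            modal.append(g if counts[g] / len(d) >= fix_threshold else None)
        flags.append(
            len(modal) == 2
            and modal[0] is not None
            and modal[1] is not None
            and modal[0] != modal[1]
        )
    return flags


def segregation_score(
    genotypes: dict[str, int],
    phenotypes: dict[str, str],
    populations: dict[str, str],
    expected_rule: dict[str, set[int]],
) -> SegregationTable:
    """Score genotype-phenotype concordance per individual, tallied by population.

    Parameters
    ----------
    genotypes : sample -> dosage (0/1/2; MISSING excluded)
    phenotypes : sample -> phenotype class (e.g. "case"/"control"); samples
        with a class absent from ``expected_rule`` (e.g. "unknown") are
        excluded and logged.
    populations : sample -> population label for the per-population rows.
    expected_rule : phenotype class -> set of dosages consistent with it
        (typically the modal genotypes of the discovery populations).
    """
    tallies: dict[str, list[int]] = {}
    n_excluded = 0
    for sample, g in genotypes.items():
        cls = phenotypes.get(sample, "unknown")
        if cls not in expected_rule or g == MISSING:
            n_excluded += 1
            continue
        pop = populations.get(sample, "?")
        t = tallies.setdefault(pop, [0, 0, 0])
        t[0] += 1
        if g in expected_rule[cls]:
            t[1] += 1
        else:
            t[2] += 1
    if n_excluded:
        logger.info("segregation: excluded %d individuals (unknown phenotype/genotype)",
                    n_excluded)
    return SegregationTable(
        populations={pop: tuple(t) for pop, t in tallies.items()}
    )


def ld_r2(
    table: VariantTable,
    site_indices: list[int] | np.ndarray,
    tol: float = COMPLETE_LD_TOL,
) -> LDResult:
    """Composite LD: squared Pearson correlation of dosages between sites.

    r-squared is computed over pairwise-complete individuals (both sites
    called); this genotype-correlation definition needs no phasing and is
    invariant under allele-label flips.  Zero-variance sites yield NaN
    against every partner and are excluded from grouping.  Complete-LD
    groups are built greedily in site order: a site joins the first group
    with which *all* pairwise r-squared >= 1 - tol.
    """
    site_indices = np.asarray(site_indices, dtype=np.intp)
    m = len(site_indices)
    if m < 2:
        raise ValueError("LD needs at least 2 sites")
    d = table.dosage[:, site_indices].astype(float)
    d[d == MISSING] = np.nan
    r2 = np.full((m, m), np.nan)
    for i in range(m):
        r2[i, i] = 1.0
        for j in range(i + 1, m):
            ok = ~np.isnan(d[:, i]) & ~np.isnan(d[:, j])
            if ok.sum() < 2:
                continue
            x, y = d[ok, i], d[ok, j]
            if x.std() == 0 or y.std() == 0:
                continue
            r = np.corrcoef(x, y)[0, 1]
            r2[i, j] = r2[j, i] = min(r * r, 1.0)

    groups: list[list[int]] = []
    for i in range(m):
        if np.isnan(r2[i]).sum() > 1:  # zero-variance vs some partner
            col = r2[i]
            if np.isnan(col[np.arange(m) != i]).all():
                continue
        placed = False
        for grp in groups:
            if all(not np.isnan(r2[i, k]) and r2[i, k] >= 1 - tol for k in grp):
                grp.append(i)
                placed = True
                break
        if not placed:
            groups.append([i])
    contig_arr = table.sites["contig"].to_numpy()
    pos_arr = table.sites["pos"].to_numpy()
    sites = [(str(contig_arr[j]), int(pos_arr[j])) for j in site_indices]
    return LDResult(sites=sites, r2=r2, groups=[g for g in groups if len(g) >= 2])
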