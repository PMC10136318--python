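"""Reading and writing the standard formats the scan pipeline touches.

The central in-memory container is :class:`VariantTable`: an ordered table of
biallelic SNP sites together with an individuals x sites allele-dosage matrix
(0/1/2 alternate-allele copies, ``MISSING`` = -1 for uncalled genotypes).
Phase is discarded on input; every downstream statistic is defined on
unphased dosages.

Coordinates are 1-based inclusive in memory (the VCF convention); BED files
on disk are 0-based half-open (the BED convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for an uncalled genotype in the dosage matrix.
MISSING: int = -1

_BASES = frozenset("ACGT")


@dataclass
class VariantTable:
    """Biallelic SNP sites with an individuals x sites dosage matrix.

    Attributes
    ----------
    contigs : list of str
        Contig identifiers in input order.
    contig_lengths : dict
        Contig id -> length in bp.
    sites : pandas.DataFrame
        Columns ``contig, pos, ref, alt`` (``pos`` 1-based), one row per
        retained site, positions strictly increasing within each contig.
    samples : list of str
        Sample identifiers, ordering the dosage rows.
    dosage : numpy.ndarray
        ``(n_samples, n_sites)`` int8 matrix of alt-allele counts in
        {0, 1, 2, MISSING}.
    """

    contigs: list[str]
    contig_lengths: dict[str, int]
    sites: pd.DataFrame
    samples: list[str]
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.samples), len(self.sites)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} != "
                f"({len(self.samples)}, {len(self.sites)})"
            )
        valid = np.isin(self.dosage, (0, 1, 2, MISSING))
        if not valid.all():
            raise ValueError("dosage entries must be in {0, 1, 2, MISSING}")
        for contig, sub in self.sites.groupby("contig", sort=False):
            pos = sub["pos"].to_numpy()
            if not (np.diff(pos) > 0).all():
                raise ValueError(f"positions not strictly increasing on {contig}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def sample_index(self, names: Iterable[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[n] for n in names], dtype=np.intp)
        except KeyError as exc:  # pragma: no cover - defensive
            raise KeyError(f"unknown sample {exc.args[0]!r}") from exc

    def site_slice(self, contig: str, start: int, end: int) -> np.ndarray:
        """Column indices of sites on ``contig`` with start <= pos <= end."""
        mask = self.sites["contig"].to_numpy() == contig
        idx = np.flatnonzero(mask)
        pos = self.sites["pos"].to_numpy()[idx]
        lo = np.searchsorted(pos, start, side="left")
        hi = np.searchsorted(pos, end, side="right")
        return idx[lo:hi]

    def subset_sites(self, indices: Sequence[int]) -> "VariantTable":
        indices = np.asarray(indices, dtype=np.intp)
        return VariantTable(
            contigs=self.contigs,
            contig_lengths=self.contig_lengths,
            sites=self.sites.iloc[indices].reset_index(drop=True),
            samples=list(self.samples),
            dosage=self.dosage[:, indices].copy(),
        )


@dataclass
class ContrastMap:
    """Sample -> population assignment plus the two contrast groups.

    ``group_a`` holds the population labels of the reference side of the
    contrast (wild, or broody) and ``group_b`` the other side (domestic, or
    non-broody).  ``phenotype`` optionally maps samples to a binary class
    (``case``/``control``/``unknown``) for the segregation stage.
    """

    populations: dict[str, str]
    group_a: frozenset[str]
    group_b: frozenset[str]
    phenotype: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.group_a = frozenset(self.group_a)
        self.group_b = frozenset(self.group_b)
        if not self.group_a or not self.group_b:
            raise ValueError("both contrast groups must be non-empty")
        if self.group_a & self.group_b:
            raise ValueError(
                f"contrast groups overlap: {sorted(self.group_a & self.group_b)}"
            )

    def samples_in(self, labels: frozenset[str]) -> list[str]:
        return [s for s, p in self.populations.items() if p in labels]

    @property
    def samples_a(self) -> list[str]:
        return self.samples_in(self.group_a)

    @property
    def samples_b(self) -> list[str]:
        return self.samples_in(self.group_b)


@dataclass(frozen=True)
class GeneModel:
    """A gene interval (1-based inclusive) used for candidate assignment."""

    gene_name: str
    contig: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_name}: start {self.start} > end {self.end}")


def read_vcf(
    path: str | Path,
    contrast: ContrastMap | None = None,
    min_call_rate_per_group: float = 0.5,
) -> VariantTable:
    """Load a VCF into a :class:`VariantTable` of biallelic SNPs.

    Multiallelic and non-SNP records are skipped (counts logged).  When a
    ``contrast`` is given, sites whose genotype call rate falls below
    ``min_call_rate_per_group`` in *either* contrast group are dropped;
    without a contrast the threshold applies to all samples jointly.

    Raises
    ------
    ValueError
        If a record lacks GT fields, or a contrast sample is absent from
        the VCF.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    if contrast is not None:
        unknown = [s for s in contrast.populations if s not in samples]
        if unknown:
            raise ValueError(f"popmap samples missing from VCF: {unknown}")

    contig_lengths: dict[str, int] = {}
    for line in vcf.raw_header.splitlines():
        if line.startswith("##contig="):
            inner = line.split("<", 1)[1].rstrip(">")
            fields = dict(kv.split("=", 1) for kv in inner.split(","))
            if "ID" in fields and "length" in fields:
                contig_lengths[fields["ID"]] = int(fields["length"])

    rows: list[tuple[str, int, str, str]] = []
    dosage_cols: list[np.ndarray] = []
    n_skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            n_skipped += 1
            continue
        if rec.REF not in _BASES or rec.ALT[0] not in _BASES:
            n_skipped += 1
            continue
        gts = rec.gt_types  # gts012: 0/1/2 dosage, 3 = unknown
        if gts is None or len(gts) != len(samples):
            raise ValueError(f"record {rec.CHROM}:{rec.POS} lacks GT fields")
        col = np.asarray(gts, dtype=np.int8)
        col[col == 3] = MISSING
        rows.append((rec.CHROM, rec.POS, rec.REF, rec.ALT[0]))
        dosage_cols.append(col)
    if n_skipped:
        logger.info("skipped %d multiallelic/non-SNP records", n_skipped)

    sites = pd.DataFrame(rows, columns=["contig", "pos", "ref", "alt"])
    dosage = (
        np.stack(dosage_cols, axis=1)
        if dosage_cols
        else np.empty((len(samples), 0), dtype=np.int8)
    )

    keep = _call_rate_mask(dosage, samples, contrast, min_call_rate_per_group)
    if not keep.all():
        logger.info("dropped %d sites below call-rate threshold", (~keep).sum())
        sites = sites[keep].reset_index(drop=True)
        dosage = dosage[:, keep]

    contigs = list(dict.fromkeys(sites["contig"]))
    for c in contigs:
        contig_lengths.setdefault(c, int(sites.loc[sites["contig"] == c, "pos"].max()))
    return VariantTable(
        contigs=contigs,
        contig_lengths=contig_lengths,
        sites=sites,
        samples=samples,
        dosage=dosage,
    )


def _call_rate_mask(
    dosage: np.ndarray,
    samples: list[str],
    contrast: ContrastMap | None,
    min_rate: float,
) -> np.ndarray:
    called = dosage != MISSING
    if contrast is None:
        groups = [np.arange(len(samples), dtype=np.intp)]
    else:
        lookup = {s: i for i, s in enumerate(samples)}
        groups = [
            np.array([lookup[s] for s in contrast.samples_a], dtype=np.intp),
            np.array([lookup[s] for s in contrast.samples_b], dtype=np.intp),
        ]
    keep = np.ones(dosage.shape[1], dtype=bool)
    for idx in groups:
        if len(idx) == 0:
            continue
        keep &= called[idx].mean(axis=0) >= min_rate
    return keep


def write_vcf(table: VariantTable, path: str | Path, header_comments: Sequence[str] = ()) -> None:
    """Write a :class:`VariantTable` back to a minimal VCF 4.2 text file.

    Dosage 1 is emitted as the unphased heterozygote ``0/1``; MISSING as
    ``./.``.  Round-tripping through :func:`read_vcf` preserves contig,
    position, alleles and dosage for every site.
    """
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for comment in header_comments:
            fh.write(f"##{comment}\n")
        for contig in table.contigs:
            fh.write(f"##contig=<ID={contig},length={table.contig_lengths[contig]}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(table.samples)
            + "\n"
        )
        contig_arr = table.sites["contig"].to_numpy()
        pos_arr = table.sites["pos"].to_numpy()
        ref_arr = table.sites["ref"].to_numpy()
        alt_arr = table.sites["alt"].to_numpy()
        for j in range(table.n_sites):
            gts = "\t".join(gt_map[int(d)] for d in table.dosage[:, j])
            fh.write(
                f"{contig_arr[j]}\t{pos_arr[j]}\t.\t{ref_arr[j]}\t{alt_arr[j]}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_popmap(
    path: str | Path,
    group_a: Iterable[str],
    group_b: Iterable[str],
    phenotype_path: str | Path | None = None,
) -> ContrastMap:
    """Read a two-column (sample, population) TSV and declare the contrast.

    ``group_a``/``group_b`` are population labels, e.g. the wild populations
    versus the domestic breeds.  An optional phenotype TSV (sample, class)
    attaches a binary phenotype for the segregation stage.
    """
    populations: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'sample<TAB>population'")
            sample, pop = parts[0], parts[1]
            if sample in populations:
                raise ValueError(f"duplicate sample {sample!r} in popmap")
            populations[sample] = pop
    phenotype: dict[str, str] = {}
    if phenotype_path is not None:
        phenotype = read_phenotype(phenotype_path)
    cmap = ContrastMap(
        populations=populations,
        group_a=frozenset(group_a),
        group_b=frozenset(group_b),
        phenotype=phenotype,
    )
    if not cmap.samples_a:
        raise ValueError(f"no samples belong to group_a {sorted(cmap.group_a)}")
    if not cmap.samples_b:
        raise ValueError(f"no samples belong to group_b {sorted(cmap.group_b)}")
    return cmap


def read_phenotype(path: str | Path) -> dict[str, str]:
    """Read a (sample, class) TSV; classes are case/control/unknown."""
    phenotype: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            phenotype[parts[0]] = parts[1]
    return phenotype


def read_genes_bed(path: str | Path) -> list[GeneModel]:
    """Read a BED4(+) gene annotation into sorted 1-based GeneModels."""
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: need >= 4 BED columns")
            contig, start0, end0, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
            if start0 >= end0:
                raise ValueError(f"{path}:{lineno}: BED start {start0} >= end {end0}")
            strand = parts[5] if len(parts) > 5 and parts[5] in "+-" else "."
            genes.append(GeneModel(name, contig, start0 + 1, end0, strand))
    genes.sort(key=lambda g: (g.contig, g.start, g.end))
    return genes


def write_genes_bed(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.contig}\t{g.start - 1}\t{g.end}\t{g.gene_name}\t.\t{g.strand}\n")


_WINDOW_COLUMNS = [
    "contig", "start", "end", "n_snps", "fst", "pi_a", "pi_b", "pi_ratio", "selected",
]


def write_window_stats(stats: pd.DataFrame, path: str | Path) -> None:
    """Write the per-window statistics table as TSV (1-based coordinates).

    Floats are printed with 6 significant digits; a round trip through
    :func:`read_window_stats` reproduces values to that precision.
    """
    out = stats.loc[:, [c for c in _WINDOW_COLUMNS if c in stats.columns]]
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_window_stats(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_regions_bed(regions: Sequence, path: str | Path) -> None:
    """Write divergent regions as BED (0-based half-open) with peak stats.

    Columns: contig, start, end, name, n_windows, peak_fst, peak_pi_ratio,
    genes (comma-joined).  Header line included for self-description.
    """
    with open(path, "w") as fh:
        fh.write("#contig\tstart\tend\tname\tn_windows\tpeak_fst\tpeak_pi_ratio\tgenes\n")
        for i, r in enumerate(regions, 1):
            genes = ",".join(r.genes) if r.genes else "."
            ratio = "inf" if np.isinf(r.peak_pi_ratio) else f"{r.peak_pi_ratio:.6g}"
            fh.write(
                f"{r.contig}\t{r.start - 1}\t{r.end}\tregion_{i}\t{r.n_windows}"
                f"\t{r.peak_fst:.6g}\t{ratio}\t{genes}\n"
            )


def annotation_fractions(class_counts: Mapping[str, int], total: int) -> dict[str, float]:
    """Percent of all SNPs in each functional class (bookkeeping helper).

    E.g. ``annotation_fractions({"nonsynonymous": 68279}, 2505100)`` gives
    ``{"nonsynonymous": 2.73}``-ish (exact value, unrounded).
    """
    if total <= 0:
        raise ValueError("total must be positive")
    return {k: 100.0 * v / total for k, v in class_counts.items()}
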