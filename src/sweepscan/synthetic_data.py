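"""Two-population genotype simulator with implanted sweeps and causal SNPs.

The generator emulates the statistical structure a domestication-scan
expects from resequencing data, without coalescent machinery:

* SNP positions are uniform at a configurable density (default 2.2 SNPs/kb,
  the density observed in the goose resequencing panel this design mirrors).
* Each site draws an ancestral frequency p0 from Beta(0.8, 0.8) truncated
  to [0.05, 0.95] (so every site is polymorphic somewhere), then per-group
  frequencies under the Balding-Nichols model:
  p_g ~ Beta(p0(1-F)/F, (1-p0)(1-F)/F) with F = ``background_fst``.  This
  gives direct analytic control of the expected genome-wide F_ST.
* Genotypes are binomial(2, p_g) per diploid (Hardy-Weinberg within group).
* Inside sweep intervals the "domestic" group's major-allele frequency is
  pushed to at least ``sweep_freq_shift`` and far enough that the expected
  per-site diversity drops by ``sweep_pi_reduction``-fold relative to the
  neutral expectation 2*p0*(1-p0)*(1-F) — a hard-sweep caricature: strong
  differentiation plus lost diversity on one side.
* Optional causal phenotype SNPs inside the first sweep interval segregate
  deterministically with a binary phenotype (cases carry the domestic
  homozygote); extra causal SNPs are exact dosage copies of the first, so
  they sit in complete LD with it (r-squared 1), mimicking linked
  candidate pairs.

Linkage elsewhere is absent by construction: neutral sites are independent
draws, which is sufficient for window statistics but understates the
spatial autocorrelation of real genomes (see the methods note).

One :class:`numpy.random.Generator` seeded from ``SimConfig.seed`` governs
every draw; the same config yields byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .vcf_io import (
    MISSING,
    ContrastMap,
    GeneModel,
    VariantTable,
    write_genes_bed,
    write_vcf,
)

__all__ = ["SimConfig", "SimTruth", "SimResult", "simulate_two_pop",
           "implant_causal_snp", "write_sim_outputs"]


@dataclass
class SimConfig:
    """Simulation parameters; defaults match the study design being emulated
    (two populations of 20 diploids at background F_ST 0.1, 2.2 SNPs/kb,
    window-sized hard sweeps with >= 10x diversity loss in the domestic
    group)."""

    seed: int = 0
    n_contigs: int = 5
    contig_length_bp: int = 2_000_000
    snp_density_per_kb: float = 2.2
    n_diploids_a: int = 20
    n_diploids_b: int = 20
    background_fst: float = 0.1
    sweep_intervals: list[tuple[str, int, int]] | None = None
    n_sweeps: int = 20                  # auto-placed when sweep_intervals is None
    sweep_length_bp: int = 40_000
    sweep_pi_reduction: float = 10.0
    sweep_freq_shift: float = 0.95
    n_causal_phenotype_snps: int = 2
    n_genes: int = 200
    gene_length_bp: int = 15_000
    freq_law_alpha: float = 0.8         # Beta(alpha, alpha) ancestral law
    freq_law_bounds: tuple[float, float] = (0.05, 0.95)

    def __post_init__(self) -> None:
        if self.snp_density_per_kb <= 0:
            raise ValueError("snp density must be positive")
        if not 0 < self.background_fst < 1:
            raise ValueError("background_fst must lie in (0, 1)")

    def contig_names(self) -> list[str]:
        return [f"contig_{i + 1}" for i in range(self.n_contigs)]

    def resolved_sweeps(self) -> list[tuple[str, int, int]]:
        """Explicit sweep intervals; auto-placement spreads ``n_sweeps``
        evenly across contigs, centred in equal-sized slots so that
        intervals never overlap and stay inside their contig."""
        if self.sweep_intervals is not None:
            for contig, start, end in self.sweep_intervals:
                if contig not in self.contig_names():
                    raise ValueError(f"sweep interval on unknown contig {contig}")
                if not 1 <= start <= end <= self.contig_length_bp:
                    raise ValueError(
                        f"sweep interval {contig}:{start}-{end} outside contig"
                    )
            return list(self.sweep_intervals)
        sweeps: list[tuple[str, int, int]] = []
        per = [self.n_sweeps // self.n_contigs] * self.n_contigs
        for i in range(self.n_sweeps % self.n_contigs):
            per[i] += 1
        for contig, k in zip(self.contig_names(), per):
            if k == 0:
                continue
            slot = self.contig_length_bp // k
            if slot < self.sweep_length_bp:
                raise ValueError("too many sweeps for contig length")
            for j in range(k):
                centre = j * slot + slot // 2
                start = max(1, centre - self.sweep_length_bp // 2 + 1)
                sweeps.append((contig, start, start + self.sweep_length_bp - 1))
        return sweeps


@dataclass
class SimTruth:
    """Ground truth emitted alongside the simulated genotypes."""

    sweep_intervals: list[tuple[str, int, int]]
    causal_sites: list[tuple[str, int]]
    expected_rule: dict[str, set[int]]
    site_freqs: pd.DataFrame  # contig, pos, p0, p_a, p_b (post-sweep)


@dataclass
class SimResult:
    table: VariantTable
    contrast: ContrastMap
    genes: list[GeneModel]
    phenotypes: dict[str, str]
    truth: SimTruth
    config: SimConfig


def _truncated_beta(rng: np.random.Generator, alpha: float,
                    bounds: tuple[float, float], size: int) -> np.ndarray:
    lo, hi = bounds
    out = rng.beta(alpha, alpha, size=size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.beta(alpha, alpha, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def _sweep_target_major_freq(p0: np.ndarray, fst: float,
                             reduction: float, shift: float) -> np.ndarray:
    """Major-allele frequency to which sweeps push the domestic group.

    Solves 2f(1-f) = 2*p0*(1-p0)*(1-F)/reduction for the larger root and
    takes the max with the configured shift, so both the frequency-shift
    and the expected diversity-reduction contracts hold simultaneously.
    """
    target_het = 2 * p0 * (1 - p0) * (1 - fst) / reduction
    f_star = 0.5 * (1 + np.sqrt(np.maximum(1 - 2 * target_het, 0.0)))
    return np.maximum(f_star, shift)


def simulate_two_pop(config: SimConfig) -> SimResult:
    """Simulate the full two-population dataset (see module docstring)."""
    rng = np.random.default_rng(config.seed)
    contigs = config.contig_names()
    contig_lengths = {c: config.contig_length_bp for c in contigs}
    sweeps = config.resolved_sweeps()

    site_rows: list[tuple[str, int, str, str]] = []
    p0_all: list[np.ndarray] = []
    lam = config.snp_density_per_kb / 1000.0
    bases = np.array(list("ACGT"))
    for contig in contigs:
        n_sites = rng.poisson(lam * config.contig_length_bp)
        n_sites = min(n_sites, config.contig_length_bp)
        pos = np.sort(
            rng.choice(config.contig_length_bp, size=n_sites, replace=False) + 1
        )
        ref_i = rng.integers(0, 4, size=n_sites)
        alt_i = (ref_i + rng.integers(1, 4, size=n_sites)) % 4
        site_rows.extend(
            (contig, int(p), bases[r], bases[a])
            for p, r, a in zip(pos, ref_i, alt_i)
        )
        p0_all.append(
            _truncated_beta(rng, config.freq_law_alpha, config.freq_law_bounds,
                            n_sites)
        )
    sites = pd.DataFrame(site_rows, columns=["contig", "pos", "ref", "alt"])
    p0 = np.concatenate(p0_all) if p0_all else np.empty(0)
    m = len(sites)

    f = config.background_fst
    shape = (1 - f) / f
    p_a = rng.beta(p0 * shape, (1 - p0) * shape)
    p_b = rng.beta(p0 * shape, (1 - p0) * shape)

    # hard-sweep implant: push the domestic group's major allele toward fixation
    contig_arr = sites["contig"].to_numpy()
    pos_arr = sites["pos"].to_numpy()
    in_sweep = np.zeros(m, dtype=bool)
    for contig, start, end in sweeps:
        in_sweep |= (contig_arr == contig) & (pos_arr >= start) & (pos_arr <= end)
    if in_sweep.any():
        fmaj = _sweep_target_major_freq(
            p0[in_sweep], f, config.sweep_pi_reduction, config.sweep_freq_shift
        )
        alt_major = p0[in_sweep] >= 0.5
        p_b[in_sweep] = np.where(
            alt_major,
            np.maximum(p_b[in_sweep], fmaj),
            np.minimum(p_b[in_sweep], 1 - fmaj),
        )

    na, nb = config.n_diploids_a, config.n_diploids_b
    dos_a = rng.binomial(2, p_a[None, :].repeat(na, axis=0))
    dos_b = rng.binomial(2, p_b[None, :].repeat(nb, axis=0))
    dosage = np.vstack([dos_a, dos_b]).astype(np.int8)

    samples = [f"wild_{i + 1:02d}" for i in range(na)] + [
        f"dom_{i + 1:02d}" for i in range(nb)
    ]
    populations = {s: ("WILD" if s.startswith("wild") else "DOM") for s in samples}
    phenotypes = {
        s: ("control" if s.startswith("wild") else "case") for s in samples
    }
    contrast = ContrastMap(
        populations=populations,
        group_a=frozenset({"WILD"}),
        group_b=frozenset({"DOM"}),
        phenotype=phenotypes,
    )

    table = VariantTable(
        contigs=contigs, contig_lengths=contig_lengths,
        sites=sites, samples=samples, dosage=dosage,
    )

    # causal phenotype SNPs: first one implanted, the rest are exact copies
    expected_rule = {"case": {0}, "control": {2}}
    causal_sites: list[tuple[str, int]] = []
    if config.n_causal_phenotype_snps > 0 and sweeps:
        interval = sweeps[0]
        idx = table.site_slice(*interval)
        if len(idx) == 0:
            raise ValueError(f"no sites in causal interval {interval}")
        k = min(config.n_causal_phenotype_snps, len(idx))
        chosen = idx[np.linspace(0, len(idx) - 1, k).astype(int)]
        table, _ = implant_causal_snp(
            table, interval, phenotypes, penetrance=1.0, rng=rng,
            site_index=int(chosen[0]), expected_rule=expected_rule,
        )
        for j in chosen[1:]:
            table.dosage[:, j] = table.dosage[:, chosen[0]]
        causal_sites = [
            (str(contig_arr[j]), int(pos_arr[j])) for j in chosen
        ]

    truth = SimTruth(
        sweep_intervals=sweeps,
        causal_sites=causal_sites,
        expected_rule=expected_rule,
        site_freqs=pd.DataFrame(
            {"contig": contig_arr, "pos": pos_arr, "p0": p0, "p_a": p_a, "p_b": p_b}
        ),
    )

    genes = _tile_genes(config)
    return SimResult(table=table, contrast=contrast, genes=genes,
                     phenotypes=phenotypes, truth=truth, config=config)


def implant_causal_snp(
    table: VariantTable,
    interval: tuple[str, int, int],
    phenotype_map: dict[str, str],
    penetrance: float = 1.0,
    rng: np.random.Generator | None = None,
    site_index: int | None = None,
    expected_rule: dict[str, set[int]] | None = None,
) -> tuple[VariantTable, dict]:
    """Force one site in ``interval`` to segregate with the phenotype.

    At penetrance 1.0 every phenotyped individual carries a genotype in its
    expected set; at penetrance q, exactly round((1-q)*n) individuals are
    given a contradicting genotype (chosen by ``rng``), so the segregation
    no-count is deterministic given the seed.

    Returns the modified table (dosage edited in place) and a truth dict
    with the site and rule used.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if expected_rule is None:
        expected_rule = {"case": {0}, "control": {2}}
    if site_index is None:
        idx = table.site_slice(*interval)
        if len(idx) == 0:
            raise ValueError(f"no sites in interval {interval}")
        site_index = int(idx[len(idx) // 2])

    phenotyped = [
        (i, s) for i, s in enumerate(table.samples)
        if phenotype_map.get(s) in expected_rule
    ]
    contradict = {0: 2, 2: 0, 1: 0}
    n = len(phenotyped)
    n_contra = int(round((1 - penetrance) * n))
    contra_rows = set(
        rng.choice(n, size=n_contra, replace=False).tolist()
    ) if n_contra else set()
    for k, (i, s) in enumerate(phenotyped):
        expected = sorted(expected_rule[phenotype_map[s]])[0]
        table.dosage[i, site_index] = (
            contradict[expected] if k in contra_rows else expected
        )
    truth = {
        "site_index": site_index,
        "contig": str(table.sites["contig"].iloc[site_index]),
        "pos": int(table.sites["pos"].iloc[site_index]),
        "expected_rule": expected_rule,
        "n_contradictions": n_contra,
    }
    return table, truth


def _tile_genes(config: SimConfig) -> list[GeneModel]:
    """Tile ``n_genes`` evenly across the genome (deterministic)."""
    genes: list[GeneModel] = []
    contigs = config.contig_names()
    per = [config.n_genes // config.n_contigs] * config.n_contigs
    for i in range(config.n_genes % config.n_contigs):
        per[i] += 1
    gid = 0
    for contig, k in zip(contigs, per):
        if k == 0:
            continue
        slot = config.contig_length_bp // k
        length = min(config.gene_length_bp, max(1, slot - 1))
        for j in range(k):
            gid += 1
            start = j * slot + max(1, (slot - length) // 2)
            genes.append(
                GeneModel(f"gene_{gid:04d}", contig, start, start + length - 1,
                          "+" if gid % 2 else "-")
            )
    return genes


def write_sim_outputs(result: SimResult, out_prefix: str | Path) -> dict[str, Path]:
    """Write VCF, popmap, genes BED, phenotype TSV and truth files.

    Every file is plain text; the VCF header records the generating config
    so a run is reproducible from its own outputs.
    """
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    cfg = result.config
    comments = [
        "sweepscan_sim=" + json.dumps(
            {
                "seed": cfg.seed, "n_contigs": cfg.n_contigs,
                "contig_length_bp": cfg.contig_length_bp,
                "snp_density_per_kb": cfg.snp_density_per_kb,
                "n_diploids_a": cfg.n_diploids_a, "n_diploids_b": cfg.n_diploids_b,
                "background_fst": cfg.background_fst,
                "n_sweeps": cfg.n_sweeps,
                "sweep_pi_reduction": cfg.sweep_pi_reduction,
                "sweep_freq_shift": cfg.sweep_freq_shift,
            },
            sort_keys=True,
        )
    ]
    paths = {
        "vcf": prefix.with_suffix(".vcf"),
        "popmap": prefix.parent / (prefix.name + ".popmap.tsv"),
        "genes": prefix.parent / (prefix.name + ".genes.bed"),
        "phenotype": prefix.parent / (prefix.name + ".phenotype.tsv"),
        "truth_bed": prefix.parent / (prefix.name + ".truth.bed"),
        "truth_json": prefix.parent / (prefix.name + ".truth.json"),
    }
    write_vcf(result.table, paths["vcf"], header_comments=comments)
    with open(paths["popmap"], "w") as fh:
        for s in result.table.samples:
            fh.write(f"{s}\t{result.contrast.populations[s]}\n")
    write_genes_bed(result.genes, paths["genes"])
    with open(paths["phenotype"], "w") as fh:
        for s in result.table.samples:
            fh.write(f"{s}\t{result.phenotypes[s]}\n")
    with open(paths["truth_bed"], "w") as fh:
        for contig, start, end in result.truth.sweep_intervals:
            fh.write(f"{contig}\t{start - 1}\t{end}\tsweep\n")
    with open(paths["truth_json"], "w") as fh:
        json.dump(
            {
                "sweep_intervals": [list(t) for t in result.truth.sweep_intervals],
                "causal_sites": [list(t) for t in result.truth.causal_sites],
                "expected_rule": {
                    k: sorted(v) for k, v in result.truth.expected_rule.items()
                },
            },
            fh, indent=2,
        )
    return paths
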