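import numpy as np
import pandas as pd
import pytest

from sweepscan import ContrastMap, ScanConfig, SimConfig, VariantTable, simulate_two_pop

MINI_VCF = """\
##fileformat=VCFv4.2
##contig=<ID=chr1,length=100000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3
chr1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1
chr1\t200\t.\tC\tT\t.\tPASS\t.\tGT\t./.\t0/0\t0/1
"""

MULTIALLELIC_VCF = """\
##fileformat=VCFv4.2
##contig=<ID=chr1,length=100000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3
chr1\t100\t.\tA\tG,T\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1
chr1\t200\t.\tC\tT\t.\tPASS\t.\tGT\t0/0\t0/0\t0/1
"""


@pytest.fixture
def mini_vcf(tmp_path):
    p = tmp_path / "mini.vcf"
    p.write_text(MINI_VCF)
    return p


@pytest.fixture
def multiallelic_vcf(tmp_path):
    p = tmp_path / "multi.vcf"
    p.write_text(MULTIALLELIC_VCF)
    return p


def make_table(dosage, positions=None, contig="chr1", contig_length=1_000_000,
               samples=None):
    """Build a VariantTable directly from a dosage matrix (rows = samples)."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n_samples, n_sites = dosage.shape
    if positions is None:
        positions = np.arange(1, n_sites + 1) * 100
    if samples is None:
        samples = [f"s{i + 1}" for i in range(n_samples)]
    sites = pd.DataFrame(
        {
            "contig": [contig] * n_sites,
            "pos": positions,
            "ref": ["A"] * n_sites,
            "alt": ["G"] * n_sites,
        }
    )
    return VariantTable(
        contigs=[contig],
        contig_lengths={contig: contig_length},
        sites=sites,
        samples=samples,
        dosage=dosage,
    )


def make_contrast(samples_a, samples_b, phenotype=None):
    populations = {s: "A" for s in samples_a} | {s: "B" for s in samples_b}
    return ContrastMap(
        populations=populations,
        group_a=frozenset({"A"}),
        group_b=frozenset({"B"}),
        phenotype=phenotype or {},
    )


@pytest.fixture(scope="session")
def default_sim():
    """The standard study conditions: 10 Mb, 20+20 diploids, F_ST 0.1,
    20 sweeps with a linked causal SNP pair."""
    return simulate_two_pop(SimConfig(seed=1))


@pytest.fixture(scope="session")
def null_sim():
    """Same conditions without sweeps or causal SNPs."""
    return simulate_two_pop(
        SimConfig(seed=1, n_sweeps=0, n_causal_phenotype_snps=0)
    )


@pytest.fixture(scope="session")
def scan_config():
    return ScanConfig()
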