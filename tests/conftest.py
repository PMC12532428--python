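import numpy as np
import pandas as pd
import pytest

from arraykit.simulate import scaled_config, simulate_cohort
from arraykit.types import GenotypeMatrix, VariantTable

TOY_VCF = """\
##fileformat=VCFv4.2
##INFO=<ID=AF,Number=A,Type=Float,Description="Alternate allele frequency">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##contig=<ID=chr1>
##contig=<ID=chr2>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3\tS4
chr1\t100\t.\tA\tG\t.\tPASS\tAF=0.25\tGT:DP\t0/0:12\t0/1:15\t0/0:18\t0/0:9
chr1\t2500\t.\tC\tT\t.\tPASS\t.\tGT:DP\t0/0:10\t0/1:11\t1/1:14\t0/1:13
chr1\t5000\t.\tG\tC\t.\tPASS\tAF=0.5\tGT:DP\t0/1:20\t0/1:22\t0/0:25\t1/1:19
chr2\t300\t.\tT\tA\t.\tPASS\tAF=0.4\tGT:DP\t0/0:8\t1/1:9\t0/1:7\t./.:.
chr2\t900\t.\tA\tC,T\t.\tPASS\tAF=0.3,0.1\tGT:DP\t0/1:16\t0/2:14\t0/0:13\t1/1:15
chr2\t4000\t.\tAT\tA\t.\tPASS\tAF=0.2\tGT:DP\t0/0:10\t0/1:12\t0/0:11\t0/0:14
"""


@pytest.fixture
def toy_vcf(tmp_path):
    path = tmp_path / "toy.vcf"
    path.write_text(TOY_VCF)
    return path


@pytest.fixture(scope="session")
def cohort():
    """Small error-carrying cohort shared by read-only tests."""
    return simulate_cohort(scaled_config(seed=11))


@pytest.fixture(scope="session")
def clean_cohort():
    """Error-free, fully-called cohort with no phenotype mislabels."""
    return simulate_cohort(scaled_config(
        seed=12, genotype_error=0.0, missing_rate=0.0,
        n_sexrev_males=0, n_masc_neomales=0))


def make_variant_table(chrom, pos, ref, alt, af, genotypes, depths=None,
                       sample_ids=None):
    """Hand-construction helper for small design fixtures."""
    genotypes = np.asarray(genotypes, dtype=np.int8)
    n_sites, n_samples = genotypes.shape
    if depths is None:
        depths = np.full((n_sites, n_samples), 15, dtype=np.int32)
    return VariantTable(
        sample_ids=sample_ids or [f"S{i+1}" for i in range(n_samples)],
        chrom=np.asarray(chrom, dtype=object),
        pos=np.asarray(pos, dtype=np.int64),
        ref=list(ref),
        alt=[tuple(a) if isinstance(a, (tuple, list)) else (a,) for a in alt],
        af=np.asarray(af, dtype=np.float64),
        genotypes=genotypes,
        depths=np.asarray(depths, dtype=np.int32),
        multiallelic=np.array([len(a) > 1 if isinstance(a, (tuple, list))
                               else False for a in alt]))


def make_gm(calls, chrom=None, pos=None, sample_ids=None, marker_ids=None):
    calls = np.asarray(calls, dtype=np.int8)
    n_samples, n_markers = calls.shape
    if pos is None:
        pos = np.arange(1, n_markers + 1) * 1000
    if chrom is None:
        chrom = np.full(n_markers, "chr1", dtype=object)
    return GenotypeMatrix(
        sample_ids=sample_ids or [f"S{i+1}" for i in range(n_samples)],
        marker_ids=marker_ids or [f"M{j+1}" for j in range(n_markers)],
        calls=calls,
        marker_chrom=np.asarray(chrom, dtype=object),
        marker_pos=np.asarray(pos, dtype=np.int64))
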