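"""Shared fixtures: tiny hand-checkable inputs, generated at test time."""

import numpy as np
import pytest

from seedsource.io import MISSING, GenotypeMatrix, SnpFunctionalTable

# Hand-transcribed VCF: 3 samples x 4 biallelic SNPs, plus one
# multiallelic record and one indel that a reader must skip.
VCF_TEXT = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=chr1>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3
chr1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1
chr1\t200\t.\tC\tT\t.\tPASS\t.\tGT\t0/1\t0/1\t./.
chr1\t300\t.\tG\tA,T\t.\tPASS\t.\tGT\t0/1\t0/0\t0/0
chr1\t400\t.\tT\tTA\t.\tPASS\t.\tGT\t0/0\t0/1\t0/0
chr1\t500\t.\tG\tC\t.\tPASS\t.\tGT\t1/1\t1/1\t1/1
chr1\t600\t.\tT\tA\t.\tPASS\t.\tGT\t0/0\t0/0\t0/0
"""

# dosages for the four retained SNPs, transcribed by eye from VCF_TEXT
# (rows S1..S3, columns pos 100/200/500/600)
VCF_EXPECTED = np.array(
    [
        [0, 1, 2, 0],
        [1, 1, 2, 0],
        [2, MISSING, 2, 0],
    ]
)

TRAITS_TEXT = """\
site,source,plot,height_cm,alive
MD,XCS,p1,28.1,1
MD,XCS,p1,,0
MD,XCS,p1,26.5,true
MD,XDS,p2,25.0,1
MD,XDS,p2,,false
MD,XDS,p2,24.2,1
"""


@pytest.fixture
def vcf_path(tmp_path):
    p = tmp_path / "panel.vcf"
    p.write_text(VCF_TEXT)
    return p


@pytest.fixture
def popmap_path(tmp_path):
    p = tmp_path / "popmap.tsv"
    p.write_text("S1\tA\nS2\tA\nS3\tB\n")
    return p


@pytest.fixture
def traits_path(tmp_path):
    p = tmp_path / "traits.csv"
    p.write_text(TRAITS_TEXT)
    return p


def make_gm(dosages, pops, snp_ids=None):
    """GenotypeMatrix from a dosage array and one population per row."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n_ind, n_snp = dosages.shape
    ids = [f"i{r}" for r in range(n_ind)]
    if snp_ids is None:
        snp_ids = [f"1:{j + 1}:A:G" for j in range(n_snp)]
    return GenotypeMatrix(
        individual_ids=ids,
        population_of={f"i{r}": pops[r] for r in range(n_ind)},
        snp_ids=list(snp_ids),
        dosages=dosages,
    )


def make_ann(snp_ids, effects):
    """SnpFunctionalTable mapping each SNP id to one raw effect label."""
    table = SnpFunctionalTable()
    for snp_id, effect in zip(snp_ids, effects):
        table.add(snp_id, effect)
    return table
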