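"""Shared fixtures: hand-built SNP records, tiny VCF/pedigree writers."""

from __future__ import annotations

import textwrap
from pathlib import Path

import pytest

from xstrlink.iohub import FEMALE, MALE, Genotype, SnpRecord, TrioRecord


def gt(*alleles, phased=True, flag=None) -> Genotype:
    return Genotype(alleles=tuple(alleles), phased=phased, flag=flag)


def make_snp(pos, genotypes, maf=0.5, chrom="chrX", ref="A", alt="G") -> SnpRecord:
    """Build a SnpRecord from {sample: Genotype}."""
    return SnpRecord(
        chrom=chrom, pos=pos, ref=ref, alt=alt, genotypes=genotypes, maf=maf
    )


@pytest.fixture
def son_trio() -> TrioRecord:
    return TrioRecord(
        family_id="F1", child_id="C1", mother_id="M1", father_id=None,
        child_sex=MALE,
    )


@pytest.fixture
def daughter_trio() -> TrioRecord:
    return TrioRecord(
        family_id="F2", child_id="C2", mother_id="M2", father_id="P2",
        child_sex=FEMALE,
    )


@pytest.fixture
def fixture_vcf(tmp_path: Path) -> Path:
    """Six sites: five biallelic SNPs plus one multiallelic (dropped by the
    reader). MOM is diploid phased, DAD haploid, SON haploid, DAU diploid."""
    text = textwrap.dedent(
        """\
        ##fileformat=VCFv4.2
        ##contig=<ID=chrX,length=156040895>
        ##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
        #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tMOM\tDAD\tSON\tDAU
        chrX\t1000\t.\tA\tG\t.\tPASS\t.\tGT\t0|1\t1\t1\t0|1
        chrX\t2000\t.\tC\tT\t.\tPASS\t.\tGT\t1|0\t0\t0\t1|0
        chrX\t3000\t.\tG\tA\t.\tPASS\t.\tGT\t0|0\t1\t0\t0|1
        chrX\t4000\t.\tT\tC,G\t.\tPASS\t.\tGT\t0|1\t2\t1\t0|2
        chrX\t5000\t.\tA\tC\t.\tPASS\t.\tGT\t0/1\t0\t1\t1|1
        chrX\t6000\t.\tC\tG\t.\tPASS\t.\tGT\t1|1\t.\t.\t.|.
        chrX\t7000\t.\tG\tT\t.\tPASS\t.\tGT\t0|1\t0\t0\t0|0
        """
    )
    path = tmp_path / "fixture.vcf"
    path.write_text(text)
    return path
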