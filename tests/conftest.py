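import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

from spex.fixtures_io import load_fixture
from spex.indel_impact import TranscriptModel
from spex.records import VariantRecord


@pytest.fixture(scope="session")
def table1():
    return load_fixture("table1_patients")


@pytest.fixture(scope="session")
def table2():
    return load_fixture("table2_snps")


@pytest.fixture(scope="session")
def table3():
    return load_fixture("table3_indels")


@pytest.fixture(scope="session")
def two_exon_model():
    """Toy transcript on chr1 (+): CDS 101-160 and 201-260, 40 codons."""
    return TranscriptModel("tx1", "chr1", "+", ((101, 160), (201, 260)))


def make_indel(pos, ref, alt, chrom="chr1", patient="P1"):
    return VariantRecord(
        patient_id=patient,
        gene="GENE",
        variant_class="indel",
        consequence="other",
        chromosome=chrom,
        position=pos,
        ref_allele=ref,
        alt_allele=alt,
        zygosity="het",
    )


def make_snp(pos, ref="A", alt="G", chrom="chr1", patient="P1", consequence="missense",
             freq=None, gene="GENE", zygosity="het"):
    return VariantRecord(
        patient_id=patient,
        gene=gene,
        variant_class="snp",
        consequence=consequence,
        chromosome=chrom,
        position=pos,
        ref_allele=ref,
        alt_allele=alt,
        zygosity=zygosity,
        population_freq=freq,
    )
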