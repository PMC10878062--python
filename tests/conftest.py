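import pytest

from crispamp import fshr_exon2_reference, fshr_synthetic_amplicon, genotype_bare_sequences
from crispamp.datasets import f1_allele_records, load_f1_phenotypes


@pytest.fixture(scope="session")
def exon2_ref():
    return fshr_exon2_reference()


@pytest.fixture(scope="session")
def amplicon_ref():
    return fshr_synthetic_amplicon()


@pytest.fixture(scope="session")
def allele_records():
    """Bundled per-fish exon-2 allele sequences, one row per allele."""
    return f1_allele_records()


@pytest.fixture(scope="session")
def phenotypes():
    return load_f1_phenotypes()


@pytest.fixture(scope="session")
def cohort_genotypes(exon2_ref, allele_records):
    """Allele tables and genotype calls for the bundled F1 cohort."""
    tables, genotypes = genotype_bare_sequences(allele_records, exon2_ref)
    return tables, genotypes


@pytest.fixture(scope="session")
def published_labels(phenotypes):
    return dict(zip(phenotypes.sample_id, phenotypes.genotype))
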