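import pytest

from eacnv.intervals import GenomicInterval
from eacnv.models import ReferenceSet
from eacnv.simulate import SyntheticCohortConfig, generate_cohort


@pytest.fixture(scope="session")
def cohort():
    """One default synthetic cohort shared across read-only tests."""
    return generate_cohort(SyntheticCohortConfig(seed=11))


@pytest.fixture
def empty_references():
    names = ("hapmap_cnp", "chop_blocks", "internal_controls", "unrelated_case_db")
    return {n: ReferenceSet(n, []) for n in names}


@pytest.fixture
def iv():
    return lambda chrom, start, end: GenomicInterval(str(chrom), start, end)
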