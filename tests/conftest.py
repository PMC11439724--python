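import logging

import pytest
from hypothesis import settings

from immunoedit.hla import (
    Cohort,
    Group,
    HlaAllele,
    Locus,
    LocusGenotype,
    Subject,
)

logging.getLogger("immunoedit").setLevel(logging.ERROR)

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def mk_allele(locus: str, f1: int, f2: int = 1) -> HlaAllele:
    return HlaAllele(Locus(locus), f1, f2)


def mk_subject(sid, genotype_spec, group=Group.CONTROL, age=None, sex=None, cohort="test"):
    """genotype_spec: {locus string: (f1, f1') or ((f1,f2),(f1',f2'))}."""
    genotypes = {}
    for locus, pair in genotype_spec.items():
        a1, a2 = pair
        a1 = mk_allele(locus, *a1) if isinstance(a1, tuple) else mk_allele(locus, a1)
        a2 = mk_allele(locus, *a2) if isinstance(a2, tuple) else mk_allele(locus, a2)
        genotypes[Locus(locus)] = LocusGenotype(a1, a2)
    return Subject(sid, cohort, group, age, sex, genotypes)


@pytest.fixture
def complete_subject():
    """Heterozygous at all three class I loci."""
    return mk_subject("S1", {"A": (1, 2), "B": (7, 8), "C": (6, 7)}, age=60.0, sex="F")


@pytest.fixture(scope="session")
def fixture_suite(tmp_path_factory):
    """One miniature generated study shared across tests that need files."""
    from immunoedit.simulate import generate_fixture_suite

    out = tmp_path_factory.mktemp("suite")
    manifest = generate_fixture_suite(out, seed=11)
    return out, manifest
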