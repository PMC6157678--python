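import pytest

from matechoice.alleles import AbsMask, Allele, LocusAlleleDb, assign_protein_classes
from matechoice.metrics import MhcGenotype
from matechoice.synthetic import SimConfig, simulate_dataset

# hand-built toy locus: 4 alleles over codons K/L/M/N/R/Q
#   A1 KLMN, A2 RLQN, A3 KLMN (synonymous twin of A1), A4 KLQN
_NT = {
    "A1": "AAACTGATGAAT",
    "A2": "CGTCTGCAAAAT",
    "A3": "AAGCTGATGAAT",
    "A4": "AAACTGCAAAAT",
}
_AA = {"A1": "KLMN", "A2": "RLQN", "A3": "KLMN", "A4": "KLQN"}


@pytest.fixture
def toy_db() -> LocusAlleleDb:
    alleles = {
        name: Allele(name=name, nt_seq=_NT[name], aa_seq=_AA[name])
        for name in ("A1", "A2", "A3", "A4")
    }
    db = LocusAlleleDb(
        locus="TOY", alleles=alleles, mask=AbsMask("TOY", (1,))
    )
    return assign_protein_classes(db)


def geno(ind: str, locus: str, a1: str | None, a2: str | None) -> MhcGenotype:
    missing = a1 is None
    return MhcGenotype(ind, locus, a1, a2, missing=missing)


@pytest.fixture
def toy_geno():
    return geno


@pytest.fixture(scope="session")
def study_scale_sim():
    """One study-scale synthetic dataset shared across tests."""
    return simulate_dataset(SimConfig(seed=42))
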