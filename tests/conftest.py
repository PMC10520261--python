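import numpy as np
import pytest

from oncosieve import CodingSequence, Signature
from oncosieve.synthetic import gen_helix_coords

# Independent standard-genetic-code lookup, written out by hand so that codon
# consequence calls can be cross-checked against a second source.
GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

BASES = "ACGT"


def oracle_consequence(codon: str, within: int, alt: str) -> str:
    """Second-source consequence call from the hand-written codon table."""
    mutated = codon[:within] + alt + codon[within + 1 :]
    aa_ref, aa_alt = GENETIC_CODE[codon], GENETIC_CODE[mutated]
    if aa_alt == "*" and aa_ref != "*":
        return "nonsense"
    if aa_alt == aa_ref:
        return "synonymous"
    return "missense"


@pytest.fixture(scope="session")
def genetic_code():
    return GENETIC_CODE


@pytest.fixture(scope="session")
def uniform_sig():
    return Signature.uniform()


@pytest.fixture
def small_cds():
    # ATG TGC CTG TAA: start, Cys, Leu, stop
    return CodingSequence(gene="g1", seq="ATGTGCCTGTAA", flank5="C", flank3="G")


@pytest.fixture(scope="session")
def helix200():
    return gen_helix_coords(200)


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)
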