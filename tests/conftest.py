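import numpy as np
import pytest

from zfbirth.motif import MotifPattern
from zfbirth.neutrality import PopAlignment

# 23-aa peptide matching the C2H2 pattern with the shortest gap expansion:
# Ø X C X2 C X3 Ø X5 Ø X2 H X3 H
MOTIF_PEPTIDE_23 = "FACAACAAALAAAAAVAAHAAAH"

# one fixed codon choice for the 23-aa peptide (any choice works)
_CODONS = {
    "F": "TTT", "A": "GCT", "C": "TGT", "L": "CTT", "V": "GTT", "H": "CAT",
}
MOTIF_DNA_69 = "".join(_CODONS[aa] for aa in MOTIF_PEPTIDE_23)


@pytest.fixture(scope="session")
def c2h2():
    return MotifPattern.c2h2()


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture(scope="session")
def toy_alignment():
    """A printed 4 x 10 toy alignment with gaps, an N and a triallelic site."""
    sample = [
        "ACGTACGTAC",
        "ACGTACGAAC",
        "AGGTACGTTC",
        "ACGT-CGTNC",
    ]
    outgroup = "ACGTACGTAC"
    return PopAlignment(
        names=[f"s{i}" for i in range(4)],
        seqs=sample,
        outgroups={"out": outgroup},
    )


@pytest.fixture(scope="session")
def tajima_zero_alignment():
    """n = 4, 8 singleton sites + 3 doubleton sites: the Tajima numerator is
    exactly zero (pi = 0.5*8 + (2/3)*3 = 6 = S/a1 = 11/(11/6))."""
    L = 11
    seqs = [["A"] * L for _ in range(4)]
    for col in range(8):  # singletons, spread over carriers
        seqs[col % 4][col] = "G"
    for col in range(8, 11):  # doubletons
        seqs[0][col] = "T"
        seqs[1][col] = "T"
    return PopAlignment(
        names=[f"s{i}" for i in range(4)],
        seqs=["".join(s) for s in seqs],
        outgroups={"out": "A" * L},
    )
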