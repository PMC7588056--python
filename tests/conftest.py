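import numpy as np
import pytest

from plastomarkers.alignment import MultipleAlignment


def random_alignment(rng: np.random.Generator, n: int, length: int,
                     alphabet: str = "ACGT") -> MultipleAlignment:
    letters = np.frombuffer(alphabet.encode(), dtype=np.uint8)
    matrix = rng.choice(letters, size=(n, length))
    return MultipleAlignment([f"s{i}" for i in range(n)], matrix)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def make_alignment():
    def _make(rows, taxa=None):
        taxa = taxa or [f"s{i}" for i in range(len(rows))]
        return MultipleAlignment.from_sequences(taxa, rows)

    return _make


GENBANK_FORWARD = """\
LOCUS       TESTREC                   12 bp    DNA     circular PLN 01-JAN-2020
DEFINITION  toy plastome fragment.
ACCESSION   TESTREC
VERSION     TESTREC.1
FEATURES             Location/Qualifiers
     source          1..12
                     /organism="toy"
     CDS             1..9
                     /gene="psbA"
ORIGIN
        1 atgaaataac cc
//
"""

GENBANK_JOIN_MINUS = """\
LOCUS       TESTJOIN                  12 bp    DNA     circular PLN 01-JAN-2020
DEFINITION  toy spliced minus-strand gene.
ACCESSION   TESTJOIN
VERSION     TESTJOIN.1
FEATURES             Location/Qualifiers
     source          1..12
                     /organism="toy"
     CDS             complement(join(1..6,10..12))
                     /gene="toyG"
ORIGIN
        1 acgtacgtac gt
//
"""


@pytest.fixture
def genbank_forward(tmp_path):
    path = tmp_path / "forward.gb"
    path.write_text(GENBANK_FORWARD)
    return path


@pytest.fixture
def genbank_join_minus(tmp_path):
    path = tmp_path / "join_minus.gb"
    path.write_text(GENBANK_JOIN_MINUS)
    return path
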