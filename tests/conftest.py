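import pytest

from pitha.datasets import load_table

TINY_PDB = """\
ATOM      1  N   GLY H   1      10.000  10.000  10.000  1.00  0.00           N
ATOM      2  CA  GLY H   1      11.400  10.000  10.000  1.00  0.00           C
ATOM      3  C   GLY H   1      12.000  11.400  10.000  1.00  0.00           C
ATOM      4  O   GLY H   1      13.200  11.500  10.000  1.00  0.00           O
ATOM      5  N   ALA L   1      20.000  20.000  20.000  1.00  0.00           N
ATOM      6  CA  ALA L   1      21.400  20.000  20.000  1.00  0.00           C
ATOM      7  CB  ALA L   1      21.900  18.600  20.000  1.00  0.00           C
ATOM      8  C   ALA L   1      22.000  21.400  20.000  1.00  0.00           C
ATOM      9  O   ALA L   1      23.200  21.500  20.000  1.00  0.00           O
END
"""

TINY_NUMBERING = """\
chain,seq_index,kabat_number,insertion,residue
H,1,26,,G
H,2,27,,F
H,3,52,A,S
"""

# PSI-BLAST -out_ascii_pssm layout: header with residue columns, then one
# row per position (only the first 20 log-odds columns are parsed)
TINY_PSSM = """\
Last position-specific scoring matrix computed

            A   R   N   D   C   Q   E   G   H   I   L   K   M   F   P   S   T   W   Y   V
    1 G     0  -3   0   1  -3  -2  -2   6  -2  -4  -4  -2  -3  -3  -2   0  -2  -3  -3  -4
    2 F    -2  -3  -3  -4  -2  -3  -3  -3  -1   0   0  -3   0   6  -4  -2  -2   1   3  -1
    3 S     1  -1   1   0  -1   0   0   0  -1  -2  -2   0  -1  -2  -1   4   1  -3  -2  -2
"""


@pytest.fixture
def tiny_pdb():
    return TINY_PDB


@pytest.fixture
def tiny_numbering():
    return TINY_NUMBERING


@pytest.fixture
def tiny_pssm():
    return TINY_PSSM


@pytest.fixture(scope="session")
def crystal_table():
    return load_table("crystal")


@pytest.fixture(scope="session")
def modeled_table():
    return load_table("modeled")


@pytest.fixture
def full_heavy_numbering():
    """A heavy chain covering framework and all three CDR ranges."""
    rows = ["chain,seq_index,kabat_number,insertion,residue"]
    residues = {52: "G", 53: "G", 54: "S", 55: "I", 56: "S"}
    idx = 0
    for kabat in range(1, 114):
        idx += 1
        rows.append(f"H,{idx},{kabat},,{residues.get(kabat, 'A')}")
        if kabat == 52:  # an insertion inside the β-turn
            idx += 1
            rows.append(f"H,{idx},52,A,G")
    return "\n".join(rows) + "\n"
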