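import numpy as np
import pytest
from hypothesis import settings

from startscan import Alignment

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


def alignment_from_columns(columns: list[str], reference_id: str = "seq0") -> Alignment:
    """Build an Alignment whose j-th column is columns[j] (rows read down)."""
    n_rows = len(columns[0])
    rows = ["".join(col[i] for col in columns) for i in range(n_rows)]
    ids = [f"seq{i}" for i in range(n_rows)]
    return Alignment(ids=ids, rows=rows, reference_id=reference_id)


@pytest.fixture
def rng():
    return np.random.default_rng(2026)


@pytest.fixture
def three_residue_pdb(tmp_path):
    """Hand-written 3-residue toy PDB (Ala-Gly-Ser), 11 atoms."""
    text = "\n".join(
        [
            "ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N",
            "ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C",
            "ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C",
            "ATOM      4  O   ALA A   1       1.251   2.390   0.000  1.00  0.00           O",
            "ATOM      5  CB  ALA A   1       1.988  -0.773  -1.199  1.00  0.00           C",
            "ATOM      6  N   GLY A   2       3.332   1.536   0.000  1.00  0.00           N",
            "ATOM      7  CA  GLY A   2       3.988   2.830   0.000  1.00  0.00           C",
            "ATOM      8  C   GLY A   2       5.504   2.705   0.000  1.00  0.00           C",
            "ATOM      9  O   GLY A   2       6.030   1.594   0.000  1.00  0.00           O",
            "ATOM     10  N   SER A   3       6.235   3.818   0.000  1.00  0.00           N",
            "ATOM     11  CA  SER A   3       7.686   3.804   0.000  1.00  0.00           C",
            "END",
        ]
    )
    path = tmp_path / "three_residues.pdb"
    path.write_text(text + "\n")
    return path
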