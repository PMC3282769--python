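import numpy as np
import pytest

from ptcsig.seq_core import SequenceRecord

AA20 = "ACDEFGHIKLMNPQRSTVWY"


def random_record(rng: np.random.Generator, length: int, rec_id: str = "rand") -> SequenceRecord:
    return SequenceRecord(id=rec_id, residues="".join(AA20[i] for i in rng.integers(0, 20, length)))


def pdb_line(serial, name, resname, chain, resseq, x, y, z, occ=1.0, element=None,
             altloc=" ", record="ATOM"):
    """One fixed-column PDB ATOM/HETATM line."""
    element = element or name[0]
    return (
        f"{record:<6}{serial:>5} {name:<4}{altloc}{resname:<3} {chain}{resseq:>4}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}          {element:>2}\n"
    )


@pytest.fixture
def tiny_pdb(tmp_path):
    """Three-atom handwritten PDB file with known coordinates."""
    text = (
        pdb_line(1, "N", "ALA", "A", 1, 1.0, 2.0, 3.0)
        + pdb_line(2, "CA", "ALA", "A", 1, 2.5, 2.0, 3.0, element="C")
        + pdb_line(3, "C", "ALA", "A", 1, 3.5, 3.0, 3.5)
        + "END\n"
    )
    path = tmp_path / "tiny.pdb"
    path.write_text(text)
    return path
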