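import numpy as np
import pytest

from hotspotter import structures
from hotspotter.structures import Atom, Residue, Structure


def pdb_line(serial, name, res, chain, resnum, x, y, z, occ=1.0, bfac=10.0,
             element=None, altloc=" ", record="ATOM  "):
    element = element or name[0]
    name_field = name if len(name) == 4 else f" {name:<3s}"
    return (f"{record}{serial:5d} {name_field}{altloc}{res:>3s} {chain}"
            f"{resnum:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{bfac:6.2f}"
            f"          {element:>2s}")


GLY_PDB = "\n".join([
    pdb_line(1, "N", "GLY", "A", 1, 10.0, 10.0, 10.0),
    pdb_line(2, "CA", "GLY", "A", 1, 11.2, 10.5, 10.0, element="C"),
    pdb_line(3, "C", "GLY", "A", 1, 12.1, 9.6, 10.4),
    pdb_line(4, "O", "GLY", "A", 1, 12.0, 8.5, 10.9),
    "END",
]) + "\n"


@pytest.fixture
def gly_pdb(tmp_path):
    path = tmp_path / "gly.pdb"
    path.write_text(GLY_PDB)
    return path


@pytest.fixture(scope="session")
def toy_complex():
    """Two-chain fixture with a 4 Å interface gap and known truth."""
    return structures.generate_fixture_complex(5, 4.0, seed=1)


@pytest.fixture(scope="session")
def far_complex():
    """Chains separated by 50 Å: no interface by construction."""
    return structures.generate_fixture_complex(5, 50.0, seed=1)


def make_structure(atom_specs, res_type="ALA", partner_split=None):
    """A free-form structure from (chain, resnum, atom_name, element, xyz)."""
    residues = {}
    for chain, resnum, name, element, xyz in atom_specs:
        key = (chain, resnum)
        if key not in residues:
            residues[key] = Residue(chain_id=chain, seq_number=resnum,
                                    res_type=res_type, atoms=[])
        residues[key].atoms.append(Atom(name=name, element=element,
                                        coord=np.asarray(xyz, float)))
    s = Structure("test", residues=list(residues.values()))
    if partner_split:
        s.set_partner_split(*partner_split)
    return s
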