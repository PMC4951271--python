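"""Coordinate model for protein complexes.

A :class:`Structure` is an ordered collection of residues grouped by chain,
with an optional ``partner_split`` naming the two interacting sides of the
complex.  PDB files are read through Biopython and normalised into this
lightweight model: first MODEL only, highest-occupancy altloc, heavy atoms
only, waters and unmapped HETATM groups dropped, selenomethionine and friends
mapped to their parent residue types.

The module also generates deterministic two-chain toy complexes whose
interface membership is known by construction, used throughout the test
suite and the synthetic pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser
from Bio.PDB.Atom import DisorderedAtom

from .errors import DataError, InputError, UsageError

log = logging.getLogger(__name__)

STANDARD_AA = (
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE "
    "LEU LYS MET PHE PRO SER THR TRP TYR VAL"
).split()

#: Non-standard residues mapped to their parent type; anything else is dropped.
NONSTANDARD_MAP = {
    "MSE": "MET", "SEC": "CYS", "CSO": "CYS", "CME": "CYS",
    "SEP": "SER", "TPO": "THR", "PTR": "TYR", "HYP": "PRO",
    "MLY": "LYS", "KCX": "LYS", "PCA": "GLU",
}

BACKBONE_ATOMS = {"N", "CA", "C", "O"}

#: Heavy-element van der Waals radii (Å), as used by common protein
#: surface-analysis tools.
VDW_RADII = {"C": 1.87, "N": 1.65, "O": 1.40, "S": 1.85, "P": 1.80, "SE": 1.90}


@dataclass
class Atom:
    name: str
    element: str
    coord: np.ndarray
    bfactor: float = 0.0

    def __post_init__(self):
        self.coord = np.asarray(self.coord, dtype=float)
        if not np.all(np.isfinite(self.coord)):
            raise InputError(f"non-finite coordinates for atom {self.name}")
        self.bfactor = max(float(self.bfactor), 0.0)

    @property
    def is_sidechain(self) -> bool:
        return self.name not in BACKBONE_ATOMS


@dataclass
class Residue:
    chain_id: str
    seq_number: int
    res_type: str
    atoms: list[Atom] = field(default_factory=list)
    insertion_code: str = ""

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_number, self.insertion_code)

    def sidechain_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.is_sidechain]

    def get_atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class Structure:
    structure_id: str
    residues: list[Residue] = field(default_factory=list)
    #: two disjoint chain-id sets defining the interacting sides, or None
    partner_split: tuple[frozenset[str], frozenset[str]] | None = None

    @property
    def chain_ids(self) -> list[str]:
        seen: list[str] = []
        for r in self.residues:
            if r.chain_id not in seen:
                seen.append(r.chain_id)
        return seen

    def atoms(self) -> list[tuple[Residue, Atom]]:
        return [(r, a) for r in self.residues for a in r.atoms]

    def coords(self) -> np.ndarray:
        if not self.residues:
            return np.empty((0, 3))
        return np.array([a.coord for _, a in self.atoms()])

    def residue(self, chain_id: str, seq_number: int, icode: str = "") -> Residue | None:
        for r in self.residues:
            if r.key == (chain_id, seq_number, icode):
                return r
        return None

    def set_partner_split(self, side_a, side_b) -> None:
        a, b = frozenset(side_a), frozenset(side_b)
        if not a or not b or a & b:
            raise UsageError("partner sides must be non-empty and disjoint")
        self.partner_split = (a, b)

    def side_of(self, chain_id: str) -> int | None:
        """0/1 for the partner side owning ``chain_id``, None if unsplit."""
        if self.partner_split is None:
            return None
        for i, side in enumerate(self.partner_split):
            if chain_id in side:
                return i
        return None


def _pick_altloc(atom):
    """Highest occupancy wins; ties broken by altloc letter order."""
    if not isinstance(atom, DisorderedAtom):
        return atom
    best = None
    for altloc in sorted(atom.child_dict):
        child = atom.child_dict[altloc]
        occ = child.get_occupancy() or 0.0
        if best is None or occ > best[0] + 1e-9:
            best = (occ, child)
    return best[1]


def read_pdb(path, structure_id: str | None = None,
             partner_split: tuple | None = None) -> Structure:
    """Read a PDB file into a :class:`Structure` (first MODEL only).

    Altloc handling keeps the highest-occupancy copy (ties: altloc letter
    order); hydrogens, waters, and unmapped non-standard residues are dropped.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    parser = PDBParser(QUIET=True)
    try:
        bio = parser.get_structure(structure_id or path.stem, str(path))
    except Exception as exc:  # Biopython raises several types here
        raise InputError(f"unreadable PDB file {path}: {exc}") from exc
    try:
        model = next(bio.get_models())
    except StopIteration:
        raise InputError(f"no coordinates in {path}")

    out = Structure(structure_id or path.stem)
    for chain in model:
        for res in chain:
            hetflag, seqnum, icode = res.get_id()
            resname = res.get_resname().strip()
            if resname in ("HOH", "WAT", "DOD"):
                continue
            res_type = resname if resname in STANDARD_AA else NONSTANDARD_MAP.get(resname)
            if res_type is None:
                if hetflag.strip():
                    continue  # plain HETATM ligand
                log.warning("dropping unmapped non-standard residue %s %s%s",
                            resname, chain.id, seqnum)
                continue
            atoms = []
            for name in sorted(res.child_dict):
                atom = _pick_altloc(res.child_dict[name])
                element = (atom.element or name[:1]).strip().upper()
                if element in ("H", "D"):
                    continue
                atoms.append(Atom(name=name.strip(), element=element,
                                  coord=atom.get_coord(),
                                  bfactor=atom.get_bfactor() or 0.0))
            if not atoms:
                continue
            names = {a.name for a in atoms}
            if not {"N", "CA", "C"} <= names:
                log.warning("dropping residue %s %s%d: incomplete backbone",
                            res_type, chain.id, seqnum)
                continue
            out.residues.append(Residue(chain_id=chain.id, seq_number=seqnum,
                                        res_type=res_type, atoms=atoms,
                                        insertion_code=icode.strip()))
    if not out.residues:
        raise InputError(f"{path}: no standard amino-acid residues found")
    if partner_split is not None:
        out.set_partner_split(*partner_split)
    return out


def write_pdb(structure: Structure, path) -> None:
    """Write the model back to fixed-width PDB text (ATOM/TER records only)."""
    lines = []
    serial = 0
    last_chain = None
    for res in structure.residues:
        if last_chain is not None and res.chain_id != last_chain:
            lines.append("TER")
        last_chain = res.chain_id
        for atom in res.atoms:
            serial += 1
            name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
            x, y, z = atom.coord
            lines.append(
                f"ATOM  {serial:5d} {name}{'':1s}{res.res_type:>3s} "
                f"{res.chain_id:1s}{res.seq_number:4d}{res.insertion_code or ' ':1s}"
                f"   {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{atom.bfactor:6.2f}"
                f"          {atom.element:>2s}"
            )
    lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def extract_partner(structure: Structure, side) -> Structure:
    """Rigid extraction of one binding partner (coordinates unchanged).

    ``side`` may be 0/1, a chain id belonging to one side, or a string of the
    side's chain ids.
    """
    if structure.partner_split is None:
        raise UsageError("structure has no partner_split defined")
    sides = structure.partner_split
    idx: int | None = None
    if side in (0, 1):
        idx = side
    elif isinstance(side, str):
        wanted = frozenset(side)
        for i, s in enumerate(sides):
            if wanted == s or (len(side) == 1 and side in s):
                idx = i
                break
    if idx is None:
        raise UsageError(f"unknown partner side {side!r}; sides are "
                         f"{sorted(sides[0])} and {sorted(sides[1])}")
    chains = sides[idx]
    sub = Structure(f"{structure.structure_id}:{''.join(sorted(chains))}")
    sub.residues = [r for r in structure.residues if r.chain_id in chains]
    if not sub.residues:
        raise DataError(f"partner side {sorted(chains)} has no residues")
    return sub


# ---------------------------------------------------------------------------
# Synthetic toy complexes

_FIXTURE_TYPES = ["LEU", "ARG", "TRP", "ASP", "SER", "PHE", "GLU", "LYS",
                  "TYR", "VAL", "ASN", "GLY", "ILE", "THR", "MET", "GLN"]


def _toy_residue(chain_id: str, seq: int, res_type: str, x: float, y: float,
                 z_plane: float, z_tip: float, rng: np.random.Generator) -> Residue:
    """A residue with a 4-atom backbone in the z=z_plane plane and (except
    glycine) a single CB pseudo side chain whose tip sits at ``z_tip``."""
    jx = float(rng.uniform(-0.1, 0.1))
    atoms = [
        Atom("N", "N", (x - 1.2 + jx, y + 0.4, z_plane)),
        Atom("CA", "C", (x, y, z_plane)),
        Atom("C", "C", (x + 1.2 + jx, y + 0.5, z_plane)),
        Atom("O", "O", (x + 1.3, y + 1.7, z_plane)),
    ]
    if res_type != "GLY":
        atoms.append(Atom("CB", "C", (x, y, z_tip)))
    for a in atoms:
        a.bfactor = float(rng.uniform(5.0, 40.0))
    return Residue(chain_id=chain_id, seq_number=seq, res_type=res_type, atoms=atoms)


def generate_fixture_complex(n_res_per_chain: int, interface_width: float,
                             seed: int) -> tuple[Structure, pd.DataFrame]:
    """Deterministic two-chain toy complex with known interface membership.

    Two roughly planar chains A and B face each other along z.  The first
    ``ceil(n/2)`` residue pairs carry CB tips exactly ``interface_width``
    apart; the remaining pairs are displaced by ±30 Å in y so they cannot
    occlude each other.  Returns the complex plus a truth table (chain,
    resnum, restype, is_interface, min_partner_distance) where a residue is
    interface by construction iff some cross-chain atom pair is closer than
    the solvent-probe occlusion reach.
    """
    if n_res_per_chain < 3:
        raise UsageError("n_res_per_chain must be >= 3")
    rng = np.random.default_rng(seed)
    n_close = (n_res_per_chain + 1) // 2
    struct = Structure(f"fixture-{seed}")
    zb = interface_width + 2.0  # backbone plane of chain B
    for i in range(n_res_per_chain):
        res_type = _FIXTURE_TYPES[int(rng.integers(len(_FIXTURE_TYPES)))]
        res_type_b = _FIXTURE_TYPES[int(rng.integers(len(_FIXTURE_TYPES)))]
        x = 3.8 * i + float(rng.uniform(-0.15, 0.15))
        y = float(rng.uniform(-0.15, 0.15))
        far = i >= n_close
        ya = y + (30.0 if far else 0.0)
        yb2 = y - (30.0 if far else 0.0)
        struct.residues.append(
            _toy_residue("A", i + 1, res_type, x, ya, 0.0, 1.0, rng))
        struct.residues.append(
            _toy_residue("B", i + 1, res_type_b, x, yb2, zb, zb - 1.0, rng))
    struct.residues.sort(key=lambda r: (r.chain_id, r.seq_number))
    struct.set_partner_split({"A"}, {"B"})

    probe = 1.4
    rows = []
    for res in struct.residues:
        other = [a for r in struct.residues if r.chain_id != res.chain_id
                 for a in r.atoms]
        best_gap = np.inf
        best_dist = np.inf
        for a in res.atoms:
            for b in other:
                d = float(np.linalg.norm(a.coord - b.coord))
                reach = VDW_RADII[a.element] + VDW_RADII[b.element] + 2 * probe
                best_gap = min(best_gap, d - reach)
                best_dist = min(best_dist, d)
        rows.append({"chain": res.chain_id, "resnum": res.seq_number,
                     "restype": res.res_type,
                     "is_interface": bool(best_gap < -0.5),
                     "min_partner_distance": round(best_dist, 4)})
    truth = pd.DataFrame(rows)
    return struct, truth
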