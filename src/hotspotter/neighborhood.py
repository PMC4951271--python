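"""Environment features of a target interface residue.

Hot spots tend to sit in tightly packed neighbourhoods, so the packing
around a residue's side chain is described at two heavy-atom distance
cutoffs (4.0 and 5.0 Å): neighbour residue/atom counts, polar/apolar and
backbone/side-chain splits, partner-side counts, neighbour B-factor and
hydrophobicity summaries — plus the side chain's own rotatable-bond counts
from a bundled per-residue-type table (single, acyclic, non-terminal heavy
bonds, CA–CB included).
"""

from __future__ import annotations

import functools
from importlib import resources

import numpy as np
import pandas as pd

from .errors import ConfigError
from .physchem import load_property_table
from .structures import Residue, Structure

CUTOFFS = (4.0, 5.0)

#: Per-cutoff feature stems, 15 per cutoff.
_PER_CUTOFF = [
    "n_res", "n_atoms", "env_hp", "n_polar_atoms", "n_nonpolar_atoms",
    "n_sc_atoms", "n_bb_atoms", "n_partner_atoms", "n_same_side_atoms",
    "mean_nb_bfactor", "max_nb_bfactor", "n_charged_res",
    "n_hydrophobic_res", "n_polar_res", "mean_nb_hp",
]

#: The 33-column neighbourhood feature group.
NEIGHBORHOOD_COLUMNS: list[str] = (
    [f"{stem}_{int(c)}A" for c in CUTOFFS for stem in _PER_CUTOFF]
    + ["n_rotatable_bonds", "weighted_rotatable_bonds", "n_sidechain_atoms"]
)


@functools.lru_cache(maxsize=1)
def load_rotatable_bond_table() -> pd.DataFrame:
    """Rotatable side-chain single bonds and side-chain heavy-atom counts."""
    src = resources.files("hotspotter.data").joinpath("rotatable_bonds.tsv")
    with src.open() as fh:
        return pd.read_csv(fh, sep="\t", index_col="res")


def count_rotatable_bonds(res_type: str) -> tuple[int, float]:
    """(count, count / side-chain heavy atoms); weighted count is 0 for Gly."""
    table = load_rotatable_bond_table()
    if res_type not in table.index:
        raise ConfigError(f"unknown residue type {res_type!r}")
    n = int(table.at[res_type, "n_rotatable"])
    n_side = int(table.at[res_type, "n_sidechain_atoms"])
    return n, (n / n_side if n_side else 0.0)


def _reference_atoms(target: Residue) -> list:
    """The target's side-chain atoms; CA stands in for glycine."""
    side = target.sidechain_atoms()
    if side:
        return side
    ca = target.get_atom("CA")
    return [ca] if ca is not None else list(target.atoms)


def find_neighbors(structure: Structure, target: Residue, cutoff: float):
    """Atoms (and their owning residues) within ``cutoff`` Å of the target
    side chain, excluding the target residue itself.

    Returns ``(neighbor_pairs, neighbor_residues)`` where ``neighbor_pairs``
    is a list of (residue, atom) and ``neighbor_residues`` preserves first-
    contact order.
    """
    refs = np.array([a.coord for a in _reference_atoms(target)])
    pairs = []
    residues = []
    for res in structure.residues:
        if res.key == target.key:
            continue
        hit = False
        for atom in res.atoms:
            d = np.linalg.norm(refs - atom.coord, axis=1).min()
            if d <= cutoff:
                pairs.append((res, atom))
                hit = True
        if hit:
            residues.append(res)
    return pairs, residues


def environment_hydrophobicity(structure: Structure, target: Residue,
                               cutoff: float,
                               property_table: pd.DataFrame | None = None) -> float:
    """Summed hydrophobicity of neighbour residues (each counted once)."""
    table = load_property_table() if property_table is None else property_table
    _, residues = find_neighbors(structure, target, cutoff)
    return float(sum(table.at[r.res_type, "hydrophobicity"] for r in residues))


def neighborhood_features(structure: Structure, target: Residue,
                          property_table: pd.DataFrame | None = None) -> dict[str, float]:
    """The 33-column neighbourhood group for one residue."""
    table = load_property_table() if property_table is None else property_table
    target_side = structure.side_of(target.chain_id)
    out: dict[str, float] = {}
    for cutoff in CUTOFFS:
        tag = f"{int(cutoff)}A"
        pairs, residues = find_neighbors(structure, target, cutoff)
        atoms = [a for _, a in pairs]
        bfactors = np.array([a.bfactor for a in atoms]) if atoms else np.empty(0)
        hps = np.array([table.at[r.res_type, "hydrophobicity"] for r in residues]) \
            if residues else np.empty(0)
        charges = [table.at[r.res_type, "charge"] for r in residues]
        hydrophil = [table.at[r.res_type, "hydrophilicity"] for r in residues]
        partner = [r for r, _ in pairs
                   if target_side is not None
                   and structure.side_of(r.chain_id) != target_side]
        out[f"n_res_{tag}"] = float(len(residues))
        out[f"n_atoms_{tag}"] = float(len(atoms))
        out[f"env_hp_{tag}"] = float(hps.sum())
        out[f"n_polar_atoms_{tag}"] = float(sum(a.element in ("N", "O") for a in atoms))
        out[f"n_nonpolar_atoms_{tag}"] = float(sum(a.element not in ("N", "O") for a in atoms))
        out[f"n_sc_atoms_{tag}"] = float(sum(a.is_sidechain for a in atoms))
        out[f"n_bb_atoms_{tag}"] = float(sum(not a.is_sidechain for a in atoms))
        out[f"n_partner_atoms_{tag}"] = float(len(partner))
        out[f"n_same_side_atoms_{tag}"] = float(len(atoms) - len(partner))
        out[f"mean_nb_bfactor_{tag}"] = float(bfactors.mean()) if len(bfactors) else 0.0
        out[f"max_nb_bfactor_{tag}"] = float(bfactors.max()) if len(bfactors) else 0.0
        out[f"n_charged_res_{tag}"] = float(sum(abs(c) > 0.5 for c in charges))
        out[f"n_hydrophobic_res_{tag}"] = float(sum(h > 0 for h in hps))
        out[f"n_polar_res_{tag}"] = float(sum(h > 0 for h in hydrophil))
        out[f"mean_nb_hp_{tag}"] = float(hps.mean()) if len(hps) else 0.0
    n_rot, weighted = count_rotatable_bonds(target.res_type)
    out["n_rotatable_bonds"] = float(n_rot)
    out["weighted_rotatable_bonds"] = float(weighted)
    out["n_sidechain_atoms"] = float(
        load_rotatable_bond_table().at[target.res_type, "n_sidechain_atoms"])
    return out
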