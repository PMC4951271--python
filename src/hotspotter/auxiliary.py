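"""The remaining per-residue descriptors: flexibility, pairing preference,
conservation and secondary structure.

Flexibility is the per-structure z-score of the residue's mean side-chain
B-factor.  The pairing preference of a residue is the sum, over partner-side
residues in heavy-atom contact, of a symmetric 20×20 residue-pair score
matrix (a deterministic synthetic stand-in matrix ships with the package).
Conservation scores (e.g. evolutionary rates) and DSSP secondary structure
are ingested from files, never computed here; missing values are flagged and
later imputed downstream.
"""

from __future__ import annotations

import functools
import logging
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.PDB.DSSP import make_dssp_dict

from .errors import ConfigError, DataError, ParseError, UsageError
from .structures import STANDARD_AA, Residue, Structure

log = logging.getLogger(__name__)

GROUP4_COLUMNS = ["pair_potential", "conservation", "bfactor_z"]

#: DSSP 8-state to 3-class collapse.
SS_CLASS = {"H": "helix", "G": "helix", "I": "helix", "E": "strand", "B": "strand"}


def normalized_bfactor(structure: Structure) -> pd.Series:
    """Per-residue B-factor z-scores (population SD over residue means).

    Each residue is summarised by the mean B of its side-chain atoms (all
    atoms for glycine); z-scores are taken across the structure.  Zero
    variance yields all-zero scores with a warning.
    """
    if len(structure.residues) < 2:
        raise UsageError("need >= 2 residues for B-factor normalization")
    means = {}
    for res in structure.residues:
        atoms = res.sidechain_atoms() or res.atoms
        means[res.key] = float(np.mean([a.bfactor for a in atoms]))
    values = pd.Series(means)
    sd = float(values.std(ddof=0))
    if sd == 0.0:
        log.warning("all residues share one B-factor; z-scores set to 0")
        return values * 0.0
    return (values - values.mean()) / sd


@functools.lru_cache(maxsize=4)
def load_pair_matrix(path: str | None = None) -> pd.DataFrame:
    """Symmetric 20×20 residue-pair preference matrix.

    The bundled default (``pair_preference_synthetic.tsv``) is a synthetic
    stand-in generated from hydrophobicity products and charge
    complementarity, not a matrix derived from real interface statistics;
    supply your own file to use empirical preferences.
    """
    if path is None:
        src = resources.files("hotspotter.data").joinpath("pair_preference_synthetic.tsv")
        with src.open() as fh:
            m = pd.read_csv(fh, sep="\t", index_col="res")
    else:
        m = pd.read_csv(Path(path), sep="\t", index_col="res")
    m = m.astype(float)
    if set(m.index) != set(STANDARD_AA) or set(m.columns) != set(STANDARD_AA):
        raise ConfigError("pair matrix must cover exactly the 20 standard residues")
    if not np.allclose(m.values, m.loc[m.columns, m.index].values.T):
        raise ConfigError("pair matrix must be symmetric")
    if not np.all(np.isfinite(m.values)):
        raise ConfigError("pair matrix contains non-finite entries")
    return m


def contacting_partner_residues(structure: Structure, target: Residue,
                                cutoff: float = 5.0) -> list[Residue]:
    """Partner-side residues with any heavy atom within ``cutoff`` of target."""
    side = structure.side_of(target.chain_id)
    if side is None:
        raise UsageError("pair potential requires a partner_split")
    tcoords = np.array([a.coord for a in target.atoms])
    out = []
    for res in structure.residues:
        if structure.side_of(res.chain_id) == side:
            continue
        for atom in res.atoms:
            if np.linalg.norm(tcoords - atom.coord, axis=1).min() <= cutoff:
                out.append(res)
                break
    return out


def pair_potential(structure: Structure, target: Residue,
                   matrix: pd.DataFrame | None = None,
                   cutoff: float = 5.0) -> float:
    """Contact-sum pairing preference of a residue across the interface."""
    matrix = load_pair_matrix() if matrix is None else matrix
    contacts = contacting_partner_residues(structure, target, cutoff)
    return float(sum(matrix.at[target.res_type, c.res_type] for c in contacts))


def ingest_conservation(path) -> dict[tuple[str, int], float]:
    """Read a tab-separated (chain, resnum, score) conservation file.

    Duplicate (chain, resnum) keys and malformed rows raise a
    :class:`ParseError` carrying the offending line number.
    """
    scores: dict[tuple[str, int], float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.lower().startswith("chain\t"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ParseError(f"expected 3 tab-separated fields, got {len(parts)}",
                                 line=lineno)
            try:
                key = (parts[0], int(parts[1]))
                value = float(parts[2])
            except ValueError as exc:
                raise ParseError(str(exc), line=lineno) from exc
            if key in scores:
                raise ParseError(f"duplicate residue key {key}", line=lineno)
            scores[key] = value
    return scores


def conservation_series(structure: Structure,
                        scores: dict[tuple[str, int], float] | None) -> pd.Series:
    """Attach conservation to every residue; absentees become NaN (flagged)."""
    scores = scores or {}
    values = {}
    n_missing = 0
    for res in structure.residues:
        v = scores.get((res.chain_id, res.seq_number))
        if v is None:
            n_missing += 1
            v = np.nan
        values[res.key] = v
    if n_missing:
        log.info("conservation missing for %d/%d residues (will be imputed)",
                 n_missing, len(structure.residues))
    return pd.Series(values)


def assign_secondary_structure(structure: Structure,
                               dssp_path=None) -> pd.Series:
    """Three-class secondary structure per residue from a DSSP output file.

    H/G/I collapse to helix, E/B to strand, everything else to coil.  With no
    DSSP file, every residue is assigned coil (flagged in the log).  Residues
    absent from the DSSP file fall back to coil with a reconciliation warning.
    """
    keys = [res.key for res in structure.residues]
    if dssp_path is None:
        log.warning("no DSSP file supplied; secondary structure set to coil")
        return pd.Series("coil", index=keys)
    dssp, _ = make_dssp_dict(str(dssp_path))
    out = {}
    n_missing = 0
    for res in structure.residues:
        entry = dssp.get((res.chain_id, (" ", res.seq_number, res.insertion_code or " ")))
        if entry is None:
            n_missing += 1
            out[res.key] = "coil"
        else:
            out[res.key] = SS_CLASS.get(entry[1], "coil")
    if n_missing:
        log.warning("%d residues absent from DSSP file; assigned coil", n_missing)
    return pd.Series(out)


def auxiliary_features(structure: Structure,
                       conservation: dict[tuple[str, int], float] | None = None,
                       pair_matrix: pd.DataFrame | None = None,
                       dssp_path=None,
                       contact_cutoff: float = 5.0) -> pd.DataFrame:
    """Group-4 feature columns (pair potential, conservation, B-factor
    z-score) plus the secondary-structure class carried as metadata."""
    if not structure.residues:
        raise DataError("empty structure")
    bz = normalized_bfactor(structure)
    cons = conservation_series(structure, conservation)
    ss = assign_secondary_structure(structure, dssp_path)
    pp = pd.Series({
        res.key: pair_potential(structure, res, pair_matrix, contact_cutoff)
        for res in structure.residues
    })
    table = pd.DataFrame({"pair_potential": pp, "conservation": cons,
                          "bfactor_z": bz, "ss_class": ss})
    table.index = pd.MultiIndex.from_tuples(table.index,
                                            names=["chain", "resnum", "icode"])
    return table
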