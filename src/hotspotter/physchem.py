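"""Per-residue physicochemical encodings.

Sixteen base amino-acid properties are looked up from a bundled,
user-overridable table (hydrophobicity on the Fauchère–Pliska scale,
Hopp–Woods hydrophilicity, isoelectric point, residue mass, 14 Å contact
number, EIIP, formal charge, and nine further published indices), plus two
derived hydrophobicity variants:

* PSHP (pseudo hydrophobicity): the hydrophobicity, multiplied by the formal
  charge (−1) for the negatively charged residues Asp and Glu, unchanged for
  every other residue type.
* CHP: the same sign flip extended to all four charged residue types
  (Asp, Glu, Lys, Arg).
"""

from __future__ import annotations

import functools
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from .structures import STANDARD_AA

NEGATIVE_RESIDUES = frozenset({"ASP", "GLU"})
CHARGED_RESIDUES = frozenset({"ASP", "GLU", "LYS", "ARG"})

#: The canonical 16 base property columns (order defines the feature layout).
PROPERTY_NAMES = [
    "hydrophobicity", "hydrophilicity", "isoelectric_point", "mass",
    "contacts_14A", "eiip", "charge", "volume", "polarity", "flexibility",
    "helix_propensity", "sheet_propensity", "turn_propensity",
    "polarizability", "buriedness", "steric_parameter",
]


@functools.lru_cache(maxsize=4)
def load_property_table(path: str | None = None) -> pd.DataFrame:
    """The 20×16 property table (rows: three-letter residue codes)."""
    if path is None:
        src = resources.files("hotspotter.data").joinpath("aa_properties.tsv")
        with src.open() as fh:
            table = pd.read_csv(fh, sep="\t", index_col="res")
    else:
        table = pd.read_csv(Path(path), sep="\t", index_col="res")
    missing = set(STANDARD_AA) - set(table.index)
    if missing:
        raise ConfigError(f"property table lacks residues: {sorted(missing)}")
    lacking = [c for c in PROPERTY_NAMES if c not in table.columns]
    if lacking:
        raise ConfigError(f"property table lacks columns: {lacking}")
    return table[PROPERTY_NAMES].astype(float)


def lookup_properties(res_type: str, table: pd.DataFrame | None = None) -> pd.Series:
    """The 16-vector of base properties for one residue type."""
    table = load_property_table() if table is None else table
    if res_type not in table.index:
        raise ConfigError(f"unknown residue type {res_type!r}")
    return table.loc[res_type]


def compute_pshp(res_type: str, table: pd.DataFrame | None = None) -> float:
    """Pseudo hydrophobicity: HP × charge for Asp/Glu, HP otherwise."""
    hp = float(lookup_properties(res_type, table)["hydrophobicity"])
    return -hp if res_type in NEGATIVE_RESIDUES else hp


def compute_chp(res_type: str, table: pd.DataFrame | None = None) -> float:
    """Charge-flipped hydrophobicity: −HP for Asp/Glu/Lys/Arg, HP otherwise."""
    hp = float(lookup_properties(res_type, table)["hydrophobicity"])
    return -hp if res_type in CHARGED_RESIDUES else hp


#: Column layout of the physicochemical feature group (16 base + PSHP = 17).
PHYSCHEM_COLUMNS: list[str] = PROPERTY_NAMES + ["pshp"]


def physchem_features(res_type: str, table: pd.DataFrame | None = None) -> dict[str, float]:
    """The 17-column physicochemical group for one residue."""
    props = lookup_properties(res_type, table)
    out = {name: float(props[name]) for name in PROPERTY_NAMES}
    out["pshp"] = compute_pshp(res_type, table)
    return out
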