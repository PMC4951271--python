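"""Solvent accessibility and shape descriptors of interface residues.

Implements the structural feature group: Shrake–Rupley accessible surface
area on a deterministic Fibonacci-spiral point lattice, relative ASA against
bundled per-residue reference maxima, the protrusion index (ratio of empty to
occupied volume in a 10 Å sphere around each heavy atom), the depth index
(distance to the nearest solvent-exposed atom), interface detection by ASA
loss upon binding, support/core/rim position classes, and the bound/unbound
relative changes — including the relative change in total mean protrusion
index (RctmPI), the shape feature hot spots are enriched in.

All geometry is deterministic: the same structure and configuration produce
bit-identical output.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import ConfigError, DataError, DegenerateStructureError
from .structures import Structure, VDW_RADII, extract_partner

POSITION_CLASSES = ("support", "core", "rim")
POSITION_CODE = {name: i for i, name in enumerate(POSITION_CLASSES)}

#: Polar heavy elements (sulfur is counted apolar by convention).
POLAR_ELEMENTS = {"N", "O"}


@dataclass(frozen=True)
class GeometryConfig:
    probe_radius: float = 1.4          # Å, water probe
    n_points: int = 960                # lattice points per atom sphere
    vdw_radii: dict = field(default_factory=lambda: dict(VDW_RADII))
    pi_sphere_radius: float = 10.0     # Å, protrusion-index sphere
    pi_atom_volume: float = 20.1       # Å^3, mean heavy-atom volume
    di_exposure_threshold: float = 1.0  # Å^2, ASA above which an atom is exposed
    interface_tolerance: float = 1e-6  # Å^2, strict-positivity tolerance for ΔASA
    rasa_low: float = 0.25             # RASA threshold for support/core/rim


DEFAULT_CONFIG = GeometryConfig()


@functools.lru_cache(maxsize=8)
def _sphere_lattice(n_points: int) -> np.ndarray:
    """Deterministic Fibonacci-spiral lattice of ``n_points`` unit vectors."""
    i = np.arange(n_points, dtype=float)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    z = 1.0 - 2.0 * (i + 0.5) / n_points
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    theta = golden * i
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def _radii(structure: Structure, config: GeometryConfig) -> np.ndarray:
    out = []
    for res, atom in structure.atoms():
        try:
            out.append(config.vdw_radii[atom.element])
        except KeyError:
            raise ConfigError(
                f"no van der Waals radius configured for element "
                f"{atom.element!r} (atom {atom.name} of {res.res_type} "
                f"{res.chain_id}{res.seq_number})"
            ) from None
    return np.asarray(out)


def compute_asa(structure: Structure, config: GeometryConfig = DEFAULT_CONFIG) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Å**2), Shrake–Rupley style.

    Each atom's sphere of radius r_vdw + probe is sampled on a fixed
    Fibonacci lattice; a sample point is accessible when it lies outside
    every other atom's expanded sphere.
    """
    if config.n_points < 100:
        raise ConfigError("n_points must be >= 100 for a usable lattice")
    coords = structure.coords()
    n = len(coords)
    if n == 0:
        return np.empty(0)
    radii = _radii(structure, config) + config.probe_radius
    lattice = _sphere_lattice(config.n_points)
    tree = cKDTree(coords)
    rmax = radii.max()
    asa = np.empty(n)
    for i in range(n):
        pts = coords[i] + radii[i] * lattice
        accessible = np.ones(config.n_points, dtype=bool)
        for j in tree.query_ball_point(coords[i], radii[i] + rmax):
            if j == i:
                continue
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            accessible &= d2 > radii[j] ** 2
        asa[i] = accessible.mean() * 4.0 * np.pi * radii[i] ** 2
    return asa


def compute_protrusion_index(structure: Structure,
                             config: GeometryConfig = DEFAULT_CONFIG) -> np.ndarray:
    """Per-atom protrusion index: empty/occupied volume in a fixed sphere.

    The occupied volume is the count of heavy-atom centres inside the sphere
    (the atom itself included) times the mean atom volume; an isolated atom
    with default constants therefore scores (4/3)π·10³/20.1 − 1 ≈ 207.4.
    """
    coords = structure.coords()
    sphere_volume = 4.0 / 3.0 * np.pi * config.pi_sphere_radius ** 3
    tree = cKDTree(coords)
    counts = np.array([len(tree.query_ball_point(c, config.pi_sphere_radius))
                       for c in coords], dtype=float)
    v_int = counts * config.pi_atom_volume
    v_ext = np.maximum(sphere_volume - v_int, 0.0)
    return v_ext / v_int


def compute_depth_index(structure: Structure, asa: np.ndarray,
                        config: GeometryConfig = DEFAULT_CONFIG) -> np.ndarray:
    """Per-atom depth index: distance (Å) to the nearest solvent-exposed atom.

    Atoms whose own ASA exceeds the exposure threshold have depth 0.
    """
    coords = structure.coords()
    exposed = asa > config.di_exposure_threshold
    if not exposed.any():
        raise DegenerateStructureError(
            "no atom exceeds the exposure threshold; depth index undefined")
    di = np.zeros(len(coords))
    buried = ~exposed
    if buried.any():
        tree = cKDTree(coords[exposed])
        di[buried], _ = tree.query(coords[buried])
    return di


@dataclass
class SurfaceProfile:
    """Per-residue aggregates of ASA/RASA and depth/protrusion indices."""

    table: pd.DataFrame            # indexed by (chain, resnum, icode)
    atom_asa: np.ndarray
    atom_pi: np.ndarray
    atom_di: np.ndarray


ASA_CLASSES = ("total", "backbone", "sidechain", "polar", "nonpolar")
SHAPE_AGGREGATES = ("total_mean", "sidechain_mean", "max", "min")


@functools.lru_cache(maxsize=1)
def load_reference_areas() -> pd.DataFrame:
    """Reference maximal ASA (Å**2) per residue type and aggregate class."""
    with resources.files("hotspotter.data").joinpath("reference_asa.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", index_col="res")


def compute_rasa(asa_row: pd.Series, res_type: str,
                 reference: pd.DataFrame | None = None) -> dict[str, float]:
    """Relative ASA per aggregate class; glycine's side-chain class is 0."""
    reference = load_reference_areas() if reference is None else reference
    if res_type not in reference.index:
        raise ConfigError(f"no reference area for residue type {res_type!r}")
    out = {}
    for cls in ASA_CLASSES:
        if cls == "sidechain" and res_type == "GLY":
            out["rasa_sidechain"] = 0.0
            continue
        out[f"rasa_{cls}"] = float(asa_row[f"asa_{cls}"] / reference.at[res_type, cls])
    return out


def _aggregate(values: np.ndarray, sidechain_mask: np.ndarray,
               ca_index: int | None) -> dict[str, float]:
    side = values[sidechain_mask]
    if side.size == 0:  # glycine: CA stands in for the side chain
        side = values[[ca_index]] if ca_index is not None else values
    return {"total_mean": float(values.mean()),
            "sidechain_mean": float(side.mean()),
            "max": float(values.max()),
            "min": float(values.min())}


def compute_surface_profile(structure: Structure,
                            config: GeometryConfig = DEFAULT_CONFIG,
                            with_depth: bool = True) -> SurfaceProfile:
    """All per-residue surface descriptors for one structure."""
    if not structure.residues:
        raise DataError("empty structure")
    asa = compute_asa(structure, config)
    pi = compute_protrusion_index(structure, config)
    try:
        di = compute_depth_index(structure, asa, config) if with_depth else np.zeros_like(asa)
    except DegenerateStructureError:
        di = np.full_like(asa, np.nan)

    rows = {}
    offset = 0
    for res in structure.residues:
        k = len(res.atoms)
        sl = slice(offset, offset + k)
        offset += k
        a = asa[sl]
        side = np.array([atom.is_sidechain for atom in res.atoms])
        polar = np.array([atom.element in POLAR_ELEMENTS for atom in res.atoms])
        ca_idx = next((i for i, atom in enumerate(res.atoms) if atom.name == "CA"), None)
        row = {
            "res_type": res.res_type,
            "asa_total": float(a.sum()),
            "asa_backbone": float(a[~side].sum()),
            "asa_sidechain": float(a[side].sum()),
            "asa_polar": float(a[polar].sum()),
            "asa_nonpolar": float(a[~polar].sum()),
        }
        row.update(compute_rasa(pd.Series(row), res.res_type))
        for name, values in (("di", di[sl]), ("pi", pi[sl])):
            for agg, v in _aggregate(values, side, ca_idx).items():
                row[f"{name}_{agg}"] = v
        rows[res.key] = row
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index = pd.MultiIndex.from_tuples(table.index, names=["chain", "resnum", "icode"])
    return SurfaceProfile(table=table, atom_asa=asa, atom_pi=pi, atom_di=di)


def binding_deltas(unbound: pd.DataFrame, bound: pd.DataFrame) -> pd.DataFrame:
    """Relative change (unbound − bound)/unbound per aggregate.

    Burial upon binding yields positive values.  Rows where the unbound value
    is zero get a relative change of 0 and are flagged in ``relchange_flagged``.
    The protrusion column ``pi_total_mean_relchange`` is RctmPI.
    """
    numeric = [c for c in unbound.columns if c != "res_type"]
    unb = unbound[numeric].astype(float)
    bnd = bound.loc[unbound.index, numeric].astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = (unb - bnd) / unb
    flagged = (unb == 0).any(axis=1)
    rel = rel.where(unb != 0, 0.0).fillna(0.0)
    rel.columns = [f"{c}_relchange" for c in numeric]
    rel["relchange_flagged"] = flagged
    return rel


def classify_position(rasa_bound: float, rasa_unbound: float,
                      r_low: float = DEFAULT_CONFIG.rasa_low) -> str:
    """Support/core/rim position of an interface residue.

    Support: buried even before binding; core: exposed when unbound but
    buried in the complex; rim: stays exposed.
    """
    if rasa_unbound < r_low:
        return "support"
    if rasa_bound < r_low:
        return "core"
    return "rim"


def detect_interface(complex_structure: Structure,
                     config: GeometryConfig = DEFAULT_CONFIG) -> pd.DataFrame:
    """Interface annotation from ASA loss between unbound chains and complex.

    Unbound states are rigid chain-group extractions.  A residue is interface
    iff its total ASA drops by more than the (near-zero) tolerance.
    """
    bound = compute_surface_profile(complex_structure, config, with_depth=False)
    parts = [compute_surface_profile(extract_partner(complex_structure, i),
                                     config, with_depth=False)
             for i in (0, 1)]
    unbound = pd.concat([p.table for p in parts]).loc[bound.table.index]
    dasa = unbound["asa_total"] - bound.table["asa_total"]
    out = pd.DataFrame({
        "dasa": dasa,
        "is_interface": dasa > config.interface_tolerance,
        "position_class": [
            classify_position(b, u, config.rasa_low)
            for b, u in zip(bound.table["rasa_total"], unbound["rasa_total"])
        ],
    }, index=bound.table.index)
    return out


def structural_features(complex_structure: Structure,
                        config: GeometryConfig = DEFAULT_CONFIG) -> pd.DataFrame:
    """The 55-column structural feature group for every residue of a complex.

    Columns: {asa,rasa} × {total,backbone,sidechain,polar,nonpolar} ×
    {unbound,bound,relchange} (30), {di,pi} × {total_mean,sidechain_mean,
    max,min} × {unbound,bound,relchange} (24), and the numeric position
    class (support=0, core=1, rim=2).
    """
    bound = compute_surface_profile(complex_structure, config)
    parts = [compute_surface_profile(extract_partner(complex_structure, i), config)
             for i in (0, 1)]
    unbound = pd.concat([p.table for p in parts]).loc[bound.table.index]
    rel = binding_deltas(unbound, bound.table)

    base = [f"{m}_{cls}" for m in ("asa", "rasa") for cls in ASA_CLASSES]
    base += [f"{m}_{agg}" for m in ("di", "pi") for agg in SHAPE_AGGREGATES]
    out = {}
    for col in base:
        out[f"{col}_unbound"] = unbound[col]
        out[f"{col}_bound"] = bound.table[col]
        out[f"{col}_relchange"] = rel[f"{col}_relchange"]
    table = pd.DataFrame(out, index=bound.table.index)
    table["position_class"] = [
        POSITION_CODE[classify_position(b, u, config.rasa_low)]
        for b, u in zip(bound.table["rasa_total"], unbound["rasa_total"])
    ]
    return table


STRUCTURAL_COLUMNS: list[str] = (
    [f"{m}_{cls}_{state}" for m in ("asa", "rasa") for cls in ASA_CLASSES
     for state in ("unbound", "bound", "relchange")]
    + [f"{m}_{agg}_{state}" for m in ("di", "pi") for agg in SHAPE_AGGREGATES
       for state in ("unbound", "bound", "relchange")]
    + ["position_class"]
)
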