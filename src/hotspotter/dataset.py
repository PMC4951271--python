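"""Labelled datasets: alanine-scanning annotations joined to computed features.

An interface residue is a *hot spot* when mutating it to alanine raises the
binding free energy by at least 2.0 kcal/mol; residues below 0.4 kcal/mol
are non-hot spots, and the 0.4–2.0 band is excluded to sharpen the contrast.
Categorical annotations (strong/intermediate/weak/insignificant) map
"strong" to hot and everything else to non-hot.

The feature matrix carries 108 named columns in four groups:
17 physicochemical, 55 structural, 33 neighbourhood, 3 other.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import auxiliary, neighborhood, physchem, surface_geometry
from .errors import ParseError, SchemaError, UsageError
from .structures import Structure

log = logging.getLogger(__name__)

HOT, NONHOT, EXCLUDED = "hot", "nonhot", "excluded"
DDG_HOT_THRESHOLD = 2.0     # kcal/mol, inclusive
DDG_NONHOT_THRESHOLD = 0.4  # kcal/mol, exclusive
CATEGORIES = ("strong", "intermediate", "weak", "insignificant")

FEATURE_GROUPS: dict[str, list[str]] = {
    "physicochemical": list(physchem.PHYSCHEM_COLUMNS),       # 17
    "structural": list(surface_geometry.STRUCTURAL_COLUMNS),  # 55
    "neighborhood": list(neighborhood.NEIGHBORHOOD_COLUMNS),  # 33
    "other": list(auxiliary.GROUP4_COLUMNS),                  # 3
}

#: The canonical 108 feature columns, in group order.
FEATURE_COLUMNS: list[str] = [c for cols in FEATURE_GROUPS.values() for c in cols]


def assign_label_ddg(ddg: float) -> str:
    """Hot iff ΔΔG ≥ 2.0 kcal/mol; non-hot iff < 0.4; excluded in between."""
    try:
        ddg = float(ddg)
    except (TypeError, ValueError) as exc:
        raise ParseError(f"non-numeric ΔΔG value {ddg!r}") from exc
    if not np.isfinite(ddg):
        raise ParseError(f"non-finite ΔΔG value {ddg!r}")
    if ddg >= DDG_HOT_THRESHOLD:
        return HOT
    if ddg < DDG_NONHOT_THRESHOLD:
        return NONHOT
    return EXCLUDED


def assign_label_category(category: str) -> str:
    """'strong' is hot; the other three categories are non-hot."""
    category = category.strip().lower()
    if category not in CATEGORIES:
        raise ParseError(f"unknown mutation-strength category {category!r}")
    return HOT if category == "strong" else NONHOT


@dataclass
class MutationRecord:
    structure_id: str
    chain: str
    resnum: int
    res_type: str
    ddg: float | None = None
    category: str | None = None

    def __post_init__(self):
        if (self.ddg is None) == (self.category is None):
            raise UsageError("exactly one of ddg / category must be given")

    def label(self) -> str:
        if self.ddg is not None:
            return assign_label_ddg(self.ddg)
        return assign_label_category(self.category)


def read_mutation_table(path) -> list[MutationRecord]:
    """Tab-separated annotations: structure_id, chain, resnum, res_type,
    and either a numeric ΔΔG or a strength category in the last field."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.lower().startswith("structure_id"):
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise ParseError(f"expected 5 fields, got {len(parts)}", line=lineno)
            sid, chain, resnum, res_type, value = parts
            try:
                resnum = int(resnum)
            except ValueError as exc:
                raise ParseError(f"bad residue number {resnum!r}", line=lineno) from exc
            try:
                records.append(MutationRecord(sid, chain, resnum, res_type.upper(),
                                              ddg=float(value)))
            except ValueError:
                records.append(MutationRecord(sid, chain, resnum, res_type.upper(),
                                              category=value))
    return records


@dataclass
class LabeledDataset:
    """Feature matrix, hot/non-hot labels, and per-row provenance."""

    features: pd.DataFrame
    labels: pd.Series
    provenance: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if list(self.features.index) != list(self.labels.index):
            raise UsageError("features and labels must share an index")
        if self.features.columns.duplicated().any():
            raise UsageError("duplicate feature columns")

    @property
    def y(self) -> np.ndarray:
        return (self.labels == HOT).to_numpy()

    def __len__(self) -> int:
        return len(self.labels)


def compute_residue_features(structure: Structure,
                             config: surface_geometry.GeometryConfig = surface_geometry.DEFAULT_CONFIG,
                             conservation=None, dssp_path=None) -> pd.DataFrame:
    """All 108 features for every residue of one complex."""
    struct_feats = surface_geometry.structural_features(structure, config)
    aux = auxiliary.auxiliary_features(structure, conservation=conservation,
                                       dssp_path=dssp_path)
    prop_table = physchem.load_property_table()
    rows = {}
    for res in structure.residues:
        row = physchem.physchem_features(res.res_type, prop_table)
        row.update(neighborhood.neighborhood_features(structure, res, prop_table))
        rows[res.key] = row
    per_res = pd.DataFrame.from_dict(rows, orient="index")
    per_res.index = pd.MultiIndex.from_tuples(per_res.index,
                                              names=["chain", "resnum", "icode"])
    out = pd.concat([per_res, struct_feats, aux], axis=1)
    return out[FEATURE_COLUMNS + ["ss_class"]]


def build_feature_table(complexes: dict[str, Structure],
                        records: list[MutationRecord],
                        config: surface_geometry.GeometryConfig = surface_geometry.DEFAULT_CONFIG,
                        conservation: dict | None = None,
                        dssp_paths: dict | None = None) -> LabeledDataset:
    """Join mutation records to computed features.

    Excluded-band records are dropped; records that do not resolve to a
    residue are skipped and reported; records resolving to non-interface
    residues are kept with a warning.
    """
    feature_cache: dict[str, pd.DataFrame] = {}
    interface_cache: dict[str, pd.DataFrame] = {}
    rows, labels, prov, errors = [], [], [], []
    for rec in records:
        label = rec.label()
        if label == EXCLUDED:
            continue
        if rec.structure_id not in complexes:
            errors.append((rec, "unknown structure id"))
            continue
        structure = complexes[rec.structure_id]
        if rec.structure_id not in feature_cache:
            feature_cache[rec.structure_id] = compute_residue_features(
                structure, config,
                conservation=(conservation or {}).get(rec.structure_id),
                dssp_path=(dssp_paths or {}).get(rec.structure_id))
            interface_cache[rec.structure_id] = surface_geometry.detect_interface(
                structure, config)
        key = (rec.chain, rec.resnum, "")
        table = feature_cache[rec.structure_id]
        if key not in table.index:
            errors.append((rec, "residue not found in structure"))
            continue
        if not interface_cache[rec.structure_id].at[key, "is_interface"]:
            log.warning("record %s %s%d is not an interface residue; kept",
                        rec.structure_id, rec.chain, rec.resnum)
        rows.append(table.loc[key, FEATURE_COLUMNS])
        labels.append(label)
        prov.append({"structure_id": rec.structure_id, "chain": rec.chain,
                     "resnum": rec.resnum, "res_type": rec.res_type})
    if errors:
        for rec, why in errors:
            log.error("skipped record %s %s%d: %s",
                      rec.structure_id, rec.chain, rec.resnum, why)
    features = pd.DataFrame(rows).reset_index(drop=True).astype(float)
    imputed = [c for c in features.columns if features[c].isna().any()]
    if imputed:
        log.info("median-imputing missing values in: %s", imputed)
        features = features.fillna(features.median().fillna(0.0))
    return LabeledDataset(
        features=features,
        labels=pd.Series(labels, name="label"),
        provenance=pd.DataFrame(prov),
        metadata={"n_skipped": len(errors),
                  "skipped": [f"{r.structure_id}:{r.chain}{r.resnum} ({why})"
                              for r, why in errors]},
    )


# ---------------------------------------------------------------------------
# Scaling / imputation (fitted on training data only; frozen into the model)

@dataclass
class ColumnTransform:
    """Median imputation followed by min–max scaling to [0, 1]."""

    medians: pd.Series
    mins: pd.Series
    maxs: pd.Series

    @classmethod
    def fit(cls, features: pd.DataFrame) -> "ColumnTransform":
        medians = features.median()
        # a column that is all-NaN imputes to 0
        medians = medians.fillna(0.0)
        filled = features.fillna(medians)
        return cls(medians=medians, mins=filled.min(), maxs=filled.max())

    def apply(self, features: pd.DataFrame) -> pd.DataFrame:
        missing = [c for c in self.medians.index if c not in features.columns]
        if missing:
            raise SchemaError(f"feature table lacks columns: {missing}")
        x = features[self.medians.index].fillna(self.medians)
        span = (self.maxs - self.mins).replace(0.0, 1.0)
        return ((x - self.mins) / span).clip(0.0, 1.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"median": self.medians, "min": self.mins,
                             "max": self.maxs})

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ColumnTransform":
        return cls(medians=frame["median"], mins=frame["min"], maxs=frame["max"])


# ---------------------------------------------------------------------------
# Table IO

def write_table(dataset: LabeledDataset, path) -> None:
    """Master feature table as TSV: provenance, label, then 108 features."""
    out = pd.concat([dataset.provenance.reset_index(drop=True),
                     dataset.labels.reset_index(drop=True),
                     dataset.features.reset_index(drop=True)], axis=1)
    out.to_csv(path, sep="\t", index=False)


def read_table(path) -> LabeledDataset:
    df = pd.read_csv(path, sep="\t")
    prov_cols = [c for c in ("structure_id", "chain", "resnum", "res_type")
                 if c in df.columns]
    missing = [c for c in FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"table lacks feature columns: {missing[:5]}...")
    return LabeledDataset(features=df[FEATURE_COLUMNS].astype(float),
                          labels=df["label"],
                          provenance=df[prov_cols])
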