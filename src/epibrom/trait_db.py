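"""Species × trait tables: I/O, validation and derived-trait computation.

The central object is :class:`TraitTable`, a species × trait grid with a
missingness mask (encoded as NaN), per-species genus annotation and a
per-cell provenance tag separating measured values from literature,
herbarium, allometrically derived and imputed ones.

Derived traits follow the allometric conventions for Bromeliaceae leaves:
leaf area from the near-triangular/rectangular leaf outline,
LA = LW·LL / 1.5, and tank water-holding capacity from leaf area via a
quadratic fit, TC = 0.0041·LA² + 1.929·LA − 22.285 (clamped at 0 mL).
The photosynthetic pathway is called from the leaf carbon isotope
signature: δ13C ≥ −20 ‰ is read as CAM, more negative values as C3.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .registry import TraitDefinition, default_registry, validate_registry

__all__ = [
    "TraitTable",
    "PathwayCall",
    "read_trait_table",
    "write_trait_table",
    "drop_sparse_species",
    "estimate_leaf_area",
    "estimate_tank_capacity",
    "call_pathway",
    "fill_derived_traits",
]

PROVENANCE_TAGS = (
    "measured", "literature", "herbarium", "derived",
    "imputed_phylo", "imputed_genus",
)

#: Auxiliary boolean columns recognised in trait CSVs but not part of the
#: trait registry: morphological flags used by the rule classifier.
AUX_COLUMNS = ("tankless", "acicular")

# Tank-capacity polynomial in leaf area (cm² -> mL).
_TC_A, _TC_B, _TC_C = 0.0041, 1.929, -22.285
# Leaf-shape divisor: bromeliad leaves sit between a triangle (2) and a
# rectangle (1).
_LA_DIVISOR = 1.5
# Pathway threshold on δ13C (‰): at or above -> CAM.
PATHWAY_THRESHOLD = -20.0


@dataclass(frozen=True)
class PathwayCall:
    """Photosynthetic-pathway call for one species."""

    label: str  # "C3" | "CAM"
    source: str = "measured-threshold"  # or "assigned"

    def __post_init__(self) -> None:
        if self.label not in ("C3", "CAM"):
            raise ValueError(f"invalid pathway label {self.label!r}")


@dataclass
class TraitTable:
    """Species × trait matrix with genus annotation and cell provenance.

    ``values`` is a float DataFrame (species index × trait abbreviation
    columns; NaN = missing).  ``provenance`` mirrors ``values`` with a tag
    per non-missing cell (empty string where missing).  ``genus`` maps each
    species to its genus.  ``flags`` holds optional boolean morphology
    columns (``tankless``, ``acicular``).
    """

    values: pd.DataFrame
    genus: pd.Series
    registry: list[TraitDefinition] = field(default_factory=default_registry)
    provenance: Optional[pd.DataFrame] = None
    flags: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        if self.provenance is None:
            prov = pd.DataFrame("", index=self.values.index,
                                columns=self.values.columns, dtype=object)
            prov[self.values.notna()] = "measured"
            self.provenance = prov
        if self.flags is None:
            self.flags = pd.DataFrame(index=self.values.index)
        for obj in (self.values, self.provenance, self.flags):
            obj.index.name = "species"
        self.genus.index.name = "species"
        self.validate()

    # -- invariants ---------------------------------------------------
    def validate(self) -> None:
        validate_registry(self.registry)
        idx = self.values.index
        if idx.duplicated().any():
            dup = sorted(idx[idx.duplicated()].unique())
            raise ValueError(f"duplicated species identifier(s): {dup}")
        if not self.genus.index.equals(idx):
            raise ValueError("genus annotation does not match species index")
        vals = self.values.to_numpy(dtype=float)
        if np.isinf(vals).any():
            raise ValueError("non-finite trait value present")
        # range invariants: phylo-imputed cells are exempt — they may sit
        # outside the physical range until the rejection stage reverts them
        if self.provenance is not None:
            checkable = self.provenance != "imputed_phylo"
        else:
            checkable = pd.DataFrame(True, index=self.values.index,
                                     columns=self.values.columns)
        for col, lower in (("TC", 0.0), ("TD", 0.0), ("SD", 0.0)):
            if col in self.values:
                bad_mask = (self.values[col] < lower) & checkable[col]
                if bad_mask.any():
                    bad = self.values.index[bad_mask].tolist()
                    raise ValueError(f"{col} < {lower} for {bad}")
        if "LI" in self.values:
            bad_mask = (self.values["LI"] <= 0) & checkable["LI"]
            if bad_mask.any():
                bad = self.values.index[bad_mask].tolist()
                raise ValueError(
                    f"LI must be positive; offending species {bad}")
        binary = [d.abbreviation for d in self.registry
                  if d.kind == "binary" and d.abbreviation in self.values]
        for col in binary:
            vals = self.values[col].dropna()
            if not vals.isin([0.0, 1.0]).all():
                raise ValueError(f"binary trait {col} has non-0/1 values")

    # -- conveniences -------------------------------------------------
    @property
    def species(self) -> list[str]:
        return list(self.values.index)

    @property
    def trait_names(self) -> list[str]:
        return list(self.values.columns)

    def n_missing(self) -> int:
        return int(self.values.isna().sum().sum())

    def copy(self) -> "TraitTable":
        return TraitTable(self.values.copy(), self.genus.copy(),
                          list(self.registry), self.provenance.copy(),
                          self.flags.copy())

    def subset_traits(self, traits: Sequence[str]) -> "TraitTable":
        traits = [t for t in traits if t in self.values.columns]
        return TraitTable(self.values[traits].copy(), self.genus.copy(),
                          list(self.registry), self.provenance[traits].copy(),
                          self.flags.copy())

    def subset_species(self, species: Iterable[str]) -> "TraitTable":
        species = [s for s in species if s in self.values.index]
        return TraitTable(self.values.loc[species].copy(),
                          self.genus.loc[species].copy(),
                          list(self.registry),
                          self.provenance.loc[species].copy(),
                          self.flags.loc[species].copy())


# ---------------------------------------------------------------------------
# I/O

def read_trait_table(path, registry: Optional[list[TraitDefinition]] = None,
                     provenance_path=None) -> TraitTable:
    """Read a trait CSV (``species,genus,<abbrev>,...``; empty cell = missing).

    Columns not in the registry (other than the recognised morphology
    flags) are reported via a ``UserWarning`` and ignored.  Duplicate
    species rows and non-numeric cells in continuous traits raise
    ``ValueError`` naming the offender.
    """
    import warnings

    reg = registry if registry is not None else default_registry()
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "species" not in raw.columns or "genus" not in raw.columns:
        raise ValueError("trait CSV must have 'species' and 'genus' columns")
    dup = raw["species"][raw["species"].duplicated()]
    if not dup.empty:
        raise ValueError(f"duplicate species row(s): {sorted(dup.unique())}")
    raw = raw.set_index("species")

    known = {d.abbreviation for d in reg}
    unknown = [c for c in raw.columns
               if c not in known and c != "genus" and c not in AUX_COLUMNS]
    if unknown:
        warnings.warn(f"ignoring unknown trait column(s): {unknown}")

    trait_cols = [d.abbreviation for d in reg if d.abbreviation in raw.columns]
    values = pd.DataFrame(index=raw.index, columns=trait_cols, dtype=float)
    for col in trait_cols:
        for sp, cell in raw[col].items():
            if cell == "":
                continue
            try:
                values.loc[sp, col] = float(cell)
            except ValueError:
                raise ValueError(
                    f"non-numeric value {cell!r} for species {sp!r}, "
                    f"trait {col!r}") from None

    flags = pd.DataFrame(index=raw.index)
    for col in AUX_COLUMNS:
        if col in raw.columns:
            flags[col] = raw[col].map(
                lambda c: bool(int(c)) if c != "" else False)

    prov = None
    if provenance_path is not None:
        prov = pd.read_csv(provenance_path, dtype=str, keep_default_na=False)
        prov = prov.set_index("species")[trait_cols]
        prov = prov.where(values.notna(), "")
    return TraitTable(values, raw["genus"], reg, prov, flags)


def write_trait_table(t: TraitTable, path, provenance_path=None) -> None:
    """Write a trait table as CSV, columns in registry order."""
    ordered = [d.abbreviation for d in t.registry
               if d.abbreviation in t.values.columns]
    out = t.values[ordered].copy()
    out.insert(0, "genus", t.genus)
    for col in t.flags.columns:
        out[col] = t.flags[col].astype(int)
    out.index.name = "species"
    out.to_csv(path, float_format="%.10g")
    if provenance_path is not None:
        prov = t.provenance[ordered].copy()
        prov.index.name = "species"
        prov.to_csv(provenance_path)


# ---------------------------------------------------------------------------
# Filtering

def drop_sparse_species(t: TraitTable, min_traits: int = 5
                        ) -> tuple[TraitTable, list[str]]:
    """Remove species with fewer than ``min_traits`` non-missing traits.

    Returns the filtered table and the list of removed species.
    """
    counts = t.values.notna().sum(axis=1)
    removed = list(t.values.index[counts < min_traits])
    kept = t.subset_species(t.values.index[counts >= min_traits])
    return kept, removed


# ---------------------------------------------------------------------------
# Allometric estimators and pathway call

def estimate_leaf_area(LW: float, LL: float) -> float:
    """Leaf area (cm²) from maximal leaf width and leaf length (cm)."""
    if LW <= 0 or LL <= 0:
        raise ValueError("leaf width and length must be positive")
    return (LW * LL) / _LA_DIVISOR


def estimate_tank_capacity(LA: float) -> float:
    """Tank capacity (mL) from leaf area (cm²), clamped at 0 mL.

    The quadratic prediction is negative below ~11.4 cm²; tank volume
    cannot be negative so those predictions are clamped to zero.
    """
    if LA <= 0:
        raise ValueError("leaf area must be positive")
    return max(0.0, _TC_A * LA * LA + _TC_B * LA + _TC_C)


def call_pathway(d13C: float) -> PathwayCall:
    """Call C3 vs CAM from leaf δ13C (‰); −20 ‰ and above is CAM."""
    if d13C is None or not np.isfinite(d13C):
        raise ValueError("d13C must be finite to call a pathway")
    label = "CAM" if d13C >= PATHWAY_THRESHOLD else "C3"
    return PathwayCall(label, "measured-threshold")


def fill_derived_traits(t: TraitTable) -> TraitTable:
    """Fill missing derived traits in place order: LI, LA, TC, PP.

    * LI := LL/LW where both present and LI missing;
    * LA from LW and LL via the leaf-shape formula;
    * TC from LA via the quadratic (tankless-flagged species get 0 mL);
    * PP (coded 0 = C3, 1 = CAM) from δ13C.

    Filled cells get provenance ``derived``.  Idempotent.
    """
    out = t.copy()
    v, prov = out.values, out.provenance
    tankless = out.flags.get("tankless")

    for sp in v.index:
        if "LI" in v.columns and pd.isna(v.at[sp, "LI"]):
            lw, ll = v.get("LW", pd.Series(dtype=float)).get(sp), \
                v.get("LL", pd.Series(dtype=float)).get(sp)
            if lw is not None and ll is not None and \
                    not pd.isna(lw) and not pd.isna(ll) and lw > 0:
                v.at[sp, "LI"] = ll / lw
                prov.at[sp, "LI"] = "derived"
        if "LA" in v.columns and pd.isna(v.at[sp, "LA"]):
            lw = v["LW"].get(sp) if "LW" in v.columns else None
            ll = v["LL"].get(sp) if "LL" in v.columns else None
            if lw is not None and ll is not None and \
                    not pd.isna(lw) and not pd.isna(ll):
                v.at[sp, "LA"] = estimate_leaf_area(lw, ll)
                prov.at[sp, "LA"] = "derived"
        if "TC" in v.columns and pd.isna(v.at[sp, "TC"]):
            if tankless is not None and bool(tankless.get(sp, False)):
                v.at[sp, "TC"] = 0.0
                prov.at[sp, "TC"] = "derived"
            elif "LA" in v.columns and not pd.isna(v.at[sp, "LA"]):
                v.at[sp, "TC"] = estimate_tank_capacity(v.at[sp, "LA"])
                prov.at[sp, "TC"] = "derived"
        if "PP" in v.columns and pd.isna(v.at[sp, "PP"]):
            if "d13C" in v.columns and not pd.isna(v.at[sp, "d13C"]):
                call = call_pathway(v.at[sp, "d13C"])
                v.at[sp, "PP"] = 1.0 if call.label == "CAM" else 0.0
                prov.at[sp, "PP"] = "derived"
    out.validate()
    return out
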