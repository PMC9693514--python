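"""Trait registry for epiphytic Bromeliaceae.

The default registry catalogues the 25 leaf, tank and physiological traits
used throughout the pipeline: abbreviation, full name, unit, kind
(continuous / binary / categorical) and whether the trait belongs to the
16-trait subset used for hierarchical clustering.  Published summary
statistics (median, range, record counts) travel with each definition so
that database-level bookkeeping (total observations, correlation pair
counts, per-genus record shares) can be recomputed from the registry alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Optional

import yaml

__all__ = [
    "TraitDefinition",
    "default_registry",
    "clustering_traits",
    "continuous_traits",
    "total_records",
    "correlation_pair_count",
    "GENUS_RECORDS",
    "genus_record_total",
    "genus_record_share",
    "load_registry",
    "dump_registry",
]


@dataclass(frozen=True)
class TraitDefinition:
    """One trait in the registry.

    ``clustering_member`` flags the 16 traits entering the two-way Ward
    clustering; ``kind`` is ``continuous``, ``binary`` or ``categorical``.
    ``median``/``range_low``/``range_high``/``records``/``n_species``/
    ``n_genera`` carry the database summary for that trait (``None`` where
    not applicable, e.g. the categorical photosynthetic pathway).
    """

    abbreviation: str
    name: str
    unit: str
    kind: str = "continuous"
    clustering_member: bool = False
    median: Optional[float] = None
    range_low: Optional[float] = None
    range_high: Optional[float] = None
    records: int = 0
    n_species: int = 0
    n_genera: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "binary", "categorical"):
            raise ValueError(f"unknown trait kind {self.kind!r}")


def _t(abbr, name, unit, med, lo, hi, rec, nsp, ng, *, kind="continuous",
       cluster=False) -> TraitDefinition:
    return TraitDefinition(abbr, name, unit, kind, cluster, med, lo, hi,
                           rec, nsp, ng)


#: The 25-trait default registry. 16 entries are clustering members; the
#: two non-continuous entries are pseudobulb presence (binary) and
#: photosynthetic pathway (categorical).
_DEFAULT = (
    _t("Height", "Adult plant height", "m", 0.4, 0.03, 2.7, 507, 126, 16, cluster=True),
    _t("FP", "Force to punch", "N mm⁻¹", 1.4, 0.17, 6.2, 706, 36, 7),
    _t("LA", "Leaf area", "cm²", 8678, 29, 1033, 1702, 201, 23, cluster=True),
    _t("C", "Leaf carbon content per dry mass", "%", 45.2, 27.9, 69.3, 502, 59, 11),
    _t("d13C", "Leaf carbon isotope signature", "‰", -15.9, -35.08, 11, 903, 197, 23, cluster=True),
    _t("LCh", "Leaf chlorophyll content per dry mass", "µg g⁻¹", 2800, 200, 12200, 43, 35, 6),
    _t("LD", "Leaf dry matter content", "mg g", 161.2, 37.3, 520, 1440, 49, 8),
    _t("LI", "Leaf index", "", 13.4, 2.2, 250, 212, 202, 22, cluster=True),
    _t("LL", "Leaf length", "cm", 38.7, 1.8, 161, 539, 204, 23, cluster=True),
    _t("d15N", "Leaf nitrogen isotope signature", "‰", -4.7, -15.2, 7.5, 643, 69, 12, cluster=True),
    _t("N", "Leaf nitrogen content per dry mass", "mg g", 7.4, 1, 25.5, 554, 71, 12, cluster=True),
    _t("P", "Leaf phosphorus content per dry mass", "mg g", 0.6, 0.02, 5, 185, 61, 11),
    _t("LT", "Leaf thickness", "mm", 0.6, 0.07, 4.5, 1751, 97, 17, cluster=True),
    _t("TD", "Leaf trichome density", "mm⁻²", 35.2, 2.8, 120.9, 1104, 74, 11, cluster=True),
    _t("LWA", "Leaf water content on area basis", "g m²", 540.8, 91.7, 6017, 936, 92, 16, cluster=True),
    _t("LW", "Leaf width", "cm", 3.0, 0.05, 17.5, 449, 202, 22, cluster=True),
    _t("Amax", "Light saturated photosynthetic rate per leaf area", "µmol m² s", 2.3, 0.7, 4.7, 42, 36, 9),
    _t("SLA", "Specific leaf area", "mm² mg⁻¹", 8.9, 0.01, 68.5, 1709, 109, 16, cluster=True),
    _t("SD", "Stomatal density", "mm⁻²", 21.0, 2.8, 88.8, 975, 102, 14, cluster=True),
    _t("SL", "Stomatal length", "µm", 39.8, 14.4, 284.3, 257, 45, 8),
    _t("SW", "Stomatal width", "µm", 35.0, 9.7, 338.5, 56, 32, 7),
    _t("TC", "Tank capacity", "mL", 85.7, 0, 4924, 213, 190, 23, cluster=True),
    _t("LWC", "Total leaf water content", "g", 3.1, 0.001, 147, 738, 92, 16, cluster=True),
    TraitDefinition("PB", "Pseudobulb presence", "", "binary", True,
                    records=204, n_species=204, n_genera=23),
    TraitDefinition("PP", "Photosynthetic pathway", "", "categorical", False,
                    records=204, n_species=204, n_genera=23),
)

#: Per-genus database summary: genus -> (records, species, traits covered).
GENUS_RECORDS: dict[str, tuple[int, int, int]] = {
    "Aechmea": (1549, 36, 25),
    "Araeococcus": (43, 2, 18),
    "Billbergia": (280, 8, 22),
    "Canistropsis": (52, 1, 10),
    "Canistrum": (18, 2, 8),
    "Catopsis": (1138, 7, 25),
    "Fascicularia": (78, 1, 11),
    "Goudaea": (15, 1, 10),
    "Guzmania": (2069, 31, 25),
    "Josemania": (13, 1, 12),
    "Lemeltonia": (206, 1, 21),
    "Lutheria": (21, 1, 18),
    "Lymania": (10, 1, 9),
    "Mezobromelia": (9, 1, 9),
    "Neoregelia": (63, 5, 14),
    "Nidularium": (92, 8, 19),
    "Quesnelia": (21, 2, 11),
    "Racinaea": (878, 5, 22),
    "Ronnbergia": (18, 2, 8),
    "Tillandsia": (9522, 81, 25),
    "Vriesea": (93, 5, 14),
    "Wallisia": (411, 1, 24),
    "Werauhia": (75, 6, 19),
}


def default_registry() -> list[TraitDefinition]:
    """Return a fresh copy of the 25-trait default registry."""
    reg = list(_DEFAULT)
    validate_registry(reg)
    return reg


def validate_registry(registry: list[TraitDefinition]) -> None:
    """Check registry invariants: unique abbreviations, finite bounds."""
    abbrs = [d.abbreviation for d in registry]
    if len(set(abbrs)) != len(abbrs):
        dup = sorted({a for a in abbrs if abbrs.count(a) > 1})
        raise ValueError(f"duplicate trait abbreviations: {dup}")


def clustering_traits(registry: Optional[list[TraitDefinition]] = None) -> list[str]:
    """Abbreviations of the traits entering hierarchical clustering."""
    reg = registry if registry is not None else default_registry()
    return [d.abbreviation for d in reg if d.clustering_member]


def continuous_traits(registry: Optional[list[TraitDefinition]] = None) -> list[str]:
    reg = registry if registry is not None else default_registry()
    return [d.abbreviation for d in reg if d.kind == "continuous"]


def total_records(registry: Optional[list[TraitDefinition]] = None) -> int:
    """Sum of per-trait record counts across the registry."""
    reg = registry if registry is not None else default_registry()
    return sum(d.records for d in reg)


def correlation_pair_count(registry: Optional[list[TraitDefinition]] = None) -> int:
    """Number of unordered pairs of continuous traits (the trait-correlation
    matrix has one cell per such pair)."""
    return comb(len(continuous_traits(registry)), 2)


def genus_record_total() -> int:
    """Sum of per-genus record counts."""
    return sum(rec for rec, _, _ in GENUS_RECORDS.values())


def genus_record_share(genus: str) -> float:
    """Percentage of all records contributed by ``genus``."""
    if genus not in GENUS_RECORDS:
        raise KeyError(f"unknown genus {genus!r}")
    return 100.0 * GENUS_RECORDS[genus][0] / genus_record_total()


# ---------------------------------------------------------------------------
# YAML round trip

def dump_registry(registry: list[TraitDefinition], path) -> None:
    """Write a registry as a YAML list of trait definitions."""
    recs = []
    for d in registry:
        recs.append({
            "abbreviation": d.abbreviation, "name": d.name, "unit": d.unit,
            "kind": d.kind, "clustering_member": d.clustering_member,
            "median": d.median, "range_low": d.range_low,
            "range_high": d.range_high, "records": d.records,
            "n_species": d.n_species, "n_genera": d.n_genera,
        })
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(recs, fh, allow_unicode=True, sort_keys=False)


def load_registry(path) -> list[TraitDefinition]:
    """Read a registry written by :func:`dump_registry`."""
    with open(path, encoding="utf-8") as fh:
        recs = yaml.safe_load(fh)
    reg = [TraitDefinition(**r) for r in recs]
    validate_registry(reg)
    return reg
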