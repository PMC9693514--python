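"""Rule engine for the five epiphytic-bromeliad functional groups.

Groups: NEB (nebulophytes: acicular, fog-intercepting leaves), BULB
(pseudobulbs), SHALLOW_T (shallow tanks, 2–61 mL), C3_T (C3 deep tanks,
> 5 mL) and CAM_T (CAM deep tanks, > 61 mL).

Decision order: (1) a pseudobulb always wins; (2) acicular morphology —
or, lacking the flag, a high leaf index with a negligible tank — makes a
nebulophyte; (3) CAM species split on tank capacity into shallow
(2–61 mL) and deep (> 61 mL) tanks; a tankless, non-acicular,
non-pseudobulb CAM plant matches no published rule and is reported as
unclassifiable with advisory candidates; (4) C3 species with > 5 mL are
deep C3 tanks, and C3 species with a negligible tank (≤ 5 mL) join the
shallow tanks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import math

import pandas as pd

__all__ = [
    "GROUPS",
    "FunctionalGroupLabel",
    "RuleThresholds",
    "classify_species",
    "classify_table",
    "reconcile_with_clusters",
    "group_composition",
    "name_clusters",
]

GROUPS = ("NEB", "BULB", "SHALLOW_T", "C3_T", "CAM_T")
UNCLASSIFIABLE = "UNCLASSIFIABLE"


@dataclass(frozen=True)
class FunctionalGroupLabel:
    value: str                     # one of GROUPS or UNCLASSIFIABLE
    provenance: str = "rule"       # cluster | rule | override
    rule_fired: str = ""
    reason: str = ""

    def __post_init__(self) -> None:
        if self.value not in GROUPS + (UNCLASSIFIABLE,):
            raise ValueError(f"unknown group {self.value!r}")
        if self.provenance not in ("cluster", "rule", "override"):
            raise ValueError(f"unknown provenance {self.provenance!r}")


@dataclass
class RuleThresholds:
    """Numeric thresholds of the rule engine.

    ``cam_shallow_tc_range``: inclusive TC window (mL) for CAM shallow
    tanks; ``c3_deep_min_tc``: TC (mL) above which a C3 species is a deep
    tank; ``nebulophyte_min_li``: leaf-index fallback used only when the
    acicular flag is unavailable; ``pathway_threshold``: δ13C (‰) at or
    above which the pathway is CAM.
    """

    cam_shallow_tc_range: tuple[float, float] = (2.0, 61.0)
    c3_deep_min_tc: float = 5.0
    nebulophyte_min_li: float = 40.0
    pathway_threshold: float = -20.0

    def __post_init__(self) -> None:
        lo, hi = self.cam_shallow_tc_range
        vals = [lo, hi, self.c3_deep_min_tc, self.nebulophyte_min_li,
                self.pathway_threshold]
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("thresholds must be finite")
        if lo >= hi:
            raise ValueError("shallow-tank TC range must have lower < upper")


def _resolve_pathway(traits: dict, thr: RuleThresholds) -> Optional[str]:
    pp = traits.get("PP")
    if pp is not None and not _isna(pp):
        return "CAM" if float(pp) >= 0.5 else "C3"
    d13c = traits.get("d13C")
    if d13c is not None and not _isna(d13c):
        return "CAM" if float(d13c) >= thr.pathway_threshold else "C3"
    return None


def _isna(x) -> bool:
    try:
        return bool(pd.isna(x))
    except (TypeError, ValueError):
        return False


def classify_species(traits: dict, thr: RuleThresholds | None = None
                     ) -> FunctionalGroupLabel:
    """Classify one species from a trait mapping.

    ``traits`` may contain ``PB`` (0/1), ``acicular`` (0/1 or absent),
    ``tankless`` (0/1), ``TC`` (mL), ``PP`` (0=C3/1=CAM) and/or ``d13C``
    (‰), ``LI``.  Unresolvable pathway or tank capacity yields an
    UNCLASSIFIABLE outcome with a reason, never a silent default.
    """
    thr = thr if thr is not None else RuleThresholds()

    pb = traits.get("PB")
    if pb is None or _isna(pb):
        return FunctionalGroupLabel(
            UNCLASSIFIABLE, "rule", "precondition",
            "pseudobulb flag missing")
    if float(pb) >= 0.5:
        return FunctionalGroupLabel("BULB", "rule", "pseudobulb",
                                    "pseudobulb present")

    tc = traits.get("TC")
    if (tc is None or _isna(tc)) and traits.get("tankless") not in (None,) \
            and not _isna(traits.get("tankless")) \
            and float(traits.get("tankless")) >= 0.5:
        tc = 0.0
    acic = traits.get("acicular")
    has_acic_flag = acic is not None and not _isna(acic)

    # nebulophyte: explicit acicular morphology, or LI fallback with a
    # negligible tank when the flag is unavailable
    if has_acic_flag and float(acic) >= 0.5:
        return FunctionalGroupLabel("NEB", "rule", "acicular",
                                    "acicular leaves")
    if not has_acic_flag:
        li = traits.get("LI")
        if li is not None and not _isna(li) and \
                float(li) >= thr.nebulophyte_min_li and \
                tc is not None and not _isna(tc) and \
                float(tc) < thr.cam_shallow_tc_range[0]:
            return FunctionalGroupLabel(
                "NEB", "rule", "leaf_index_fallback",
                f"LI >= {thr.nebulophyte_min_li} with negligible tank")

    pathway = _resolve_pathway(traits, thr)
    if pathway is None:
        return FunctionalGroupLabel(
            UNCLASSIFIABLE, "rule", "precondition",
            "photosynthetic pathway unresolvable (no PP, no d13C)")
    if tc is None or _isna(tc):
        return FunctionalGroupLabel(
            UNCLASSIFIABLE, "rule", "precondition",
            "tank capacity unresolvable (no TC, no tankless flag)")
    tc = float(tc)

    lo, hi = thr.cam_shallow_tc_range
    if pathway == "CAM":
        if lo <= tc <= hi:
            return FunctionalGroupLabel("SHALLOW_T", "rule",
                                        "cam_shallow_tc",
                                        f"CAM with TC in [{lo}, {hi}] mL")
        if tc > hi:
            return FunctionalGroupLabel("CAM_T", "rule", "cam_deep_tc",
                                        f"CAM with TC > {hi} mL")
        return FunctionalGroupLabel(
            UNCLASSIFIABLE, "rule", "cam_tankless_gap",
            "CAM, tankless, non-acicular, no pseudobulb: no published "
            "rule; candidates NEB or BULB")
    # C3
    if tc > thr.c3_deep_min_tc:
        return FunctionalGroupLabel("C3_T", "rule", "c3_deep_tc",
                                    f"C3 with TC > {thr.c3_deep_min_tc} mL")
    return FunctionalGroupLabel("SHALLOW_T", "rule", "c3_negligible_tc",
                                "C3 with negligible tank capacity")


def classify_table(values: pd.DataFrame, flags: pd.DataFrame | None = None,
                   thr: RuleThresholds | None = None) -> pd.DataFrame:
    """Classify every row of a trait table; returns a frame with columns
    species (index), label, provenance, rule_fired, reason."""
    rows = {}
    for sp in values.index:
        traits = values.loc[sp].to_dict()
        if flags is not None and sp in flags.index:
            for col in flags.columns:
                traits[col] = float(bool(flags.at[sp, col]))
        lab = classify_species(traits, thr)
        rows[sp] = {"label": lab.value, "provenance": lab.provenance,
                    "rule_fired": lab.rule_fired, "reason": lab.reason}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "species"
    return out


# ---------------------------------------------------------------------------
# Cluster reconciliation

def name_clusters(cluster_map: dict[str, int], rule_labels: pd.Series
                  ) -> dict[int, str]:
    """Name each cluster by the majority rule-derived label among its
    members (ties broken by group order NEB..CAM_T)."""
    by_cluster: dict[int, list[str]] = {}
    for sp, cid in cluster_map.items():
        lab = rule_labels.get(sp)
        if lab in GROUPS:
            by_cluster.setdefault(cid, []).append(lab)
    names = {}
    for cid, labs in by_cluster.items():
        counts = {g: labs.count(g) for g in GROUPS}
        names[cid] = max(GROUPS, key=lambda g: (counts[g], -GROUPS.index(g)))
    return names


def reconcile_with_clusters(cluster_map: dict[str, int],
                            traits: pd.DataFrame,
                            flags: pd.DataFrame | None = None,
                            thr: RuleThresholds | None = None,
                            cluster_names: dict[int, str] | None = None
                            ) -> tuple[pd.DataFrame, list[dict]]:
    """Override cluster-derived labels that contradict physiology/morphology.

    Two published reclassification rules: a CAM species landing in the
    C3-tank cluster moves to CAM_T ("pathway mismatch"); an acicular
    species landing in the shallow-tank cluster moves to NEB.  Idempotent;
    every move is logged.
    """
    thr = thr if thr is not None else RuleThresholds()
    rule = classify_table(traits, flags, thr)
    if cluster_names is None:
        cluster_names = name_clusters(cluster_map, rule["label"])
    log: list[dict] = []
    rows = {}
    for sp, cid in cluster_map.items():
        label = cluster_names[cid]
        provenance = "cluster"
        reason = ""
        tr = traits.loc[sp].to_dict() if sp in traits.index else {}
        if flags is not None and sp in flags.index:
            for col in flags.columns:
                tr[col] = float(bool(flags.at[sp, col]))
        pathway = _resolve_pathway(tr, thr)
        acic = tr.get("acicular")
        if label == "C3_T" and pathway == "CAM":
            label, provenance, reason = "CAM_T", "override", "pathway mismatch"
            log.append({"species": sp, "from": "C3_T", "to": "CAM_T",
                        "reason": reason})
        elif label == "SHALLOW_T" and acic is not None and \
                not _isna(acic) and float(acic) >= 0.5:
            label, provenance, reason = "NEB", "override", \
                "acicular morphology"
            log.append({"species": sp, "from": "SHALLOW_T", "to": "NEB",
                        "reason": reason})
        rows[sp] = {"label": label, "provenance": provenance,
                    "reason": reason, "cluster_id": cid}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "species"
    return out, log


def group_composition(labels: pd.Series | list) -> pd.DataFrame:
    """Counts, exact fractions and integer-rounded percentages per group."""
    s = pd.Series(labels)
    s = s[s.isin(GROUPS)]
    if s.empty:
        raise ValueError("no classifiable labels")
    counts = s.value_counts().reindex(GROUPS, fill_value=0)
    frac = counts / counts.sum()
    out = pd.DataFrame({
        "count": counts,
        "fraction": frac,
        "percent": (100 * frac).round().astype(int),
    })
    out.index.name = "group"
    return out
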