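"""Synthetic bromeliad datasets with the structure the pipeline assumes.

Generates (a) pure-birth (Yule) phylogenies, (b) species × trait tables
built from five functional-group archetypes — nebulophytes, pseudobulbs,
shallow tanks, C3 deep tanks, CAM deep tanks — with Brownian-motion
deviations along the tree plus independent noise and missing-at-random
cells, and (c) per-species occurrence records with group-specific climate
niches and ecological-zone memberships.  Everything is driven by a single
integer seed and is bit-reproducible.

Archetype defaults are calibrated to the published trait medians/ranges
and the directional group contrasts (nebulophytes: high leaf index, tiny
leaves, no tank; pseudobulbs: succulent, thick leaves, no tank; shallow
tanks: 2–61 mL; CAM deep tanks: large, > 61 mL; C3 deep tanks: most
negative δ13C, highest SLA).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .fg_classify import GROUPS
from .phylo_impute import Phylogeny
from .trait_db import TraitTable
from .registry import default_registry

__all__ = [
    "SyntheticConfig",
    "GroupArchetype",
    "simulate_tree",
    "simulate_traits",
    "mask_missing",
    "simulate_env_records",
    "simulate_dataset",
]

#: Traits simulated for each species (the 16 clustering traits).
SIM_TRAITS = ("Height", "LA", "d13C", "LI", "LL", "d15N", "N", "LT", "TD",
              "LWA", "LW", "SLA", "SD", "TC", "LWC", "PB")

#: Traits that cannot be negative (clamped after noise).
_NONNEG = ("Height", "LA", "LI", "LL", "N", "LT", "TD", "LWA", "LW",
           "SLA", "SD", "TC", "LWC")


@dataclass(frozen=True)
class GroupArchetype:
    """Trait means/SDs, morphology flags and climate niche of one group."""

    name: str
    trait_mean: dict[str, float]
    trait_sd: dict[str, float]
    pseudobulb: bool = False
    acicular: bool = False
    tankless: bool = False
    env_mean: dict[str, float] = field(default_factory=dict)
    env_sd: dict[str, float] = field(default_factory=dict)
    ecozone_probs: dict[str, float] = field(default_factory=dict)
    lat_center: float = 15.0
    lon_center: float = -90.0


def _arch(name, mean, sd, **kw) -> GroupArchetype:
    return GroupArchetype(name, mean, sd, **kw)


def _default_archetypes() -> dict[str, GroupArchetype]:
    # Trait scales follow the published medians/ranges; contrasts follow
    # the printed group differences.
    common_sd = {"Height": 0.10, "LA": 0.2, "d13C": 1.3, "LI": 0.2,
                 "LL": 0.2, "d15N": 1.5, "N": 1.5, "LT": 0.12, "TD": 0.2,
                 "LWA": 0.2, "LW": 0.2, "SLA": 0.2, "SD": 0.2, "TC": 0.2,
                 "LWC": 0.25}
    # SDs for positive traits are log10-scale (multiplicative spread);
    # d13C, d15N, N, Height, LT additive.
    neb = _arch(
        "NEB",
        {"Height": 0.30, "LA": 12.0, "d13C": -14.0, "LI": 85.0, "LL": 30.0,
         "d15N": -8.0, "N": 7.0, "LT": 0.45, "TD": 55.0, "LWA": 220.0,
         "LW": 0.35, "SLA": 9.0, "SD": 8.0, "TC": 0.0, "LWC": 0.3,
         "PB": 0.0},
        common_sd, acicular=True, tankless=True,
        env_mean={"VPD": 1.9, "PPT": 650.0, "TMIN": 8.0, "TMAX": 31.0,
                  "ET0": 1750.0, "AI": 0.45, "Elev": 1400.0},
        env_sd={"VPD": 0.25, "PPT": 180.0, "TMIN": 3.0, "TMAX": 2.5,
                "ET0": 150.0, "AI": 0.12, "Elev": 450.0},
        ecozone_probs={"Tropical mountain system": 0.30,
                       "Subtropical desert": 0.20,
                       "Tropical dry forest": 0.20,
                       "Temperate oceanic forest": 0.10,
                       "Tropical moist deciduous forest": 0.10,
                       "Tropical rainforest": 0.10},
        lat_center=22.0, lon_center=-101.0)
    bulb = _arch(
        "BULB",
        {"Height": 0.25, "LA": 55.0, "d13C": -13.5, "LI": 9.0, "LL": 28.0,
         "d15N": -5.0, "N": 7.0, "LT": 1.6, "TD": 45.0, "LWA": 1600.0,
         "LW": 1.5, "SLA": 4.5, "SD": 9.0, "TC": 0.0, "LWC": 2.0,
         "PB": 1.0},
        common_sd, pseudobulb=True, tankless=True,
        env_mean={"VPD": 1.6, "PPT": 1100.0, "TMIN": 17.0, "TMAX": 33.0,
                  "ET0": 1650.0, "AI": 0.75, "Elev": 250.0},
        env_sd={"VPD": 0.2, "PPT": 250.0, "TMIN": 2.0, "TMAX": 2.0,
                "ET0": 130.0, "AI": 0.15, "Elev": 150.0},
        ecozone_probs={"Tropical moist deciduous forest": 0.35,
                       "Tropical dry forest": 0.30,
                       "Tropical rainforest": 0.25,
                       "Tropical mountain system": 0.10},
        lat_center=18.0, lon_center=-95.0)
    shall = _arch(
        "SHALLOW_T",
        {"Height": 0.35, "LA": 140.0, "d13C": -15.5, "LI": 16.0, "LL": 40.0,
         "d15N": -5.0, "N": 7.2, "LT": 0.7, "TD": 36.0, "LWA": 550.0,
         "LW": 2.6, "SLA": 8.5, "SD": 13.0, "TC": 20.0, "LWC": 3.0,
         "PB": 0.0},
        {**common_sd, "TC": 0.18},
        env_mean={"VPD": 1.5, "PPT": 1250.0, "TMIN": 15.0, "TMAX": 32.0,
                  "ET0": 1550.0, "AI": 0.85, "Elev": 600.0},
        env_sd={"VPD": 0.2, "PPT": 260.0, "TMIN": 2.5, "TMAX": 2.0,
                "ET0": 130.0, "AI": 0.16, "Elev": 250.0},
        ecozone_probs={"Tropical moist deciduous forest": 0.30,
                       "Tropical rainforest": 0.30,
                       "Tropical dry forest": 0.20,
                       "Tropical mountain system": 0.20},
        lat_center=17.0, lon_center=-92.0)
    cam_t = _arch(
        "CAM_T",
        {"Height": 0.85, "LA": 850.0, "d13C": -14.5, "LI": 13.0, "LL": 85.0,
         "d15N": -3.0, "N": 7.5, "LT": 0.9, "TD": 26.0, "LWA": 850.0,
         "LW": 6.0, "SLA": 7.0, "SD": 26.0, "TC": 650.0, "LWC": 32.0,
         "PB": 0.0},
        {**common_sd, "TC": 0.22},
        env_mean={"VPD": 1.4, "PPT": 1700.0, "TMIN": 18.0, "TMAX": 33.0,
                  "ET0": 1500.0, "AI": 1.1, "Elev": 200.0},
        env_sd={"VPD": 0.18, "PPT": 320.0, "TMIN": 2.0, "TMAX": 1.8,
                "ET0": 120.0, "AI": 0.2, "Elev": 120.0},
        ecozone_probs={"Tropical rainforest": 0.40,
                       "Tropical moist deciduous forest": 0.35,
                       "Tropical dry forest": 0.20,
                       "Tropical mountain system": 0.05},
        lat_center=10.0, lon_center=-84.0)
    c3_t = _arch(
        "C3_T",
        {"Height": 0.60, "LA": 450.0, "d13C": -28.5, "LI": 15.0, "LL": 60.0,
         "d15N": -2.0, "N": 8.0, "LT": 0.35, "TD": 8.0, "LWA": 360.0,
         "LW": 4.2, "SLA": 16.0, "SD": 23.0, "TC": 160.0, "LWC": 11.0,
         "PB": 0.0},
        {**common_sd, "TC": 0.22},
        env_mean={"VPD": 0.9, "PPT": 2300.0, "TMIN": 11.0, "TMAX": 26.0,
                  "ET0": 1250.0, "AI": 1.6, "Elev": 1800.0},
        env_sd={"VPD": 0.15, "PPT": 380.0, "TMIN": 2.5, "TMAX": 2.0,
                "ET0": 110.0, "AI": 0.25, "Elev": 450.0},
        ecozone_probs={"Tropical mountain system": 0.45,
                       "Tropical rainforest": 0.40,
                       "Tropical moist deciduous forest": 0.15},
        lat_center=5.0, lon_center=-76.0)
    return {"NEB": neb, "BULB": bulb, "SHALLOW_T": shall,
            "CAM_T": cam_t, "C3_T": c3_t}


@dataclass
class SyntheticConfig:
    """Study-condition defaults for the generator.

    76 species split as 29 C3 tanks, 22 CAM tanks, 12 shallow tanks,
    8 nebulophytes, 5 pseudobulbs (the published 38/29/16/11/5 proportions
    at the cluster-analysis sample size); 7.2 % missing cells; a Yule tree
    with unit birth rate; a small BM rate adding phylogenetic signal on
    top of the archetype means.
    """

    seed: int = 0
    n_per_group: dict[str, int] = field(default_factory=lambda: {
        "C3_T": 29, "CAM_T": 22, "SHALLOW_T": 12, "NEB": 8, "BULB": 5})
    archetypes: dict[str, GroupArchetype] = \
        field(default_factory=_default_archetypes)
    missing_rate: float = 0.072
    birth_rate: float = 1.0
    bm_rate: float = 0.003          # BM variance per unit tree depth
    # at the default Yule depth (~3.9 for 76 tips) this yields correlated
    # per-species deviations of ~0.1 dex, well inside the ~0.5 dex group
    # contrasts, so the archetypes stay separable as configured
    bm_trait_corr: float = 0.3      # common correlation of BM deviations
    noise_scale: float = 1.0        # multiplier on archetype SDs
    n_genera: int = 12
    records_per_species: int = 20

    def validate(self) -> None:
        if not 0 <= self.missing_rate <= 0.5:
            raise ValueError("missing_rate must lie in [0, 0.5]")
        for g in self.n_per_group:
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r}")
        for g, arch in self.archetypes.items():
            tc = arch.trait_mean.get("TC", 0.0)
            if g == "SHALLOW_T" and not 2.0 <= tc <= 61.0:
                raise ValueError(
                    f"SHALLOW_T archetype TC mean {tc} outside [2, 61] mL")
            if g == "CAM_T" and tc <= 61.0:
                raise ValueError(f"CAM_T archetype TC mean {tc} <= 61 mL")
            if g == "C3_T":
                if tc <= 5.0:
                    raise ValueError(f"C3_T archetype TC mean {tc} <= 5 mL")
                if arch.trait_mean.get("d13C", 0.0) >= -20.0:
                    raise ValueError("C3_T archetype d13C must be < -20 per mil")
            if g in ("NEB", "BULB") and not arch.tankless:
                raise ValueError(f"{g} archetype must be tankless")


# ---------------------------------------------------------------------------
# Yule trees

def simulate_tree(n_tips: int, birth_rate: float = 1.0, seed: int = 0,
                  labels: list[str] | None = None) -> Phylogeny:
    """Pure-birth (Yule) ultrametric tree.

    Starting from two lineages at the root, each interval with k lineages
    lasts Exp(k·λ); a uniformly chosen lineage splits until n tips exist,
    plus a final Exp(n·λ) hold, so the expected root-to-tip depth is
    Σ_{k=2..n} 1/(k·λ).
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = np.random.default_rng(seed)
    if labels is None:
        labels = [f"sp{i:03d}" for i in range(n_tips)]
    if len(labels) != n_tips:
        raise ValueError("label count must equal n_tips")

    # grow: each live lineage tracked as (birth_time, children-or-label)
    next_id = 0
    nodes: dict[int, dict] = {}

    def new_node(tstart: float) -> int:
        nonlocal next_id
        nid = next_id
        next_id += 1
        nodes[nid] = {"t": tstart, "children": None, "label": None}
        return nid

    root_t = 0.0
    live = [new_node(root_t), new_node(root_t)]
    t = 0.0
    for k in range(2, n_tips + 1):
        t += rng.exponential(1.0 / (k * birth_rate))
        if k == n_tips:
            break
        idx = rng.integers(len(live))
        parent = live[idx]
        c1, c2 = new_node(t), new_node(t)
        nodes[parent]["children"] = (c1, c2)
        live[idx] = c1
        live.append(c2)
    depth = t
    perm = rng.permutation(n_tips)
    for i, nid in enumerate(live):
        nodes[nid]["label"] = labels[perm[i]]

    root_children = [0, 1]  # the two lineages created at the root

    def render(nid: int) -> str:
        node = nodes[nid]
        if node["children"] is None:
            return f"{node['label']}"
        c1, c2 = node["children"]
        t1 = _node_len(nodes, c1, depth)
        t2 = _node_len(nodes, c2, depth)
        return (f"({render(c1)}:{t1:.17g},{render(c2)}:{t2:.17g})")

    s = (f"({render(root_children[0])}:"
         f"{_node_len(nodes, root_children[0], depth):.17g},"
         f"{render(root_children[1])}:"
         f"{_node_len(nodes, root_children[1], depth):.17g});")
    tree = dendropy.Tree.get(data=s, schema="newick")
    return Phylogeny(tree)


def _node_len(nodes: dict, nid: int, depth: float) -> float:
    node = nodes[nid]
    if node["children"] is None:
        return depth - node["t"]
    return nodes[node["children"][0]]["t"] - node["t"]


# ---------------------------------------------------------------------------
# Trait tables

_LOG_SD_TRAITS = ("Height", "LA", "LI", "LL", "LT", "TD", "LWA", "LW",
                  "SLA", "SD", "TC", "LWC")


def simulate_traits(cfg: SyntheticConfig, tree: Phylogeny | None = None
                    ) -> tuple[TraitTable, pd.Series]:
    """Simulate a trait table from the group archetypes.

    Positive size-like traits are drawn log-normally (archetype SD on the
    log10 scale); signed traits (δ13C, δ15N) and contents (N, Height, LT)
    are Gaussian.  A Brownian-motion deviation simulated along the tree is
    added to every continuous trait (on its sampling scale) to create
    phylogenetic signal.  Returns the table and the true group labels.
    """
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 101]))
    species, genera, labels = [], [], []
    i = 0
    for g in GROUPS:
        n = cfg.n_per_group.get(g, 0)
        for j in range(n):
            species.append(f"sp{i:03d}")
            genera.append(f"genus{(i % cfg.n_genera):02d}")
            labels.append(g)
            i += 1
    n_sp = len(species)
    labels_s = pd.Series(labels, index=species, name="group")

    # BM deviations on the tree (if provided): correlated across traits
    p = len([tr for tr in SIM_TRAITS if tr != "PB"])
    bm_dev = np.zeros((n_sp, p))
    if tree is not None and cfg.bm_rate > 0:
        order = [s for s in species if s in set(tree.tip_labels)]
        if order:
            C = tree.vcv(order=order).to_numpy()
            R = cfg.bm_rate * (
                (1 - cfg.bm_trait_corr) * np.eye(p)
                + cfg.bm_trait_corr * np.ones((p, p)))
            L_C = np.linalg.cholesky(C + 1e-12 * np.eye(len(order)))
            L_R = np.linalg.cholesky(R + 1e-12 * np.eye(p))
            Z = rng.standard_normal((len(order), p))
            dev = L_C @ Z @ L_R.T
            pos = {s: k for k, s in enumerate(species)}
            for k, s in enumerate(order):
                bm_dev[pos[s]] = dev[k]

    cont_traits = [tr for tr in SIM_TRAITS if tr != "PB"]
    values = pd.DataFrame(index=species, columns=list(SIM_TRAITS),
                          dtype=float)
    flags = pd.DataFrame(False, index=species,
                         columns=["tankless", "acicular"])
    for idx, sp in enumerate(species):
        arch = cfg.archetypes[labels[idx]]
        for tj, tr in enumerate(cont_traits):
            mu = arch.trait_mean[tr]
            sd = arch.trait_sd.get(tr, 0.0) * cfg.noise_scale
            dev = bm_dev[idx, tj]
            if tr in _LOG_SD_TRAITS and mu > 0:
                # multiplicative spread: SD interpreted on the log10 scale
                x = 10 ** (np.log10(mu) + rng.normal(0.0, sd) + dev)
            else:
                # additive spread: SD in trait units
                x = mu + rng.normal(0.0, sd) + dev
            if tr in _NONNEG:
                x = max(x, 0.0)
            values.at[sp, tr] = x
        if arch.tankless:
            values.at[sp, "TC"] = 0.0
            flags.at[sp, "tankless"] = True
        values.at[sp, "PB"] = 1.0 if arch.pseudobulb else 0.0
        flags.at[sp, "acicular"] = arch.acicular
        # keep LI consistent with LL/LW where all three are simulated
        if values.at[sp, "LW"] > 0:
            values.at[sp, "LI"] = values.at[sp, "LL"] / values.at[sp, "LW"]

    table = TraitTable(values, pd.Series(genera, index=species, name="genus"),
                       default_registry(), None, flags)
    return table, labels_s


def mask_missing(t: TraitTable, rate: float, seed: int = 0,
                 min_traits: int = 5) -> TraitTable:
    """Mask cells missing-completely-at-random at ``rate``.

    Never drops a species below ``min_traits`` observed values; the
    achieved count is within one cell of ``round(rate · n_cells)`` unless
    the floor binds first.
    """
    if not 0 <= rate <= 0.5:
        raise ValueError("rate must lie in [0, 0.5]")
    out = t.copy()
    if rate == 0:
        return out
    rng = np.random.default_rng(np.random.SeedSequence([seed, 202]))
    n_sp, n_tr = out.values.shape
    target = int(round(rate * n_sp * n_tr))
    cells = [(i, j) for i in range(n_sp) for j in range(n_tr)
             if not pd.isna(out.values.iat[i, j])]
    rng.shuffle(cells)
    per_row_obs = out.values.notna().sum(axis=1).to_numpy().copy()
    masked = 0
    for i, j in cells:
        if masked >= target:
            break
        if per_row_obs[i] - 1 < min_traits:
            continue
        out.values.iat[i, j] = np.nan
        out.provenance.iat[i, j] = ""
        per_row_obs[i] -= 1
        masked += 1
    return out


# ---------------------------------------------------------------------------
# Occurrence records

def simulate_env_records(cfg: SyntheticConfig, labels: pd.Series,
                         records_per_species: int | None = None,
                         seed: int | None = None) -> pd.DataFrame:
    """Occurrence records with group-specific climate niches.

    Each species gets exactly ``records_per_species`` records; every
    environmental variable is a Gaussian draw around the group niche and
    the ecological zone a categorical draw from the group distribution.
    """
    nrec = records_per_species if records_per_species is not None \
        else cfg.records_per_species
    seed = seed if seed is not None else cfg.seed
    rng = np.random.default_rng(np.random.SeedSequence([seed, 303]))
    rows = []
    for sp, g in labels.items():
        arch = cfg.archetypes[g]
        zones = list(arch.ecozone_probs)
        probs = np.array([arch.ecozone_probs[z] for z in zones])
        probs = probs / probs.sum()
        for _ in range(nrec):
            row = {"species": sp,
                   "lat": float(np.clip(
                       rng.normal(arch.lat_center, 4.0), -60, 60)),
                   "lon": float(np.clip(
                       rng.normal(arch.lon_center, 6.0), -130, -30))}
            for var, mu in arch.env_mean.items():
                sd = arch.env_sd.get(var, 0.0)
                val = rng.normal(mu, sd) if sd > 0 else mu
                if var in ("PPT", "ET0", "AI", "VPD"):
                    val = max(val, 0.0)
                row[var] = float(val)
            row["ecozone"] = zones[rng.choice(len(zones), p=probs)]
            rows.append(row)
    return pd.DataFrame(rows)


def simulate_dataset(cfg: SyntheticConfig
                     ) -> tuple[TraitTable, Phylogeny, pd.Series, pd.DataFrame]:
    """Full bundle: masked trait table, tree, true labels, records.

    The tree covers all species (the imputation stage may be handed a
    pruned copy to emulate partial tree coverage).
    """
    n_total = sum(cfg.n_per_group.values())
    labels_order = [f"sp{i:03d}" for i in range(n_total)]
    tree = simulate_tree(n_total, cfg.birth_rate, cfg.seed,
                         labels=labels_order)
    table, labels = simulate_traits(cfg, tree)
    masked = mask_missing(table, cfg.missing_rate, cfg.seed)
    records = simulate_env_records(cfg, labels)
    return masked, tree, labels, records
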