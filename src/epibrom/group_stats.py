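"""Trait and environment comparisons across functional groups.

Implements the comparison toolbox used throughout the analysis: Spearman
rank correlations over all trait pairs (pairwise-complete, midranks for
ties, t-approximation p-values, no multiple-testing correction by
default), Kruskal–Wallis omnibus tests with Wilcoxon rank-sum post-hocs,
one-way ANOVA with Tukey HSD, compact letter displays summarising the
pairwise results, and species-presence summaries per ecological zone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrelationMatrix",
    "GroupComparison",
    "ENV_VARIABLES",
    "spearman_matrix",
    "compact_letter_display",
    "kw_posthoc",
    "anova_tukey",
    "ecozone_presence",
    "env_group_compare",
    "read_env_records",
]

ENV_VARIABLES = ("VPD", "PPT", "TMIN", "TMAX", "ET0", "AI", "Elev")

#: FAO-style ecological-zone vocabulary accepted in records files.
ECOZONES = (
    "Tropical rainforest",
    "Tropical moist deciduous forest",
    "Tropical dry forest",
    "Tropical shrubland",
    "Tropical desert",
    "Tropical mountain system",
    "Subtropical humid forest",
    "Subtropical dry forest",
    "Subtropical steppe",
    "Subtropical desert",
    "Subtropical mountain system",
    "Temperate oceanic forest",
    "Temperate continental forest",
    "Temperate steppe",
    "Temperate desert",
    "Temperate mountain system",
    "Boreal coniferous forest",
    "Boreal tundra woodland",
    "Boreal mountain system",
    "Polar",
)


@dataclass
class CorrelationMatrix:
    rho: pd.DataFrame
    p: pd.DataFrame
    alpha: float = 0.05

    @property
    def significant(self) -> pd.DataFrame:
        return (self.p < self.alpha) & self.rho.notna()

    def n_significant_pairs(self) -> int:
        mask = self.significant.to_numpy()
        return int(np.triu(mask, k=1).sum())

    def n_defined_pairs(self) -> int:
        mask = self.rho.notna().to_numpy()
        return int(np.triu(mask, k=1).sum())

    def strong_pairs(self, r2_min: float = 0.60) -> pd.DataFrame:
        """Pairs with p < alpha and rho² above ``r2_min``."""
        rows = []
        cols = list(self.rho.columns)
        for i, a in enumerate(cols):
            for b in cols[i + 1:]:
                r, pv = self.rho.at[a, b], self.p.at[a, b]
                if pd.notna(r) and pv < self.alpha and r * r > r2_min:
                    rows.append({"trait_a": a, "trait_b": b,
                                 "rho": r, "p": pv})
        return pd.DataFrame(rows, columns=["trait_a", "trait_b", "rho", "p"])


@dataclass
class GroupComparison:
    """One variable compared across groups."""

    variable: str
    groups: list[str]
    n: pd.Series
    median: pd.Series
    mean: pd.Series
    statistic: float               # H or F
    statistic_name: str            # "H" | "F"
    df: float
    p: float
    pairwise_p: pd.DataFrame
    letters: dict[str, str]
    alpha: float = 0.05
    notes: list[str] = field(default_factory=list)

    def check_letters(self) -> None:
        """Verify the compact-letter-display consistency invariant."""
        for a, b in combinations(self.groups, 2):
            share = set(self.letters[a]) & set(self.letters[b])
            pv = self.pairwise_p.at[a, b]
            if pv < self.alpha and share:
                raise AssertionError(
                    f"{a} and {b} share a letter but p={pv:.4g} < alpha")
            if pv >= self.alpha and not share:
                raise AssertionError(
                    f"{a} and {b} share no letter but p={pv:.4g} >= alpha")

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"n": self.n, "median": self.median,
                            "mean": self.mean,
                            "letters": pd.Series(self.letters)})
        out.index.name = "group"
        return out


# ---------------------------------------------------------------------------
# Spearman

def spearman_matrix(values: pd.DataFrame, alpha: float = 0.05,
                    min_pairs: int = 3, holm: bool = False
                    ) -> CorrelationMatrix:
    """Spearman rho and two-sided p for every pair of columns.

    Pairwise-complete observations; cells with fewer than ``min_pairs``
    complete pairs are left undefined (NaN).  ``holm=True`` applies a Holm
    correction across the upper-triangle p-values (off by default).
    """
    cols = list(values.columns)
    k = len(cols)
    rho = pd.DataFrame(np.eye(k), index=cols, columns=cols, dtype=float)
    p = pd.DataFrame(np.zeros((k, k)), index=cols, columns=cols, dtype=float)
    for i, a in enumerate(cols):
        for j in range(i + 1, k):
            b = cols[j]
            sub = values[[a, b]].dropna()
            if len(sub) < min_pairs or sub[a].nunique() < 2 \
                    or sub[b].nunique() < 2:
                rho.at[a, b] = rho.at[b, a] = np.nan
                p.at[a, b] = p.at[b, a] = np.nan
                continue
            r, pv = stats.spearmanr(sub[a], sub[b])
            rho.at[a, b] = rho.at[b, a] = r
            p.at[a, b] = p.at[b, a] = pv
    if holm:
        pairs = [(cols[i], cols[j]) for i in range(k) for j in range(i + 1, k)
                 if pd.notna(p.at[cols[i], cols[j]])]
        raw = np.array([p.at[a, b] for a, b in pairs])
        order = np.argsort(raw)
        m = len(raw)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * raw[idx])
            adj[idx] = min(1.0, running)
        for (a, b), v in zip(pairs, adj):
            p.at[a, b] = p.at[b, a] = v
    return CorrelationMatrix(rho=rho, p=p, alpha=alpha)


# ---------------------------------------------------------------------------
# Compact letter display

def compact_letter_display(groups: list[str], pairwise_p: pd.DataFrame,
                           alpha: float = 0.05) -> dict[str, str]:
    """Greedy insert-absorb letter assignment.

    Groups sharing a letter are pairwise non-significant; groups sharing
    no letter differ at ``alpha``.
    """
    letter_sets: list[set[str]] = []
    for g in groups:
        placed = False
        for s in letter_sets:
            if all(pairwise_p.at[g, h] >= alpha for h in s):
                s.add(g)
                placed = True
        if not placed:
            # new letter set seeded with g plus every compatible earlier group
            new = {g}
            for h in groups:
                if h == g:
                    continue
                if all(pairwise_p.at[h, m] >= alpha for m in new):
                    new.add(h)
            letter_sets.append(new)
    # absorb: drop sets fully contained in another
    letter_sets = [s for i, s in enumerate(letter_sets)
                   if not any(s < t for j, t in enumerate(letter_sets)
                              if i != j)]
    # ensure every non-significant pair shares a set
    for a, b in combinations(groups, 2):
        if pairwise_p.at[a, b] >= alpha and \
                not any(a in s and b in s for s in letter_sets):
            letter_sets.append({a, b})
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in groups}
    for s, ch in zip(letter_sets, alphabet):
        for g in sorted(s):
            letters[g] += ch
    for g in groups:
        letters[g] = "".join(sorted(letters[g]))
    return letters


# ---------------------------------------------------------------------------
# Omnibus + post-hoc machines

def _prepare_groups(values: pd.Series, groups: pd.Series, min_n: int = 2
                    ) -> tuple[dict[str, np.ndarray], list[str]]:
    df = pd.DataFrame({"v": values, "g": groups}).dropna()
    data, notes = {}, []
    for g, sub in df.groupby("g", sort=True):
        arr = sub["v"].to_numpy(dtype=float)
        if len(arr) < min_n:
            notes.append(f"group {g} excluded (n={len(arr)} < {min_n})")
            warnings.warn(notes[-1])
            continue
        data[str(g)] = arr
    return data, notes


def _rank_sum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p: exact enumeration for small tie-free
    samples, normal approximation with tie/continuity correction otherwise."""
    if np.ptp(np.concatenate([a, b])) == 0:
        return 1.0
    small = len(a) <= 10 and len(b) <= 10
    no_ties = len(np.unique(np.concatenate([a, b]))) == len(a) + len(b)
    method = "exact" if (small and no_ties) else "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                    method=method).pvalue)


def _pairwise_frame(data: dict[str, np.ndarray], fn) -> pd.DataFrame:
    gs = list(data)
    out = pd.DataFrame(np.ones((len(gs), len(gs))), index=gs, columns=gs)
    for a, b in combinations(gs, 2):
        pv = fn(data[a], data[b])
        out.at[a, b] = out.at[b, a] = pv
    return out


def _comparison(variable, data, notes, stat, stat_name, df_, p, pairwise,
                alpha) -> GroupComparison:
    gs = list(data)
    comp = GroupComparison(
        variable=variable, groups=gs,
        n=pd.Series({g: len(v) for g, v in data.items()}),
        median=pd.Series({g: float(np.median(v)) for g, v in data.items()}),
        mean=pd.Series({g: float(np.mean(v)) for g, v in data.items()}),
        statistic=stat, statistic_name=stat_name, df=df_, p=p,
        pairwise_p=pairwise,
        letters=compact_letter_display(gs, pairwise, alpha),
        alpha=alpha, notes=notes)
    comp.check_letters()
    # flag internally inconsistent omnibus reports (large statistic but
    # non-significant p cannot happen at these df)
    crit = stats.chi2.ppf(1 - alpha, df_) if stat_name == "H" else None
    if crit is not None and stat > crit and p >= alpha:
        comp.notes.append(
            f"inconsistent omnibus report: {stat_name}={stat:.3g} exceeds "
            f"the critical value at df={df_:g} yet p={p:.3g} >= {alpha}")
    return comp


def kw_posthoc(values: pd.Series, groups: pd.Series, alpha: float = 0.05
               ) -> GroupComparison:
    """Kruskal–Wallis omnibus (tie-corrected) + pairwise rank-sum post-hocs
    with a compact letter display."""
    data, notes = _prepare_groups(values, groups)
    if len(data) < 2:
        raise ValueError("need at least 2 groups with >= 2 observations")
    arrays = list(data.values())
    if np.ptp(np.concatenate(arrays)) == 0:
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*arrays)
    pairwise = _pairwise_frame(data, _rank_sum_p)
    return _comparison(values.name or "value", data, notes, float(h), "H",
                       len(data) - 1, float(p), pairwise, alpha)


def anova_tukey(values: pd.Series, groups: pd.Series, alpha: float = 0.05
                ) -> GroupComparison:
    """One-way ANOVA + Tukey HSD post-hocs with a compact letter display."""
    data, notes = _prepare_groups(values, groups)
    if len(data) < 2:
        raise ValueError("need at least 2 groups with >= 2 observations")
    arrays = list(data.values())
    if np.ptp(np.concatenate(arrays)) == 0:
        f, p = 0.0, 1.0
        gs = list(data)
        pairwise = pd.DataFrame(np.ones((len(gs), len(gs))),
                                index=gs, columns=gs)
    else:
        f, p = stats.f_oneway(*arrays)
        res = stats.tukey_hsd(*arrays)
        gs = list(data)
        pairwise = pd.DataFrame(res.pvalue, index=gs, columns=gs)
        np.fill_diagonal(pairwise.to_numpy(), 1.0)
        for i, g in enumerate(gs):
            pairwise.at[g, g] = 1.0
    return _comparison(values.name or "value", data, notes, float(f), "F",
                       len(data) - 1, float(p), pairwise, alpha)


# ---------------------------------------------------------------------------
# Environmental records

def read_env_records(path) -> pd.DataFrame:
    """Read an occurrence-records CSV:
    ``species,lat,lon,VPD,PPT,TMIN,TMAX,ET0,AI,Elev,ecozone``."""
    rec = pd.read_csv(path)
    required = {"species", "lat", "lon", "ecozone"}
    missing = required - set(rec.columns)
    if missing:
        raise ValueError(f"records CSV missing column(s): {sorted(missing)}")
    if ((rec["lat"] < -90) | (rec["lat"] > 90)).any():
        raise ValueError("latitude out of [-90, 90]")
    if ((rec["lon"] < -180) | (rec["lon"] > 180)).any():
        raise ValueError("longitude out of [-180, 180]")
    unknown = set(rec["ecozone"]) - set(ECOZONES)
    if unknown:
        warnings.warn(f"ecozone label(s) outside the FAO vocabulary: "
                      f"{sorted(unknown)}")
    return rec


def ecozone_presence(records: pd.DataFrame, labels: pd.Series
                     ) -> pd.DataFrame:
    """Species richness per (functional group, ecological zone).

    Cell (g, z) counts distinct species of group g with at least one
    record in zone z; duplicated records never inflate the count.
    Records of unlabeled species are excluded with a warning.
    """
    rec = records.copy()
    rec["group"] = rec["species"].map(labels)
    unlab = rec["species"][rec["group"].isna()].unique()
    if len(unlab):
        warnings.warn(f"excluding records of unlabeled species: "
                      f"{sorted(unlab)}")
        rec = rec[rec["group"].notna()]
    out = (rec.drop_duplicates(["species", "ecozone"])
              .groupby(["group", "ecozone"], observed=True)["species"]
              .nunique().unstack(fill_value=0))
    return out


def env_group_compare(records: pd.DataFrame, labels: pd.Series,
                      variables: tuple[str, ...] = ENV_VARIABLES,
                      alpha: float = 0.05, per_species_mean: bool = False
                      ) -> dict[str, GroupComparison]:
    """Kruskal–Wallis + rank-sum post-hocs per environmental variable.

    The comparison unit is the raw record; ``per_species_mean=True``
    collapses to one mean per species first (non-default).
    """
    rec = records.copy()
    rec["group"] = rec["species"].map(labels)
    rec = rec[rec["group"].notna()]
    if rec["group"].nunique() < 2:
        warnings.warn("fewer than 2 labeled groups; comparisons skipped")
        return {}
    out = {}
    for var in variables:
        if var not in rec.columns:
            warnings.warn(f"variable {var} absent from records; skipped")
            continue
        sub = rec[["species", "group", var]].dropna()
        if per_species_mean:
            sub = (sub.groupby(["species", "group"], observed=True)[var]
                      .mean().reset_index())
        comp = kw_posthoc(sub[var].rename(var), sub["group"], alpha=alpha)
        out[var] = comp
    return out
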