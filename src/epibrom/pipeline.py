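"""End-to-end orchestration: ingest → derive → filter → impute →
transform → cluster → discriminant validation → classify → statistics.

Every stage writes its artifact under the run directory and logs its
input/output shapes; the run ends with a machine-readable ``summary.json``
(stage counts, Mahalanobis matrix, group composition, letters tables).
Optional inputs degrade gracefully: without a tree the imputation falls
through to genus means; without occurrence records the environmental
stages are skipped with a warning.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import cluster_da, fg_classify, group_stats, phylo_impute, preprocess
from .registry import clustering_traits, default_registry, load_registry
from .trait_db import (TraitTable, drop_sparse_species, fill_derived_traits,
                       read_trait_table, write_trait_table)

logger = logging.getLogger("epibrom")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    traits_path: str
    out_dir: str
    tree_path: str | None = None
    records_path: str | None = None
    registry_path: str | None = None
    k: int = 5
    alpha: float = 0.05
    seed: int = 0
    min_traits: int = 5
    coverage_frac: float = 0.70
    include_pb: bool = True
    shrinkage: float = 0.01
    thresholds: fg_classify.RuleThresholds = \
        field(default_factory=fg_classify.RuleThresholds)

    def validate(self) -> None:
        if not Path(self.traits_path).exists():
            raise FileNotFoundError(f"traits file {self.traits_path}")
        for p in (self.tree_path, self.records_path, self.registry_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        thr = raw.pop("thresholds", None)
        cfg = cls(**raw)
        if thr:
            if "cam_shallow_tc_range" in thr:
                thr["cam_shallow_tc_range"] = tuple(
                    thr["cam_shallow_tc_range"])
            cfg.thresholds = fg_classify.RuleThresholds(**thr)
        return cfg


def _stage(summary: dict, name: str, **info) -> None:
    summary["stages"].append({"stage": name, **info})
    logger.info("stage %-18s %s", name,
                " ".join(f"{k}={v}" for k, v in info.items()))


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full pipeline; returns (and writes) the run summary."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": cfg.seed, "k": cfg.k, "alpha": cfg.alpha,
                     "stages": [], "warnings": []}

    registry = load_registry(cfg.registry_path) if cfg.registry_path \
        else default_registry()
    table = read_trait_table(cfg.traits_path, registry)
    _stage(summary, "ingest", n_species=len(table.species),
           n_traits=len(table.trait_names))

    table = fill_derived_traits(table)
    _stage(summary, "derive", n_missing=table.n_missing())

    table, removed = drop_sparse_species(table, cfg.min_traits)
    _stage(summary, "sparse_filter", n_species=len(table.species),
           n_removed=len(removed), removed=removed)

    cluster_cols = [c for c in clustering_traits(registry)
                    if c in table.values.columns]
    if not cfg.include_pb and "PB" in cluster_cols:
        cluster_cols.remove("PB")
    clust = table.subset_traits(cluster_cols)
    clust = phylo_impute.coverage_filter(clust, cfg.coverage_frac)
    _stage(summary, "coverage_filter", n_species=len(clust.species),
           n_traits=len(clust.trait_names))

    tree = None
    if cfg.tree_path:
        tree = phylo_impute.read_newick(cfg.tree_path)
        imp, report = phylo_impute.impute_bm(clust, tree)
        imp, report = phylo_impute.reject_out_of_range(imp, report)
    else:
        summary["warnings"].append(
            "no tree supplied: imputation falls through to genus means")
        imp = clust
        report = phylo_impute.ImputationReport(
            n_missing_before=clust.n_missing())
    imp, report = phylo_impute.impute_genus_mean(imp, report)
    report.check_balance()
    report.to_frame().to_csv(out / "imputation_report.csv", index=False)
    summary["imputation"] = report.summary()
    _stage(summary, "impute", **report.summary())

    # species still missing a clustering cell cannot enter the distance
    # computation (monotypic-genus holes)
    complete = imp.values.dropna().index
    n_dropped = len(imp.species) - len(complete)
    if n_dropped:
        summary["warnings"].append(
            f"{n_dropped} species dropped before clustering "
            "(unfillable cells)")
    analysis = imp.subset_species(list(complete))

    spec = preprocess.default_transform_spec(include_pb=cfg.include_pb)
    matrix = preprocess.transform(analysis, spec)
    matrix.to_csv(out / "transformed_matrix.csv", float_format="%.9g")
    _stage(summary, "transform", shape=list(matrix.shape))

    row_tree, col_tree, ordered = cluster_da.two_way_cluster(matrix)
    row_tree.to_merge_frame().to_csv(out / "species_linkage.csv",
                                     index=False)
    col_tree.to_merge_frame().to_csv(out / "trait_linkage.csv", index=False)
    (out / "species_dendrogram.nwk").write_text(row_tree.to_newick() + "\n")
    ordered.to_csv(out / "heatmap_matrix.csv", float_format="%.9g")
    cluster_map = cluster_da.cut_tree(row_tree, cfg.k)
    pd.Series(cluster_map, name="cluster_id").rename_axis("species") \
        .to_csv(out / "clusters.csv")
    _stage(summary, "cluster", k=cfg.k)

    labels_frame, moves = fg_classify.reconcile_with_clusters(
        cluster_map, analysis.values, analysis.flags, cfg.thresholds)
    labels = labels_frame["label"].reindex(matrix.index)
    summary["reconciliation_moves"] = moves
    _stage(summary, "reconcile", n_moves=len(moves))

    model = cluster_da.fit_discriminant(matrix, labels,
                                        shrinkage=cfg.shrinkage)
    dmat = cluster_da.mahalanobis_matrix(model)
    dmat.to_csv(out / "mahalanobis_matrix.csv", float_format="%.6g")
    summary["mahalanobis"] = {
        f"{a}|{b}": round(float(dmat.at[a, b]), 6)
        for i, a in enumerate(dmat.index) for b in dmat.index[i + 1:]}
    agreement = float((model.classify(matrix) == labels).mean())
    summary["da_training_agreement"] = round(agreement, 4)
    _stage(summary, "discriminant", training_agreement=round(agreement, 4))

    # rule-based classification of the full table (beyond the cluster set)
    rule_frame = fg_classify.classify_table(table.values, table.flags,
                                            cfg.thresholds)
    merged = rule_frame["label"].copy()
    merged.loc[labels.index] = labels
    rule_frame.to_csv(out / "classification.csv")
    comp = fg_classify.group_composition(
        merged[merged.isin(fg_classify.GROUPS)])
    comp.to_csv(out / "group_composition.csv")
    summary["group_percent"] = {g: int(comp.at[g, "percent"])
                                for g in comp.index}
    summary["group_count"] = {g: int(comp.at[g, "count"])
                              for g in comp.index}
    _stage(summary, "classify", n_classified=int(comp["count"].sum()))

    corr = group_stats.spearman_matrix(table.values[
        [c for c in table.values.columns
         if c not in ("PB", "PP")]], alpha=cfg.alpha)
    corr.rho.to_csv(out / "spearman_rho.csv", float_format="%.6g")
    corr.p.to_csv(out / "spearman_p.csv", float_format="%.6g")
    summary["spearman"] = {
        "n_pairs": corr.n_defined_pairs(),
        "n_significant": corr.n_significant_pairs()}
    _stage(summary, "correlations", **summary["spearman"])

    letters = {}
    for trait in analysis.values.columns:
        try:
            cmpn = group_stats.kw_posthoc(analysis.values[trait],
                                          merged.loc[analysis.species],
                                          alpha=cfg.alpha)
        except ValueError:
            continue
        letters[trait] = {"H": round(cmpn.statistic, 4),
                          "p": float(cmpn.p), "letters": cmpn.letters}
    summary["trait_comparisons"] = letters
    _stage(summary, "trait_stats", n_traits=len(letters))

    if cfg.records_path:
        records = group_stats.read_env_records(cfg.records_path)
        richness = group_stats.ecozone_presence(records, merged)
        richness.to_csv(out / "ecozone_richness.csv")
        envcmp = group_stats.env_group_compare(records, merged,
                                               alpha=cfg.alpha)
        summary["environment"] = {
            var: {"H": round(c.statistic, 4), "p": float(c.p),
                  "letters": c.letters}
            for var, c in envcmp.items()}
        _stage(summary, "environment", n_variables=len(envcmp))
    else:
        summary["warnings"].append(
            "no occurrence records supplied: environmental stages skipped")

    write_trait_table(table, out / "trait_table_filled.csv",
                      out / "trait_provenance.csv")
    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
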