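"""Gap-filling of the clustering trait matrix.

Pipeline order: (1) iteratively drop traits with < 70 % species coverage
and species with < 70 % trait coverage; (2) impute missing cells of
tree-member species under a multivariate Brownian-motion model fitted by
maximum likelihood (EM over the missing entries); (3) reject imputed
values outside the observed per-trait range; (4) fall back to genus means
for everything still missing, leaving cells empty when the genus offers no
reference value.

The Brownian-motion model treats the p traits of the n tips as one
matrix-normal draw: stacking species-major, the joint covariance is
C ⊗ R, where C is the n × n matrix of shared root-to-ancestor path lengths
on the tree and R the p × p trait rate (co)variance matrix; the mean is
the ancestral trait vector replicated over tips.  Missing cells are filled
with their conditional expectation given the observed cells under the
fitted (μ, R).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .trait_db import TraitTable

__all__ = [
    "Phylogeny",
    "ImputationReport",
    "coverage_filter",
    "read_newick",
    "write_newick",
    "impute_bm",
    "reject_out_of_range",
    "impute_genus_mean",
    "impute_pipeline",
]


class Phylogeny:
    """Rooted tree with branch lengths, thin wrapper over dendropy."""

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        labels = self.tip_labels
        if len(set(labels)) != len(labels):
            dup = sorted({x for x in labels if labels.count(x) > 1})
            raise ValueError(f"duplicated tip label(s): {dup}")
        for edge in tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise ValueError("negative branch length")

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def __len__(self) -> int:
        return len(self.tree.leaf_nodes())

    def vcv(self, order: list[str] | None = None) -> pd.DataFrame:
        """Phylogenetic covariance matrix: entry (i, j) is the root-to-MRCA
        path length of tips i and j (branch lengths summed)."""
        pdm = self.tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in self.tree.taxon_namespace
                if t.label in set(self.tip_labels)}
        labels = order if order is not None else self.tip_labels
        depth = {}
        for leaf in self.tree.leaf_node_iter():
            depth[leaf.taxon.label] = leaf.distance_from_root()
        n = len(labels)
        C = np.zeros((n, n))
        for i, a in enumerate(labels):
            C[i, i] = depth[a]
            for j in range(i + 1, n):
                b = labels[j]
                d = pdm.distance(taxa[a], taxa[b])
                shared = 0.5 * (depth[a] + depth[b] - d)
                C[i, j] = C[j, i] = shared
        return pd.DataFrame(C, index=labels, columns=labels)

    def to_newick(self) -> str:
        return self.tree.as_string(schema="newick",
                                   suppress_rooting=True).strip()


@dataclass
class ImputationReport:
    """Bookkeeping for the gap-filling chain.

    Invariant: ``n_missing_before == n_imputed_phylo + n_imputed_genus +
    n_left_empty`` — rejected phylo-imputations re-enter the genus-mean
    pool, so they are not counted separately in the balance.
    """

    n_missing_before: int = 0
    n_imputed_phylo: int = 0
    n_rejected: int = 0
    n_imputed_genus: int = 0
    n_left_empty: int = 0
    records: list[dict] = field(default_factory=list)

    def add(self, species: str, trait: str, method: str, value) -> None:
        self.records.append({"species": species, "trait": trait,
                             "method": method, "value": value})

    def check_balance(self) -> None:
        total = self.n_imputed_phylo + self.n_imputed_genus + self.n_left_empty
        if self.n_missing_before != total:
            raise AssertionError(
                f"imputation balance broken: {self.n_missing_before} missing "
                f"!= {self.n_imputed_phylo} phylo + {self.n_imputed_genus} "
                f"genus + {self.n_left_empty} empty")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records,
                            columns=["species", "trait", "method", "value"])

    def summary(self) -> dict:
        return {
            "n_missing_before": self.n_missing_before,
            "n_imputed_phylo": self.n_imputed_phylo,
            "n_rejected": self.n_rejected,
            "n_imputed_genus": self.n_imputed_genus,
            "n_left_empty": self.n_left_empty,
        }


# ---------------------------------------------------------------------------
# Coverage filter

def coverage_filter(t: TraitTable, min_frac: float = 0.70) -> TraitTable:
    """Iteratively drop traits then species below ``min_frac`` coverage.

    Traits are dropped first (coverage = fraction of species with data for
    the trait), then species (fraction of remaining traits with data),
    repeating to a fixed point.  Deterministic by construction.
    """
    if t.values.empty:
        raise ValueError("coverage filter received an empty table")
    cur = t.copy()
    while True:
        vals = cur.values
        trait_cov = vals.notna().mean(axis=0)
        keep_traits = trait_cov.index[trait_cov >= min_frac]
        changed = len(keep_traits) < vals.shape[1]
        cur = cur.subset_traits(list(keep_traits))
        if cur.values.shape[1] == 0:
            raise ValueError("coverage filter removed all rows")
        sp_cov = cur.values.notna().mean(axis=1)
        keep_sp = sp_cov.index[sp_cov >= min_frac]
        changed = changed or len(keep_sp) < cur.values.shape[0]
        cur = cur.subset_species(list(keep_sp))
        if cur.values.shape[0] == 0:
            raise ValueError("coverage filter removed all rows")
        if not changed:
            return cur


# ---------------------------------------------------------------------------
# Newick I/O

def read_newick(path_or_string) -> Phylogeny:
    """Read a newick tree from a path or a literal newick string."""
    src = str(path_or_string)
    try:
        if src.strip().startswith("(") and src.strip().endswith(";"):
            tree = dendropy.Tree.get(data=src, schema="newick")
        else:
            tree = dendropy.Tree.get(path=src, schema="newick")
    except Exception as exc:
        msg = str(exc)
        if "Duplicate taxon" in msg or "Multiple occurrences" in msg:
            raise ValueError(f"duplicated tip label in newick: {msg}") \
                from exc
        raise ValueError(f"malformed newick: {msg}") from exc
    return Phylogeny(tree)


def write_newick(phy: Phylogeny, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(phy.to_newick() + "\n")


# ---------------------------------------------------------------------------
# Multivariate Brownian-motion imputation

def _bm_em(X: np.ndarray, C: np.ndarray, max_iter: int = 500,
           tol: float = 1e-8) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fit ancestral mean μ and rate matrix R by EM; return (mu, R, Xhat).

    ``X`` is n × p with NaN for missing; ``C`` the n × n tree covariance.
    ``Xhat`` carries conditional expectations in the missing cells.

    Columns are standardised internally (the model class is closed under
    per-column affine maps, so the imputed values are unaffected; the
    conditioning of the joint covariance improves enormously when traits
    span very different scales).
    """
    loc = np.nanmean(X, axis=0)
    scale = np.nanstd(X, axis=0)
    scale[scale <= 0] = 1.0
    mu_s, R_s, Xhat_s = _bm_em_standardised((X - loc) / scale, C,
                                            max_iter, tol)
    mu = loc + scale * mu_s
    R = R_s * np.outer(scale, scale)
    return mu, R, loc + scale * Xhat_s


def _bm_em_standardised(X: np.ndarray, C: np.ndarray, max_iter: int,
                        tol: float) -> tuple[np.ndarray, np.ndarray,
                                             np.ndarray]:
    n, p = X.shape
    mask = np.isnan(X)
    Cinv = np.linalg.inv(C)
    one = np.ones(n)
    w = Cinv @ one / (one @ Cinv @ one)  # GLS weights for the mean

    # init: column means / covariance on available data
    mu = np.nanmean(X, axis=0)
    Xf = np.where(mask, mu, X)
    R = np.cov(Xf, rowvar=False, bias=True)
    R = np.atleast_2d(R)
    _regularize(R)

    miss_flat = mask.ravel()  # species-major flattening, consistent with kron
    obs_flat = ~miss_flat
    ll_old = -np.inf
    Xhat = Xf.copy()
    for _ in range(max_iter):
        Sigma = np.kron(C, R)
        mvec = np.tile(mu, n)
        Soo = Sigma[np.ix_(obs_flat, obs_flat)]
        xo = X.ravel()[obs_flat]
        ro = xo - mvec[obs_flat]
        ridge = 1e-10 * np.trace(Soo) / Soo.shape[0]
        for _attempt in range(12):
            try:
                Loo = np.linalg.cholesky(
                    Soo if _attempt == 0
                    else Soo + ridge * np.eye(Soo.shape[0]))
                break
            except np.linalg.LinAlgError:
                ridge *= 100.0
        else:
            raise np.linalg.LinAlgError(
                "observed-block covariance not positive definite")
        alpha = np.linalg.solve(Loo.T, np.linalg.solve(Loo, ro))
        ll = -0.5 * (ro @ alpha) - np.log(np.diag(Loo)).sum() \
            - 0.5 * obs_flat.sum() * np.log(2 * np.pi)

        if miss_flat.any():
            Smo = Sigma[np.ix_(miss_flat, obs_flat)]
            cond_mean = mvec[miss_flat] + Smo @ alpha
            # conditional covariance of the missing block
            tmp = np.linalg.solve(Loo, Smo.T)
            Vmm = Sigma[np.ix_(miss_flat, miss_flat)] - tmp.T @ tmp
        else:
            cond_mean = np.empty(0)
            Vmm = np.zeros((0, 0))

        z = X.ravel().copy()
        z[miss_flat] = cond_mean
        Xhat = z.reshape(n, p)

        # M-step.  mu: GLS mean of the completed data.
        mu = Xhat.T @ w
        Res = Xhat - mu  # n × p
        S = Res.T @ Cinv @ Res
        # correction from conditional covariance of missing entries
        if miss_flat.any():
            midx = np.flatnonzero(miss_flat)
            sp_i, tr_a = np.divmod(midx, p)
            Cw = Cinv[np.ix_(sp_i, sp_i)] * Vmm  # elementwise: (C^-1)_{ij} V
            # accumulate into S[a, b]
            for a in range(p):
                ia = tr_a == a
                if not ia.any():
                    continue
                for b in range(p):
                    ib = tr_a == b
                    if not ib.any():
                        continue
                    S[a, b] += Cw[np.ix_(ia, ib)].sum()
        R = S / n
        _regularize(R)

        if abs(ll - ll_old) < tol:
            break
        ll_old = ll
    return mu, R, Xhat


def _regularize(R: np.ndarray) -> None:
    # symmetrise first: roundoff asymmetry from the M-step compounds
    # geometrically over EM iterations if left in place
    p = R.shape[0]
    R[:] = 0.5 * (R + R.T)
    R += np.eye(p) * (1e-8 * max(np.trace(R), 1e-12) / p)


def impute_bm(t: TraitTable, tree: Phylogeny
              ) -> tuple[TraitTable, ImputationReport]:
    """Impute missing cells of tree-member species under multivariate BM.

    Species absent from the tree are untouched (they fall through to the
    genus-mean stage).  Filled cells get provenance ``imputed_phylo``.
    """
    report = ImputationReport(n_missing_before=t.n_missing())
    tips = [s for s in t.species if s in set(tree.tip_labels)]
    if not tips or t.n_missing() == 0:
        return t.copy(), report

    sub = t.values.loc[tips]
    if not sub.isna().any().any():
        return t.copy(), report
    C = tree.vcv(order=tips).to_numpy()
    X = sub.to_numpy(dtype=float)
    try:
        mu, R, Xhat = _bm_em(X, C)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "degenerate trait covariance in BM imputation; consider the "
            "genus-mean fallback") from exc

    out = t.copy()
    mask = np.isnan(X)
    binary = {d.abbreviation for d in t.registry if d.kind == "binary"}
    for i, sp in enumerate(tips):
        for j, trait in enumerate(sub.columns):
            if mask[i, j]:
                val = Xhat[i, j]
                if trait in binary:
                    # conditional expectation thresholded back to presence
                    val = 1.0 if val >= 0.5 else 0.0
                out.values.at[sp, trait] = val
                out.provenance.at[sp, trait] = "imputed_phylo"
                report.n_imputed_phylo += 1
                report.add(sp, trait, "imputed_phylo", val)
    return out, report


def reject_out_of_range(t: TraitTable, report: ImputationReport
                        ) -> tuple[TraitTable, ImputationReport]:
    """Revert phylo-imputed values outside the observed per-trait range.

    The expected range is the [min, max] of non-imputed cells for that
    trait.  Rejected cells become missing again and are re-counted out of
    the phylo-imputation tally (they re-enter the genus-mean pool).
    """
    out = t.copy()
    imput = out.provenance == "imputed_phylo"
    for trait in out.values.columns:
        col = out.values[trait]
        observed = col[~imput[trait] & col.notna()]
        if observed.empty:
            continue
        lo, hi = observed.min(), observed.max()
        for sp in out.values.index:
            if imput.at[sp, trait] and not pd.isna(col.at[sp]):
                val = col.at[sp]
                if val < lo or val > hi:
                    out.values.at[sp, trait] = np.nan
                    out.provenance.at[sp, trait] = ""
                    report.n_rejected += 1
                    report.n_imputed_phylo -= 1
                    report.add(sp, trait, "rejected", val)
    return out, report


def impute_genus_mean(t: TraitTable,
                      report: ImputationReport | None = None
                      ) -> tuple[TraitTable, ImputationReport]:
    """Fill remaining missing cells with the genus mean of the trait.

    Cells in genera with no other value for the trait stay empty and are
    counted as ``n_left_empty``.  Provenance ``imputed_genus``.
    """
    if report is None:
        report = ImputationReport(n_missing_before=t.n_missing())
    out = t.copy()
    binary = {d.abbreviation for d in t.registry if d.kind == "binary"}
    for trait in out.values.columns:
        col = out.values[trait]
        if not col.isna().any():
            continue
        means = col.groupby(out.genus).mean()
        for sp in out.values.index[col.isna()]:
            g = out.genus.at[sp]
            m = means.get(g)
            if m is not None and not pd.isna(m):
                if trait in binary:
                    m = 1.0 if m >= 0.5 else 0.0
                out.values.at[sp, trait] = m
                out.provenance.at[sp, trait] = "imputed_genus"
                report.n_imputed_genus += 1
                report.add(sp, trait, "imputed_genus", m)
            else:
                report.n_left_empty += 1
                report.add(sp, trait, "left_empty", np.nan)
    return out, report


def impute_pipeline(t: TraitTable, tree: Phylogeny | None = None,
                    min_frac: float = 0.70
                    ) -> tuple[TraitTable, ImputationReport]:
    """Full gap-filling chain: coverage filter → BM → range check → genus."""
    filtered = coverage_filter(t, min_frac=min_frac)
    if tree is not None:
        imp, report = impute_bm(filtered, tree)
        imp, report = reject_out_of_range(imp, report)
    else:
        imp = filtered
        report = ImputationReport(n_missing_before=filtered.n_missing())
    imp, report = impute_genus_mean(imp, report)
    report.check_balance()
    return imp, report
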