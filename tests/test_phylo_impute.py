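"""Coverage filtering, newick I/O and Brownian-motion gap-filling."""

import itertools

import numpy as np
import pandas as pd
import pytest

from epibrom.phylo_impute import (ImputationReport, coverage_filter,
                                  impute_bm, impute_genus_mean,
                                  impute_pipeline, read_newick,
                                  reject_out_of_range, write_newick)
from epibrom.benchmarks import imputation_mse_comparison

from conftest import make_table


def star_tree(n, prefix="sp"):
    return read_newick(
        "(" + ",".join(f"{prefix}{i}:1" for i in range(n)) + ");")


# ---------------------------------------------------------------------------
# Coverage filter

def test_coverage_filter_identity_on_complete():
    t = make_table({"TC": [1.0] * 10, "LW": [2.0] * 10})
    out = coverage_filter(t)
    pd.testing.assert_frame_equal(out.values, t.values)


def test_coverage_filter_drops_sparse_trait():
    # one trait observed for 6 of 10 species (60 %) falls below 70 %
    t = make_table({"Height": [1.0] * 10, "LA": [1.0] * 10,
                    "LL": [1.0] * 10, "TD": [1.0] * 6 + [np.nan] * 4})
    out = coverage_filter(t)
    assert "TD" not in out.values.columns
    assert len(out.species) == 10


def brute_force_coverage(values: pd.DataFrame, min_frac=0.70):
    """Exhaustive oracle: over all row/column subsets meeting both
    coverage criteria, return the one retaining the most cells."""
    best, best_cells = None, -1
    rows, cols = list(values.index), list(values.columns)
    for r in range(1, len(rows) + 1):
        for rsub in itertools.combinations(rows, r):
            for c in range(1, len(cols) + 1):
                for csub in itertools.combinations(cols, c):
                    sub = values.loc[list(rsub), list(csub)]
                    if (sub.notna().mean(axis=0) >= min_frac).all() and \
                       (sub.notna().mean(axis=1) >= min_frac).all():
                        cells = int(sub.notna().sum().sum())
                        if cells > best_cells:
                            best, best_cells = (set(rsub), set(csub)), cells
    return best


def test_coverage_filter_matches_exhaustive_oracle():
    # alternating missingness on a 6 x 4 instance: the iterative fixed
    # point equals the exhaustive retained-cells maximiser
    m = np.nan
    vals = pd.DataFrame(
        [[1.0, 1.0, 1.0, m],
         [1.0, 1.0, 1.0, m],
         [1.0, 1.0, 1.0, 1.0],
         [1.0, 1.0, m, m],
         [1.0, 1.0, 1.0, 1.0],
         [1.0, 1.0, 1.0, m]],
        columns=["Height", "LA", "LL", "TD"],
        index=[f"sp{i}" for i in range(6)])
    t = make_table({c: vals[c].tolist() for c in vals.columns})
    out = coverage_filter(t)
    oracle_rows, oracle_cols = brute_force_coverage(vals)
    assert set(out.species) == oracle_rows
    assert set(out.values.columns) == oracle_cols


def test_coverage_filter_all_removed_errors():
    t = make_table({"Height": [np.nan, 1.0, np.nan, np.nan, np.nan]})
    with pytest.raises(ValueError, match="removed all rows"):
        coverage_filter(t)


# ---------------------------------------------------------------------------
# Newick I/O

def test_read_newick_literal_and_round_trip(tmp_path):
    phy = read_newick("((A:1,B:1):1,C:2);")
    assert sorted(phy.tip_labels) == ["A", "B", "C"]
    assert len(phy) == 3
    path = tmp_path / "t.nwk"
    write_newick(phy, path)
    back = read_newick(path)
    assert sorted(back.tip_labels) == ["A", "B", "C"]
    C1 = phy.vcv(order=["A", "B", "C"]).to_numpy()
    C2 = back.vcv(order=["A", "B", "C"]).to_numpy()
    np.testing.assert_allclose(C1, C2, atol=1e-9)


def test_duplicate_tip_label_rejected():
    with pytest.raises(ValueError, match="duplicated tip"):
        read_newick("((A:1,A:1):1,C:2);")


def test_vcv_shared_path_lengths():
    C = read_newick("((A:1,B:1):1,C:2);").vcv(order=["A", "B", "C"])
    assert C.at["A", "A"] == pytest.approx(2.0)
    assert C.at["A", "B"] == pytest.approx(1.0)
    assert C.at["A", "C"] == pytest.approx(0.0)


# ---------------------------------------------------------------------------
# BM imputation

def test_star_tree_single_trait_imputes_mean():
    # independent tips under BM: the conditional expectation of a missing
    # tip is the GLS mean = arithmetic mean of the observed tips
    t = make_table({"TC": [1.0, 2.0, 3.0, 4.0, 5.0, np.nan]})
    out, report = impute_bm(t, star_tree(6))
    assert out.values.at["sp5", "TC"] == pytest.approx(3.0, abs=1e-6)
    assert report.n_imputed_phylo == 1
    assert out.provenance.at["sp5", "TC"] == "imputed_phylo"


def test_perfectly_correlated_traits_conditional_fill():
    rng = np.random.default_rng(3)
    x = rng.normal(5, 2, 12)
    y = 2 * x + 1
    vals = {"LL": x.tolist(), "LW": y.tolist()}
    vals["LW"][4] = np.nan
    t = make_table(vals)
    out, _ = impute_bm(t, star_tree(12))
    assert out.values.at["sp4", "LW"] == pytest.approx(2 * x[4] + 1,
                                                       abs=1e-6)


def test_no_missing_is_identity():
    t = make_table({"TC": [1.0, 2.0, 3.0]})
    out, report = impute_bm(t, star_tree(3))
    pd.testing.assert_frame_equal(out.values, t.values)
    assert report.summary() == {"n_missing_before": 0,
                                "n_imputed_phylo": 0, "n_rejected": 0,
                                "n_imputed_genus": 0, "n_left_empty": 0}


def test_species_off_tree_left_untouched():
    t = make_table({"TC": [1.0, 2.0, 3.0, np.nan]})
    out, report = impute_bm(t, star_tree(3))    # sp3 not on the tree
    assert pd.isna(out.values.at["sp3", "TC"])
    assert report.n_imputed_phylo == 0


# ---------------------------------------------------------------------------
# Range rejection and genus means

def test_reject_out_of_range_reverts_value():
    t = make_table({"TC": [0.0, 10.0, 4924.0, np.nan]})
    imp, report = impute_bm(t, star_tree(4))
    # force an out-of-range value to exercise the check
    imp.values.at["sp3", "TC"] = -4.0
    out, report = reject_out_of_range(imp, report)
    assert pd.isna(out.values.at["sp3", "TC"])
    assert report.n_rejected == 1
    assert report.n_imputed_phylo == 0


def test_reject_in_range_kept():
    t = make_table({"TC": [0.0, 10.0, 4924.0, np.nan]})
    imp, report = impute_bm(t, star_tree(4))
    val = imp.values.at["sp3", "TC"]
    assert 0.0 <= val <= 4924.0
    out, report = reject_out_of_range(imp, report)
    assert out.values.at["sp3", "TC"] == val
    assert report.n_rejected == 0


def test_genus_mean_fill_and_monotypic_left_empty():
    t = make_table({"TC": [2.0, 4.0, np.nan, np.nan]},
                   genus=["GenA", "GenA", "GenA", "GenB"])
    out, report = impute_genus_mean(t)
    assert out.values.at["sp2", "TC"] == pytest.approx(3.0)
    assert out.provenance.at["sp2", "TC"] == "imputed_genus"
    assert pd.isna(out.values.at["sp3", "TC"])      # monotypic genus
    assert report.n_imputed_genus == 1
    assert report.n_left_empty == 1
    report.check_balance()


def test_genus_mean_identity_when_complete():
    t = make_table({"TC": [2.0, 4.0]})
    out, report = impute_genus_mean(t)
    pd.testing.assert_frame_equal(out.values, t.values)
    assert report.n_imputed_genus == 0


# ---------------------------------------------------------------------------
# Chain properties

def test_chain_never_alters_observed_cells(default_dataset):
    table, tree, labels, _ = default_dataset
    observed_mask = table.values.notna()
    imputed, report = impute_pipeline(table, tree)
    common_sp = [s for s in imputed.species]
    common_tr = [c for c in imputed.values.columns]
    before = table.values.loc[common_sp, common_tr]
    after = imputed.values.loc[common_sp, common_tr]
    mask = observed_mask.loc[common_sp, common_tr]
    assert (before[mask] == after[mask]).all().all() or \
        np.allclose(before.values[mask.values],
                    after.values[mask.values], equal_nan=True)
    report.check_balance()


def test_imputed_fraction_matches_mask_difference(default_dataset):
    table, tree, _, _ = default_dataset
    imputed, report = impute_pipeline(table, tree)
    filled = table.values.loc[imputed.species,
                              imputed.values.columns].isna().sum().sum() \
        - imputed.values.isna().sum().sum()
    assert filled == report.n_imputed_phylo + report.n_imputed_genus


def test_bm_beats_genus_mean_under_signal_matches_on_star():
    strong = imputation_mse_comparison(seed=0, star=False)
    star = imputation_mse_comparison(seed=0, star=True)
    assert strong["mse_bm"] < strong["mse_genus"]
    assert abs(star["ratio"] - 1.0) <= 0.2
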