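"""Correlations, omnibus tests, compact letters, ecozone summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from epibrom.group_stats import (anova_tukey, compact_letter_display,
                                 ecozone_presence, env_group_compare,
                                 kw_posthoc, read_env_records,
                                 spearman_matrix)


# ---------------------------------------------------------------------------
# Spearman

def midrank_pearson(x, y):
    """Brute-force oracle: Pearson correlation of midranks."""
    def midranks(v):
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v), dtype=float)
        i = 0
        sv = np.asarray(v)[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sv[j + 1] == sv[i]:
                j += 1
            ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return ranks
    rx, ry = midranks(x), midranks(y)
    return np.corrcoef(rx, ry)[0, 1]


def test_perfect_monotone_pairs():
    df = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0],
                       "b": [10.0, 20.0, 40.0, 80.0],
                       "c": [8.0, 6.0, 4.0, 2.0]})
    m = spearman_matrix(df)
    assert m.rho.at["a", "b"] == pytest.approx(1.0)
    assert m.rho.at["a", "c"] == pytest.approx(-1.0)
    assert (np.diag(m.rho.to_numpy()) == 1.0).all()


def test_spearman_with_ties_matches_midrank_oracle():
    x = [1.0, 2.0, 2.0, 3.0, 5.0, 5.0, 5.0, 9.0]
    y = [2.0, 1.0, 4.0, 4.0, 4.0, 8.0, 7.0, 9.0]
    df = pd.DataFrame({"x": x, "y": y})
    m = spearman_matrix(df)
    assert m.rho.at["x", "y"] == pytest.approx(midrank_pearson(x, y),
                                               abs=1e-12)


def test_spearman_pairwise_complete_and_undefined_cells():
    df = pd.DataFrame({"x": [1.0, 2.0, 3.0, np.nan],
                       "y": [2.0, 4.0, np.nan, 8.0],
                       "z": [np.nan, np.nan, 1.0, 2.0]})
    m = spearman_matrix(df, min_pairs=3)
    assert pd.isna(m.rho.at["x", "z"])      # fewer than 3 complete pairs
    assert pd.isna(m.rho.at["x", "y"])      # 2 complete pairs only


def test_spearman_monotone_invariance():
    rng = np.random.default_rng(2)
    x = rng.normal(size=30)
    y = x + rng.normal(0, 0.5, size=30)
    m1 = spearman_matrix(pd.DataFrame({"x": x, "y": y}))
    m2 = spearman_matrix(pd.DataFrame({"x": np.exp(x), "y": y ** 3}))
    assert m1.rho.at["x", "y"] == pytest.approx(m2.rho.at["x", "y"])
    assert np.allclose(m1.rho.to_numpy(), m1.rho.to_numpy().T)


def test_spearman_strong_pair_filter():
    rng = np.random.default_rng(4)
    x = rng.normal(size=40)
    df = pd.DataFrame({"x": x, "y": x + rng.normal(0, 0.2, 40),
                       "z": rng.normal(size=40)})
    m = spearman_matrix(df)
    strong = m.strong_pairs(r2_min=0.60)
    assert {"x", "y"} == set(strong.iloc[0][["trait_a", "trait_b"]])
    assert len(strong) == 1


# ---------------------------------------------------------------------------
# Compact letter display

def test_cld_consistency_random_p_matrices():
    rng = np.random.default_rng(8)
    groups = list("abcde")
    for _ in range(50):
        P = pd.DataFrame(np.ones((5, 5)), index=groups, columns=groups)
        for g, h in itertools.combinations(groups, 2):
            P.at[g, h] = P.at[h, g] = rng.uniform(0, 1)
        letters = compact_letter_display(groups, P, alpha=0.3)
        for g, h in itertools.combinations(groups, 2):
            share = set(letters[g]) & set(letters[h])
            if P.at[g, h] < 0.3:
                assert not share
            else:
                assert share


# ---------------------------------------------------------------------------
# Kruskal-Wallis + rank-sum

def test_kw_identical_groups_share_letter():
    v = pd.Series([5.0] * 12, name="x")
    g = pd.Series(["a"] * 4 + ["b"] * 4 + ["c"] * 4)
    comp = kw_posthoc(v, g)
    assert comp.statistic == 0.0
    assert len(set(comp.letters.values())) == 1


def test_kw_three_disjoint_groups_all_letters_differ():
    # n = 4 per group, no overlap: exact two-sided rank-sum p = 2/70
    v = pd.Series([1, 2, 3, 4, 11, 12, 13, 14, 21, 22, 23, 24],
                  dtype=float, name="x")
    g = pd.Series(["a"] * 4 + ["b"] * 4 + ["c"] * 4)
    comp = kw_posthoc(v, g)
    assert comp.pairwise_p.at["a", "b"] == pytest.approx(2 / 70)
    letters = list(comp.letters.values())
    assert len(set(letters)) == 3
    assert all(len(l) == 1 for l in letters)


def test_kw_statistic_matches_algebraic_identity():
    # no ties: H = 12/(N(N+1)) * sum n_i (Rbar_i - Rbar)^2
    rng = np.random.default_rng(12)
    v = pd.Series(rng.permutation(np.arange(1.0, 31.0)), name="x")
    g = pd.Series(["a"] * 10 + ["b"] * 10 + ["c"] * 10)
    comp = kw_posthoc(v, g)
    ranks = v.rank()
    N = len(v)
    grand = ranks.mean()
    H = 12.0 / (N * (N + 1)) * sum(
        (ranks[g == grp].mean() - grand) ** 2 * (g == grp).sum()
        for grp in ("a", "b", "c"))
    assert comp.statistic == pytest.approx(H, rel=1e-12)


def test_kw_small_group_excluded_with_warning():
    v = pd.Series([1.0, 2.0, 3.0, 4.0, 9.0], name="x")
    g = pd.Series(["a", "a", "b", "b", "c"])
    with pytest.warns(UserWarning, match="excluded"):
        comp = kw_posthoc(v, g)
    assert "c" not in comp.groups


def test_kw_flags_inconsistent_omnibus():
    # a large H with a non-significant p cannot happen at these df; the
    # comparison object flags such reports rather than reproducing them
    from epibrom.group_stats import _comparison
    data = {"a": np.arange(5.0), "b": np.arange(5.0) + 10}
    P = pd.DataFrame([[1.0, 0.5], [0.5, 1.0]], index=["a", "b"],
                     columns=["a", "b"])
    comp = _comparison("x", data, [], 23.8, "H", 4, 0.2, P, 0.05)
    assert any("inconsistent" in n for n in comp.notes)


# ---------------------------------------------------------------------------
# ANOVA + Tukey

def test_anova_equal_means_share_letter():
    rng = np.random.default_rng(3)
    v = pd.Series(np.concatenate([rng.normal(0, 1, 8)] * 3), name="x")
    g = pd.Series(["a"] * 8 + ["b"] * 8 + ["c"] * 8)
    comp = anova_tukey(v, g)
    assert comp.statistic == pytest.approx(0.0, abs=1e-10)
    assert len(set(comp.letters.values())) == 1


def test_anova_separated_groups_distinct_letters():
    v = pd.Series([0.0, 0.01, -0.01, 100.0, 100.01, 99.99], name="x")
    g = pd.Series(["a"] * 3 + ["b"] * 3)
    comp = anova_tukey(v, g)
    assert comp.p < 1e-6
    assert set(comp.letters["a"]) != set(comp.letters["b"])


def test_anova_f_matches_hand_computation():
    # balanced 3 x 5 fixture with hand-computable mean squares
    v = pd.Series([1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14, 15],
                  dtype=float, name="x")
    g = pd.Series(["a"] * 5 + ["b"] * 5 + ["c"] * 5)
    comp = anova_tukey(v, g)
    # group means 3, 8, 13; grand 8; SSB = 5*(25+0+25) = 250; MSB = 125
    # within each group SS = 10; SSW = 30; MSW = 30/12 = 2.5; F = 50
    assert comp.statistic == pytest.approx(50.0, rel=1e-9)


# ---------------------------------------------------------------------------
# Ecozone presence & environment

def records_frame(rows):
    return pd.DataFrame(rows, columns=["species", "lat", "lon",
                                       "PPT", "ecozone"])


def test_presence_not_abundance():
    rec = records_frame([("s1", 10, -80, 1000, "Tropical rainforest")] * 100)
    labels = pd.Series({"s1": "C3_T"})
    out = ecozone_presence(rec, labels)
    assert out.at["C3_T", "Tropical rainforest"] == 1


def test_species_spanning_zones_counts_once_each():
    rec = records_frame([
        ("s1", 10, -80, 900, "Tropical rainforest"),
        ("s1", 11, -81, 900, "Tropical dry forest"),
        ("s1", 12, -82, 900, "Tropical mountain system"),
        ("s2", 13, -83, 900, "Tropical rainforest"),
    ])
    labels = pd.Series({"s1": "NEB", "s2": "NEB"})
    out = ecozone_presence(rec, labels)
    assert out.loc["NEB"].sum() == 4
    assert out.at["NEB", "Tropical rainforest"] == 2


def test_presence_invariant_under_duplication():
    rec = records_frame([
        ("s1", 10, -80, 900, "Tropical rainforest"),
        ("s2", 13, -83, 900, "Tropical dry forest"),
    ])
    labels = pd.Series({"s1": "NEB", "s2": "BULB"})
    once = ecozone_presence(rec, labels)
    twice = ecozone_presence(pd.concat([rec, rec]), labels)
    pd.testing.assert_frame_equal(once, twice)


def test_unlabeled_species_excluded_with_warning():
    rec = records_frame([("s1", 10, -80, 900, "Tropical rainforest"),
                         ("sX", 11, -80, 900, "Tropical rainforest")])
    labels = pd.Series({"s1": "NEB"})
    with pytest.warns(UserWarning, match="sX"):
        out = ecozone_presence(rec, labels)
    assert out.to_numpy().sum() == 1


def test_env_compare_null_and_signal(default_dataset):
    table, tree, labels, records = default_dataset
    comps = env_group_compare(records, labels)
    assert set(comps) == {"VPD", "PPT", "TMIN", "TMAX", "ET0", "AI", "Elev"}
    ppt = comps["PPT"]
    ppt.check_letters()
    # generator gives nebulophytes the driest niche and C3 tanks the
    # wettest: their letters must differ for precipitation
    assert not (set(ppt.letters["NEB"]) & set(ppt.letters["C3_T"]))


def test_env_compare_single_group_skipped():
    rec = records_frame([("s1", 10, -80, 900, "Tropical rainforest"),
                         ("s1", 11, -80, 800, "Tropical rainforest")])
    labels = pd.Series({"s1": "NEB"})
    with pytest.warns(UserWarning, match="fewer than 2"):
        out = env_group_compare(rec, labels, variables=("PPT",))
    assert out == {}


def test_read_env_records_validation(tmp_path):
    good = tmp_path / "r.csv"
    good.write_text("species,lat,lon,PPT,ecozone\n"
                    "s1,10,-80,1000,Tropical rainforest\n")
    rec = read_env_records(good)
    assert len(rec) == 1
    bad = tmp_path / "bad.csv"
    bad.write_text("species,lat,lon,PPT,ecozone\ns1,95,-80,1000,Polar\n")
    with pytest.raises(ValueError, match="latitude"):
        read_env_records(bad)
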