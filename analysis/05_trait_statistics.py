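#!/usr/bin/env python
"""Trait correlations and between-group trait comparisons.

Spearman rank correlations over all trait pairs (raw values,
pairwise-complete) and Kruskal–Wallis tests with Wilcoxon rank-sum
post-hocs per trait, summarised with compact letter displays.
"""

import argparse
from pathlib import Path

import pandas as pd

from epibrom.group_stats import kw_posthoc, spearman_matrix
from epibrom.trait_db import read_trait_table


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results/stats"))
    ap.add_argument("--alpha", type=float, default=0.05)
    args = ap.parse_args()

    table = read_trait_table(args.data / "traits.csv")
    labels = pd.read_csv(args.data / "labels.csv",
                         index_col="species").iloc[:, 0]

    continuous = [c for c in table.values.columns if c not in ("PB", "PP")]
    corr = spearman_matrix(table.values[continuous], alpha=args.alpha)
    args.out.mkdir(parents=True, exist_ok=True)
    corr.rho.to_csv(args.out / "spearman_rho.csv", float_format="%.6g")
    corr.p.to_csv(args.out / "spearman_p.csv", float_format="%.6g")
    strong = corr.strong_pairs(r2_min=0.60)
    strong.to_csv(args.out / "strong_correlations.csv", index=False)

    rows = []
    for trait in continuous:
        try:
            comp = kw_posthoc(table.values[trait], labels.loc[table.species],
                              alpha=args.alpha)
        except ValueError:
            continue
        rows.append({"trait": trait, "H": round(comp.statistic, 3),
                     "df": comp.df, "p": comp.p,
                     **{f"letter_{g}": l
                        for g, l in comp.letters.items()}})
    frame = pd.DataFrame(rows)
    frame.to_csv(args.out / "trait_comparisons.csv", index=False)

    print(f"{corr.n_significant_pairs()} of {corr.n_defined_pairs()} "
          f"trait pairs significantly correlated at alpha={args.alpha}; "
          f"{len(strong)} strong (rho^2 > 0.6)")
    sig = frame[frame["p"] < args.alpha]
    print(f"{len(sig)} of {len(frame)} traits differ among the five "
          f"groups (Kruskal-Wallis)")


if __name__ == "__main__":
    main()
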