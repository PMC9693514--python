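#!/usr/bin/env python
"""Climate-niche contrasts and ecological-zone presence per group.

Kruskal–Wallis tests with rank-sum post-hocs on the raw occurrence
records for each environmental variable (VPD, PPT, Tmin, Tmax, ET0,
aridity index, elevation) and a species-presence matrix per ecological
zone.
"""

import argparse
from pathlib import Path

import pandas as pd

from epibrom.group_stats import (ecozone_presence, env_group_compare,
                                 read_env_records)


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results/env"))
    ap.add_argument("--alpha", type=float, default=0.05)
    args = ap.parse_args()

    records = read_env_records(args.data / "records.csv")
    labels = pd.read_csv(args.data / "labels.csv",
                         index_col="species").iloc[:, 0]

    args.out.mkdir(parents=True, exist_ok=True)
    richness = ecozone_presence(records, labels)
    richness.to_csv(args.out / "ecozone_richness.csv")

    comps = env_group_compare(records, labels, alpha=args.alpha)
    rows = []
    for var, comp in comps.items():
        rows.append({"variable": var, "H": round(comp.statistic, 2),
                     "df": comp.df, "p": comp.p,
                     **{f"letter_{g}": l
                        for g, l in comp.letters.items()},
                     **{f"median_{g}": round(m, 2)
                        for g, m in comp.median.items()}})
    frame = pd.DataFrame(rows)
    frame.to_csv(args.out / "env_comparisons.csv", index=False)

    print(f"{len(records)} records over {records['species'].nunique()} "
          f"species; {len(comps)} environmental variables compared")
    print("per-variable compact letters (groups sharing a letter do not "
          "differ):")
    cols = ["variable"] + [c for c in frame.columns
                           if c.startswith("letter_")]
    print(frame[cols].to_string(index=False))
    print("species richness per ecological zone:")
    print(richness.to_string())


if __name__ == "__main__":
    main()
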