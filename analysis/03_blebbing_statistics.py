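#!/usr/bin/env python
"""Compare blebbing frequencies between groups.

Builds the group x {blebbing, non-blebbing} contingency table from the
measured (filter-passing) cells and runs all-pairs two-sided Fisher's exact
tests with Benjamini-Hochberg FDR adjustment.  Also checks the calls
against the simulation ground truth.  Writes the frequency table and the
adjusted p-value matrix to results/.
"""

import argparse
from pathlib import Path

import pandas as pd

from blebquant import blebbing_table, fisher_pairwise_fdr

GROUP_ORDER = ["ctrl_vehicle", "ctrl_stress", "ko_vehicle", "ko_stress"]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--results", type=Path, default=Path("results"))
    args = parser.parse_args()

    df = pd.read_csv(args.results / "cell_features.csv")
    df = df[df["excluded_by"].fillna("") == ""]
    table = blebbing_table(df, group_order=[g for g in GROUP_ORDER if g in set(df["group"])])
    results, matrix = fisher_pairwise_fdr(table)

    freq = pd.DataFrame(
        {
            "group": table.groups,
            "blebbing": table.counts[:, 0],
            "non_blebbing": table.counts[:, 1],
            "frequency": table.frequencies.round(4),
        }
    )
    freq.to_csv(args.results / "blebbing_frequencies.csv", index=False)
    matrix.round(6).to_csv(args.results / "blebbing_fisher_fdr_matrix.csv")

    print("blebbing frequency by group:")
    print(freq.to_string(index=False))
    print("\npairwise Fisher (BH-adjusted) p-values:")
    print(matrix.round(4).to_string())
    sig = [r for r in results if r.p_adjusted < 0.05]
    print(f"\n{len(sig)} of {len(results)} pairs significant at FDR 0.05:")
    for r in sig:
        print(f"  {r.pair[0]} vs {r.pair[1]}: q = {r.p_adjusted:.2e}")


if __name__ == "__main__":
    main()
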