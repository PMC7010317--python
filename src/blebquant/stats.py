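"""Group-level statistics on per-cell readouts.

Blebbing frequencies are compared between groups with pairwise two-sided
Fisher's exact tests (point-probability convention) adjusted across all
pairs by Benjamini–Hochberg FDR.  Focal-adhesion counts are compared on a
log10 scale with a two-way fixed-effects ANOVA (with interaction) followed
by Tukey HSD across the four factor combinations; a rank-based alternative
(pairwise Mann–Whitney U + BH) is reported alongside.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, mannwhitneyu
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ContingencyTable",
    "ComparisonResult",
    "blebbing_table",
    "fisher_pairwise_fdr",
    "fa_group_test",
    "spreading_sample_size",
]


@dataclass
class ContingencyTable:
    """Per-group (blebbing, non-blebbing) counts, in a fixed group order."""

    groups: list
    counts: np.ndarray  # (n_groups, 2) ints: [blebbing, non_blebbing]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.groups), 2):
            raise ValueError("counts must be (n_groups, 2)")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if len(set(self.groups)) != len(self.groups):
            raise ValueError("group labels must be unique")

    @property
    def frequencies(self) -> np.ndarray:
        totals = self.counts.sum(axis=1)
        return self.counts[:, 0] / totals


@dataclass
class ComparisonResult:
    """One pairwise comparison with raw and adjusted p-values."""

    pair: tuple
    statistic: float
    p_raw: float
    p_adjusted: float
    method: str
    extra: dict = field(default_factory=dict)


def blebbing_table(records: pd.DataFrame, group_col: str = "group",
                   bleb_col: str = "blebbing",
                   group_order: list | None = None) -> ContingencyTable:
    """Tally blebbing / non-blebbing cells per group.

    ``group_order`` fixes the output ordering (default: order of first
    appearance).  Groups present in the order but empty in the data raise.
    """
    if group_order is None:
        group_order = list(dict.fromkeys(records[group_col]))
    counts = []
    for g in group_order:
        sub = records[records[group_col] == g]
        if len(sub) == 0:
            raise ValueError(f"group {g!r} has no cells")
        n_bleb = int(sub[bleb_col].astype(bool).sum())
        counts.append([n_bleb, len(sub) - n_bleb])
    return ContingencyTable(groups=list(group_order), counts=np.array(counts))


def fisher_pairwise_fdr(table: ContingencyTable) -> tuple[list[ComparisonResult], pd.DataFrame]:
    """All-pairs two-sided Fisher tests with BH adjustment.

    Returns the list of comparisons and a symmetric adjusted-p matrix with a
    unit diagonal (groups in table order).
    """
    k = len(table.groups)
    if k < 2:
        raise ValueError("need at least 2 groups")
    pairs = list(itertools.combinations(range(k), 2))
    raw = []
    odds = []
    for i, j in pairs:
        sub = np.array([table.counts[i], table.counts[j]])
        if sub.sum() == 0:
            raise ValueError(
                f"pair ({table.groups[i]!r}, {table.groups[j]!r}) has zero total"
            )
        o, p = fisher_exact(sub, alternative="two-sided")
        raw.append(p)
        odds.append(o)
    adj = multipletests(raw, method="fdr_bh")[1]
    results = [
        ComparisonResult(
            pair=(table.groups[i], table.groups[j]),
            statistic=float(o),
            p_raw=float(p),
            p_adjusted=float(q),
            method="fisher_fdr",
        )
        for (i, j), o, p, q in zip(pairs, odds, raw, adj)
    ]
    mat = pd.DataFrame(np.eye(k), index=table.groups, columns=table.groups)
    for (i, j), q in zip(pairs, adj):
        mat.iloc[i, j] = mat.iloc[j, i] = q
    return results, mat


def fa_group_test(
    records: pd.DataFrame,
    factor_a: str,
    factor_b: str,
    response: str = "fa_count",
    alpha: float = 0.05,
) -> dict:
    """Two-way ANOVA + Tukey on log10 counts, plus a rank-based alternative.

    Every cell must belong to one combination of the two factors and carry a
    count >= 1 (the log is undefined otherwise; the upstream low-count
    cutoff guarantees this).  When the response carries no variance at all
    the ANOVA F is undefined; this degenerate case is reported as
    ``no_variance`` with all p-values 1 rather than raised.
    """
    df = records.copy()
    for fac in (factor_a, factor_b):
        if df[fac].isna().any():
            raise ValueError(f"missing values in factor {fac!r}")
    levels_a = sorted(df[factor_a].astype(str).unique())
    levels_b = sorted(df[factor_b].astype(str).unique())
    for la in levels_a:
        for lb in levels_b:
            n = ((df[factor_a].astype(str) == la) & (df[factor_b].astype(str) == lb)).sum()
            if n == 0:
                raise ValueError(f"empty design cell ({la}, {lb})")
    if (df[response] < 1).any():
        raise ValueError(f"{response} must be >= 1 for the log10 transform")
    df["_y"] = np.log10(df[response].astype(float))
    df["_a"] = df[factor_a].astype(str)
    df["_b"] = df[factor_b].astype(str)
    df["_cell"] = df["_a"] + "/" + df["_b"]

    out: dict = {"response": response, "transform": "log10"}
    if np.ptp(df["_y"].to_numpy()) == 0.0:
        groups = sorted(df["_cell"].unique())
        out["anova"] = None
        out["no_variance"] = True
        out["tukey"] = [
            ComparisonResult(pair=p, statistic=0.0, p_raw=1.0, p_adjusted=1.0,
                             method="anova_tukey")
            for p in itertools.combinations(groups, 2)
        ]
        out["rank"] = [
            ComparisonResult(pair=p, statistic=np.nan, p_raw=1.0, p_adjusted=1.0,
                             method="rank_mw_fdr")
            for p in itertools.combinations(groups, 2)
        ]
        return out
    out["no_variance"] = False

    model = ols("_y ~ C(_a) * C(_b)", data=df).fit()
    out["anova"] = anova_lm(model, typ=2)
    out["interaction_p"] = float(out["anova"].loc["C(_a):C(_b)", "PR(>F)"])

    tukey = pairwise_tukeyhsd(df["_y"].to_numpy(), df["_cell"].to_numpy(), alpha=alpha)
    tk = tukey.summary().data[1:]
    out["tukey"] = [
        ComparisonResult(
            pair=(row[0], row[1]),
            statistic=float(row[2]),
            p_raw=float(row[3]),
            p_adjusted=float(row[3]),  # Tukey HSD p is already family-adjusted
            method="anova_tukey",
            extra={"reject": bool(row[6])},
        )
        for row in tk
    ]

    groups = sorted(df["_cell"].unique())
    pairs = list(itertools.combinations(groups, 2))
    raw = []
    stats = []
    for ga, gb in pairs:
        xa = df.loc[df["_cell"] == ga, response].to_numpy(dtype=float)
        xb = df.loc[df["_cell"] == gb, response].to_numpy(dtype=float)
        u, p = mannwhitneyu(xa, xb, alternative="two-sided")
        raw.append(p)
        stats.append(u)
    adj = multipletests(raw, method="fdr_bh")[1]
    out["rank"] = [
        ComparisonResult(pair=pair, statistic=float(u), p_raw=float(p),
                         p_adjusted=float(q), method="rank_mw_fdr")
        for pair, u, p, q in zip(pairs, stats, raw, adj)
    ]
    return out


def spreading_sample_size(
    cells_per_field: int, fields_per_plate: int, plates_per_point: int
) -> int:
    """Cells aggregated into one spreading-assay data point.

    The sampling design selects a fixed number of the most-spread cells per
    field, in several fields per plate, over several plates per time point;
    the total is the plain product of the three counts.
    """
    for name, v in (
        ("cells_per_field", cells_per_field),
        ("fields_per_plate", fields_per_plate),
        ("plates_per_point", plates_per_point),
    ):
        if v < 1:
            raise ValueError(f"{name} must be >= 1")
    return int(cells_per_field) * int(fields_per_plate) * int(plates_per_point)
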