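"""Evolutionary-age stratification of repeat signal.

Repeat names carry an ordinal clade rank (oldest clade in which orthologous
copies occur; low rank = old, high rank = recently incorporated).  This
module summarizes per-copy abundance by clade with the rank-test annotations
used for clade boxplots, quantifies the monotone age gradient with a
Spearman trend statistic, and selects clade-restricted catalog subsets
(e.g. repeats restricted to Hominoidea and descendant clades).

The Spearman trend is added plumbing for testability: clade gradients are
conventionally shown as ordered boxplots with rank tests, and the trend
statistic condenses that ordering into one number.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .catalog import RepeatCatalog
from .stats import kruskal_wallis, wilcoxon_vs_reference

__all__ = ["clade_summary", "age_trend", "select_clade_restricted"]


def _ranked_values(table: pd.DataFrame, catalog: RepeatCatalog, track: str) -> pd.DataFrame:
    df = catalog.copies
    if "clade_rank" not in df.columns:
        raise ValueError("catalog has no clade ranks; run assign_clades first")
    merged = df[["copy_id", "repeat_name", "clade_rank"]].merge(
        table[[track]], left_on="copy_id", right_index=True, how="inner"
    )
    assigned = merged[merged["clade_rank"].notna()].copy()
    assigned["clade_rank"] = assigned["clade_rank"].astype(int)
    return assigned, int(merged["clade_rank"].isna().sum())


def clade_summary(table: pd.DataFrame, catalog: RepeatCatalog, track: str) -> dict:
    """Per-clade distribution summary with rank-test annotations.

    Groups copies by clade rank and reports n, median and quartiles per
    clade, the Kruskal-Wallis omnibus p over clades, and a per-clade
    one-sample Wilcoxon signed-rank test against the reference median (the
    median over all clade-assigned copies in the table, i.e. the comparison
    universe).  Copies without a clade are excluded and counted.
    """
    assigned, n_unassigned = _ranked_values(table, catalog, track)
    if assigned["clade_rank"].nunique() < 2:
        raise ValueError("clade_summary needs >= 2 non-empty clades")
    reference = float(assigned[track].median())
    rows = []
    groups = {}
    for rank, sub in assigned.groupby("clade_rank", sort=True):
        vals = sub[track].to_numpy()
        groups[rank] = vals
        p, direction = wilcoxon_vs_reference(vals, reference)
        rows.append(
            {
                "clade_rank": rank,
                "n": len(vals),
                "median": float(np.median(vals)),
                "q1": float(np.quantile(vals, 0.25)),
                "q3": float(np.quantile(vals, 0.75)),
                "wilcoxon_p": p,
                "direction": direction,
            }
        )
    return {
        "summary": pd.DataFrame(rows),
        "kruskal_p": kruskal_wallis({str(k): v for k, v in groups.items()}),
        "reference_median": reference,
        "n_unassigned": n_unassigned,
    }


def age_trend(
    table: pd.DataFrame, catalog: RepeatCatalog, track: str, level: str = "copy"
):
    """Spearman correlation between clade rank and abundance.

    ``level='copy'`` correlates per-copy abundance with the copy's clade
    rank; ``level='repeat_name'`` first averages copy abundances per repeat
    name.  Returns (rho, p); (nan, nan) when abundance is constant (rho
    undefined).
    """
    assigned, _ = _ranked_values(table, catalog, track)
    if level == "repeat_name":
        per_name = assigned.groupby("repeat_name").agg(
            clade_rank=("clade_rank", "first"), value=(track, "mean")
        )
        ranks = per_name["clade_rank"].to_numpy(dtype=float)
        values = per_name["value"].to_numpy()
    elif level == "copy":
        ranks = assigned["clade_rank"].to_numpy(dtype=float)
        values = assigned[track].to_numpy()
    else:
        raise ValueError(f"unknown level {level!r}")
    if len(np.unique(ranks)) < 3:
        raise ValueError("age_trend needs >= 3 distinct clade ranks")
    if np.all(values == values[0]):
        return float("nan"), float("nan")
    rho, p = sps.spearmanr(ranks, values)
    return float(rho), float(p)


def select_clade_restricted(catalog: RepeatCatalog, min_rank: int) -> RepeatCatalog:
    """Subset of the catalog with clade_rank >= min_rank (younger repeats)."""
    df = catalog.copies
    if "clade_rank" not in df.columns:
        raise ValueError("catalog has no clade ranks; run assign_clades first")
    keep = df["clade_rank"].notna() & (df["clade_rank"] >= min_rank)
    return catalog.subset(keep)
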