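"""Repeat-level expression: counting, expressed splits, knock-down changes.

Reads are assigned to the repeat copy with the largest overlap; multi-mapping
reads can be split fractionally (1/n_hits per alignment).  Copies are called
expressed when their mean count over a condition's replicates reaches a
threshold (default 3 reads, inclusive).  Knock-down versus control changes
are classified with a simple negative-binomial two-group test on
library-size-normalized counts -- a deliberately transparent test with
method-of-moments dispersion, not a shrinkage estimator; an externally
produced fold-change/adjusted-p table can be substituted via
:func:`classify_from_table` when a full DE fit is available.  Deregulated
repeats use the |FC| > 1.5, BH-adjusted p < 0.05 rule; read-change
categories (never_expressed / became_expressed / increased / decreased /
became_silent / unchanged) describe coarser count shifts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .catalog import RepeatCatalog
from .stats import benjamini_hochberg

__all__ = [
    "SampleSheet",
    "count_reads",
    "expressed_split",
    "differential_classification",
    "classify_from_table",
    "group_proportions",
    "read_change_categories",
    "read_counts_tsv",
    "write_counts_tsv",
]

PSEUDOCOUNT = 0.5


@dataclass(frozen=True)
class SampleSheet:
    """Sample -> (condition, replicate) metadata for a count matrix."""

    table: pd.DataFrame  # columns: sample, condition, replicate

    def samples_of(self, condition: str) -> list:
        sub = self.table[self.table["condition"] == condition]
        if len(sub) == 0:
            raise KeyError(f"unknown condition {condition!r}")
        return sub["sample"].tolist()

    @property
    def conditions(self) -> list:
        return list(dict.fromkeys(self.table["condition"]))

    @classmethod
    def read(cls, path) -> "SampleSheet":
        return cls(pd.read_csv(path, sep="\t", dtype={"sample": str}))

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def count_reads(alignments, catalog: RepeatCatalog, policy: str = "unique_only") -> pd.Series:
    """Assign read weight to repeat copies by largest overlap.

    ``alignments`` is an iterable of (chrom, start, end, n_hits).  Each
    alignment goes entirely to the copy with the largest overlap (>= 1 bp);
    ties break to the leftmost copy start then smallest copy_id.  Under
    ``fractional`` the unit read weight is divided by n_hits before
    assignment; under ``unique_only`` alignments with n_hits > 1 are
    skipped.  Returns a per-copy weight Series indexed by copy_id (one
    sample column of a count matrix).
    """
    if policy not in ("unique_only", "fractional"):
        raise ValueError(f"unknown policy {policy!r}")
    cat = catalog.copies
    by_chrom = {}
    for chrom, sub in cat.groupby("chrom", sort=False):
        sub = sub.sort_values(["start", "end"])
        by_chrom[chrom] = (
            sub["start"].to_numpy(),
            sub["end"].to_numpy(),
            sub["copy_id"].to_numpy(),
        )
    max_len = {c: int((e - s).max()) if len(s) else 0 for c, (s, e, _) in by_chrom.items()}
    counts = dict.fromkeys(cat["copy_id"], 0.0)
    for chrom, start, end, n_hits in alignments:
        if end < start:
            raise ValueError(f"negative-length alignment [{start},{end})")
        if policy == "unique_only" and n_hits != 1:
            continue
        w = 1.0 if policy == "unique_only" else 1.0 / n_hits
        entry = by_chrom.get(chrom)
        if entry is None:
            continue
        starts, ends, ids = entry
        hi = np.searchsorted(starts, end, side="left")
        lo = np.searchsorted(starts, start - max_len[chrom], side="left")
        best = None
        for k in range(lo, hi):
            ov = min(ends[k], end) - max(starts[k], start)
            if ov >= 1:
                key = (-ov, starts[k], ids[k])
                if best is None or key < best[0]:
                    best = (key, ids[k])
        if best is not None:
            counts[best[1]] += w
    return pd.Series(counts, name="count")


def expressed_split(
    counts: pd.DataFrame, sheet: SampleSheet, condition: str, threshold: float = 3.0
) -> pd.Series:
    """E/Ne call per copy: E iff mean count over the condition's replicates
    is >= threshold (inclusive)."""
    samples = sheet.samples_of(condition)
    means = counts[samples].mean(axis=1)
    return pd.Series(np.where(means >= threshold, "E", "Ne"), index=counts.index, name="expressed")


def _size_factors(counts: pd.DataFrame) -> pd.Series:
    totals = counts.sum(axis=0)
    return totals / totals.mean()


def differential_classification(
    counts: pd.DataFrame,
    sheet: SampleSheet,
    control: str = "control",
    kd: str = "kd",
    fc_threshold: float = 1.5,
    alpha: float = 0.05,
    min_total: float = 10.0,
) -> pd.DataFrame:
    """Two-group NB test of kd vs control per repeat copy.

    Counts are normalized by per-sample total-count size factors.  A single
    moderated dispersion -- the mean of per-copy method-of-moments NB
    dispersion estimates over all tested copies -- feeds a delta-method
    standard error of the log fold change, which is referred to the normal
    distribution (Wald test).  Pooling the dispersion across copies is what
    makes the normal approximation usable at 2-3 replicates per group; the
    per-copy estimates alone are far too noisy.  Copies with total raw
    count below ``min_total`` are excluded from testing (independent
    filtering) and reported with NaN p-values.

    log2 fold change uses pseudocount 0.5.  BH adjustment runs over tested
    copies only; status is 'up'/'down' when |FC| exceeds ``fc_threshold``
    (linear scale) at padj < alpha, else 'ns'.
    """
    c_samples = sheet.samples_of(control)
    k_samples = sheet.samples_of(kd)
    if len(c_samples) < 2 or len(k_samples) < 2:
        raise ValueError("each condition needs >= 2 replicates")
    sf = _size_factors(counts[c_samples + k_samples])
    norm = counts[c_samples + k_samples].div(sf, axis=1)
    nc, nk = len(c_samples), len(k_samples)
    mc = norm[c_samples].mean(axis=1)
    mk = norm[k_samples].mean(axis=1)
    vc = norm[c_samples].var(axis=1, ddof=1)
    vk = norm[k_samples].var(axis=1, ddof=1)
    pooled_var = ((nc - 1) * vc + (nk - 1) * vk) / (nc + nk - 2)
    grand_mean = (nc * mc + nk * mk) / (nc + nk)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp_mom = np.maximum((pooled_var - grand_mean) / grand_mean**2, 0.0)
    log2fc = np.log2((mk + PSEUDOCOUNT) / (mc + PSEUDOCOUNT))

    tested = counts[c_samples + k_samples].sum(axis=1) >= min_total
    disp_mom[grand_mean == 0] = np.nan
    pool = disp_mom[tested & disp_mom.notna()]
    dispersion = float(pool.mean()) if len(pool) else 0.0
    # delta-method variance of log(mean + pc) per group under NB(mu, alpha)
    var_log_c = (mc + dispersion * mc**2) / (nc * (mc + PSEUDOCOUNT) ** 2)
    var_log_k = (mk + dispersion * mk**2) / (nk * (mk + PSEUDOCOUNT) ** 2)
    se = np.sqrt(var_log_c + var_log_k)
    lfc_nat = np.log((mk + PSEUDOCOUNT) / (mc + PSEUDOCOUNT))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = lfc_nat / se
    p = 2.0 * sps.norm.sf(np.abs(z))
    p = np.where(se == 0, 1.0, p)
    p = pd.Series(p, index=counts.index)
    p[~tested] = np.nan

    padj = pd.Series(np.nan, index=counts.index)
    if tested.any():
        padj[tested] = benjamini_hochberg(p[tested].to_numpy())
    lfc_cut = np.log2(fc_threshold)
    status = pd.Series("ns", index=counts.index)
    sig = tested & (padj < alpha)
    status[sig & (log2fc >= lfc_cut)] = "up"
    status[sig & (log2fc <= -lfc_cut)] = "down"
    return pd.DataFrame(
        {
            "baseMean_control": mc,
            "baseMean_kd": mk,
            "log2FoldChange": log2fc,
            "dispersion": dispersion,
            "pvalue": p,
            "padj": padj,
            "tested": tested,
            "status": status,
        }
    )


def classify_from_table(
    table: pd.DataFrame, fc_threshold: float = 1.5, alpha: float = 0.05
) -> pd.DataFrame:
    """Apply the deregulation rule to an external log2FC / padj table.

    Accepts output of any DE fit (e.g. a shrinkage-based one) with columns
    log2FoldChange and padj, and adds the up/down/ns status column under the
    same |FC| and padj thresholds as :func:`differential_classification`.
    """
    out = table.copy()
    lfc_cut = np.log2(fc_threshold)
    sig = out["padj"].notna() & (out["padj"] < alpha)
    status = pd.Series("ns", index=out.index)
    status[sig & (out["log2FoldChange"] >= lfc_cut)] = "up"
    status[sig & (out["log2FoldChange"] <= -lfc_cut)] = "down"
    out["status"] = status
    return out


def group_proportions(de: pd.DataFrame, grouping: pd.Series) -> pd.DataFrame:
    """Observed vs expected share of up-regulated copies per group.

    ``grouping`` maps copy_id -> group label and must cover the tested
    copies.  Observed% is the group's share of all up-regulated copies;
    expected% is the group's share of all tested copies; a group is flagged
    enriched when observed exceeds expected.
    """
    tested = de[de["tested"]] if "tested" in de.columns else de
    up = tested[tested["status"] == "up"]
    n_tested, n_up = len(tested), len(up)
    rows = []
    for group in sorted(grouping.loc[tested.index].unique()):
        in_group = grouping.loc[tested.index] == group
        up_in_group = int((grouping.loc[up.index] == group).sum()) if n_up else 0
        observed = 100.0 * up_in_group / n_up if n_up else np.nan
        expected = 100.0 * int(in_group.sum()) / n_tested if n_tested else np.nan
        rows.append(
            {
                "group": group,
                "n_up": up_in_group,
                "n_tested": int(in_group.sum()),
                "observed_pct": observed,
                "expected_pct": expected,
                "enriched": bool(observed > expected) if n_up else False,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["n_up_total"] = n_up
    out.attrs["n_tested_total"] = n_tested
    return out


CATEGORIES = (
    "never_expressed",
    "became_expressed",
    "became_silent",
    "increased",
    "decreased",
    "unchanged",
)


def read_change_categories(
    counts: pd.DataFrame,
    sheet: SampleSheet,
    express_threshold: float = 3.0,
    change_factor: float = 1.5,
) -> pd.DataFrame:
    """Coarse read-change category per copy between exactly two conditions.

    Categories: never_expressed (below the expressed threshold in both),
    became_expressed / became_silent (threshold crossed between control and
    knock-down), and, among copies expressed in both, increased / decreased
    when the pseudocounted mean ratio reaches ``change_factor`` (resp. its
    reciprocal), else unchanged.  Returns the per-copy category plus the
    category percentages over all copies (they sum to 100).
    """
    conditions = sheet.conditions
    if len(conditions) != 2:
        raise ValueError(f"need exactly 2 conditions, got {conditions}")
    control, kd = conditions
    mc = counts[sheet.samples_of(control)].mean(axis=1)
    mk = counts[sheet.samples_of(kd)].mean(axis=1)
    e_c = mc >= express_threshold
    e_k = mk >= express_threshold
    ratio = (mk + PSEUDOCOUNT) / (mc + PSEUDOCOUNT)
    category = pd.Series("unchanged", index=counts.index)
    category[~e_c & ~e_k] = "never_expressed"
    category[~e_c & e_k] = "became_expressed"
    category[e_c & ~e_k] = "became_silent"
    both = e_c & e_k
    category[both & (ratio >= change_factor)] = "increased"
    category[both & (ratio <= 1.0 / change_factor)] = "decreased"
    fractions = (
        category.value_counts(normalize=True)
        .reindex(CATEGORIES, fill_value=0.0)
        .mul(100.0)
        .rename("percent")
    )
    return pd.DataFrame({"category": category}), fractions


def read_counts_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_counts_tsv(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="copy_id")
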