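"""Tandem-position classification of repeat copies.

Young retrotransposons (notably SVA families) frequently occur in tandem
runs.  Each focal copy is labeled by its position relative to neighboring
copies of the same superfamily within a fixed window: ``alone`` (no neighbor
within the window on either side), ``first`` (neighbor only 3', i.e. at
higher coordinates), ``last`` (neighbor only 5'), ``internal`` (both sides).
Positions are genomic (coordinate order), not element strand; gaps are
measured end-to-start, with overlapping or adjacent neighbors counting as
distance 0 and the window boundary inclusive.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .metaprofile import ProfileMatrix, scaled_profile

__all__ = ["classify_tandem", "stratified_profiles", "write_labels_bed"]

LABELS = ("alone", "first", "internal", "last")


def classify_tandem(focal: pd.DataFrame, context: pd.DataFrame, window_bp: int = 500) -> dict:
    """Label each focal copy alone/first/internal/last.

    ``focal`` and ``context`` are catalog-style DataFrames (chrom, start,
    end, copy_id).  The context may contain the focal copies themselves; a
    copy never counts as its own neighbor.  A context copy flanks 5' when its
    interval ends at most ``window_bp`` before the focal start (gap
    focal.start - ctx.end in [<= window_bp]); symmetric for 3'.  Overlapping
    context copies flank at distance 0.
    """
    if window_bp < 0:
        raise ValueError(f"window_bp must be >= 0, got {window_bp}")
    by_chrom = {}
    for chrom, sub in context.groupby("chrom", sort=False):
        sub = sub.sort_values(["start", "end"])
        by_chrom[chrom] = (
            sub["start"].to_numpy(),
            sub["end"].to_numpy(),
            sub["copy_id"].to_numpy(),
        )
    labels = {}
    for chrom, f_start, f_end, f_id in focal[
        ["chrom", "start", "end", "copy_id"]
    ].itertuples(index=False):
        has5 = has3 = False
        entry = by_chrom.get(chrom)
        if entry is not None:
            starts, ends, ids = entry
            # candidate neighbors: start <= f_end + window and end >= f_start - window
            hi = np.searchsorted(starts, f_end + window_bp, side="right")
            for k in range(hi):
                if ids[k] == f_id:
                    continue
                if ends[k] < f_start - window_bp:
                    continue
                s, e = starts[k], ends[k]
                # a neighbor flanks 5' when it extends below the focal start
                # within the window; 3' symmetrically.  An overlapping copy
                # counts on the side(s) it extends toward (distance 0), and
                # the window boundary is inclusive.
                if s < f_start and f_start - e <= window_bp:
                    has5 = True
                if e > f_end and s - f_end <= window_bp:
                    has3 = True
                if has5 and has3:
                    break
        if has5 and has3:
            labels[f_id] = "internal"
        elif has5:
            labels[f_id] = "last"
        elif has3:
            labels[f_id] = "first"
        else:
            labels[f_id] = "alone"
    return labels


def stratified_profiles(
    track,
    focal: pd.DataFrame,
    labels: dict,
    **profile_params,
) -> dict:
    """One scaled meta-repeat ProfileMatrix per tandem label class.

    Empty label classes are omitted.  Returns label -> ProfileMatrix.
    """
    out = {}
    for label in LABELS:
        ids = [cid for cid, lab in labels.items() if lab == label]
        sub = focal[focal["copy_id"].isin(ids)]
        if len(sub) == 0:
            continue
        out[label] = scaled_profile(track, sub, **profile_params)
    return out


def write_labels_bed(focal: pd.DataFrame, labels: dict, path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, cid in focal[
            ["chrom", "start", "end", "copy_id"]
        ].itertuples(index=False):
            fh.write(f"{chrom}\t{start}\t{end}\t{labels[cid]}\n")
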