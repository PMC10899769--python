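"""Meta-repeat profiles: scaled-body binning with fixed flanks.

Every copy of a repeat group is scaled to a common number of body bins
(``scale-regions`` semantics) and extended by fixed-width flanks, so signal
over copies of very different lengths can be averaged into one meta-repeat
profile or displayed as a per-copy heatmap.  Bins use fractional base
apportioning: a bin covering [a, b) in real coordinates takes the
length-weighted mean of the piecewise-constant track over exactly that
interval, so the mean of a copy's body bins reproduces the mean over the
copy.  Bins that fall off the chromosome end are NaN (missing), never zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage

from .coverage import CoverageTrack

__all__ = [
    "ProfileMatrix",
    "scaled_profile",
    "reference_point_profile",
    "scale_and_order",
    "plot_average_profile",
]


@dataclass
class ProfileMatrix:
    """Binned signal per copy: 5' flank bins + body bins + 3' flank bins."""

    values: np.ndarray  # rows x (flank_bins + body_bins + flank_bins)
    copy_ids: list
    body_bins: int
    flank_bins: int
    flank_bp: int
    oriented: bool = True
    meta: dict = field(default_factory=dict)

    @property
    def n_columns(self) -> int:
        return self.body_bins + 2 * self.flank_bins

    def average_profile(self) -> np.ndarray:
        """Column means over copies; missing bins excluded, not zero-filled."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.values, axis=0)

    def to_frame(self) -> pd.DataFrame:
        cols = (
            [f"flank5_{i}" for i in range(self.flank_bins)]
            + [f"body_{i}" for i in range(self.body_bins)]
            + [f"flank3_{i}" for i in range(self.flank_bins)]
        )
        return pd.DataFrame(self.values, index=self.copy_ids, columns=cols)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="copy_id")


def _bin_means(track: CoverageTrack, chrom: str, edges: np.ndarray) -> np.ndarray:
    """Mean of the track over each [edges[i], edges[i+1]); NaN off-chromosome."""
    length = track.genome[chrom]
    out = np.empty(len(edges) - 1)
    for i, (a, b) in enumerate(zip(edges[:-1], edges[1:])):
        if a < 0 or b > length:
            out[i] = np.nan
        else:
            out[i] = track.integral(chrom, a, b) / (b - a)
    return out


def scaled_profile(
    track: CoverageTrack,
    copies,
    body_bins: int = 100,
    flank_bp: int = 3000,
    flank_bins: int = 60,
    orient_by_strand: bool = True,
) -> ProfileMatrix:
    """Scaled-body profile over repeat copies with fixed flanks.

    ``copies`` is a DataFrame with chrom/start/end/strand/copy_id columns.
    Each copy body is divided into ``body_bins`` equal fractional
    sub-intervals; flanks of ``flank_bp`` bases are divided into
    ``flank_bins`` fixed-width bins.  Minus-strand copies are reversed
    (5'->3' orientation) when ``orient_by_strand``.
    """
    if body_bins < 1:
        raise ValueError("body_bins must be >= 1")
    if flank_bp < 0:
        raise ValueError("flank_bp must be >= 0")
    if flank_bins < 0 or (flank_bp > 0) != (flank_bins > 0):
        raise ValueError("flank_bp and flank_bins must be both zero or both positive")
    rows = copies[["chrom", "start", "end", "strand", "copy_id"]].itertuples(index=False)
    n = len(copies)
    if n == 0:
        raise ValueError("no copies given")
    width = body_bins + 2 * flank_bins
    values = np.full((n, width), np.nan)
    ids = []
    for r, (chrom, start, end, strand, copy_id) in enumerate(rows):
        if end <= start:
            raise ValueError(f"zero-length copy {copy_id}")
        body_edges = start + (end - start) * np.arange(body_bins + 1) / body_bins
        if flank_bins:
            step = flank_bp / flank_bins
            left_edges = start - flank_bp + step * np.arange(flank_bins + 1)
            right_edges = end + step * np.arange(flank_bins + 1)
            row = np.concatenate(
                [
                    _bin_means(track, chrom, left_edges),
                    _bin_means(track, chrom, body_edges),
                    _bin_means(track, chrom, right_edges),
                ]
            )
        else:
            row = _bin_means(track, chrom, body_edges)
        if orient_by_strand and strand == "-":
            row = row[::-1]
        values[r] = row
        ids.append(copy_id)
    return ProfileMatrix(
        values,
        ids,
        body_bins,
        flank_bins,
        flank_bp,
        oriented=orient_by_strand,
        meta={"mode": "scale-regions"},
    )


def reference_point_profile(
    track: CoverageTrack,
    points,
    flank_bp: int,
    bin_bp: int,
) -> ProfileMatrix:
    """Fixed-width profile in a symmetric window around reference points.

    ``points`` is an iterable of (chrom, position, strand).  The window spans
    position +/- flank_bp in ``bin_bp``-wide bins (bin_bp must divide
    2*flank_bp); minus-strand points are mirrored.  Window parts off the
    chromosome are NaN.
    """
    if (2 * flank_bp) % bin_bp != 0:
        raise ValueError("bin_bp must divide 2*flank_bp")
    n_bins = 2 * flank_bp // bin_bp
    points = list(points)
    values = np.full((len(points), n_bins), np.nan)
    ids = []
    for r, (chrom, pos, strand) in enumerate(points):
        edges = pos - flank_bp + bin_bp * np.arange(n_bins + 1, dtype=float)
        row = _bin_means(track, chrom, edges)
        if strand == "-":
            row = row[::-1]
        values[r] = row
        ids.append(f"{chrom}:{pos}:{strand}")
    half = n_bins // 2
    return ProfileMatrix(
        values,
        ids,
        body_bins=0,
        flank_bins=half,
        flank_bp=flank_bp,
        meta={"mode": "reference-point", "bin_bp": bin_bp},
    )


def scale_and_order(
    matrix: pd.DataFrame,
    scale: str = "row_z",
    order: str = "cluster",
):
    """Row-scale a group-by-track summary matrix and order it for display.

    ``scale='row_z'`` subtracts the row mean and divides by the row standard
    deviation (constant rows map to all zeros).  ``order='cluster'`` orders
    rows and columns by agglomerative clustering (euclidean distance,
    complete linkage) of the scaled matrix; rows are pre-sorted by label so
    leaf order is deterministic and permutation-invariant.  Returns
    (scaled DataFrame reordered, row order, column order).
    """
    if scale not in ("row_z", "none"):
        raise ValueError(f"unknown scale {scale!r}")
    if order not in ("cluster", "given"):
        raise ValueError(f"unknown order {order!r}")
    df = matrix.copy()
    flagged_constant = []
    if scale == "row_z":
        arr = df.to_numpy(dtype=float)
        mean = arr.mean(axis=1, keepdims=True)
        sd = arr.std(axis=1, ddof=0, keepdims=True)
        constant = (sd == 0).ravel()
        sd[sd == 0] = 1.0
        df = pd.DataFrame((arr - mean) / sd, index=df.index, columns=df.columns)
        flagged_constant = list(df.index[constant])
    if order == "given":
        return df, list(df.index), list(df.columns)
    if len(df) < 2:
        raise ValueError("clustering requires at least 2 rows")
    # canonical input order -> deterministic, permutation-invariant leaves
    df = df.sort_index(axis=0).sort_index(axis=1)
    row_leaves = leaves_list(linkage(df.to_numpy(), method="complete", metric="euclidean"))
    row_order = [df.index[i] for i in row_leaves]
    if df.shape[1] >= 2:
        col_leaves = leaves_list(
            linkage(df.to_numpy().T, method="complete", metric="euclidean")
        )
        col_order = [df.columns[i] for i in col_leaves]
    else:
        col_order = list(df.columns)
    out = df.loc[row_order, col_order]
    out.attrs["constant_rows"] = flagged_constant
    return out, row_order, col_order


def plot_average_profile(profiles: dict, path, title: str = "") -> None:
    """Line plot of average meta-repeat profiles (one line per group)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for name, pm in profiles.items():
        ax.plot(pm.average_profile(), label=str(name))
        if pm.flank_bins:
            ax.axvline(pm.flank_bins - 0.5, color="gray", lw=0.5, ls="--")
            ax.axvline(pm.flank_bins + pm.body_bins - 0.5, color="gray", lw=0.5, ls="--")
    ax.set_xlabel("bin (5' flank | scaled body | 3' flank)")
    ax.set_ylabel("mean signal")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
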