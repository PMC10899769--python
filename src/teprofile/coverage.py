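"""Piecewise-constant coverage tracks and per-repeat abundance.

A :class:`CoverageTrack` stores, per chromosome, a full tiling of the
chromosome into runs of constant value (zero-coverage runs included, matching
``bedtools genomecov -bga`` output).  Tracks support reads-per-million
scaling, per-base subtraction (ChIP minus input), length-weighted means over
intervals (with fractional base positions, used by the meta-profilers), and
aggregation into per-copy abundance tables.

Negative values are legal: input-subtracted tracks keep their sign.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .catalog import GenomeLayout, RepeatCatalog

__all__ = [
    "CoverageTrack",
    "coverage_from_reads",
    "rpm_normalize",
    "subtract_input",
    "mean_over",
    "abundance_table",
    "filter_by_quantile",
    "read_bedgraph",
    "write_bedgraph",
]


def _canonicalize(bounds: np.ndarray, values: np.ndarray):
    """Drop empty runs and merge adjacent runs of equal value."""
    widths = np.diff(bounds)
    keep = widths > 0
    values = values[keep]
    starts = bounds[:-1][keep]
    ends = bounds[1:][keep]
    if len(values) == 0:
        return np.array([0.0]), np.array([], dtype=float)
    change = np.concatenate([[True], values[1:] != values[:-1]])
    starts = starts[change]
    values = values[change]
    ends = np.concatenate([starts[1:], ends[-1:]])
    new_bounds = np.concatenate([starts, ends[-1:]])
    return new_bounds, values


@dataclass
class CoverageTrack:
    """Per-chromosome runs of constant signal covering the whole chromosome.

    ``runs[chrom] = (bounds, values)`` where ``bounds`` has length k+1 with
    bounds[0] == 0 and bounds[-1] == chromosome length, and ``values`` holds
    the constant value on [bounds[i], bounds[i+1]).
    """

    genome: GenomeLayout
    runs: dict

    @classmethod
    def constant(cls, genome: GenomeLayout, value: float = 0.0) -> "CoverageTrack":
        runs = {
            chrom: (np.array([0.0, length], dtype=float), np.array([value], dtype=float))
            for chrom, length in genome.lengths.items()
        }
        return cls(genome, runs)

    @classmethod
    def from_bounds(cls, genome: GenomeLayout, per_chrom: dict) -> "CoverageTrack":
        runs = {}
        for chrom, length in genome.lengths.items():
            if chrom in per_chrom:
                bounds, values = per_chrom[chrom]
                bounds = np.asarray(bounds, dtype=float)
                values = np.asarray(values, dtype=float)
                if bounds[0] != 0 or bounds[-1] != length:
                    raise ValueError(
                        f"{chrom}: run bounds must span [0, {length}], got "
                        f"[{bounds[0]}, {bounds[-1]}]"
                    )
                runs[chrom] = _canonicalize(bounds, values)
            else:
                runs[chrom] = (
                    np.array([0.0, length], dtype=float),
                    np.array([0.0]),
                )
        return cls(genome, runs)

    def to_dense(self, chrom: str) -> np.ndarray:
        """Per-base value array (for small chromosomes / testing)."""
        bounds, values = self.runs[chrom]
        out = np.empty(int(self.genome[chrom]), dtype=float)
        for s, e, v in zip(bounds[:-1], bounds[1:], values):
            out[int(s) : int(e)] = v
        return out

    def value_at(self, chrom: str, pos: float) -> float:
        bounds, values = self.runs[chrom]
        idx = int(np.searchsorted(bounds, pos, side="right")) - 1
        idx = min(max(idx, 0), len(values) - 1)
        return float(values[idx])

    def integral(self, chrom: str, start: float, end: float) -> float:
        """Integral of the track over [start, end); fractional coords allowed.

        The interval must lie within the chromosome.
        """
        if end <= start:
            raise ValueError(f"empty interval [{start}, {end})")
        length = self.genome[chrom]
        if start < 0 or end > length:
            raise ValueError(f"interval [{start},{end}) outside {chrom} (length {length})")
        bounds, values = self.runs[chrom]
        i = int(np.searchsorted(bounds, start, side="right")) - 1
        j = int(np.searchsorted(bounds, end, side="left"))
        cut = np.concatenate([[start], bounds[i + 1 : j], [end]])
        widths = np.diff(cut)
        return float(np.dot(widths, values[i : i + len(widths)]))

    def scale(self, factor: float) -> "CoverageTrack":
        return CoverageTrack(
            self.genome,
            {c: (b.copy(), v * factor) for c, (b, v) in self.runs.items()},
        )

    def __add__(self, other: "CoverageTrack") -> "CoverageTrack":
        return _combine(self, other, lambda a, b: a + b)

    def __sub__(self, other: "CoverageTrack") -> "CoverageTrack":
        return _combine(self, other, lambda a, b: a - b)


def _combine(a: CoverageTrack, b: CoverageTrack, op) -> CoverageTrack:
    if set(a.genome.lengths) != set(b.genome.lengths):
        raise ValueError("tracks cover different chromosome sets")
    runs = {}
    for chrom in a.genome.lengths:
        ba, va = a.runs[chrom]
        bb, vb = b.runs[chrom]
        bounds = np.union1d(ba, bb)
        ia = np.searchsorted(ba, bounds[:-1], side="right") - 1
        ib = np.searchsorted(bb, bounds[:-1], side="right") - 1
        runs[chrom] = _canonicalize(bounds, op(va[ia], vb[ib]))
    return CoverageTrack(a.genome, runs)


def coverage_from_reads(alignments, policy: str, genome: GenomeLayout):
    """Build a coverage track from alignment spans.

    ``alignments`` is an iterable of (chrom, start, end, n_hits).  Under
    ``unique_only`` a read contributes weight 1 to every covered base iff
    n_hits == 1; under ``fractional`` every alignment contributes 1/n_hits
    (equal splitting of multi-mapping reads across their hits).  Returns the
    track and the total contributed weight.
    """
    if policy not in ("unique_only", "fractional"):
        raise ValueError(f"unknown policy {policy!r}")
    events = {chrom: {} for chrom in genome.lengths}
    total_weight = 0.0
    for chrom, start, end, n_hits in alignments:
        if end < start:
            raise ValueError(f"negative-length alignment [{start},{end}) on {chrom}")
        if end == start:
            continue
        if n_hits < 1:
            raise ValueError(f"n_hits must be >= 1, got {n_hits}")
        if chrom not in events:
            raise ValueError(f"unknown chromosome {chrom!r}")
        if start < 0 or end > genome[chrom]:
            raise ValueError(f"alignment [{start},{end}) outside {chrom}")
        if policy == "unique_only":
            if n_hits != 1:
                continue
            w = 1.0
        else:
            w = 1.0 / n_hits
        ev = events[chrom]
        ev[start] = ev.get(start, 0.0) + w
        ev[end] = ev.get(end, 0.0) - w
        total_weight += w
    per_chrom = {}
    for chrom, ev in events.items():
        length = genome[chrom]
        if not ev:
            continue
        pos = np.array(sorted(ev), dtype=float)
        delta = np.array([ev[p] for p in pos])
        values = np.cumsum(delta)
        bounds = pos
        if bounds[0] != 0:
            bounds = np.concatenate([[0.0], bounds])
            values = np.concatenate([[0.0], values])
        else:
            values = values  # first event at 0 already cumulative
        if bounds[-1] != length:
            bounds = np.concatenate([bounds, [length]])
        else:
            values = values[:-1]
        per_chrom[chrom] = (bounds, values)
    track = CoverageTrack.from_bounds(genome, per_chrom)
    return track, total_weight


def rpm_normalize(track: CoverageTrack, total_reads: float) -> CoverageTrack:
    """Scale every value by 1e6 / total_reads (reads-per-million)."""
    if total_reads <= 0:
        raise ValueError(f"total_reads must be > 0, got {total_reads}")
    return track.scale(1e6 / total_reads)


def subtract_input(chip: CoverageTrack, input_track: CoverageTrack) -> CoverageTrack:
    """Per-base ChIP minus input signal; negative values are retained."""
    return chip - input_track


def mean_over(track: CoverageTrack, interval) -> float:
    """Length-weighted mean of the track over (chrom, start, end)."""
    chrom, start, end = interval
    if end <= start:
        raise ValueError(f"zero-length interval [{start},{end})")
    return track.integral(chrom, start, end) / (end - start)


def abundance_table(tracks: dict, catalog: RepeatCatalog) -> pd.DataFrame:
    """Per-copy mean signal for each named track.

    Rows are copy_ids (in catalog order), columns are track names; the cell is
    the length-weighted mean of the track over the copy interval.
    """
    df = catalog.copies
    data = {}
    for name, track in tracks.items():
        vals = np.empty(len(df))
        for i, (chrom, start, end) in enumerate(
            df[["chrom", "start", "end"]].itertuples(index=False)
        ):
            vals[i] = track.integral(chrom, start, end) / (end - start)
        data[name] = vals
    return pd.DataFrame(data, index=pd.Index(df["copy_id"], name="copy_id"))


def filter_by_quantile(
    table: pd.DataFrame,
    track: str,
    group,
    side: str,
    fraction: float,
) -> list:
    """Copies in the requested tail of the group's abundance distribution.

    ``group`` is an iterable of copy_ids; returns the ceil(fraction * n)
    copies with the highest (side='top') or lowest (side='bottom') value on
    the named track.  Ties are broken by copy_id order so the selection is
    deterministic.
    """
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must be in (0,1), got {fraction}")
    if side not in ("top", "bottom"):
        raise ValueError(f"side must be 'top' or 'bottom', got {side!r}")
    members = set(group)
    ids = [c for c in table.index if c in members]
    if not ids:
        raise ValueError("empty group")
    sub = table.loc[ids, track]
    k = int(np.ceil(fraction * len(sub)))
    order = sorted(
        sub.items(), key=(lambda kv: (-kv[1], kv[0])) if side == "top" else (lambda kv: (kv[1], kv[0]))
    )
    return [cid for cid, _ in order[:k]]


def read_bedgraph(path, genome: GenomeLayout) -> CoverageTrack:
    """Read a 4-column bedGraph; gaps are filled with zero coverage."""
    per_chrom_runs: dict = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, value = line.split()[:4]
            per_chrom_runs.setdefault(chrom, []).append(
                (int(start), int(end), float(value))
            )
    per_chrom = {}
    for chrom, rows in per_chrom_runs.items():
        if chrom not in genome:
            raise ValueError(f"bedGraph chromosome {chrom!r} not in genome")
        rows.sort()
        length = genome[chrom]
        bounds, values = [0.0], []
        for s, e, v in rows:
            if s < bounds[-1]:
                raise ValueError(f"overlapping bedGraph runs on {chrom} at {s}")
            if s > bounds[-1]:
                values.append(0.0)
                bounds.append(float(s))
            values.append(v)
            bounds.append(float(e))
        if bounds[-1] < length:
            values.append(0.0)
            bounds.append(float(length))
        per_chrom[chrom] = (np.array(bounds), np.array(values))
    return CoverageTrack.from_bounds(genome, per_chrom)


def write_bedgraph(track: CoverageTrack, path) -> None:
    """Write all runs, zero-coverage runs included (bga convention)."""
    with open(path, "w") as fh:
        for chrom in track.genome.lengths:
            bounds, values = track.runs[chrom]
            for s, e, v in zip(bounds[:-1], bounds[1:], values):
                fh.write(f"{chrom}\t{int(s)}\t{int(e)}\t{v:.12g}\n")
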