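"""Repeat annotation handling.

Repeat copies (RepeatMasker-style annotations) are organized hierarchically:
class (SINE, LINE, LTR, ...) -> family (Alu, L1, ERV1, ...) -> repeat name
(AluYa5, L1HS, SVA_F, ...) -> individual genomic copies.  This module parses
GTF/BED annotations into a :class:`RepeatCatalog`, applies the standard
exclusions (uncertain '?' classifications, blacklist overlap), computes genome
occupancy, partitions labeled genomic segments into repetitive (R) and
non-repetitive (NR) sub-segments, and attaches evolutionary clade ranks.

All coordinates are 0-based half-open internally.  GTF input (1-based
inclusive) is converted on read and reconverted on write.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenomeLayout",
    "RepeatCatalog",
    "CladeTable",
    "DEFAULT_CLADES",
    "read_genome_layout",
    "read_repeat_annotation",
    "read_blacklist",
    "read_segments",
    "apply_exclusions",
    "occupancy",
    "partition_repetitive",
    "assign_clades",
    "write_catalog_bed",
]

#: Ordered oldest -> youngest taxonomic clades used for repeat age ranking.
DEFAULT_CLADES = [
    "Non-Primates",
    "Primates",
    "Simiiformes",
    "Catarrhini",
    "Hominoidea",
    "Hominidae",
    "Homo sapiens",
]

CATALOG_COLUMNS = [
    "chrom",
    "start",
    "end",
    "strand",
    "repeat_name",
    "family",
    "class_name",
    "copy_id",
]


class AnnotationError(ValueError):
    """Malformed annotation record or coordinate outside the genome."""


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome name -> length (bp) table."""

    lengths: dict

    def __post_init__(self):
        for chrom, length in self.lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {chrom!r} has non-positive length {length}")

    @property
    def chromosomes(self):
        return list(self.lengths)

    @property
    def total_bp(self) -> int:
        return int(sum(self.lengths.values()))

    def __contains__(self, chrom) -> bool:
        return chrom in self.lengths

    def __getitem__(self, chrom) -> int:
        return self.lengths[chrom]

    def write(self, path) -> None:
        with open(path, "w") as fh:
            for chrom, length in self.lengths.items():
                fh.write(f"{chrom}\t{length}\n")


def read_genome_layout(path) -> GenomeLayout:
    """Read a two-column chrom.sizes TSV."""
    lengths = {}
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) < 2:
                raise AnnotationError(f"{path}:{i}: expected 'chrom\\tlength'")
            chrom, length = parts[0], int(parts[1])
            if chrom in lengths:
                raise AnnotationError(f"{path}:{i}: duplicate chromosome {chrom!r}")
            lengths[chrom] = length
    return GenomeLayout(lengths)


@dataclass(frozen=True)
class CladeTable:
    """Repeat name -> oldest taxonomic clade, with ordered integer ranks.

    The clade list is ordered oldest -> youngest; rank 0 is the oldest clade.
    A repeat's clade is the oldest clade in which orthologous copies occur,
    so low rank = evolutionarily old, high rank = recently incorporated.
    """

    mapping: dict
    clades: tuple

    def __post_init__(self):
        known = set(self.clades)
        bad = {c for c in self.mapping.values() if c not in known}
        if bad:
            raise ValueError(f"clade labels not in ordered list: {sorted(bad)}")

    @property
    def ranks(self) -> dict:
        return {clade: i for i, clade in enumerate(self.clades)}

    def rank_of(self, repeat_name):
        clade = self.mapping.get(repeat_name)
        return None if clade is None else self.ranks[clade]

    @classmethod
    def read(cls, path, clades=None) -> "CladeTable":
        """Read a two-column TSV (repeat_name, clade label)."""
        mapping = {}
        seen_order = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                name, clade = line.split("\t")[:2]
                mapping[name] = clade
                if clade not in seen_order:
                    seen_order.append(clade)
        if clades is None:
            clades = [c for c in DEFAULT_CLADES if c in set(seen_order)] or seen_order
        return cls(mapping, tuple(clades))

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# clade order (oldest first): " + ", ".join(self.clades) + "\n")
            for name, clade in self.mapping.items():
                fh.write(f"{name}\t{clade}\n")


@dataclass
class RepeatCatalog:
    """Hierarchical collection of repeat copies.

    ``copies`` is a DataFrame with columns chrom, start, end, strand,
    repeat_name, family, class_name, copy_id and (after :func:`assign_clades`)
    clade_rank.  Provenance flags record which exclusions have been applied.
    """

    copies: pd.DataFrame
    genome: GenomeLayout
    uncertain_excluded: bool = False
    blacklist_excluded: bool = False
    exclusion_counts: dict = field(default_factory=dict)

    def __post_init__(self):
        missing = [c for c in CATALOG_COLUMNS if c not in self.copies.columns]
        if missing:
            raise ValueError(f"catalog missing columns: {missing}")
        self.copies = self.copies.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.copies)

    @property
    def hierarchy(self) -> dict:
        """class -> family -> sorted list of repeat names."""
        out: dict = {}
        if len(self.copies) == 0:
            return out
        trio = self.copies[["class_name", "family", "repeat_name"]].drop_duplicates()
        for class_name, family, name in trio.itertuples(index=False):
            out.setdefault(class_name, {}).setdefault(family, []).append(name)
        for fams in out.values():
            for names in fams.values():
                names.sort()
        return out

    def subset(self, mask_or_ids) -> "RepeatCatalog":
        if isinstance(mask_or_ids, (list, set, frozenset, pd.Index)):
            mask = self.copies["copy_id"].isin(set(mask_or_ids))
        else:
            mask = mask_or_ids
        return RepeatCatalog(
            self.copies[mask].copy(),
            self.genome,
            self.uncertain_excluded,
            self.blacklist_excluded,
            dict(self.exclusion_counts),
        )

    def copies_of(self, level: str, group: str) -> pd.DataFrame:
        if level not in ("class_name", "family", "repeat_name"):
            raise ValueError(f"unknown level {level!r}")
        return self.copies[self.copies[level] == group]

    def intervals_by_chrom(self) -> dict:
        """chrom -> (starts, ends) int arrays, sorted by start."""
        out = {}
        for chrom, sub in self.copies.groupby("chrom", sort=False):
            sub = sub.sort_values(["start", "end"])
            out[chrom] = (sub["start"].to_numpy(), sub["end"].to_numpy())
        return out


def _check_consistent_hierarchy(df: pd.DataFrame) -> None:
    grouped = df.groupby("repeat_name")[["family", "class_name"]].nunique()
    bad = grouped[(grouped["family"] > 1) | (grouped["class_name"] > 1)]
    if len(bad):
        offenders = []
        for name in bad.index:
            ids = df.loc[df["repeat_name"] == name, "copy_id"].tolist()
            offenders.append(f"{name}: {', '.join(ids)}")
        raise AnnotationError(
            "inconsistent family/class labels for repeat name(s): " + "; ".join(offenders)
        )


_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_gtf_line(line: str, lineno: int):
    parts = line.rstrip("\n").split("\t")
    if len(parts) < 9:
        raise AnnotationError(f"line {lineno}: expected 9 GTF columns, got {len(parts)}")
    chrom, _, _, start, end, _, strand, _, attrs = parts[:9]
    attributes = dict(_GTF_ATTR.findall(attrs))
    try:
        start_i, end_i = int(start), int(end)
    except ValueError as exc:
        raise AnnotationError(f"line {lineno}: non-integer coordinates") from exc
    for key in ("gene_id", "family_id", "class_id"):
        if key not in attributes:
            raise AnnotationError(f"line {lineno}: missing GTF attribute {key!r}")
    # GTF is 1-based inclusive -> 0-based half-open
    return (
        chrom,
        start_i - 1,
        end_i,
        strand if strand in "+-" else ".",
        attributes.get("transcript_id", attributes["gene_id"]),
        attributes["family_id"],
        attributes["class_id"],
    )


def _parse_bed_line(line: str, lineno: int):
    parts = line.rstrip("\n").split("\t")
    if len(parts) < 4:
        raise AnnotationError(f"line {lineno}: expected >=4 BED columns")
    chrom, start, end, name = parts[:4]
    strand = parts[5] if len(parts) >= 6 and parts[5] in "+-" else "."
    fields = name.split("/")
    if len(fields) != 3:
        raise AnnotationError(
            f"line {lineno}: BED name must be class/family/repeat_name, got {name!r}"
        )
    try:
        start_i, end_i = int(start), int(end)
    except ValueError as exc:
        raise AnnotationError(f"line {lineno}: non-integer coordinates") from exc
    class_name, family, repeat_name = fields
    return chrom, start_i, end_i, strand, repeat_name, family, class_name


def read_repeat_annotation(path, dialect: str, genome: GenomeLayout) -> RepeatCatalog:
    """Parse a repeat annotation file into a catalog.

    ``dialect='gtf'`` expects TEtranscripts-style attributes (gene_id,
    transcript_id, family_id, class_id); ``dialect='bed'`` expects a 4+ column
    BED whose name field encodes class/family/repeat_name.  Copy ids are
    assigned deterministically as ``chrom:start-end:repeat_name``.
    """
    if dialect not in ("gtf", "bed"):
        raise ValueError(f"unknown dialect {dialect!r}")
    parse = _parse_gtf_line if dialect == "gtf" else _parse_bed_line
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            rec = parse(line, lineno)
            chrom, start, end, *_ = rec
            if chrom not in genome:
                raise AnnotationError(f"line {lineno}: unknown chromosome {chrom!r}")
            if not (0 <= start < end <= genome[chrom]):
                raise AnnotationError(
                    f"line {lineno}: interval [{start},{end}) outside {chrom} "
                    f"(length {genome[chrom]})"
                )
            records.append(rec)
    df = pd.DataFrame(
        records,
        columns=["chrom", "start", "end", "strand", "repeat_name", "family", "class_name"],
    )
    if len(df) == 0:
        df = df.reindex(columns=CATALOG_COLUMNS)
        df["copy_id"] = pd.Series(dtype=str)
        return RepeatCatalog(df, genome)
    df["copy_id"] = (
        df["chrom"]
        + ":"
        + df["start"].astype(str)
        + "-"
        + df["end"].astype(str)
        + ":"
        + df["repeat_name"]
    )
    _check_consistent_hierarchy(df)
    return RepeatCatalog(df, genome)


def read_blacklist(path) -> list:
    """Read BED3 blacklist intervals as (chrom, start, end) tuples."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start, end = line.split("\t")[:3]
            out.append((chrom, int(start), int(end)))
    return out


def read_segments(path) -> pd.DataFrame:
    """Read labeled intervals (e.g. A/B compartment segments) from BED4."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.rstrip("\n").split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            label = parts[3] if len(parts) > 3 else "."
            rows.append((chrom, start, end, label))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "label"])


def _overlaps_any(chrom, start, end, blacklist_by_chrom) -> bool:
    iv = blacklist_by_chrom.get(chrom)
    if iv is None:
        return False
    starts, ends = iv
    # >= 1 bp overlap: some blacklist interval with b.start < end and b.end > start
    idx = np.searchsorted(starts, end, side="left")
    return bool(np.any(ends[:idx] > start))


def apply_exclusions(catalog: RepeatCatalog, blacklist=()) -> RepeatCatalog:
    """Remove uncertainly classified and blacklist-overlapping copies.

    Copies whose class or family name ends in '?' (unsure RepeatMasker
    classification, e.g. ``SINE?``) are dropped, as is every copy overlapping
    any blacklist interval by >= 1 bp.  Idempotent; counts per removal reason
    are recorded on the returned catalog.
    """
    df = catalog.copies
    uncertain = df["class_name"].str.endswith("?") | df["family"].str.endswith("?")

    bl_by_chrom = {}
    for chrom, start, end in blacklist:
        bl_by_chrom.setdefault(chrom, []).append((start, end))
    for chrom in bl_by_chrom:
        arr = sorted(bl_by_chrom[chrom])
        bl_by_chrom[chrom] = (
            np.array([a for a, _ in arr]),
            np.array([b for _, b in arr]),
        )

    in_blacklist = df.apply(
        lambda r: _overlaps_any(r["chrom"], r["start"], r["end"], bl_by_chrom), axis=1
    ) if len(df) and bl_by_chrom else pd.Series(False, index=df.index)

    keep = ~(uncertain | in_blacklist)
    out = RepeatCatalog(
        df[keep].copy(),
        catalog.genome,
        uncertain_excluded=True,
        blacklist_excluded=True,
        exclusion_counts={
            "uncertain": int(uncertain.sum()),
            "blacklist": int((in_blacklist & ~uncertain).sum()),
        },
    )
    return out


def _union_length(starts: np.ndarray, ends: np.ndarray) -> int:
    """Total bp covered by the union of intervals (one chromosome)."""
    if len(starts) == 0:
        return 0
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    total = 0
    cur_s, cur_e = int(starts[0]), int(ends[0])
    for s, e in zip(starts[1:], ends[1:]):
        if s > cur_e:
            total += cur_e - cur_s
            cur_s, cur_e = int(s), int(e)
        else:
            cur_e = max(cur_e, int(e))
    total += cur_e - cur_s
    return total


def _union_intervals(starts: np.ndarray, ends: np.ndarray):
    """Merged (start, end) arrays of the union of intervals."""
    if len(starts) == 0:
        return np.array([], dtype=int), np.array([], dtype=int)
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    out_s, out_e = [int(starts[0])], [int(ends[0])]
    for s, e in zip(starts[1:], ends[1:]):
        if s > out_e[-1]:
            out_s.append(int(s))
            out_e.append(int(e))
        else:
            out_e[-1] = max(out_e[-1], int(e))
    return np.array(out_s), np.array(out_e)


def occupancy(catalog: RepeatCatalog, genome: GenomeLayout, level: str = "class") -> pd.DataFrame:
    """Per-group genome occupancy: union bp and percent of the genome.

    Overlapping copies within a group are not double-counted (per-base union).
    ``level`` is one of class, family, repeat_name, all.
    """
    if genome.total_bp == 0:
        raise ValueError("zero-length genome")
    column = {
        "class": "class_name",
        "family": "family",
        "repeat_name": "repeat_name",
    }.get(level)
    if level == "all":
        groups = {"all": catalog.copies} if len(catalog) else {}
    elif column is None:
        raise ValueError(f"unknown level {level!r}")
    else:
        groups = {g: sub for g, sub in catalog.copies.groupby(column, sort=True)}
    rows = []
    for group, sub in groups.items():
        bp = 0
        for _, chrom_sub in sub.groupby("chrom", sort=False):
            bp += _union_length(chrom_sub["start"].to_numpy(), chrom_sub["end"].to_numpy())
        rows.append((group, bp, 100.0 * bp / genome.total_bp))
    return pd.DataFrame(rows, columns=["group", "bp", "percent"])


def partition_repetitive(segments: pd.DataFrame, catalog: RepeatCatalog) -> pd.DataFrame:
    """Split labeled segments into repetitive (R) and non-repetitive (NR) parts.

    Each segment is cut at the boundaries of the repeat union; sub-segments
    inside the union are labeled R, the remainder NR.  The R and NR pieces
    exactly tile each input segment.
    """
    unions = {}
    for chrom, sub in catalog.copies.groupby("chrom", sort=False):
        unions[chrom] = _union_intervals(sub["start"].to_numpy(), sub["end"].to_numpy())
    rows = []
    for chrom, seg_start, seg_end, label in segments[
        ["chrom", "start", "end", "label"]
    ].itertuples(index=False):
        u = unions.get(chrom)
        pieces = []
        if u is None or len(u[0]) == 0:
            pieces = [(seg_start, seg_end, "NR")]
        else:
            us, ue = u
            lo = np.searchsorted(ue, seg_start, side="right")
            pos = seg_start
            for s, e in zip(us[lo:], ue[lo:]):
                if s >= seg_end:
                    break
                s_c, e_c = max(s, seg_start), min(e, seg_end)
                if pos < s_c:
                    pieces.append((pos, s_c, "NR"))
                pieces.append((s_c, e_c, "R"))
                pos = e_c
            if pos < seg_end:
                pieces.append((pos, seg_end, "NR"))
        for s, e, cls in pieces:
            if e > s:
                rows.append((chrom, s, e, cls, label))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "repeat_status", "label"])


def assign_clades(
    catalog: RepeatCatalog, clades: CladeTable, on_missing: str = "label_unknown"
) -> RepeatCatalog:
    """Attach an integer clade rank (older = lower) to every copy.

    Ranks are looked up per repeat name.  Missing names are either flagged
    (``clade_rank`` left as NaN, ``clade_unknown`` True) or raise, per policy.
    """
    if on_missing not in ("label_unknown", "error"):
        raise ValueError(f"unknown on_missing policy {on_missing!r}")
    df = catalog.copies.copy()
    ranks = df["repeat_name"].map(lambda n: clades.rank_of(n))
    missing = ranks.isna()
    if on_missing == "error" and missing.any():
        names = sorted(df.loc[missing, "repeat_name"].unique())
        raise KeyError(f"repeat name(s) absent from clade table: {names}")
    df["clade_rank"] = ranks.astype(float)
    df["clade_unknown"] = missing
    out = RepeatCatalog(
        df,
        catalog.genome,
        catalog.uncertain_excluded,
        catalog.blacklist_excluded,
        dict(catalog.exclusion_counts, clade_missing=int(missing.sum())),
    )
    return out


def write_catalog_bed(catalog: RepeatCatalog, path) -> None:
    """Write the catalog as 6-column BED with name = class/family/repeat_name."""
    df = catalog.copies
    with open(path, "w") as fh:
        for chrom, start, end, strand, name, family, class_name in df[
            ["chrom", "start", "end", "strand", "repeat_name", "family", "class_name"]
        ].itertuples(index=False):
            fh.write(
                f"{chrom}\t{start}\t{end}\t{class_name}/{family}/{name}\t0\t"
                f"{strand if strand in '+-' else '.'}\n"
            )
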