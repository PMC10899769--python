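"""Seeded synthetic fixtures: toy genomes with planted repeat structure.

The generator emulates the statistical structure of a TE-centric epigenomic
study without any sequence data: a small multi-chromosome genome carries
repeat families of graded evolutionary age (clade ranks), young families may
occur in tandem clusters, named signal tracks get multiplicative per-family
enrichments with optional linearly decaying flank spillover plus Gaussian
run-level noise, peaks sit exactly on enriched copy bodies, and a
negative-binomial count matrix carries planted knock-down fold changes
concentrated in young families.  Everything is deterministic per seed.

What it does NOT emulate: mappability structure, copy divergence, GC bias,
fragment-level read placement -- per-base signal is planted directly, so
passing tests demonstrate correctness of the pipeline arithmetic, not
robustness to alignment artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .catalog import (
    CladeTable,
    DEFAULT_CLADES,
    GenomeLayout,
    RepeatCatalog,
)
from .coverage import CoverageTrack, write_bedgraph

__all__ = ["FamilySpec", "FixtureSpec", "Fixture", "make_fixture",
           "simulate_tracks", "simulate_peaks", "simulate_counts",
           "write_fixture_dir"]


@dataclass(frozen=True)
class FamilySpec:
    """One repeat name to plant: hierarchy, age, copy number and geometry."""

    class_name: str
    family: str
    repeat_name: str
    clade: str
    n_copies: int
    length_range: tuple = (300, 1500)
    tandem_fraction: float = 0.0  # fraction of copies placed in clusters
    tandem_size: int = 3  # copies per cluster


def _default_families() -> list:
    return [
        FamilySpec("LINE", "L1", "L1ME", "Non-Primates", 120, (500, 2000)),
        FamilySpec("LINE", "L1", "L1MB", "Primates", 120, (500, 2000)),
        FamilySpec("LINE", "L1", "L1PA8", "Catarrhini", 100, (500, 2000)),
        FamilySpec("LINE", "L1", "L1HS", "Homo sapiens", 80, (500, 2000)),
        FamilySpec("SINE", "MIR", "MIR", "Non-Primates", 150, (150, 300)),
        FamilySpec("SINE", "Alu", "AluJb", "Primates", 150, (250, 320)),
        FamilySpec("SINE", "Alu", "AluSx", "Simiiformes", 150, (250, 320)),
        FamilySpec("SINE", "Alu", "AluY", "Hominoidea", 120, (250, 320)),
        FamilySpec("SINE", "Alu", "AluYa5", "Homo sapiens", 80, (250, 320)),
        FamilySpec("LTR", "ERV1", "MER41B", "Simiiformes", 100, (300, 800)),
        FamilySpec("LTR", "ERV1", "LTR12C", "Hominoidea", 80, (500, 1200)),
        FamilySpec("DNA", "TcMar-Tigger", "Tigger1", "Non-Primates", 100, (300, 900)),
        FamilySpec("Other", "SVA", "SVA_A", "Hominoidea", 60, (700, 1600)),
        FamilySpec("Other", "SVA", "SVA_D", "Hominidae", 60, (700, 1600), 0.3, 3),
        FamilySpec("Other", "SVA", "SVA_F", "Homo sapiens", 60, (700, 1600), 0.6, 3),
    ]


@dataclass
class FixtureSpec:
    """Study conditions for one synthetic fixture.

    Defaults describe a 2 x 1 Mb toy genome with ~1.5k copies across classes
    and clades, a 2x planted enrichment of the 'young' track on the youngest
    families with 500 bp of flank spillover, Gaussian run noise of sd 0.2
    around baseline 1.0, peaks on enriched copies, and 4-fold knock-down
    upregulation planted in the human-restricted families.
    """

    chromosomes: dict = field(default_factory=lambda: {"chr1": 1_500_000, "chr2": 1_500_000})
    families: list = field(default_factory=_default_families)
    clades: tuple = tuple(DEFAULT_CLADES)
    blacklist_fraction: float = 0.01
    blacklist_segment_bp: int = 2000
    compartment_bp: int = 100_000
    # track name -> {repeat_name: effect}, multiplicative on the baseline
    enrichment: dict = field(
        default_factory=lambda: {
            "young_mark": {
                "SVA_F": 2.0, "SVA_D": 1.8, "AluYa5": 2.0, "AluY": 1.7, "L1HS": 2.0,
                "LTR12C": 1.6, "L1PA8": 1.4, "AluSx": 1.3,
            },
            "old_mark": {
                "L1ME": 2.0, "MIR": 1.8, "Tigger1": 1.8, "AluJb": 1.5, "L1MB": 1.6,
            },
        }
    )
    spillover_bp: int = 500
    baseline: float = 1.0
    noise_sd: float = 0.2
    noise_run_bp: int = 200
    peak_threshold: float = 1.5  # on the noise-free planted signal
    count_mean: float = 20.0
    count_dispersion: float = 0.1
    # repeat_name -> log2 fold change planted in the knock-down samples
    kd_log2fc: dict = field(
        default_factory=lambda: {"SVA_F": 2.0, "AluYa5": 2.0, "L1HS": 2.0, "SVA_D": 1.0}
    )
    n_replicates: int = 3
    min_gap_bp: int = 100
    seed: int = 0


@dataclass
class Fixture:
    genome: GenomeLayout
    catalog: RepeatCatalog
    clades: CladeTable
    blacklist: list
    compartments: pd.DataFrame
    spec: FixtureSpec


def _place_copies(spec: FixtureSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Place all copies without overlap; tandem clusters as runs (<500 bp gaps)."""
    chroms = list(spec.chromosomes)
    occupied = {c: ([], []) for c in chroms}  # sorted starts/ends incl. gap margin

    import bisect

    def try_place(chrom, span):
        # uniform over all feasible start positions (free-gap sampling),
        # keeping min_gap_bp clearance to already placed copies
        length = spec.chromosomes[chrom]
        starts, ends = occupied[chrom]
        gap = spec.min_gap_bp
        free = []  # (first_valid_start, n_valid_starts)
        prev_end = 0
        bounds = list(zip(starts, ends)) + [(length + gap, length + gap)]
        for s_occ, e_occ in bounds:
            lo = prev_end + gap if prev_end > 0 else 0
            hi = min(s_occ - gap, length) - span
            if hi >= lo:
                free.append((lo, hi - lo + 1))
            prev_end = e_occ
        total = sum(n for _, n in free)
        if total == 0:
            return None
        pick = int(rng.integers(0, total))
        for lo, n in free:
            if pick < n:
                s = lo + pick
                i = bisect.bisect_right(starts, s)
                starts.insert(i, s)
                ends.insert(i, s + span)
                return s
            pick -= n
        return None

    records = []
    total_requested = sum(
        f.n_copies * (f.length_range[0] + f.length_range[1]) / 2 for f in spec.families
    )
    genome_bp = sum(spec.chromosomes.values())
    if total_requested > 0.6 * genome_bp:
        raise ValueError(
            f"infeasible packing: ~{total_requested:.0f} requested bp vs "
            f"{genome_bp} bp genome (>60% occupancy)"
        )
    for fam in spec.families:
        lo, hi = fam.length_range
        n_tandem_clusters = int(round(fam.n_copies * fam.tandem_fraction / fam.tandem_size))
        n_singleton = fam.n_copies - n_tandem_clusters * fam.tandem_size
        placed = 0
        for _ in range(n_tandem_clusters):
            sizes = rng.integers(lo, hi + 1, size=fam.tandem_size)
            gaps = rng.integers(0, 450, size=fam.tandem_size - 1)
            span = int(sizes.sum() + gaps.sum())
            chrom = chroms[int(rng.integers(len(chroms)))]
            s = try_place(chrom, span)
            if s is None:
                raise ValueError(f"infeasible packing for tandem cluster of {fam.repeat_name}")
            pos = s
            for j, size in enumerate(sizes):
                strand = "+" if rng.random() < 0.5 else "-"
                records.append((chrom, pos, pos + int(size), strand, fam))
                placed += 1
                pos += int(size) + (int(gaps[j]) if j < len(gaps) else 0)
        for _ in range(n_singleton):
            size = int(rng.integers(lo, hi + 1))
            chrom = chroms[int(rng.integers(len(chroms)))]
            s = try_place(chrom, size)
            if s is None:
                raise ValueError(f"infeasible packing for {fam.repeat_name}")
            strand = "+" if rng.random() < 0.5 else "-"
            records.append((chrom, s, s + size, strand, fam))
            placed += 1
    rows = [
        {
            "chrom": chrom,
            "start": start,
            "end": end,
            "strand": strand,
            "repeat_name": fam.repeat_name,
            "family": fam.family,
            "class_name": fam.class_name,
            "copy_id": f"{chrom}:{start}-{end}:{fam.repeat_name}",
        }
        for chrom, start, end, strand, fam in records
    ]
    df = pd.DataFrame(rows).sort_values(["chrom", "start"]).reset_index(drop=True)
    return df


def make_fixture(spec: FixtureSpec) -> Fixture:
    """Deterministically generate genome, catalog, clades, blacklist, segments."""
    rng = np.random.default_rng(spec.seed)
    genome = GenomeLayout(dict(spec.chromosomes))
    copies = _place_copies(spec, rng)
    catalog = RepeatCatalog(copies, genome)

    clade_map = {f.repeat_name: f.clade for f in spec.families}
    clades = CladeTable(clade_map, tuple(spec.clades))

    blacklist = []
    n_bl = int(genome.total_bp * spec.blacklist_fraction / spec.blacklist_segment_bp)
    chroms = list(spec.chromosomes)
    for _ in range(n_bl):
        chrom = chroms[int(rng.integers(len(chroms)))]
        s = int(rng.integers(0, spec.chromosomes[chrom] - spec.blacklist_segment_bp + 1))
        blacklist.append((chrom, s, s + spec.blacklist_segment_bp))
    blacklist.sort()

    seg_rows = []
    for chrom, length in spec.chromosomes.items():
        label = "A"
        pos = 0
        while pos < length:
            end = min(pos + spec.compartment_bp, length)
            seg_rows.append((chrom, pos, end, label))
            label = "B" if label == "A" else "A"
            pos = end
    compartments = pd.DataFrame(seg_rows, columns=["chrom", "start", "end", "label"])
    return Fixture(genome, catalog, clades, blacklist, compartments, spec)


def _planted_dense(fixture: Fixture, effects: dict, step: int = 50) -> dict:
    """Noise-free planted signal per chromosome, quantized to `step`-bp blocks."""
    spec = fixture.spec
    dense = {}
    for chrom, length in spec.chromosomes.items():
        n_blocks = int(np.ceil(length / step))
        dense[chrom] = np.full(n_blocks, spec.baseline)
    sub = fixture.catalog.copies
    for chrom, start, end, name in sub[["chrom", "start", "end", "repeat_name"]].itertuples(
        index=False
    ):
        effect = effects.get(name)
        if not effect or effect == 1.0:
            continue
        arr = dense[chrom]
        peak_value = spec.baseline * effect
        b0, b1 = start // step, -(-end // step)  # blocks covering the body
        arr[b0:b1] = np.maximum(arr[b0:b1], peak_value)
        if spec.spillover_bp > 0:
            n_sp = spec.spillover_bp // step
            for k in range(1, n_sp + 1):
                frac = 1.0 - k / (n_sp + 1)  # linear decay toward baseline
                val = spec.baseline + (peak_value - spec.baseline) * frac
                if b0 - k >= 0:
                    arr[b0 - k] = max(arr[b0 - k], val)
                if b1 - 1 + k < len(arr):
                    arr[b1 - 1 + k] = max(arr[b1 - 1 + k], val)
    return dense


def _dense_to_track(fixture: Fixture, dense: dict, step: int) -> CoverageTrack:
    per_chrom = {}
    for chrom, arr in dense.items():
        length = fixture.spec.chromosomes[chrom]
        bounds = np.minimum(np.arange(len(arr) + 1, dtype=float) * step, length)
        per_chrom[chrom] = (bounds, arr.astype(float))
    return CoverageTrack.from_bounds(fixture.genome, per_chrom)


def simulate_tracks(fixture: Fixture, step: int = 50) -> dict:
    """Named coverage tracks with planted enrichments and run-level noise."""
    spec = fixture.spec
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    tracks = {}
    for track_name in spec.enrichment:
        dense = _planted_dense(fixture, spec.enrichment[track_name], step)
        if spec.noise_sd > 0:
            blocks_per_run = max(1, spec.noise_run_bp // step)
            for chrom in dense:
                arr = dense[chrom]
                n_runs = -(-len(arr) // blocks_per_run)
                noise = rng.normal(0.0, spec.noise_sd, size=n_runs)
                arr += np.repeat(noise, blocks_per_run)[: len(arr)]
        tracks[track_name] = _dense_to_track(fixture, dense, step)
    return tracks


def simulate_peaks(fixture: Fixture, step: int = 50) -> dict:
    """One peak per enriched copy body (planted signal above threshold)."""
    spec = fixture.spec
    out = {}
    for track_name, effects in spec.enrichment.items():
        rows = []
        for chrom, start, end, name in fixture.catalog.copies[
            ["chrom", "start", "end", "repeat_name"]
        ].itertuples(index=False):
            effect = effects.get(name, 1.0)
            if spec.baseline * effect > spec.peak_threshold:
                rows.append((chrom, start, end, spec.baseline * effect))
        out[track_name] = pd.DataFrame(rows, columns=["chrom", "start", "end", "score"])
    return out


def simulate_counts(fixture: Fixture):
    """NB count matrix (copies x samples) with planted knock-down effects."""
    spec = fixture.spec
    if spec.n_replicates < 2:
        raise ValueError("need >= 2 replicates per condition")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2]))
    ids = fixture.catalog.copies["copy_id"].tolist()
    names = fixture.catalog.copies["repeat_name"].tolist()
    mu = np.full(len(ids), spec.count_mean)
    fc = np.array([2.0 ** spec.kd_log2fc.get(n, 0.0) for n in names])
    alpha = spec.count_dispersion

    def nb_draw(mean_vec, size_cols):
        n_param = 1.0 / alpha
        p_param = n_param / (n_param + mean_vec)
        return np.column_stack(
            [rng.negative_binomial(n_param, p_param) for _ in range(size_cols)]
        )

    control = nb_draw(mu, spec.n_replicates)
    kd = nb_draw(mu * fc, spec.n_replicates)
    samples = [f"control_{i+1}" for i in range(spec.n_replicates)] + [
        f"kd_{i+1}" for i in range(spec.n_replicates)
    ]
    counts = pd.DataFrame(
        np.column_stack([control, kd]).astype(float), index=pd.Index(ids, name="copy_id"),
        columns=samples,
    )
    sheet_rows = [
        {"sample": s, "condition": "control" if s.startswith("control") else "kd",
         "replicate": int(s.split("_")[1])}
        for s in samples
    ]
    from .expression import SampleSheet

    return counts, SampleSheet(pd.DataFrame(sheet_rows))


def write_fixture_dir(fixture: Fixture, outdir, tracks=None, peaks=None, counts=None, sheet=None) -> None:
    """Write the complete fixture as plain-text files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fixture.genome.write(outdir / "genome.chrom.sizes")
    from .catalog import write_catalog_bed

    write_catalog_bed(fixture.catalog, outdir / "repeats.bed")
    with open(outdir / "repeats.gtf", "w") as fh:
        for chrom, start, end, strand, name, family, class_name in fixture.catalog.copies[
            ["chrom", "start", "end", "strand", "repeat_name", "family", "class_name"]
        ].itertuples(index=False):
            attrs = (
                f'gene_id "{name}"; transcript_id "{name}"; '
                f'family_id "{family}"; class_id "{class_name}";'
            )
            fh.write(
                f"{chrom}\tsynthetic\texon\t{start + 1}\t{end}\t.\t"
                f"{strand if strand in '+-' else '.'}\t.\t{attrs}\n"
            )
    fixture.clades.write(outdir / "clades.tsv")
    with open(outdir / "blacklist.bed", "w") as fh:
        for chrom, s, e in fixture.blacklist:
            fh.write(f"{chrom}\t{s}\t{e}\n")
    fixture.compartments.to_csv(
        outdir / "compartments.bed", sep="\t", header=False, index=False
    )
    if tracks:
        for name, track in tracks.items():
            write_bedgraph(track, outdir / f"{name}.bedgraph")
    if peaks:
        for name, pk in peaks.items():
            pk[["chrom", "start", "end"]].to_csv(
                outdir / f"{name}.peaks.bed", sep="\t", header=False, index=False
            )
    if counts is not None:
        counts.to_csv(outdir / "counts.tsv", sep="\t", index_label="copy_id")
    if sheet is not None:
        sheet.write(outdir / "samples.tsv")
    def _plain(obj):
        if isinstance(obj, dict):
            return {k: _plain(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_plain(v) for v in obj]
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        return obj

    with open(outdir / "spec.yaml", "w") as fh:
        yaml.safe_dump(_plain(asdict(fixture.spec)), fh, sort_keys=True)
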