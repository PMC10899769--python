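# teprofile

Transposable-element-centric epigenomic profiling in Python.

Chromatin marks and chromatin-associated proteins (histone variants,
KRAB-zinc-finger repressors, methylation) are not uniformly distributed over
the repetitive half of mammalian genomes: recently incorporated
retrotransposon families (SVA, AluY, young L1PA elements) often carry a
distinct chromatin state from ancient ones.  `teprofile` provides the
analysis layer for asking such questions from standard genomics files — no
aligner, peak caller, or database download required:

- **Repeat catalogs** — parse RepeatMasker/TEtranscripts-style GTF or BED
  annotations into a class → family → repeat-name hierarchy; drop uncertain
  (`SINE?`) classifications and blacklist-overlapping copies; compute genome
  occupancy; partition labeled segments (e.g. Hi-C A/B compartments) into
  repetitive (R) and non-repetitive (NR) fractions.
- **Signal aggregation** — run-length coverage tracks from bedGraph or
  alignment spans, reads-per-million scaling, input subtraction (negative
  values retained), length-weighted per-copy abundance tables, and
  top/bottom quantile filtering within repeat groups.
- **Meta-repeat profiles** — every copy scaled to a common number of body
  bins plus fixed flanks (`scale-regions` semantics, fractional base
  apportioning), reference-point profiles, row-z scaling and
  euclidean/complete-linkage ordering for heatmaps.
- **Peak enrichment** — peaks assigned to the repeat copy overlapping ≥ 50 %
  of the peak, per-class percentages calibrated against a constrained
  shuffled null (same chromosome, same lengths, no blacklist or mutual
  overlap), and per-family "fraction of copies carrying a peak" tables.
- **Tandem decomposition** — alone / first / internal / last labels for
  copies of a focal family relative to superfamily neighbors within 500 bp.
- **Evolutionary age** — ordinal clade ranks (oldest taxonomic clade with
  orthologous copies, Non-Primates → Homo sapiens), per-clade summaries with
  Kruskal–Wallis and one-sample Wilcoxon annotations, and a Spearman age
  trend ρ(clade rank, abundance).
- **Repeat expression** — largest-overlap read counting with fractional
  multi-map weighting (1/k), the ≥ 3-reads expressed/not-expressed split,
  a transparent negative-binomial two-group test with pooled
  method-of-moments dispersion, |FC| > 1.5 & BH-adjusted p < 0.05
  deregulation calls, observed-vs-expected group proportions of up-regulated
  elements, and coarse read-change categories (never expressed, became
  expressed, increased, decreased, became silent, unchanged).
- **Synthetic fixtures** — a seeded generator of toy genomes with planted
  family enrichments, flank spillover, tandem clusters, age gradients, and
  knock-down effects, so the whole pipeline is testable end to end.

## Worked example

```python
import teprofile as tp

spec = tp.FixtureSpec(seed=1)          # 2 x 1.5 Mb toy genome, ~1530 copies
fx = tp.make_fixture(spec)
cat = tp.apply_exclusions(fx.catalog, fx.blacklist)
cat = tp.assign_clades(cat, fx.clades)

print(tp.occupancy(cat, fx.genome, level="all"))
#   group       bp    percent
# 0   all  1090177  36.339233

tracks = tp.simulate_tracks(fx)        # planted 'young_mark' / 'old_mark'
table = tp.abundance_table(tracks, cat)
rho, p = tp.age_trend(table, cat, "young_mark")
print(f"age trend rho={rho:.3f} p={p:.2e}")
# age trend rho=0.795 p=0.00e+00
```

The positive ρ says the `young_mark` signal increases monotonically with
clade rank — the planted gradient toward human-restricted repeats is
recovered from the abundance table alone.  Peak enrichment works the same
way:

```python
peaks = tp.simulate_peaks(fx)["young_mark"]
rep = tp.enrichment_report(peaks, cat, fx.genome, n_shuffles=50, seed=2,
                           blacklist=fx.blacklist)
print(rep.percent_peaks_in_repeats)    # 97.9 (planted peaks on excluded
                                       # copies stay unassigned)
print(rep.per_class[["class_name", "observed_pct", "null_mean_pct", "ratio"]])
```

A command-line pipeline mirrors the library (`teprofile fixture`,
`catalog`, `abundance`, `profile`, `peaks`, `tandem`, `age`,
`expression`), each stage driven by a YAML config and accompanied by a
manifest of input checksums, parameters, and seed.

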