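# Methods

This note documents the models, conventions, and numerical choices behind
`teprofile`, and what the synthetic fixtures do and do not emulate.

## Coordinates and interval arithmetic

All internal coordinates are 0-based half-open (`[start, end)`), the BED
convention.  GTF input (1-based inclusive) is converted on read and
reconverted on write.  Blacklist exclusion removes any copy with ≥ 1 bp of
overlap — "overlapping" without a threshold is ambiguous, so the strictest
reading is the default and the blacklist is an explicit argument.  Strand is
stored but ignored by occupancy and R/NR partitioning (those are per-base,
strand-blind quantities); only meta-profiles honor it, reversing
minus-strand copies so flanks read 5′ → 3′.

Occupancy is the per-base union of copy intervals within a group, so
overlapping copies are never double-counted.  Segment partitioning cuts each
labeled segment at repeat-union boundaries; the R and NR pieces tile the
input exactly, which is asserted as a test invariant.

## Coverage tracks

A track is a per-chromosome tiling into runs of constant value, including
zero runs (the `bedtools genomecov -bga` convention), canonicalized by
merging equal-valued neighbors.  Reads contribute over their recorded spans
(no fragment extension — extension belongs to peak callers, which this
package consumes rather than reimplements).  Multi-mapping policy is either
`unique_only` (n_hits = 1 reads only, weight 1) or `fractional` (every
alignment weighted 1/n_hits), mirroring the two featureCounts modes used in
repeat quantification; fractional weighting conserves total read mass
exactly, which is a test invariant.  Input subtraction is per-base ChIP
minus input after reads-per-million scaling; negative values are retained —
clipping would bias the per-repeat boxplot summaries toward zero.

The per-copy summary statistic is the **length-weighted mean** of the
subtracted signal.  "Abundance" per repeat could equally be a sum; the mean
is scale-free across copy lengths (a 300 bp Alu and a 6 kb L1 become
comparable) and is the default, with sum/median available through pandas on
the abundance table.

## Meta-repeat profiles

Scaled-body profiles divide each copy into `body_bins` equal fractional
sub-intervals and add fixed-width flank bins (defaults: 100 body bins,
3 000 bp flanks in 60 × 50 bp bins; only the 3 kb flank width is a
domain-standard figure, the bin counts are resolution choices).  Bins use
fractional base apportioning — a base straddling a bin boundary contributes
proportionally — so the mean of a copy's body bins equals the mean over the
copy to floating-point accuracy, a property the tests assert.  Bins beyond
chromosome ends are NaN and are excluded from averages, never zero-filled
(zero-filling would fabricate depletion at chromosome-edge copies).

Group-level heatmaps are row-z scaled (constant rows map to zeros and are
flagged) and ordered by agglomerative clustering with euclidean distance and
complete linkage.  Rows are canonically sorted by label before linkage so
the leaf order is deterministic and invariant to input permutation.

## Peak–repeat enrichment

A peak is repeat-assigned when a single copy overlaps at least half of the
peak's length, inclusive at exactly 50 %.  When several copies qualify the
largest overlap wins, with ties broken by leftmost start then copy id —
single assignment keeps per-class percentages summing to 100.

The null model re-places every peak uniformly at random on its own
chromosome, preserving length, and rejecting placements that touch the
blacklist or a previously placed peak (the `-chrom -noOverlapping` shuffle
semantics).  Peaks are placed longest-first so the hardest placements see
the emptiest genome; placement is deterministic per seed.  The null is
summarized by the mean and standard deviation of per-class percentages
across replicates, plus an empirical two-sided rank p-value (extra
calibration output, not part of the core enrichment ratio).  Known
limitation: the shuffle preserves chromosome and length but not inter-peak
spacing, so clustered peak architectures are dispersed under the null.

## Tandem decomposition

A focal copy is `alone`, `first`, `internal`, or `last` according to whether
a same-superfamily neighbor lies within 500 bp upstream and/or downstream.
Sides are genomic (coordinate order), not element strand.  The gap is
measured end-to-start, the 500 bp boundary is inclusive, and an overlapping
neighbor counts at distance 0 on the side(s) it extends toward.  The context
defaults to all copies of the focal family's class-level superfamily.  The
sorted-sweep implementation is validated against an O(n²) all-pairs scan,
including exact-boundary gaps.

## Evolutionary age

Repeat names carry an ordinal clade rank from a user-supplied table — the
oldest taxonomic clade in which orthologous copies occur (default seven
labels, Non-Primates through Homo sapiens; the table abstraction admits any
granularity).  Clade summaries report n/median/quartiles per rank with a
Kruskal–Wallis omnibus test and per-clade one-sample Wilcoxon signed-rank
tests against the median of the comparison universe.  The Spearman age
trend ρ(clade rank, abundance) condenses the ordered-boxplot gradient into
one number for quantitative testing; it is deliberately simple plumbing, not
a standard figure statistic.  Per-name aggregation uses the mean of copy
means (median available via the table).

## Expression changes after knock-down

Reads are assigned to the copy with the largest overlap (≥ 1 bp,
deterministic tie-break).  A copy is *expressed* when its mean count over a
condition's replicates is ≥ 3 (inclusive).

The differential test is a deliberately transparent stand-in for a full
shrinkage-based NB fit: counts are scaled by per-sample total-count size
factors; per-copy method-of-moments dispersions (pooled within-group
variance vs grand mean) are averaged over all tested copies into one
moderated dispersion; the Wald statistic is the log fold change over its
delta-method standard error, referred to the normal distribution.  The
cross-copy pooling is essential — at 2–3 replicates the per-copy dispersion
estimate is so noisy that a normal reference is anti-conservative and a
t(df = 4) reference has no multiplicity-surviving power; with pooling the
empirical type-I error at α = 0.05 sits near 0.05 on NB nulls (asserted in
the tests).  Copies below a total-count floor (default 10) are excluded
before testing (independent filtering).  Fold changes use pseudocount 0.5;
BH adjustment runs over tested copies; deregulation requires linear
|FC| > 1.5 and adjusted p < 0.05.  `classify_from_table` applies the same
thresholds to an externally produced log2FC/padj table, so output of a full
DESeq2-style fit can be dropped in.

Read-change categories use the same ≥ 3-read expressed rule at both ends
and a 1.5-fold pseudocounted mean ratio for increased/decreased among
copies expressed in both conditions.  These thresholds are analysis
conventions, not estimands; both are arguments.

## Synthetic fixtures

The generator emulates the *statistical structure* of a TE profiling study:
a 2 × 1.5 Mb toy genome (≈ 1 530 copies across SINE/LINE/LTR/DNA/SVA
families spanning all seven clade ranks — sized so that placement stays
below ~40 % occupancy and the whole suite runs in seconds), tandem-prone
young SVA families, a blacklist covering 1 % of the genome, alternating
100 kb A/B segments, multiplicative per-family track enrichments (so row-z
heatmap scaling behaves as on real scaled heatmaps) with linearly decaying
flank spillover quantized to 50 bp blocks, Gaussian noise per 200 bp run,
one peak per enriched copy body, and NB counts (mean 20, dispersion 0.1,
3 + 3 replicates) with planted knock-down log2 fold changes concentrated in
human-restricted families.  Copy placement samples uniformly over all
feasible gap positions, so packing is deterministic per seed and fails only
when genuinely infeasible.

Not emulated: sequence content, mappability and copy divergence, GC bias,
fragment-level read placement, inter-sample batch effects.  Passing tests
therefore demonstrate the correctness of the pipeline arithmetic and the
calibration of its statistics under the stated models — not robustness to
alignment artifacts in real sequencing data.

## Numerical choices and degenerate inputs

- Quantile filtering selects ceil(f·n) copies, ties broken by copy id.
- Constant rows in row-z scaling become zero rows and are flagged.
- Constant abundance makes the age trend ρ undefined → (NaN, NaN).
- Constant columns in the Spearman matrix give NaN ρ, masked False.
- Empty peak sets produce an explicit empty report, never a division.
- Signed-rank/U tests use exact null distributions for small samples
  (n < 26, no ties) and tie/continuity-corrected normal approximations
  otherwise; exact zeros against the reference are dropped before the
  signed-rank test.
- All random processes are driven by `numpy.random.default_rng` with seeds
  derived via `SeedSequence`, so every output is reproducible per seed
  across platforms.
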