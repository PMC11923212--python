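# Methods

## Scope and coordinates

`trcmap` implements the genomic arm of a DSB-mapping study: sBLISS
read processing, BLISS+ region calling, annotation against replication
timing (ERRs) and S-phase transcription, head-on / co-directional TRC
classification, and spike-in normalization of count tables. Read
alignment, genome liftover and the negative-binomial differential test
are out of scope; the differential modules consume an externally
computed table (gene id, log2FoldChange, padj). All coordinates are
0-based half-open, in memory and on disk (BED convention).

## Break-read processing

A read's first 8 nt are the UMI, the next 8 nt the sample barcode,
matched against a whitelist with at most one substitution
(`parse_prefix`). Whitelists must keep pairwise Hamming distance above
twice the tolerance; an observed barcode equidistant from two entries
raises rather than guessing. Reads with MAPQ < 30 are removed
(`filter_mapq`; the boundary is "lower than 30", so 30 is kept).

Duplicate collapse (`deduplicate`) builds the graph whose edges join
reads on one chromosome at most `pos_window` (10) bp apart with UMIs at
most `max_umi_mismatch` (1) substitutions apart, and takes connected
components (single-linkage). The linkage is deliberately transitive:
"adjacent" duplicates chain, and the result is independent of input
order. The cluster representative is the smallest position (UMI
lexicographic tie-break), and the emitted table has one row per
(chromosome, representative position) with the number of clusters
there — the unique-UMI count. Dedup is strand-agnostic by default
(`strand_aware=True` splits by strand); reads never cluster across
chromosomes or samples. Whether the original pipeline's collapse was
greedy-pairwise or transitive is not observable from its description;
single-linkage was chosen because it is order-independent, and the
equivalence oracle in the tests pins this semantics exactly.

## Hotspot calling

Down-sampling precedes calling and operates on deduplicated UMI events:
each sample is reduced to the smallest sample's total by drawing
individual UMIs uniformly without replacement (an event with k UMIs
contributes k units). Per-sample RNG streams are derived from the seed
in sorted sample order, so results do not depend on dict ordering.

Bins are `bin_size` (2000) bp, anchored at coordinate 0 of each
chromosome; the trailing partial bin is kept and thresholded
identically. A bin is BLISS+ when its UMI coverage is strictly greater
than `threshold` (22) — the comparator is configurable because the
boundary reading ("above which") is strict. Positive bins whose
end-to-start gap is at most `max_gap` (2000) bp merge into a region
spanning its member bins, carrying `n_bins` and `total_coverage`.
Replicate sets are unioned (overlapping or book-ended intervals
coalesce). The overlap matrix entry (A, B) is the fraction of A's
regions with ≥ 1 bp overlap of any B region; it is intentionally
asymmetric, the diagonal is 1 for non-empty sets, and an empty
condition contributes a zero row with a warning.

## Annotation

Promoters are strand-aware TSS windows, default −2000/+500 bp. The
paper-scale analysis never defines "promoter"; this default is the
common convention and of the same order as the bin size. Precedence is
promoter > intragenic > extragenic, so every region gets exactly one
category. ERR / transcript flags use ≥ 1 bp overlap; a
`proximal_distance` slack (default 0) pads the features first. The
transcript set is the expressed genes (baseMean filter) when counts are
supplied.

The two flags define three determinate clusters (1 = transcript∧ERR,
2 = ERR-only, 3 = transcript-only; neither flag leaves a region
unclustered). A fourth label used in the source analysis splits the
transcript∧ERR class by an undocumented rule; since the split cannot be
reconstructed from the flags, `assign_cluster` exposes the mapping as
configuration (`cluster_map`, plus a `split_both` mask that moves
selected transcript∧ERR regions to label 4) rather than hard-coding a
guess.

Metagene profiles resample each region's center ± `flank` window to
`n_points` (midpoint sampling per point), zero-padding beyond
chromosome ends, and average per cluster.

## TRC classification

The replication origin of an ERR is the argmax of its EdU-HU signal
after a centered moving average of `smooth_bins` (5) track windows;
ties resolve to the plateau midpoint, so a flat profile yields the ERR
midpoint. An all-zero ERR raises unless `fallback_midpoint` is set.
The smoothed argmax resolves the origin to about one track window, so
the windows should be coarse relative to the ERR (roughly 10–25
windows per ERR); at much finer grids, per-window noise dominates the
triangle slope.

Fork direction at a position is right of the origin → "right", left →
"left"; the origin itself is degenerate. A region is associated with
the nearest ERR and nearest expressed gene within `assoc_window`
(10 kb) of its midpoint — the "proximal" language of the source
analysis gives no distances, so both the window and the association
rule are configuration. Regions spanning the inferred origin are
unclassified rather than arbitrarily assigned. Classification is a
pure function of (fork direction, gene strand): co-directional when
they agree, head-on when they oppose. Summaries count classes per
cluster; fractions are over classified calls and NaN when none.

## Spike-in normalization

Size factors are DESeq2-style median-of-ratios restricted to spike-in
rows: per sample, the median over spike rows of log(count) minus the
row's log geometric mean, exponentiated. Rows containing any zero are
excluded from the reference (standard convention). The factors carry
geometric mean ≈ 1; ratios between samples are the meaningful
quantity, and the equal-count degenerate case returns exactly 1.
Normalized counts are counts / factor; baseMean is their mean across
samples; expressed means baseMean strictly above `base_mean_min` (32).
Gene-interval extension adds round(0.1 × length) bp at both ends,
strand-independently, clipped to chromosome bounds. DEG labels
(padj < 0.05, sign of fold change) and the control sample (n = 500
uniform among padj > 0.5) are pure filters on the external table.

## Synthetic data

The generator emulates the statistical structure the analysis assumes,
with exported ground truth:

* **Genome.** `n_chroms` × `chrom_length` (2 × 1 Mb) chromosomes;
  `n_genes` (50) pairwise-disjoint genes with uniform random strands,
  lengths uniform in `gene_length_range` (5–20 kb); `n_errs` (8)
  non-overlapping ERRs of 40–80 kb placed independently of genes, each
  with its origin at the midpoint. Feature placement is rejection
  sampling with bounded retries; configurations that cannot fit raise.
* **Hotspots.** `n_hotspots` (20) windows of `hotspot_width` (2 kb)
  centered on TSSs planted inside ERRs, at least one window-width from
  the origin so the fork direction is uniform across the window and a
  signal-estimated origin cannot land inside it. Each records its
  planted rate, fork direction (left/right of origin) and implied TRC
  class; hotspots beyond the available genes fall back to background
  placement with class "none".
* **Signal.** EdU-HU is triangular per ERR — 1.0 at the origin,
  linear to 0 at the edges — the fork-symmetric profile of outward
  replication from one origin. EU is a constant per-gene level
  (lognormal across genes) apportioned by window coverage, so the
  track integral equals level × length.
* **Reads.** Unique molecules are Poisson(`background_break_rate` ×
  length) uniform per chromosome — the source analysis states no
  background noise model, so Poisson-uniform is an explicit assumption
  — plus Poisson(rate × (multiplier − 1) × width) extra molecules per
  hotspot, giving multiplier-scaled hotspot rates. Each molecule gets
  a random UMI, a whitelist barcode (pairwise Hamming ≥ 3) and a
  strand; with probability `pcr_duplication_rate` (0.3) it is
  re-emitted once with uniform jitter in ±`pos_jitter_max` (10) bp, one
  UMI substitution with probability `umi_error_rate` (0.1) and one
  barcode substitution with probability `barcode_error_rate` (0.05).
  MAPQ is a two-component mixture with `mapq_fail_rate` (0.1) below
  30 — only the filter boundary matters.
* **Counts.** Host and spike means are lognormal; spike expectations
  are equal across samples before each sample's true factor scales
  everything; noise is Poisson (or deterministic rounding with
  `noise="none"`).

Defaults are the study conditions of the recovery analyses. The
default `hotspot_rate_multiplier` of 150 keeps the expected hotspot
bin coverage at ≥ 3× the calling threshold per sample even in the
worst case (a window straddling a bin boundary, two samples, 10 %
MAPQ failures: 10⁻³ × 150 × 1000 × 0.45 ≈ 67 > 66), while background
expectation stays at 2 per bin ≤ threshold/3. All RNG streams derive
from `SimConfig.seed` via per-stage `SeedSequence` children, so
identical configs give byte-identical outputs.

What the generator does **not** emulate: chromatin-dependent break
propensity, sequence-composition biases, fragment-length effects,
multi-copy PCR duplicate chains, origin asymmetry or multi-origin
ERRs, and expression heterogeneity beyond a per-gene constant. Passing
recovery tests therefore show the algorithms are correct under the
stated noise model, not that real libraries meet that model.

## Numerical and degenerate-input choices

* Dedup tie-break: smallest position, then lexicographic UMI — makes
  representatives permutation-invariant.
* Events outside chromosome bounds fail loudly, naming the record.
* Down-sampling of an already-minimal sample is the identity.
* `union_regions` of empty sets returns an empty frame; the overlap
  matrix warns on empty conditions instead of dividing by zero.
* Size factors require at least one all-positive spike row; matrices
  violating this raise rather than returning NaN.
* The simulated count matrix requires ≥ 8 spike rows (median stability).
* Pipeline summaries are JSON with sorted keys; reruns with one config
  are byte-identical, which the tests assert with file comparison.

## Problem sizes

Tests and the acceptance script run the default 2 × 1 Mb genome
(~10⁴ reads per study; 20 seeds for recovery and size-factor checks,
50 seeds for down-sampling uniformity), chosen so the complete suite
runs in well under a minute while keeping every Monte-Carlo interval
tight enough for 3σ assertions.
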