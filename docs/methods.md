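# Methods

## Scope and model

The package quantifies, per gene, the effect of Supt4h (DSIF) knockdown on
RNA polymerase II (Ser2-phosphorylated) template occupancy, and relates that
effect to template G+C content. The occupancy unit is FPKM — fragments per
kilobase of gene body per million mapped fragments — computed from ChIP-seq
fragment intervals; the per-gene effect statistic is
ESKOR = log2(FPKM_KD / FPKM_UNT). All coordinates are 0-based half-open
internally; the gene body is the TSS→TTS span including introns, and the
gene length is that span. "5′→3′" always means transcription direction:
minus-strand genes are processed on the reverse complement, windows and bins
advancing leftward in genomic coordinates.

## Coordinate and counting conventions

* **Fragment assignment.** A fragment is assigned to a gene iff its midpoint
  ⌊(start+end)/2⌋ lies in [tx_start, tx_end). Each fragment counts for at
  most one gene; among overlapping genes the one with the smallest tx_start
  (then lexicographically smallest id) wins. Midpoint assignment was chosen
  over overlap counting because it assigns unambiguously, conserves counts,
  and matches the one-fragment/one-feature behavior of standard gene-level
  counters. Replicate libraries are pooled by concatenation (library sizes
  add) before any counting.
* **Gene filters.** Analyzed genes have gene length ≥ 5 kb, ChIP FPKM > 0.5
  in *both* conditions (the two-sided version keeps the log ratio finite and
  makes the statistic symmetric under condition exchange), and appear in the
  RNA expression table. Each gene's representative isoform is the one with
  the highest untreated RNA FPKM; ties go to the longer isoform, then the
  lexicographically first id, so selection is deterministic.
* **G+C content.** Whole-gene G+C excludes the first 1 kb downstream of the
  TSS, which for nearly all genes covers a G+C-rich promoter region that
  would otherwise compress between-gene contrast. Windowed G+C uses
  non-overlapping 100 bp tiles from the TSS (the step equals the window, so
  a 10 kb span yields exactly 100 columns in the heatmap); the trailing
  partial window is dropped. Ambiguous bases (N) are excluded from both
  numerator and denominator, and a window that is ≥ 50% N is reported
  missing rather than biasing the percentage in assembly gaps.
  Mono/dinucleotide frequencies are computed on the sense strand by default
  with a `template` switch; the G+C total is strand-invariant either way.
  Dinucleotide percent is count / (region length − 1) × 100.
* **Ranking and smoothing.** Genes are sorted by ESKOR descending (ties by
  id). The G+C moving average uses a centered window of `window` neighboring
  genes (default 100, i.e. ±50), shrunk symmetrically at the ends so every
  rank has a value. The ESKOR–G+C association is the Pearson product-moment
  correlation; it is reported missing with a warning when either variable is
  constant.
* **Segments.** Consecutive 500 bp segments start 1 kb 3′ of the TSS;
  the trailing partial segment is dropped, genes with fewer than two
  segments are excluded, and the highest/lowest-G+C picks break ties toward
  the 5′-most segment. A gene whose segments all tie (e.g. a homopolymer in
  simulation) is flagged degenerate and excluded from the highest-vs-lowest
  contrast. Per-segment counts use the same midpoint rule, binned at 25 bp
  and normalized per million mapped; the cohort statistic is the per-gene
  segment total (sum of the 20 bins), averaged across genes with
  SEM = SD/√n. Condition comparisons use the two-sample equal-variance
  (pooled) Student's t-test, two-tailed; with zero pooled variance the
  p-value is defined as 1 when the means agree and is an error otherwise.
* **Metagene.** Each gene body is split into 100 bins at edges
  TSS + round(j·L/100); 1 kb flanks are binned at a fixed 25 bp (40 bins per
  side). Because body bins vary in width across genes, bin values are
  densities — counts per million mapped per kilobase of bin width — so body
  and flank bins are directly comparable and genes of different lengths
  aggregate meaningfully. Profiles are not rescaled to unit area: the
  figures of interest show absolute occupancy differences between
  conditions, which unit-area scaling would erase. Flank bins that fall off
  the chromosome are missing (NaN) and are skipped, with per-bin counts
  tracked, when averaging.
* **Stratification.** Length groups (5–15, 15–30, 30–70, 70–230 kb) and G+C
  ranges (45–50, 50–55, 55–60%) are half-open; genes outside them are
  reported separately. Quantiles use linear interpolation between order
  statistics (NumPy's default), fixed here so violin summaries are
  bit-reproducible. Fold-change rankings break ties by gene id.

## The synthetic-data generator

The generator produces the minimal data structure the analysis assumes, not
a realistic genome. One chromosome carries non-overlapping single-isoform
genes separated by 2 kb gaps, with lengths log-uniform on 5–230 kb, strands
random, and per-gene target G+C uniform on 35–65%. Within a gene, sequence
is drawn per base from a per-block (500 bp) G+C probability jittered around
the target (SD 8 percentage points, clipped to 5–95%), which gives every
gene distinct highest- and lowest-G+C 500 bp segments while keeping realized
whole-gene G+C tightly coupled to the target.

Occupancy follows a linear trend per condition,
FPKM_c = intercept_c + slope_c · gc (floored at 0.05), with per-gene
fragment counts Poisson(FPKM_c × length_kb × depth_millions) and fragment 5′
ends uniform along the gene body. Defaults: slope 0.0502 (untreated) and
0.0328 (knockdown) FPKM per G+C point; depth 2 × 10⁶ fragments per
condition (the reported library size both conditions are normalized to);
fragment length 200 bp; 1% of the depth as uniform genome-wide background
(an intercept-only nuisance that leaves the fitted slopes unbiased).

The two trendlines cross at `gc_pivot` (default 62%): the knockdown
intercept is derived as intercept_unt + (slope_unt − slope_kd) · pivot.
A high crossing point reflects how per-million normalization redistributes
signal — when high-G+C genes lose occupancy under knockdown, the relative
(per-million) occupancy of low-G+C genes rises — and it gives the expected
ESKOR enough spread across the G+C range (≈ +0.65 at 35% G+C to ≈ 0 at 65%)
that the ESKOR–G+C correlation is identifiable above the Poisson sampling
noise of desk-scale libraries. At the defaults the ESKOR noise SD from
counting alone is ≈ 0.1–0.4 per gene (dominated by short genes), which caps
the attainable Pearson correlation near −0.6; published analyses at
hundred-fold deeper sequencing report correlations near −0.8 that are not
reachable, and not targeted, at this scale.

Two optional knockdown effects, both off by default:

* **Positional decay** (`decay`, per kb per G+C point above the pivot):
  knockdown fragment positions follow a truncated exponential toward the
  TSS, and the expected count shrinks by the mean survival
  (1 − e^−λR)/(λR) — a lossy decay modelling polymerase dissociation along
  the template, so longer and more G+C-rich genes lose more total occupancy
  and their coverage tilts 5′.
* **Block thinning** (`kd_gc_suppression`): knockdown fragments whose
  midpoint falls in a sequence block above the pivot G+C are kept with this
  probability, modelling a knockdown effect confined to G+C-rich template
  segments while A+T-rich segments are untouched.

The truth table records the expected FPKM and ESKOR per gene including the
deterministic decay-survival and (uniform-placement) thinning factors; when
both knobs are combined the recorded thinning expectation is approximate.
RNA expression couples to the expected occupancy effect:
baseline FPKM log-normal (median 20, σ = 1), fold change
2^(coupling · expected_ESKOR + ε) with ε ~ N(0, 0.1² log2 units), and raw
counts Poisson at a 2 × 10⁷ library.

What the generator does *not* emulate: mappability, nucleosome or CpG-island
structure, paired-end insert-size variation, replicate batch effects, and
overdispersion beyond Poisson. Passing tests therefore demonstrate that the
pipeline's estimators recover the generating parameters under clean sampling
noise — not that real libraries are this well behaved.

## Validation design and problem sizes

Unit tests check every operation against closed-form examples and
independent brute-force recomputation (per-fragment counting scans, naive
window recounts, midpoint histograms, sort-based quantiles) on batches of
20 randomized small instances with fixed seeds. End-to-end validation runs
the full pipeline on the reference simulation (2000 genes, 2 × 10⁶
fragments/condition, a few seconds on one CPU) and checks recovery of the
generating slopes within 15%, the slope-drop within ±3 percentage points of
35%, and an ESKOR–G+C correlation below −0.5; a null simulation with equal
trends shows |r| < 0.1 and mean ESKOR within 3 SE of zero. The
segment-contrast check uses 500 genes with thinning confined to blocks above
55% G+C (the equal-variance t-test rejects for highest-G+C segment totals
and not for lowest-G+C); the metagene polarity check uses 300 genes with
positional decay (Spearman trend of the KD/UNT body-bin ratio strongly
negative, flat in the null). The t-test's type-I error is calibrated on
5000 vectorized null replicates. These sizes keep the full suite under a
minute while leaving each check several standard errors of margin.

## Known limitations

* The sliding-window step, flank-bin width and metagene normalization are
  conventions chosen here (non-overlapping tiling, 25 bp, per-kb density);
  other tools make other choices, so bin-level values are comparable only
  within this package.
* ESKOR requires strictly positive FPKM in both conditions; genes with zero
  counts in either library are excluded by the FPKM filter rather than
  rescued with pseudocounts (RNA fold changes, by contrast, use a 0.01
  pseudocount).
* The expression module reports plain log2 FPKM ratios; no
  shrinkage/dispersion modelling is attempted, and no multiple-testing
  correction is applied anywhere because the headline statistics are single
  cohort-level tests.
* The fragment counter's fast path assumes non-overlapping gene spans per
  chromosome (always true for the generator); with overlapping annotation it
  falls back to a per-midpoint scan that is correct but slower.
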