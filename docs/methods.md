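# Methods

## Scope and model

`isomirkit` implements the computational path from raw small-RNA reads to
5'isomiR biology: isomiR classification in the two-offset notation,
collapsing of 3' variants into canonical-vs-5'isomiR groups, reads-per-million
quantification, detection of highly expressed miRNA/5'isomiR pairs,
shifted-seed 3'UTR target scanning with a seed-site enrichment test, a
two-condition downregulation filter with Venn intersection, and
patient-cohort statistics (isoform correlation, clinical group comparisons,
quartile survival analysis). A synthetic-data generator produces every input
with recorded ground truth so each stage can be tested for recovery.

### IsomiR notation and collapsing

A read placed on a precursor is described by two signed offsets relative to
the annotated mature miRNA: `d5 = read_start − mature_start` and
`d3 = read_end − mature_end`, rendered `d5|d3` (e.g. `+1|+2`). Because 3'
heterogeneity is common and believed to be functionally neutral while a 5'
shift moves the seed, all reads of 18–24 nt sharing a miRNA and a 5' offset
are collapsed into one isoform group `(miRNA, d5)`; the group at `d5 = 0` is
the canonical miRNA and `d5 = +1` is the 5'isomiR of interest. The length
window is applied to the read, not to an enumerated `d3` range: for a 21-nt
mature, `+1|+4` (24 nt) is therefore collapsed even though it sits outside
the `+1|-2 … +1|+3` enumeration sometimes used as shorthand for the same
idea — the prose length rule and the enumerated windows disagree at exactly
this edge, and the length rule is the one implemented.

### Quantification pipeline

1. **Adapter trimming** — the longest read suffix that exactly matches a
   prefix of the 3' adapter (≥ 6 nt overlap) is removed. Reads outside
   15–30 nt after trimming are rejected with a recorded reason, never
   silently dropped. This is a deterministic, exactly testable replacement
   for a general-purpose trimmer; it has no quality-aware or
   mismatch-tolerant behaviour.
2. **Mapping** — exact substring matching of the trimmed read against the
   precursor set, sense strand only, zero mismatches (small-RNA libraries
   are stranded, and the annotation-intersected genome mapping used for real
   libraries reduces to precursor-space matching for annotated miRNAs; this
   is a deliberate simplification, and multi-locus families collapse onto
   their precursor entries). Lookups go through a hash index over all
   reference substrings in the read-length window; a sliding-window scan is
   the test oracle.
3. **Offset assignment** — among the precursor's matures, the annotation
   minimising |d5| wins (ties: smaller |d3|, then the 5p arm). Assignments
   with |d5| > 5 are discarded: beyond that distance a read is better
   regarded as an unannotated species than as an isomiR of the mature.
4. **Multi-mapping** — a read whose surviving assignments span n distinct
   miRNA names contributes weight 1/n to each; duplicate precursors of one
   family count once, so families are not double-counted.
5. **rpm** — the per-sample denominator is the total collapsed weight, not
   the raw read count, so per-sample rpm sums to exactly 10⁶ and the matrix
   is self-contained. (Whether published rpm values used total, mapped or
   miRNA-assigned denominators is generally unstated; the assigned-weight
   denominator is the one choice that makes the conservation invariant
   exact.)

### Pair detection and seed scanning

A miRNA qualifies as a highly expressed miRNA/5'isomiR pair when the
canonical group's mean expression across samples is ≥ 100 rpm and the
isomiR:canonical expression ratio is ≥ 0.2 (1:5). The ratio is the ratio of
per-sample means by default — robust when individual samples approach zero —
with the mean-of-per-sample-ratios reading available behind a flag; the
packaged 12-row worked example passes under both readings. Both thresholds
are inclusive ("at least").

The seed is nucleotides 2–8 of the mature sequence, so a +1 5'isomiR's seed
equals positions 3–9 of the canonical mature, and its target site — the
reverse complement of the seed — differs accordingly. UTR scanning reports
every (possibly overlapping) exact 7-mer site occurrence; no 7mer-A1/8mer
distinction and no wobble pairing. Enrichment of site-bearing genes among a
downregulated set is a one-sided Fisher exact test on the 2×2
(downregulated × has-site) table over a background set; this in-repo scan is
an analogue of, not a reproduction of, database-driven target prediction.

### Downregulation filter

A gene is downregulated under a condition when, in every required cell
line, treated/control expression is strictly below 0.65 (at least 35 %
reduction) and the corrected p-value is strictly below 0.05. The correction
method is unstated in the source analysis; Benjamini–Hochberg is the
default (standard for microarray differential expression), Bonferroni is
available. Correction is applied within each (cell line, condition) stratum
across genes. When a table carries replicate expressions instead of
precomputed p-values, per-gene p comes from the same two-tailed unpaired t
test used for the group comparisons. Two-condition results are reported as
a Venn partition (specific-to-A, specific-to-B, shared).

### Cohort statistics

- **Correlation** — Pearson by default on the supplied expression scale,
  with Spearman and a log2(x+1) transform available. The choice matters for
  calibration: on strongly right-skewed (log-normal-like) expression the
  Fisher-z confidence interval is anti-conservative for raw-scale Pearson r
  (measured ~84 % coverage at n = 616, log-sd 0.5), while on the log scale
  it holds its nominal 95 %. Calibration checks therefore run on the log
  scale; headline r values are reported on the raw scale, where the
  estimator is unbiased.
- **Group comparisons** — two-tailed unpaired Student's t test on the
  supplied scale, unknowns dropped, direction of difference reported.
- **Quartile survival** — 'high' and 'low' groups are the upper and lower
  quartiles of an expression vector (median-unbiased quantiles; ties at a
  cut join the group rather than the excluded middle). The two-group
  log-rank statistic is computed in the observed-vs-expected risk-table
  form, vectorised over event times, with the chi-square p on 1 df;
  lifelines' implementation is the independent oracle in tests and supplies
  the Kaplan–Meier curves. When both groups are fully censored the
  statistic is 0 with a warning.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes, not
the technology that produced the real data:

- **Reference** — random precursors (default 80 nt) each embedding one
  mature (20–23 nt, ≥ 5 nt flanks), mutually non-substring and unique across
  the reference, so mapping is unambiguous unless a test plants ambiguity.
- **Reads** — per sample, miRNA abundances are log-normal (default mean-log
  log 100, sd-log 1 — a realistic several-decade spread), offsets are drawn
  from a per-miRNA (d5, d3) probability table, every read is an exact
  precursor substring plus the appended adapter, and optional per-base
  corruption (rate ≤ 0.05) makes reads unmappable under the 0-mismatch
  policy — mimicking how sequencing errors silently vanish from exact-match
  counts (the assigned fraction ≈ (1−e)^length, asserted in tests).
- **DE tables** — planted hits get fold ratios in [0.40, 0.62] and raw p ≤
  10⁻⁶·⁵ in every line (which survives Benjamini–Hochberg at α = 0.05 for
  any table of the sizes used); null genes get ratios in [0.70, 1.30],
  strictly above the 0.65 threshold — so planted Venn counts are recovered
  exactly, by construction.
- **Cohorts** — expressions are bivariate log-normal; the latent normal
  correlation is solved in closed form from the log-normal moment relation
  so the output-scale Pearson correlation hits its target (default 0.85, a
  strong isoform–isoform coupling) without tuning. Default n = 616 patients,
  75 % ER-positive, 10 % metastatic; ER-negative patients get a +0.4
  log-scale shift on both isoforms and metastatic patients the same
  magnitude downward (there is no separate metastasis-effect parameter; a
  zero effect size keeps the correlation target exact, and calibration runs
  use zero). Survival is exponential with median 2000 days; the upper
  expression quartile's hazard is scaled by the configured ratio (default
  0.5, i.e. high expression protective), the middle half geometrically in
  between, and censoring is independent exponential calibrated to the
  configured expected censored fraction (default 0.5).

What the generator does **not** emulate: quality-score structure,
non-templated 3' additions, RNA editing, PCR duplication, array
normalisation artefacts, or the covariate structure of a real clinical
cohort. Passing recovery tests therefore demonstrates the correctness of
the pipeline's logic under its stated model, not robustness to everything
real libraries do.

## Numerical and design choices

- Coordinates are 0-based half-open internally; GFF3 (1-based inclusive) is
  converted only at file boundaries. U and T are interchangeable on input;
  the internal alphabet is DNA, RNA is emitted only in human-facing output.
- All stochastic behaviour lives in the generator behind a single integer
  seed; the pipeline itself is deterministic given inputs, and seeded
  generator runs are byte-identical on disk (gzip written with a zero
  mtime).
- rpm conservation holds to ≤ 10⁻⁶ relative error (a pure floating-point
  sum); equality is by construction of the denominator.
- Degenerate inputs fail loudly: empty libraries name the sample, constant
  vectors make correlation raise, groups smaller than two raise, fully
  censored survival returns a warning rather than a spurious statistic.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run entirely on synthetic data and
the packaged 12-row expression table: quantification recovery at 20 000
reads per sample; oracle agreement on 1000 reads × 50 precursors and 1000
random 500-nt UTRs; correlation recovery over 100 seeded cohorts of 616
patients; log-rank null calibration over 1000 replicates of 200-patient
cohorts; downregulation recovery on 500-gene tables with 30/10/4 planted
hits. These sizes give stable statistics at interactive runtimes.

## Known limitations

- Exact-match mapping to precursors cannot distinguish multi-locus family
  members that share a mature sequence; they receive fractional weights by
  name, not by locus.
- The enrichment test treats "has ≥ 1 seed site" as binary and ignores site
  context, conservation and free energy.
- The quartile convention (median-unbiased, ties to the included side) is
  one of several defensible readings of "upper and lower quartiles"; it is
  configurable.
- Real-deposit loaders (a patient table with deposit-specific headers) are
  supported through an explicit column mapping; no real data ships with the
  package.
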