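# Methods

## The analysis model

`todcourse` treats each condition of a diurnal study as an independent
gene × timepoint intensity matrix sampled on a uniform Zeitgeber-time (ZT)
grid covering at least two full 24 h cycles (default ZT6–ZT54 every 2 h,
25 samples). The analysis proceeds in five stages.

**Normalization.** Each condition is quantile-normalized across its
samples: after normalization every sample's sorted value vector equals the
per-rank mean of the input samples' sorted vectors. Tied values receive
the mean of the reference values at their tied ranks. Note that with ties
this convention makes the "identical sorted columns" identity and strict
idempotence hold only up to the tie blocks; both are exact on tie-free
data. Normalization is deliberately per condition, not joint across
conditions — downstream cross-condition comparisons use phases, which are
scale-free, rather than intensities.

**Expressed gating.** A gene counts as expressed when at least 2
consecutive samples exceed the 20th percentile of the whole matrix (both
knobs are config). The threshold is a pragmatic stand-in for
platform-specific detection flags, which raw public matrices usually lack.
Genes whose input rows needed more than one interpolated missing value are
gated out here as well.

**Rhythmicity and phase.** The model library holds six 24 h-periodic
template shapes — cosine, sharpened cosine (squared raised cosine),
50%-duty box, ≤1 h spike, and rising/falling sawtooth ramps — at every
integer phase offset, evaluated on the ZT grid and standardized to zero
mean/unit variance (144 templates). Analysis is on log2(intensity + 1).
A gene's score is the maximum Pearson correlation over the library;
rhythmic ⇔ R ≥ `r_min` (default 0.8, the empirically established cutoff
for this design class; implemented as ≥ rather than the nominal >, a
distinction that is immaterial in floating point). Phase is the best
template's offset; ties resolve deterministically to the earlier phase,
then shape order. Constant profiles have undefined correlation and are
never rhythmic. One identifiability caveat: on a 2 h grid the sampled
sawtooth at an odd phase is affinely identical to its even-phase
neighbour, so ramp phases are only identifiable to the grid resolution —
the tie-break then yields the earlier hour.

**Summary convention.** Per-condition summaries report not-expressed and
not-rhythmic percentages relative to *all* genes, but the rhythmic
percentage relative to *expressed* genes, each rounded half-up to an
integer. This mixed-denominator convention matches how cycling surveys
print such tables; the three counts always partition the total.

**Phase shifts.** Between two conditions, only genes rhythmic in both are
compared. The primary statistic is the forward circular shift
(φ_target − φ_ref) mod 24 in [0, 24) — required so that asymmetric late
shift classes such as 6–19 h are expressible — with the signed shift in
[−12, 12) as auxiliary. The baseline analysis anchors every condition to
the first developmental stage; the incremental analysis walks consecutive
pairs. The "same phase" fraction uses exact 1 h-bin equality by default
with an optional circular tolerance.

**Element discovery.** For each (condition × phase bin) gene list, every
3–8 bp word (Σ₄ᵏ = 87,360) is tested for promoter *presence*
overrepresentation (once per promoter regardless of copy number; windows
containing N skipped) against the full promoter universe by an upper-tail
hypergeometric test, then BH-adjusted *within the list* across the full
87,360-word family; significance is q < 0.05 in at least one list.
Presence rather than occurrence counts makes the statistic robust to
repeats; counting is forward-strand by default because the canonical
diurnal elements are strand-specific strings (a both-strands flag unions
reverse-complement presence). Significant words are clustered by greedy
single linkage: two words link iff some ungapped offset alignment with
overlap ≥ 3 matches at least min(length) − 1 positions. Members are
aligned to the longest member (lexicographic tie-break) by best offset to
build the position-frequency matrix; for chain-linked members this frame
is a heuristic, as no exact frame exists for single linkage. TOD profiles
report −log10(q) (capped, default 10) per (condition, bin) where
significant, zero elsewhere; clusters take each cell's best member.

**GO enrichment.** Identical hypergeometric + BH machinery per (condition
× phase bin) list, with the universe defaulting to that condition's
expressed genes — enrichment of a phase list should be judged against
genes that could have been phased (an all-genes option exists). The
annotation is used as-is with no ancestor propagation, matching maps
extracted directly from a functional annotation; DAG-aware propagation
would require an ontology file and is out of scope. Summaries count terms
significant at ≥ 1 bin per condition and each term's occurrences per day;
overlap analyses compute the all-condition intersection, sliding-window
(default width 2) intersections in developmental order, and 3-way Venn
cells over named condition groups (group term sets are unions over their
conditions).

**Phase bins.** 24 hourly bins by default. A 23-bin option merges the two
adjacent hourly bins with the smallest combined membership (the merged
list keeps the lower label), mirroring published analyses that report 23
phase lists per time course; with 11 conditions this schedules 253 lists.

**QC.** The sample correlation matrix is computed on log2 values of the
common gene set across all conditions' samples. Classical (Torgerson) MDS
embeds distance 1 − r — not 1 − r², because the sign of correlation is
informative between tissues. Axes are sign-fixed (largest-magnitude
coordinate positive) for determinism; relative stress is reported.

## The synthetic generator

The generator emulates the statistical structure the analysis assumes:
signals are built on log2 intensity and exponentiated, so emitted matrices
are linear like raw array intensities. Defaults describe the emulated
study:

| parameter | default | rationale |
|---|---|---|
| `zt_grid` | ZT6…ZT54, 2 h | two-day, 2-hourly field design |
| `not_expressed_fraction` | 0.17 | matches the published first-stage leaf marginals |
| `cycling_fraction` | 0.57 | fraction of all genes; 0.57/0.83 ≈ 69% of expressed |
| `phase_distribution` | bimodal, modes ZT20/ZT9 | dawn/dusk pile-up (ZT0 = 10:00, sunrise ≈ 05–06 h, sunset ≈ 19 h local) |
| `waveform_mix` | 0.35/0.2/0.15/0.1/0.1/0.1 over the six shapes | cosine-like profiles dominate diurnal transcriptomes, with a tail of sharp and asymmetric shapes |
| `noise_sd` | 0.55 (log2 units) | places the median best-template R of detected genes near 0.9, the intended operating point |
| `baseline_log_mean/sd` | 8 / 1.5 | lognormal-ish microarray intensities |
| `amplitude_log_mean/sd` | 2 / 0.4 (clipped ≥ 0.5) | typical 3–6-fold peak-to-trough cycling |
| `phase_drift` | per condition, constant | emulates seasonal entrainment shift; a per-gene jitter sd is available |

Status counts are applied deterministically by rounding (e.g. 1,000 genes
at cycling fraction 0.6 yields exactly 600 cycling genes); which genes get
which status, and all continuous draws, come from one seeded generator, so
identical seed + config is bitwise-identical. Waveforms are shared with
the detector's library, making recovery well-posed; passing an off-library
mix tests robustness instead. Planted promoter kmers are inserted once at
a random position into a rounded fraction of the genes whose
first-condition phase falls in the target bin; planted GO terms raise
carriage odds in their bin (odds 1 = independence, ∞ = bin-exclusive over
a background carriage probability).

What the generator does **not** emulate: probe effects and saturation,
spatially correlated array artifacts, temperature/photoperiod traces,
gene-gene correlation beyond shared phase, and promoter base composition
(background is uniform ACGT). Passing recovery tests therefore
demonstrate the pipeline's correctness and statistical calibration under
the assumed generative model, not robustness to platform artifacts or
compositional biases of real promoters.

## Numerical choices and degenerate inputs

* Hypergeometric p-values via the exact survival function; BH step-up
  supports a family size larger than the materialized p-vector (absent
  tests sit at p = 1 and cannot change rejections below 1).
* Empty phase lists are scheduled but skipped with a log entry; empty
  inputs yield empty, well-typed results rather than errors wherever the
  operation is total.
* A single missing expression cell per gene is linearly interpolated from
  flanking timepoints; two or more exclude the gene from rhythmicity
  calling (counted as not expressed). Readers reject ragged rows,
  duplicate ids and non-numeric cells by name and line.
* ZT labelling: the first sample is labelled ZT6 by default (sampling
  started 6 h after the nominal set point); a configurable label offset
  reproduces the alternative convention in which the first sample is ZT0.
  All phases are reported mod 24 in label space, so the choice shifts
  labels, never intervals.

## Problem sizes

The test suite and the acceptance script run the generator at 1,000 genes
× 25 timepoints × 3 conditions (drifts 0/+2/+6 h) for recovery checks,
10,000 genes for the pure-noise false-positive experiment, and 11
conditions at reduced gene count for list-scheduling checks — sizes at
which every recovery statistic is stable across seeds while the whole
suite stays fast.

## Known limitations

* The exact model-shape set of the original HAYSTACK-class analyses is
  not recoverable from the literature; the six shapes here are the
  canonical classes, and the set is configurable.
* Cluster counts from the greedy single-linkage motif clustering depend
  on the linkage threshold; reproduction of any particular published
  motif count is not claimed.
* Re-analysis of the original field arrays requires downloading the
  public expression series and exporting tab-delimited matrices; the
  published-settings profile is recorded in
  `todcourse.pipeline.paper_profile()`, but the original expressed-gating
  and model set being unpublished means exact count reproduction is not
  guaranteed.
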