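# Methods

## Data model and coordinate conventions

Internal genomic coordinates are 0-based half-open (BED-native); GTF/GFF3
input is shifted at the I/O boundary and shifted back on write, so a
GTF → internal → GTF round trip reproduces the original 1-based inclusive
coordinates exactly. The transcription start site (TSS) is `start` on the
`+` strand and `end − 1` on the `−` strand. Gene-level records carry their
exon structure (sorted, non-overlapping, contained in the span); introns
are the gaps between consecutive exons. Expression matrices are features ×
samples with tumor/control labels; `scale` distinguishes log2 values from
raw counts. The pipeline keys on whatever feature identifiers the user
supplies and never merges them.

## Normalization and differential expression

*Quantile normalization* maps every sample onto the common target
distribution (the row means of the column-sorted matrix); ties receive the
mean of the target values at their tied ranks. *Size factors* are
median-of-ratios: the per-feature reference is the geometric mean across
samples over features positive everywhere, and each sample's factor is the
median of its count/reference ratios. The pipeline treats log2 input
matrices as already normalised upstream (the usual array-processing
convention, and the scale on which the synthetic generator emits data);
`PipelineConfig.quantile_normalize` re-normalises them when the input is
raw. Re-normalising data that already sit on the normalised scale is not
neutral at small feature counts: a shifted feature near the top of the
value distribution keeps the same rank in both groups and its shift is
erased.

Differential expression uses a Welch t-test by default (pooled-variance
optional via `welch=False`); the log2 fold change is the difference of
group means on the log2 scale and the linear fold change is `2**|Δ|`.
Benjamini–Hochberg FDR is computed across all tested features; each
pipeline stage applies its own threshold block (lncRNA main list:
FC ≥ 1.5, p < 0.05; mRNA: FC ≥ 2.0, p < 0.05; sponge input: FC ≥ 1.5,
FDR < 0.05). Zero-variance features yield p = 1 with a warning. Features
detected (Present/Marginal) in fewer than 7 samples are removed when
detection flags are present; without flags the filter is a warned no-op.

## Positional subtype classification

Exactly one subtype per lncRNA, chosen by precedence (strongest positional
evidence first): same-strand exon overlap → *exon sense overlapping*;
opposite-strand exon overlap → *natural antisense*; span inside an intron,
same strand → *intron sense overlapping*; opposite strand → *intronic
antisense*; opposite strands, disjoint spans, TSS-to-TSS distance ≤ 1,000
bp (inclusive) → *bidirectional*; otherwise *intergenic*. When several
mRNAs qualify at the same precedence the nearest is the partner. The
exon-overlap removal rule flags exon-sense-overlapping lncRNAs whose whole
span is contained in one merged interval of the union of same-strand mRNA
exons — containment in the exonic footprint, not the gene span, because
the motivating concern is probe ambiguity with mRNA signal, which arises
only over exons. Partial overlaps are retained.

Note that flipping the strands of both genes preserves all overlap-based
classes but not *bidirectional*: a divergent pair becomes a convergent one
with distant TSSs, which is correctly no longer bidirectional.

## Co-expression networks

Spearman's ρ with mean-rank ties, p-values from the t approximation on
n − 2 degrees of freedom (|ρ| = 1 maps to p = 0); constant vectors are
skipped with a counter. Correlation runs over tumor samples only by
default (`tumor_only_correlation=False` includes controls). A pair is
*cis* iff both genes share a chromosome and the partner span intersects
the lncRNA span extended by the 500 kb window, boundary inclusive — a
span-to-span gap of exactly 500,000 bp is cis, 500,001 is trans. Cis pairs
are kept at p < 0.05; trans pairs additionally need |ρ| > 0.9. Raw p
(not FDR) is the filter, matching the correlation-screening convention;
an FDR column is emitted for downstream users. Each retained pair records
the regulation quadrant (up_up, down_down, up_down, down_up) from the two
DE directions; quadrants are recorded, not filtered. Pair enumeration is
chunked so the full cross product is never materialised. For
lncRNA–lncRNA mode, self pairs are removed and A–B/B–A duplicates
collapsed to one record with `a_id < b_id` (the quadrant is reoriented
with the swap).

## miRNA host mapping

A host pair is any ≥ 1 bp overlap between a lncRNA span and a miRNA
hairpin interval, same strand by default (a host transcript must encode
the hairpin on its own strand; `require_same_strand=False` reproduces
strand-blind intersection). Hairpin, not mature, coordinates are assumed.
Pairs are kept when host and miRNA move in the same DE direction — the
two calls may come from different assay platforms, so each uses its own
stage thresholds — and annotated with the host–miRNA Spearman correlation
when both matrices share ≥ 4 samples; otherwise the pair is retained on
direction alone.

## Sponge (ceRNA) module inference

The six-filter chain: (1) DE lncRNAs of the sponge input stage; (2)
predicted lncRNA–miRNA pairs with negative correlation; (3) validated
miRNA–mRNA pairs with negative correlation; (4) inner join on the shared
miRNA; (5) all three molecules upregulated and lncRNA–mRNA correlation
positive; (6) lncRNA abundance significantly above mRNA abundance across
tumor samples. Negative/positive correlation filters require p < 0.05 by
default (`sponge_require_corr_p=False` switches to sign-only). The
abundance test is a one-sided Wilcoxon signed-rank on per-sample
(lncRNA − mRNA) log2 differences — a paired nonparametric test is the most
defensible reading of "significantly higher abundance"; a paired t-test is
available via config. Spearman is used throughout this stage for
consistency with the co-expression module. Every filter's attrition count
is recorded; tightening any threshold can only shrink the module set, and
every emitted module satisfies the sign/direction invariants by
construction (violations raise).

## Survival signature

Eligible features belong to an allowed subtype set (default: intergenic
and intron-sense-overlapping, the classes whose quantitation is reliable)
and are detected — value > 0, i.e. at least one read before normalisation
— in ≥ 30% of samples (inclusive). Univariate Cox proportional-hazards
fits (lifelines, Wald p) screen each feature; non-converged fits are
excluded. The top k = 5 features by p-value (|coefficient| breaks ties)
form the signature; the selection criterion is a declared default, not an
inference. The risk score is the coefficient-weighted sum of log2
expression; samples are split at the cohort median, ties going to
low-risk. Kaplan–Meier median survival is the smallest time with estimated
survival ≤ 0.5 (infinite = not reached); group difference is the two-group
log-rank test. The multivariate model fits the continuous score (the
dichotomised group is available) jointly with age, G-CIMP, IDH1 and MGMT;
the score leads the design matrix, so a clinical covariate collinear with
it is the one flagged and the model refit without it.

## Synthetic data generator

The generator emulates the study's inputs, not raw measurements: log2
Gaussian expression (mRNA ~ N(8,1), lncRNA ~ N(6,1), miRNA ~ N(7,1),
unit within-group noise), already on the normalised scale. Its defaults
are the study conditions: 19 tumors / 9 controls (microarray-like preset)
or 150 tumors (RNA-Seq-like), planted log2 effect 2.0 (4-fold), cis
correlation 0.9, sponge coupling β = 0.8, 30% censoring.

* **Geometry.** mRNA genes (2–10 exons of 1 kb, 5 kb introns) sit on
  1.5 Mb slots so that cis relations are controlled by construction;
  lncRNAs are placed to realise every subtype, including boundary cases at
  exactly 1,000 bp TSS distance and span gaps of exactly 500,000 and
  500,001 bp; each planted cis pair gets its own partner mRNA (capped at
  n_mrna − 2), and host miRNAs are embedded inside intergenic lncRNAs on
  the same strand.
* **Cis pairs** share a latent factor: deviations `√ρ·z + √(1−ρ)·ε` give
  Pearson ρ (Spearman ≈ 0.96·ρ for Gaussian data).
* **Sponge chains** couple within-group deviations down the chain with
  slope −β (residual sd √(1−β²)), so miRNA and mRNA can be upregulated
  while the chain correlations are (−, −, +); the sponge lncRNA baseline
  sits +2 log2 units above its mRNA, making the abundance test decisive.
  500 decoy triplets with no engineered correlation are threaded through
  the same interaction tables to measure false positives.
* **Survival** times are exponential with rate ∝ exp(Σ β_f·(x_f − mean)),
  a 5-feature intergenic signature (+0.5 ×4, −0.5 ×1, the protective
  pattern). Censoring is an independent exponential clock whose rate is
  solved (Brent) so the expected censored fraction matches the target; a
  uniform-over-[0, T] clock would be informative censoring and bias the
  Cox fits the generator exists to validate.
* **Determinism.** Each file class uses its own RNG stream seeded from
  `seed` plus a fixed offset; identical seeds give byte-identical files.

What the generator does *not* model: probe-level microarray noise,
count overdispersion beyond the Poisson count mode, correlated null
features, batch effects, or non-proportional hazards. Passing tests
demonstrate that the implementation recovers structure it is pointed at
under clean conditions, not that the thresholds are optimal on real data.

## Numerical conventions and test calibration

* DE power checks plant 4-fold effects at within-group log2 sd 0.5 — the
  typical microarray noise level — and call at BH q < 0.05; at sd 1.0 a
  4-fold effect is a 2σ shift and the expected BH sensitivity at
  n = 10/group is only ~0.8.
* The log-rank power check (HR 2, n = 150, ~20% censoring) is asserted as
  a rejection fraction over 40 replicates at α = 0.01 against the analytic
  power of ≈ 0.89, not as a per-seed guarantee.
* Ties at the risk-score median go to low-risk; `a_id < b_id` breaks
  pair-ordering ties; BH is the only multiple-testing procedure.
* Degenerate inputs: constant expression rows are skipped from
  correlation with a counter; zero-variance DE features get p = 1;
  identical abundance vectors give p = 1; all-censored groups report
  median survival as not reached.

## Known limitations

Transcript-isoform multi-calls, partial correlation, penalized signature
selection, time-dependent covariates, enrichment analysis and
raw-read processing are out of scope. Subtype definitions are operational
(vendor annotation pipelines may differ in their exact geometric rules).
The full-scale pair counts (tens of millions of correlations) are
exercised arithmetically and on scaled-down matrices, not at full scale.
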