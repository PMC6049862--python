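# lncscape

Integrative analysis of the long non-coding RNA (lncRNA) regulatory
landscape in glioblastoma (GBM), packaged as a tested, reusable pipeline.
Starting from expression matrices (tumor vs. control), gene annotation and
miRNA interaction tables, it reconstructs the regulatory roles a lncRNA can
play:

1. **Differential expression** — per-feature two-sample t-test on log2
   expression with fold-change and Benjamini–Hochberg FDR filters
   (plus quantile normalization, median-of-ratios size factors and a
   Present/Marginal detection-flag filter for raw inputs).
2. **Positional subtype classification** — each lncRNA is assigned one of
   six classes relative to protein-coding genes (*intergenic*, *intronic
   antisense*, *intron sense overlapping*, *natural antisense*, *exon sense
   overlapping*, *bidirectional* — divergent transcription with TSS-to-TSS
   distance ≤ 1 kb), and exon-sense-overlapping lncRNAs fully contained in
   same-strand mRNA exons are removed (their array probes cannot separate
   lncRNA from mRNA signal).
3. **Cis/trans co-expression** — sample-wise Spearman correlation of all DE
   lncRNA × DE mRNA (and lncRNA × lncRNA) pairs over tumor samples; a pair
   is *cis* when the partner lies within ±500 kb of the lncRNA span
   (retained at p < 0.05) and *trans* otherwise (retained at p < 0.05 and
   |ρ| > 0.9); lncRNA–lncRNA self pairs are removed and symmetric
   duplicates collapsed.
4. **miRNA host mapping** — interval intersection of lncRNA spans with
   miRNA hairpin coordinates (≥ 1 bp, same strand), keeping concordantly
   regulated host–miRNA pairs.
5. **ceRNA (sponge) module inference** — lncRNA–miRNA–mRNA triplets built
   from predicted lncRNA⊣miRNA and validated miRNA⊣mRNA interactions where
   both correlations are negative, the lncRNA–mRNA correlation is positive,
   all three molecules are upregulated, and the lncRNA is significantly
   more abundant than the mRNA (one-sided paired Wilcoxon) — the conditions
   under which the lncRNA can titrate the shared miRNA away from the mRNA.
6. **Survival signature** — univariate Cox screening of eligible lncRNAs
   (allowed subtypes, detected in ≥ 30% of samples), a per-sample risk
   score

   `score(s) = Σ_i β_i · log2 x_i(s)`

   over the top-k features (k = 5 by default, ranked by Wald p), strict
   median-split stratification into low/high risk, Kaplan–Meier curves with
   the log-rank test, and a multivariate Cox model adjusting the score for
   age, G-CIMP, IDH1 and MGMT status.

A synthetic-data generator (`lncscape.simulate`) emits every input with
known ground truth — planted DE, latent-factor cis pairs, sponge chains,
host-embedded miRNAs and proportional-hazards survival — so each stage is
testable end to end without downloads.

## Worked example

```sh
lncscape simulate --preset tcga-like --seed 7 --out data
lncscape all --data data --out results
```

The second command prints per-stage output counts:

```
{
 "normalize_lnc": 120,
 "normalize_mrna": 80,
 "normalize_mirna": 40,
 "de_lnc": 80,
 "de_mrna": 57,
 "de_mirna": 34,
 "subtypes": 77,
 "coexpression_lnc_mrna": 21,
 "coexpression_lnc_lnc": 0,
 "mirna_hosts": 10,
 "sponge": 20,
 "survival": 5
}
```

Of the 120 simulated lncRNAs, 80 are called differentially expressed; 77
survive the exon-overlap removal; 21 significant lncRNA–mRNA pairs are
found (including the 21 planted cis pairs), all 10 planted host–miRNA
pairs and all 20 planted sponge modules are recovered, and a 5-lncRNA risk
signature is selected. `results/risk_scores.tsv` holds the per-sample
scores and risk groups:

```
sample_id  score    group
T001       9.71129  low
T002       9.04709  low
T003       10.5318  high
```

and `results/run_summary.json` records the stratification: log-rank
p = 6.4e-15 with median survival 24.2 months (low-risk) vs 3.3 months
(high-risk) on this simulated cohort. Every stage also writes its own TSV
(DE tables, subtype calls, correlation pairs, host pairs, sponge modules
with their per-filter attrition JSON, Cox tables).

The same stages are available as library functions
(`lncscape.differential_expression`, `classify_all`, `build_network`,
`intersect_hosts`, `filter_modules`, `risk_score`, …) and as individual
subcommands (`de`, `classify`, `coexpress`, `hosts`, `sponge`,
`survival`).

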